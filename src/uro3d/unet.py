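"""Lightweight trainable encoder–decoder segmenter.

No deep-learning framework is available in this environment, so the
trainable backend is a deliberately small, fully deterministic stand-in for
the encoder–decoder networks used for this task in practice:

* **Encoder** — a Gaussian pyramid: the frame is repeatedly blurred and
  downsampled by 2, producing context maps at successively coarser scales.
* **Decoder with skips** — every pyramid level is bilinearly upsampled back
  to full resolution and concatenated with the native-resolution frame and
  its gradient magnitude, mirroring skip connections that reinject
  fine-scale detail alongside coarse context.
* **Head** — a learned per-pixel softmax over the 4 classes, trained by
  gradient descent on a per-pixel cross-entropy plus soft-Dice loss with
  class-balanced pixel sampling.

The model is linear per pixel given its multi-scale features, so it trains
in seconds on a CPU, is exactly reproducible from its seed, and is honest
about what it is: a pipeline-contract stand-in exercised on synthetic data,
not a reproduction of a clinical-grade network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .seg_metrics import dice

__all__ = ["PyramidSegmenter"]

_N_LEVELS = 4  # pyramid depth (sigma 1 blur + /2 downsample per level)


def _features(frame: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack: frame, gradient magnitude, pyramid levels, radius."""
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    feats = [frame]
    gx, gy = np.gradient(ndimage.gaussian_filter(frame, 1.0))
    feats.append(np.hypot(gx, gy))
    level = frame
    upsampled = []
    for _ in range(_N_LEVELS):
        level = ndimage.gaussian_filter(level, 1.0)[::2, ::2]
        upsampled.append(resize(level, (h, w), order=1, mode="edge", anti_aliasing=False))
    feats.extend(upsampled)
    # difference-of-Gaussian (bandpass) skips: locally bright/dark foci such
    # as fibrosis stand out against their surrounding tissue
    feats.append(upsampled[0] - upsampled[2])
    feats.append(upsampled[1] - upsampled[3])
    # normalised distance from the frame centre: a weak spatial prior that the
    # lumen is central in a sonourethrography sweep
    rr = (np.arange(h) - (h - 1) / 2) / h
    cc = (np.arange(w) - (w - 1) / 2) / w
    feats.append(np.hypot(rr[:, None], cc[None, :]) * np.ones((h, w)))
    return np.stack(feats, axis=-1)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class PyramidSegmenter:
    """Gaussian-pyramid encoder–decoder with a learned softmax head."""

    config: "object" = None  # SegModelConfig
    weights: np.ndarray | None = None  # (n_features + 1, n_classes)
    feat_mean: np.ndarray | None = None
    feat_std: np.ndarray | None = None
    validation_dice: dict = field(default_factory=dict)

    # -- training ---------------------------------------------------------

    def fit(self, frames, masks, val_frames=None, val_masks=None) -> "PyramidSegmenter":
        from .segmentation import SegModelConfig

        if self.config is None:
            self.config = SegModelConfig(backend="unet")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        X, y = self._collect(frames, masks)
        self.feat_mean = X.mean(axis=0)
        self.feat_std = X.std(axis=0) + 1e-8
        Xn = (X - self.feat_mean) / self.feat_std
        Xn = np.concatenate([Xn, np.ones((len(Xn), 1))], axis=1)

        n_feat = Xn.shape[1]
        C = cfg.n_classes
        W = np.zeros((n_feat, C))
        onehot = np.eye(C)[y]

        for epoch in range(cfg.epochs):
            idx = self._balanced_sample(y, rng, per_class=8 * max(cfg.batch_size, 1024))
            rng.shuffle(idx)
            lr = cfg.learning_rate / (1 + epoch)
            for start in range(0, len(idx), cfg.batch_size):
                batch = idx[start : start + cfg.batch_size]
                xb, yb = Xn[batch], onehot[batch]
                p = _softmax(xb @ W)
                # cross-entropy gradient
                g_ce = xb.T @ (p - yb) / len(batch)
                # soft-Dice gradient on the batch
                g_dice = xb.T @ self._soft_dice_grad(p, yb) / len(batch)
                W -= lr * (g_ce + g_dice)
        self.weights = W

        if val_frames is not None and val_masks is not None:
            self.validation_dice = self._validate(val_frames, val_masks)
        return self

    @staticmethod
    def _soft_dice_grad(p: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Gradient (w.r.t. logits, pre-multiplied through softmax) of 1 - mean soft Dice."""
        eps = 1e-8
        P = p.sum(axis=0)
        Y = y.sum(axis=0)
        I = (p * y).sum(axis=0)
        # d(1 - D_c)/dp_ic, averaged over classes
        dldp = -(2 * y * (P + Y) - 2 * I) / ((P + Y) ** 2 + eps) / p.shape[1]
        # backprop through softmax: dL/dz = p * (dL/dp - sum_c dL/dp_c p_c)
        inner = (dldp * p).sum(axis=1, keepdims=True)
        return p * (dldp - inner)

    def _collect(self, frames, masks):
        xs, ys = [], []
        for f, m in zip(frames, masks):
            feats = _features(f)
            xs.append(feats.reshape(-1, feats.shape[-1]))
            ys.append(np.asarray(m).reshape(-1).astype(int))
        return np.concatenate(xs), np.concatenate(ys)

    @staticmethod
    def _balanced_sample(y: np.ndarray, rng, per_class: int) -> np.ndarray:
        picks = []
        for cls in np.unique(y):
            pool = np.flatnonzero(y == cls)
            take = min(per_class, len(pool))
            picks.append(rng.choice(pool, size=take, replace=False))
        return np.concatenate(picks)

    def _validate(self, frames, masks) -> dict:
        from .geometry import CLASS_NAMES

        scores: dict[str, list[float]] = {}
        for f, m in zip(frames, masks):
            pred = self.predict(f)
            m = np.asarray(m).astype(int)
            for cls, name in CLASS_NAMES.items():
                if not (m == cls).any() and not (pred == cls).any():
                    continue
                scores.setdefault(name, []).append(dice(pred == cls, m == cls))
        return {name: float(np.mean(v)) for name, v in scores.items()}

    # -- inference --------------------------------------------------------

    def predict_proba(self, frame: np.ndarray) -> np.ndarray:
        if self.weights is None:
            raise ValueError("model is untrained")
        feats = _features(frame)
        shape = feats.shape[:2]
        X = feats.reshape(-1, feats.shape[-1])
        Xn = (X - self.feat_mean) / self.feat_std
        Xn = np.concatenate([Xn, np.ones((len(Xn), 1))], axis=1)
        p = _softmax(Xn @ self.weights)
        return p.reshape(shape + (p.shape[-1],))

    def predict(self, frame: np.ndarray) -> np.ndarray:
        return self.predict_proba(frame).argmax(axis=-1).astype(np.uint8)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(
            path,
            weights=self.weights,
            feat_mean=self.feat_mean,
            feat_std=self.feat_std,
            seed=self.config.seed,
            epochs=self.config.epochs,
            learning_rate=self.config.learning_rate,
            batch_size=self.config.batch_size,
        )
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "PyramidSegmenter":
        from .segmentation import SegModelConfig

        with np.load(Path(path)) as z:
            cfg = SegModelConfig(
                backend="unet",
                seed=int(z["seed"]),
                epochs=int(z["epochs"]),
                learning_rate=float(z["learning_rate"]),
                batch_size=int(z["batch_size"]),
            )
            return cls(
                config=cfg,
                weights=z["weights"],
                feat_mean=z["feat_mean"],
                feat_std=z["feat_std"],
            )
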