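"""Per-frame 4-class segmentation and dataset preparation.

Two backends share one contract (frame in, 4-class mask out):

* ``classical`` — a deterministic intensity/morphology pipeline built on
  multi-Otsu thresholding.  The fluid-filled lumen is the most central dark
  blob that does not touch the frame border; the corpus spongiosum is the
  band of tissue immediately surrounding it, recovered by geodesic
  reconstruction; bright voxels inside that tissue are marked as fibrosis.
* ``unet`` — a small trainable encoder–decoder (Gaussian-pyramid encoder,
  upsampling decoder with per-scale skip features, learned softmax head) in
  :mod:`uro3d.unet`, exercised only on synthetic data.

Frames are resized to a 256 x 256 grayscale input for either backend and the
predicted mask is resized back to the native frame shape with
nearest-neighbour interpolation so no fractional class codes are created.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.morphology import disk
from skimage.transform import resize

from .geometry import (
    BACKGROUND,
    FIBROSIS,
    LUMEN,
    SPONGIOSUM,
    FrameStack,
    LabelVolume,
)

__all__ = [
    "SplitSpec",
    "SegModelConfig",
    "split_dataset",
    "preprocess_frame",
    "segment_classical",
    "segment_stack",
    "train_unet",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test proportions and the rounding rule.

    Validation and test sizes are ``round(p * n)`` (half away from zero) and
    the training set takes the remainder — the only convention that yields
    442/148/148 from 738 items at 6:2:2.
    """

    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be three positive proportions")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {sum(self.ratios)}")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(
    n_items: int,
    spec: SplitSpec = SplitSpec(),
    seed: int = 0,
    groups=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Randomly partition item indices into train/val/test sets.

    Sizes follow the SplitSpec rounding rule; the assignment is a seeded random
    permutation, so the three sets are disjoint, exhaustive and reproducible.
    With ``groups`` (one id per item, e.g. the subject a frame came from) the
    split is performed over unique group ids so all items of one group land
    in the same set.
    """
    if n_items < 3:
        raise ValueError("need at least 3 items to form three non-empty splits")
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != n_items:
            raise ValueError("groups must have one id per item")
        uniq = np.unique(groups)
        tr_g, va_g, te_g = split_dataset(len(uniq), spec, seed=seed)
        sets = (set(uniq[tr_g]), set(uniq[va_g]), set(uniq[te_g]))
        idx = np.arange(n_items)
        return tuple(
            np.array([i for i in idx if groups[i] in s], dtype=int) for s in sets
        )
    n_val = _round_half_up(spec.ratios[1] * n_items)
    n_test = _round_half_up(spec.ratios[2] * n_items)
    n_train = n_items - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n_items={n_items} too small for ratios {spec.ratios}")
    perm = np.random.default_rng(seed).permutation(n_items)
    train = np.sort(perm[:n_train])
    val = np.sort(perm[n_train : n_train + n_val])
    test = np.sort(perm[n_train + n_val :])
    return train, val, test


@dataclass
class SegModelConfig:
    """Backend selection and hyperparameters.

    ``input_size`` defaults to the network input of 256 x 256 grayscale;
    the training fields apply to the ``unet`` backend only.
    """

    input_size: tuple[int, int] = (256, 256)
    n_classes: int = 4
    backend: str = "classical"
    epochs: int = 5
    learning_rate: float = 0.5
    batch_size: int = 4096
    seed: int = 0
    smooth_sigma: float = 1.0  # pre-threshold denoising blur for the classical backend


def preprocess_frame(
    frame: np.ndarray, size: tuple[int, int] = (256, 256), normalize: bool = True
) -> np.ndarray:
    """Bilinear resize to the network input size and min-max normalise to [0, 1].

    A constant frame maps to all zeros; ``normalize=False`` returns the
    resized intensities untouched.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2D frame, got shape {frame.shape}")
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.shape != tuple(size):
        frame = resize(frame, size, order=1, mode="edge", anti_aliasing=False)
    if not normalize:
        return frame
    lo, hi = frame.min(), frame.max()
    if hi - lo == 0:
        return np.zeros(size, dtype=float)
    return (frame - lo) / (hi - lo)


def _central_nonborder_component(mask: np.ndarray) -> np.ndarray:
    """Largest-score connected component: most central, non-border-touching."""
    lab, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    centre = (np.array(mask.shape) - 1) / 2
    best, best_score = None, None
    for comp in range(1, n + 1):
        comp_mask = lab == comp
        coords = np.argwhere(comp_mask)
        touches_border = (
            (coords[:, 0].min() == 0)
            or (coords[:, 1].min() == 0)
            or (coords[:, 0].max() == mask.shape[0] - 1)
            or (coords[:, 1].max() == mask.shape[1] - 1)
        )
        if touches_border:
            continue
        centroid = coords.mean(axis=0)
        dist = np.linalg.norm((centroid - centre) / np.array(mask.shape))
        score = (-dist, comp_mask.sum())  # central first, size as tie-break
        if best_score is None or score > best_score:
            best, best_score = comp_mask, score
    if best is None:
        return np.zeros_like(mask, dtype=bool)
    return best


def segment_classical(frame: np.ndarray, config: SegModelConfig | None = None) -> np.ndarray:
    """Deterministic 4-class segmentation of one preprocessed frame.

    Multi-Otsu splits the (optionally denoised) frame into dark/mid/bright
    bands.  The lumen is the most central dark component away from the frame
    border; the spongiosum band is whichever band dominates a thin ring
    around the lumen, and the spongiosum region is the geodesic
    reconstruction of that-or-brighter tissue from the ring; brighter voxels
    inside the region become fibrosis; everything else is background.
    Frames with no interior dark component yield no lumen pixels.
    """
    if config is None:
        config = SegModelConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2D frame, got shape {frame.shape}")
    work = (
        ndimage.gaussian_filter(frame, config.smooth_sigma)
        if config.smooth_sigma > 0
        else frame
    )
    out = np.full(frame.shape, BACKGROUND, dtype=np.uint8)
    n_unique = len(np.unique(work))
    if n_unique < 3:
        return out  # no dark/mid/bright structure to exploit
    thresholds = threshold_multiotsu(work, classes=3)
    bands = np.digitize(work, thresholds)  # 0 dark, 1 mid, 2 bright

    lumen = _central_nonborder_component(bands == 0)
    out[lumen] = LUMEN
    if not lumen.any():
        return out

    # sample the wall band in an annulus placed beyond the PSF-blurred
    # lumen-wall transition (a thin ring would sit on transition pixels)
    dist_out = ndimage.distance_transform_edt(~lumen)
    ring = (dist_out >= 6) & (dist_out <= 12)
    if not ring.any():
        ring = ndimage.binary_dilation(lumen, structure=disk(3)) & ~lumen
    if not ring.any():
        return out
    ring_bands = bands[ring]
    spong_band = int(np.bincount(ring_bands, minlength=3).argmax())

    # refine the lumen boundary: the PSF is symmetric, so the true edge lies
    # on the midpoint-intensity contour between lumen and wall medians —
    # Otsu's band cut is generally offset from it and would bias areas
    thr = 0.5 * (np.median(work[lumen]) + np.median(work[ring]))
    refined = _reconstruct(lumen, work <= thr)
    if refined.any():
        coords = np.argwhere(refined)
        touches = (
            coords[:, 0].min() == 0
            or coords[:, 1].min() == 0
            or coords[:, 0].max() == frame.shape[0] - 1
            or coords[:, 1].max() == frame.shape[1] - 1
        )
        if not touches:
            out[lumen] = BACKGROUND
            lumen = refined
            out[lumen] = LUMEN
            dist_out = ndimage.distance_transform_edt(~lumen)
            ring = (dist_out >= 6) & (dist_out <= 12)
            if not ring.any():
                ring = ndimage.binary_dilation(lumen, structure=disk(3)) & ~lumen
    if spong_band == 0:
        return out  # lumen surrounded by dark: no recognisable wall
    tissue = bands >= spong_band
    # geodesic reconstruction of the tissue component attached to the lumen
    seed = ring & tissue
    region = _reconstruct(seed, tissue)
    out[region & (bands == spong_band)] = SPONGIOSUM
    out[region & (bands > spong_band)] = FIBROSIS
    out[lumen] = LUMEN
    return out


def _reconstruct(seed: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Binary geodesic reconstruction (connected component of mask hit by seed)."""
    lab, n = ndimage.label(mask)
    if n == 0 or not seed.any():
        return np.zeros_like(mask, dtype=bool)
    hit = np.unique(lab[seed & mask])
    hit = hit[hit > 0]
    return np.isin(lab, hit)


def _resize_labels(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if mask.shape == tuple(shape):
        return mask
    return resize(
        mask, shape, order=0, preserve_range=True, anti_aliasing=False
    ).astype(np.uint8)


def segment_stack(
    stack: FrameStack,
    model_or_backend="classical",
    config: SegModelConfig | None = None,
) -> LabelVolume:
    """Segment every frame of a stack into a co-registered label volume.

    ``model_or_backend`` is ``"classical"``, a trained model from
    :func:`train_unet`, or ``"unet"`` together with a model in
    ``config`` — anything else is a configuration error.  Each frame is
    preprocessed to the model input size; predicted masks are resized back
    with nearest-neighbour interpolation.
    """
    from .unet import PyramidSegmenter

    if config is None:
        config = SegModelConfig()
    if isinstance(model_or_backend, PyramidSegmenter):
        predict = model_or_backend.predict
    elif model_or_backend == "classical":
        predict = lambda f: segment_classical(f, config)  # noqa: E731
    else:
        raise ValueError(
            f"unknown backend {model_or_backend!r}: pass 'classical' or a trained model"
        )
    if len(stack) == 0:
        raise ValueError("cannot segment an empty stack")
    native_shape = stack.frame_shape
    masks = []
    for frame in stack.frames:
        pre = preprocess_frame(frame, config.input_size)
        masks.append(_resize_labels(predict(pre), native_shape))
    g = stack.geometry
    return LabelVolume(
        labels=np.stack(masks, axis=2),
        voxel_mm=(g.pixel_mm[0], g.pixel_mm[1], g.slice_spacing_mm),
    )


def train_unet(frames, masks, config: SegModelConfig | None = None, val_frames=None, val_masks=None):
    """Train the lightweight encoder–decoder backend on frame/mask pairs.

    Thin wrapper over :class:`uro3d.unet.PyramidSegmenter`; returns the
    trained model, which carries its config, seed and per-class validation
    Dice scores.
    """
    from .unet import PyramidSegmenter

    if config is None:
        config = SegModelConfig(backend="unet")
    if len(frames) == 0:
        raise ValueError("empty training set")
    model = PyramidSegmenter(config)
    model.fit(frames, masks, val_frames=val_frames, val_masks=val_masks)
    return model
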