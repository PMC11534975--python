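"""Synthetic sonourethrography phantom.

Generates ground-truth 4-class label volumes of a straight, fluid-distended
urethra with a configurable stricture and periurethral fibrosis, and renders
them into speckled B-mode-like frame stacks.  This gives every downstream
stage (segmentation, quantification, rendering, statistics) a fully known
truth without any patient data.

The lumen is a tube along the elevational axis whose radius narrows under a
raised-cosine stricture profile::

    r(z) = lumen_radius * (1 - depth * w(z))
    w(z) = 0.5 * (1 + cos(2*pi*(z - center)/length))   for |z - center| <= length/2
    w(z) = 0                                           elsewhere

so ``w`` is 1 at the stricture centre and falls smoothly to 0 at its edges,
making ratio-threshold crossings well defined at sub-slice resolution.

The B-mode forward model is deliberately minimal: per-class mean
echogenicity, an in-plane Gaussian point-spread blur, and fully developed
multiplicative speckle modelled as unit-mean Gamma noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import (
    BACKGROUND,
    FIBROSIS,
    LUMEN,
    SPONGIOSUM,
    AcquisitionGeometry,
    FrameStack,
    LabelVolume,
)

__all__ = [
    "PhantomSpec",
    "generate_labels",
    "simulate_frames",
    "ground_truth_measurement",
    "stricture_radius_profile",
    "analytic_supra_threshold_span_mm",
]

_PATTERNS = ("none", "dotted", "massive")

# Default per-class mean intensities: fluid-filled lumen is anechoic (dark),
# spongiosum mid-echogenic, scar tissue hyperechoic (bright).  The real
# echogenicity of fibrosis is not quantitatively characterised; these values
# are a synthetic convention chosen for class separability.
DEFAULT_ECHOGENICITY = {
    "lumen": 0.05,
    "spongiosum": 0.50,
    "fibrosis": 0.85,
    "background": 0.25,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric ground truth for a synthetic anterior urethra.

    Defaults describe the reference acquisition (35 mm travel, 21 s at
    20 fps, 0.1 mm pixels) around a urethra distended to a 3 mm lumen radius
    with a 14 mm stricture — the scale of the mean stricture length reported
    clinically — narrowing the lumen radius by 70 % at its centre.
    """

    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    frame_shape: tuple[int, int] = (160, 160)
    lumen_radius_mm: float = 3.0
    spongiosum_radius_mm: float = 6.0
    stricture_center_mm: float = 17.5
    stricture_length_mm: float = 14.0
    stricture_depth: float = 0.7
    fibrosis_pattern: str = "dotted"
    fibrosis_fraction: float = 0.15
    echogenicity: dict = field(default_factory=lambda: dict(DEFAULT_ECHOGENICITY))
    speckle_sigma: float = 0.3
    psf_sigma_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lumen_radius_mm < self.spongiosum_radius_mm):
            raise ValueError("require 0 < lumen_radius_mm < spongiosum_radius_mm")
        if not (0 <= self.stricture_depth <= 1):
            raise ValueError("stricture_depth must lie in [0, 1]")
        if self.stricture_length_mm < 0:
            raise ValueError("stricture_length_mm must be non-negative")
        if self.stricture_depth > 0 and self.stricture_length_mm > 0:
            lo = self.stricture_center_mm - self.stricture_length_mm / 2
            hi = self.stricture_center_mm + self.stricture_length_mm / 2
            if lo < 0 or hi > self.geometry.travel_mm:
                raise ValueError(
                    "stricture segment "
                    f"[{lo:.2f}, {hi:.2f}] mm must lie inside the scanned extent "
                    f"[0, {self.geometry.travel_mm}] mm"
                )
        if self.fibrosis_pattern not in _PATTERNS:
            raise ValueError(f"fibrosis_pattern must be one of {_PATTERNS}")
        if not (0 <= self.fibrosis_fraction < 1):
            raise ValueError("fibrosis_fraction must lie in [0, 1)")
        e = self.echogenicity
        if not (e["lumen"] < e["spongiosum"] < e["fibrosis"]):
            raise ValueError("echogenicity must order lumen < spongiosum < fibrosis")
        if self.speckle_sigma < 0 or self.psf_sigma_px < 0:
            raise ValueError("noise and PSF scales must be non-negative")

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "frame_shape": list(self.frame_shape),
            "lumen_radius_mm": self.lumen_radius_mm,
            "spongiosum_radius_mm": self.spongiosum_radius_mm,
            "stricture_center_mm": self.stricture_center_mm,
            "stricture_length_mm": self.stricture_length_mm,
            "stricture_depth": self.stricture_depth,
            "fibrosis_pattern": self.fibrosis_pattern,
            "fibrosis_fraction": self.fibrosis_fraction,
            "echogenicity": dict(self.echogenicity),
            "speckle_sigma": self.speckle_sigma,
            "psf_sigma_px": self.psf_sigma_px,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "geometry" in d:
            d["geometry"] = AcquisitionGeometry.from_dict(d["geometry"])
        if "frame_shape" in d:
            d["frame_shape"] = tuple(int(v) for v in d["frame_shape"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def stricture_radius_profile(spec: PhantomSpec, z_mm: np.ndarray) -> np.ndarray:
    """Lumen radius r(z) under the raised-cosine stricture window."""
    z = np.asarray(z_mm, dtype=float)
    w = np.zeros_like(z)
    if spec.stricture_length_mm > 0:
        u = z - spec.stricture_center_mm
        inside = np.abs(u) <= spec.stricture_length_mm / 2
        w[inside] = 0.5 * (1 + np.cos(2 * np.pi * u[inside] / spec.stricture_length_mm))
    return spec.lumen_radius_mm * (1 - spec.stricture_depth * w)


def analytic_supra_threshold_span_mm(spec: PhantomSpec, threshold_pct: float) -> float:
    """Closed-form span of z where the area-based stricture ratio >= threshold.

    Assumes the reference area equals the unstrictured lumen area, so the
    ratio at z is ``(1 - (r(z)/r0)^2) * 100``.  Inverting the raised-cosine
    window gives the physical width of the supra-threshold segment.
    """
    if spec.stricture_depth == 0 or spec.stricture_length_mm == 0:
        return 0.0
    w_star = (1 - np.sqrt(1 - threshold_pct / 100.0)) / spec.stricture_depth
    if w_star > 1:
        return 0.0
    if w_star <= 0:
        return spec.stricture_length_mm
    return spec.stricture_length_mm / np.pi * np.arccos(2 * w_star - 1)


def _grid(spec: PhantomSpec):
    rows, cols = spec.frame_shape
    g = spec.geometry
    rr = (np.arange(rows) - (rows - 1) / 2) * g.pixel_mm[0]
    cc = (np.arange(cols) - (cols - 1) / 2) * g.pixel_mm[1]
    zz = g.slice_positions_mm()
    return rr, cc, zz


def generate_labels(spec: PhantomSpec) -> LabelVolume:
    """Rasterise the phantom into a 4-class label volume.

    Deterministic given ``spec.seed`` (the seed controls only the random
    fibrosis placement).
    """
    rr, cc, zz = _grid(spec)
    g = spec.geometry
    r2 = rr[:, None] ** 2 + cc[None, :] ** 2  # in-plane squared distance, mm^2
    radius_z = stricture_radius_profile(spec, zz)

    labels = np.zeros((len(rr), len(cc), len(zz)), dtype=np.uint8)
    spong_mask2d = r2 <= spec.spongiosum_radius_mm**2
    for k, rk in enumerate(radius_z):
        sl = np.where(spong_mask2d, SPONGIOSUM, BACKGROUND).astype(np.uint8)
        sl[r2 <= rk**2] = LUMEN
        labels[:, :, k] = sl

    if spec.fibrosis_pattern != "none" and spec.fibrosis_fraction > 0:
        _add_fibrosis(labels, spec, rr, cc, zz)

    return LabelVolume(
        labels=labels,
        voxel_mm=(g.pixel_mm[0], g.pixel_mm[1], g.slice_spacing_mm),
    )


def _stricture_zone(spec: PhantomSpec, zz: np.ndarray) -> np.ndarray:
    if spec.stricture_length_mm == 0:
        # degenerate: place fibrosis around the centre slice
        return np.abs(zz - spec.stricture_center_mm) <= 2 * spec.geometry.slice_spacing_mm
    return np.abs(zz - spec.stricture_center_mm) <= spec.stricture_length_mm / 2


def _add_fibrosis(labels, spec, rr, cc, zz) -> None:
    rng = np.random.default_rng([spec.seed, 0])
    zone = _stricture_zone(spec, zz)
    spong = labels == SPONGIOSUM
    spong_zone = spong & zone[None, None, :]
    n_target = int(round(spec.fibrosis_fraction * spong_zone.sum()))
    if n_target == 0:
        return
    coords = np.argwhere(spong_zone)

    if spec.fibrosis_pattern == "massive":
        # single contiguous blob: ellipsoidal sub-level set grown to the target
        # fraction by taking the exact quantile of the ellipsoidal distance
        centre_idx = coords[rng.integers(len(coords))]
        x0 = rr[centre_idx[0]]
        y0 = cc[centre_idx[1]]
        z0 = zz[centre_idx[2]]
        half_len = max(spec.stricture_length_mm / 2, spec.geometry.slice_spacing_mm)
        ax = max(spec.spongiosum_radius_mm - spec.lumen_radius_mm, 1e-6)
        e = (
            ((rr[:, None, None] - x0) / ax) ** 2
            + ((cc[None, :, None] - y0) / ax) ** 2
            + ((zz[None, None, :] - z0) / half_len) ** 2
        )
        vals = e[spong_zone]
        cutoff = np.quantile(vals, spec.fibrosis_fraction)
        blob = (e <= cutoff) & spong_zone
        labels[blob] = FIBROSIS
        return

    # dotted: small spheres at Poisson-disc-like centres until the target
    # voxel fraction is reached
    vr, vc = spec.geometry.pixel_mm
    vs = spec.geometry.slice_spacing_mm
    placed_centres: list[np.ndarray] = []
    n_marked = 0
    order = rng.permutation(len(coords))
    min_sep_mm = 1.2  # centre-to-centre exclusion radius
    for idx in order:
        if n_marked >= n_target:
            break
        ci = coords[idx]
        pos = np.array([rr[ci[0]], cc[ci[1]], zz[ci[2]]])
        if any(np.linalg.norm(pos - p) < min_sep_mm for p in placed_centres):
            continue
        radius_vox = rng.integers(2, 5)  # spheres of 2-4 voxel radius
        # sphere in voxel units around ci, bounded box for speed
        rad = int(radius_vox)
        sl = tuple(
            slice(max(ci[d] - rad, 0), min(ci[d] + rad + 1, labels.shape[d]))
            for d in range(3)
        )
        ii, jj, kk = np.meshgrid(
            np.arange(sl[0].start, sl[0].stop),
            np.arange(sl[1].start, sl[1].stop),
            np.arange(sl[2].start, sl[2].stop),
            indexing="ij",
        )
        d2 = (ii - ci[0]) ** 2 + (jj - ci[1]) ** 2 + (kk - ci[2]) ** 2
        sphere = d2 <= radius_vox**2
        target_box = labels[sl]
        eligible = sphere & (target_box == SPONGIOSUM) & zone[None, None, sl[2]]
        target_box[eligible] = FIBROSIS
        labels[sl] = target_box
        n_marked += int(eligible.sum())
        placed_centres.append(pos)


def simulate_frames(labels: LabelVolume, spec: PhantomSpec) -> FrameStack:
    """Render labels into a speckled B-mode-like frame stack.

    Per-voxel intensity is the class echogenicity, blurred in-plane by a
    Gaussian PSF of ``psf_sigma_px`` pixels, then multiplied by i.i.d.
    unit-mean Gamma speckle with shape ``1/speckle_sigma**2`` and clipped to
    [0, 1].  Deterministic given ``spec.seed``.
    """
    e = spec.echogenicity
    lut = np.array([e["background"], e["lumen"], e["spongiosum"], e["fibrosis"]])
    intensity = lut[labels.labels]
    if spec.psf_sigma_px > 0:
        intensity = ndimage.gaussian_filter(
            intensity, sigma=(spec.psf_sigma_px, spec.psf_sigma_px, 0.0)
        )
    if spec.speckle_sigma > 0:
        rng = np.random.default_rng([spec.seed, 1])
        shape = 1.0 / spec.speckle_sigma**2
        speckle = rng.gamma(shape, 1.0 / shape, size=intensity.shape)
        intensity = intensity * speckle
    intensity = np.clip(intensity, 0.0, 1.0)
    frames = [intensity[:, :, k] for k in range(intensity.shape[2])]
    return FrameStack(frames=frames, geometry=spec.geometry)


def ground_truth_measurement(
    labels: LabelVolume,
    threshold_pct: float = 50.0,
    reference_method: str = "p90",
):
    """Stricture measurement on perfect labels — the recovery target.

    Runs the same curve/length logic the pipeline applies to predicted
    labels, so measured-vs-truth comparisons isolate segmentation error.
    """
    from .quantify import measure_stricture_length, stricture_ratio_curve

    curve = stricture_ratio_curve(labels, reference_method=reference_method)
    return measure_stricture_length(curve, threshold_pct=threshold_pct)
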