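"""Stricture quantification from a 4-class label volume.

Per slice k the lumen cross-sectional area is the lumen voxel count times the
in-plane pixel area.  The stricture ratio compares each slice with a
reference lumen area::

    ratio(k) = (reference_area - area_k) / reference_area * 100   (clipped at 0)

Plotting the ratio against elevational position gives the stricture curve;
the longest contiguous supra-threshold run of slices gives the stricture
extent, and its slice count times the slice spacing gives the stricture
length in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import LUMEN, LabelVolume

__all__ = [
    "StrictureCurve",
    "StrictureMeasurement",
    "lumen_area_per_slice",
    "reference_area",
    "stricture_ratio",
    "stricture_ratio_curve",
    "measure_stricture_length",
]

REFERENCE_METHODS = ("p90", "median", "max")


@dataclass
class StrictureCurve:
    """Per-slice lumen area and stricture ratio along the elevational axis."""

    z_mm: np.ndarray
    lumen_area_mm2: np.ndarray
    ratio_pct: np.ndarray
    reference_area_mm2: float
    slice_spacing_mm: float

    def __post_init__(self) -> None:
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.lumen_area_mm2 = np.asarray(self.lumen_area_mm2, dtype=float)
        self.ratio_pct = np.asarray(self.ratio_pct, dtype=float)
        n = len(self.z_mm)
        if not (len(self.lumen_area_mm2) == len(self.ratio_pct) == n):
            raise ValueError("curve arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.z_mm) > 0):
            raise ValueError("z_mm must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slice": np.arange(len(self.z_mm)),
                "z_mm": self.z_mm,
                "lumen_area_mm2": self.lumen_area_mm2,
                "ratio_pct": self.ratio_pct,
            }
        )


@dataclass
class StrictureMeasurement:
    """Detected stricture extent and physical length.

    ``extent`` is the inclusive (first, last) slice-index pair of the longest
    contiguous run with ratio >= threshold, or ``None`` when no slice
    qualifies.  ``runs`` lists every supra-threshold run as secondary
    findings for multifocal curves.
    """

    length_mm: float
    extent: tuple[int, int] | None
    max_ratio_pct: float
    threshold_pct: float
    reference_area_mm2: float
    runs: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "length_mm": self.length_mm,
            "extent": list(self.extent) if self.extent is not None else None,
            "max_ratio_pct": self.max_ratio_pct,
            "threshold_pct": self.threshold_pct,
            "reference_area_mm2": self.reference_area_mm2,
            "runs": [list(r) for r in self.runs],
        }


def lumen_area_per_slice(labels: LabelVolume) -> np.ndarray:
    """Lumen cross-sectional area per slice: voxel count x pixel area (mm^2)."""
    counts = (labels.labels == LUMEN).sum(axis=(0, 1))
    pixel_area = labels.voxel_mm[0] * labels.voxel_mm[1]
    return counts.astype(float) * pixel_area


def reference_area(areas: np.ndarray, method: str = "p90") -> float:
    """Reference urethral lumen area from the per-slice areas.

    The default is the 90th percentile of the per-slice areas, which tracks
    the healthy calibre as long as the stricture occupies roughly the lower
    decile of the scan; ``median`` and ``max`` are available, and a plain
    number may be passed to fix the reference explicitly.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0 or not np.any(areas > 0):
        raise ValueError("degenerate anatomy: no slice has a positive lumen area")
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        if method <= 0:
            raise ValueError("fixed reference area must be positive")
        return float(method)
    if method == "p90":
        return float(np.percentile(areas, 90))
    if method == "median":
        return float(np.median(areas))
    if method == "max":
        return float(areas.max())
    raise ValueError(f"unknown reference method {method!r}; expected {REFERENCE_METHODS} or a number")


def stricture_ratio(reference_area_mm2: float, area_mm2) -> np.ndarray | float:
    """The stricture ratio (%): (reference - area) / reference * 100, floored at 0."""
    if reference_area_mm2 <= 0:
        raise ValueError("reference area must be positive")
    ratio = (reference_area_mm2 - np.asarray(area_mm2, dtype=float)) / reference_area_mm2 * 100.0
    return np.clip(ratio, 0.0, 100.0)


def stricture_ratio_curve(
    labels: LabelVolume, reference_method: str | float = "p90"
) -> StrictureCurve:
    """Compute the stricture curve of a label volume."""
    areas = lumen_area_per_slice(labels)
    ref = reference_area(areas, reference_method)
    ratios = stricture_ratio(ref, areas)
    spacing = labels.voxel_mm[2]
    z = np.arange(labels.shape[2]) * spacing
    return StrictureCurve(
        z_mm=z,
        lumen_area_mm2=areas,
        ratio_pct=ratios,
        reference_area_mm2=ref,
        slice_spacing_mm=spacing,
    )


def _runs_at_or_above(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def measure_stricture_length(
    curve: StrictureCurve, threshold_pct: float = 50.0
) -> StrictureMeasurement:
    """Detect the stricture and measure its physical length.

    The detected extent is the longest contiguous run of slices whose ratio
    meets or exceeds the threshold (earliest run wins ties); its length is
    the run's slice count times the slice spacing.  A curve with no
    qualifying slice yields length 0 and an empty extent.
    """
    if not (0 < threshold_pct < 100):
        raise ValueError("threshold_pct must lie strictly between 0 and 100")
    mask = curve.ratio_pct >= threshold_pct
    runs = _runs_at_or_above(mask)
    if not runs:
        return StrictureMeasurement(
            length_mm=0.0,
            extent=None,
            max_ratio_pct=float(curve.ratio_pct.max(initial=0.0)),
            threshold_pct=threshold_pct,
            reference_area_mm2=curve.reference_area_mm2,
            runs=[],
        )
    longest = max(runs, key=lambda r: r[1] - r[0])
    n_slices = longest[1] - longest[0] + 1
    return StrictureMeasurement(
        length_mm=n_slices * curve.slice_spacing_mm,
        extent=longest,
        max_ratio_pct=float(curve.ratio_pct.max()),
        threshold_pct=threshold_pct,
        reference_area_mm2=curve.reference_area_mm2,
        runs=runs,
    )
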