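"""Segmentation evaluation: per-class Dice coefficient and HD95.

Dice measures volumetric overlap, ``2|A∩B| / (|A|+|B|)``.  HD95 is the 95th
percentile of the boundary-to-boundary nearest-neighbour distances and is
the conventional outlier-robust variant of the Hausdorff distance.

Conventions pinned here because implementations differ:

* HD95 pools the two directed nearest-neighbour distance sets (A→B and B→A)
  and takes a single percentile of the pooled set — the symmetric form used
  by most medical-imaging toolkits — rather than the max of two directed
  percentiles.
* The percentile uses linear interpolation between order statistics.
* Boundary voxels are mask voxels 4-adjacent (2D) / 6-adjacent (3D) to a
  non-mask voxel; voxels on the array edge count as boundary.
* Empty masks make HD95 undefined (reported as NaN, never 0), so empty
  predictions are not silently rewarded; two empty masks have Dice 1 by the
  perfect-agreement convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import CLASS_NAMES, LabelVolume

__all__ = ["dice", "hd95", "boundary_mask", "evaluate_segmentation"]


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks.

    Two empty masks agree perfectly and return 1.0.
    """
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(true_mask, dtype=bool)
    _check_shapes(a, b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Mask voxels orthogonally adjacent to a non-mask voxel (or the array edge)."""
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def hd95(
    pred_mask: np.ndarray,
    true_mask: np.ndarray,
    spacing=None,
    percentile: float = 95.0,
) -> float:
    """95th-percentile symmetric Hausdorff distance between two binary masks.

    Parameters
    ----------
    spacing:
        Physical size per axis; distances are Euclidean in the scaled
        coordinates.  Defaults to unit (pixel) spacing.
    """
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(true_mask, dtype=bool)
    _check_shapes(a, b)
    if not a.any() or not b.any():
        raise ValueError("HD95 is undefined for an empty mask")
    if spacing is None:
        spacing = np.ones(a.ndim)
    spacing = np.asarray(spacing, dtype=float)
    pa = np.argwhere(boundary_mask(a)) * spacing
    pb = np.argwhere(boundary_mask(b)) * spacing
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    pooled = np.concatenate([d_ab, d_ba])
    return float(np.percentile(pooled, percentile))


def evaluate_segmentation(
    pred: LabelVolume,
    truth: LabelVolume,
    classes=(1, 2, 3),
) -> pd.DataFrame:
    """Per-class Dice and HD95 for a predicted-vs-truth label pair.

    Returns one row per requested class plus a ``mean`` row over the
    foreground classes; a class absent from the truth (or an empty
    prediction) gets NaN HD95, and NaN Dice when absent from both is
    impossible by the Dice convention.  HD95 is reported both in voxel units
    and in mm using the shared voxel size.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if not np.allclose(pred.voxel_mm, truth.voxel_mm):
        raise ValueError("pred and truth voxel sizes differ")
    rows = []
    for cls in classes:
        p = pred.labels == cls
        t = truth.labels == cls
        row = {
            "class": int(cls),
            "name": CLASS_NAMES.get(int(cls), str(cls)),
            "present_in_truth": bool(t.any()),
            "dice": dice(p, t),
        }
        try:
            row["hd95_px"] = hd95(p, t)
            row["hd95_mm"] = hd95(p, t, spacing=truth.voxel_mm)
        except ValueError:
            row["hd95_px"] = np.nan
            row["hd95_mm"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {
        "class": -1,
        "name": "mean",
        "present_in_truth": True,
        "dice": df["dice"].mean(),
        "hd95_px": df["hd95_px"].mean(),
        "hd95_mm": df["hd95_mm"].mean(),
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
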