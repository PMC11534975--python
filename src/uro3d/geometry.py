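"""Acquisition geometry, volume assembly and multiplanar reformation.

The scanner translates a linear-array probe along the urethra (the
*elevational* axis) while recording 2D B-mode frames at a fixed rate, so the
elevational slice spacing is fully determined by three numbers: probe travel
distance, scan duration and frame rate.  Frames are stacked, in acquisition
order, into an anisotropic voxel grid whose third axis is the elevational
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BACKGROUND",
    "LUMEN",
    "SPONGIOSUM",
    "FIBROSIS",
    "CLASS_NAMES",
    "AcquisitionGeometry",
    "FrameStack",
    "Volume",
    "LabelVolume",
    "compute_frame_count",
    "compute_slice_spacing",
    "assemble_volume",
    "disassemble_volume",
    "extract_plane",
]

# Fixed 4-class label codes used across the whole toolkit.
BACKGROUND = 0  # all other tissue
LUMEN = 1  # fluid-filled urethral lumen
SPONGIOSUM = 2  # corpus spongiosum
FIBROSIS = 3  # periurethral fibrosis (spongiofibrosis)

CLASS_NAMES = {
    BACKGROUND: "background",
    LUMEN: "lumen",
    SPONGIOSUM: "spongiosum",
    FIBROSIS: "fibrosis",
}


def compute_frame_count(scan_time_s: float, frame_rate_hz: float) -> int:
    """Number of frames acquired in ``scan_time_s`` seconds at ``frame_rate_hz``.

    Rounds half away from zero so that a non-integer product still yields a
    well-defined count; the reference acquisition (21 s at 20 Hz) is exact and
    gives 420 frames.
    """
    if scan_time_s <= 0 or frame_rate_hz <= 0:
        raise ValueError(
            f"scan_time_s and frame_rate_hz must be positive, got "
            f"{scan_time_s!r}, {frame_rate_hz!r}"
        )
    product = scan_time_s * frame_rate_hz
    count = int(np.floor(product + 0.5))  # round half away from zero (positive args)
    return max(count, 1)


def compute_slice_spacing(travel_mm: float, frame_count: int) -> float:
    """Elevational sampling interval: probe travel divided by frame count.

    35 mm of travel over 420 frames gives 0.0833 mm between slice planes.
    """
    if travel_mm <= 0:
        raise ValueError(f"travel_mm must be positive, got {travel_mm!r}")
    if frame_count < 1:
        raise ValueError(f"frame_count must be >= 1, got {frame_count!r}")
    return travel_mm / frame_count


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Motor kinematics and pixel calibration of one linear sweep.

    Parameters
    ----------
    travel_mm:
        Total probe translation along the elevational axis, mm.
    scan_time_s:
        Acquisition duration, s.
    frame_rate_hz:
        Frame rate, Hz.
    pixel_mm:
        In-plane pixel size as ``(row_mm, col_mm)``.
    """

    travel_mm: float = 35.0
    scan_time_s: float = 21.0
    frame_rate_hz: float = 20.0
    pixel_mm: tuple[float, float] = (0.1, 0.1)

    def __post_init__(self) -> None:
        for name in ("travel_mm", "scan_time_s", "frame_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if len(self.pixel_mm) != 2 or any(p <= 0 for p in self.pixel_mm):
            raise ValueError("pixel_mm must be two strictly positive sizes (row, col)")

    @property
    def frame_count(self) -> int:
        return compute_frame_count(self.scan_time_s, self.frame_rate_hz)

    @property
    def slice_spacing_mm(self) -> float:
        return compute_slice_spacing(self.travel_mm, self.frame_count)

    def slice_positions_mm(self) -> np.ndarray:
        """Voxel-centre elevational positions z_k = k * spacing."""
        return np.arange(self.frame_count) * self.slice_spacing_mm

    def to_dict(self) -> dict:
        return {
            "travel_mm": self.travel_mm,
            "scan_time_s": self.scan_time_s,
            "frame_rate_hz": self.frame_rate_hz,
            "pixel_mm": list(self.pixel_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(
            travel_mm=float(d["travel_mm"]),
            scan_time_s=float(d["scan_time_s"]),
            frame_rate_hz=float(d["frame_rate_hz"]),
            pixel_mm=tuple(float(p) for p in d["pixel_mm"]),
        )


@dataclass
class FrameStack:
    """Ordered grayscale frames plus the geometry that produced them.

    Frame ``k`` sits at elevational position ``k * slice_spacing_mm``; values
    are floating intensities in [0, 1].
    """

    frames: list[np.ndarray] = field(default_factory=list)
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        if self.frames:
            shape = self.frames[0].shape
            for k, f in enumerate(self.frames):
                if f.ndim != 2:
                    raise ValueError(f"frame {k} is not 2D (shape {f.shape})")
                if f.shape != shape:
                    raise ValueError(
                        f"frame {k} shape {f.shape} differs from frame 0 shape {shape}"
                    )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        if not self.frames:
            raise ValueError("empty stack has no frame shape")
        return self.frames[0].shape


@dataclass
class Volume:
    """3D intensity grid ``(rows, cols, slices)`` with physical voxel sizes."""

    voxels: np.ndarray
    voxel_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be three strictly positive sizes")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelVolume:
    """3D integer label grid using the fixed 4-class codes (0..3)."""

    labels: np.ndarray
    voxel_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.array_equal(rounded, self.labels):
                raise ValueError("labels must be integer class codes")
            self.labels = rounded.astype(np.uint8)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 3):
            raise ValueError("label codes must lie in {0, 1, 2, 3}")
        self.labels = self.labels.astype(np.uint8)
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be three strictly positive sizes")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def assemble_volume(stack: FrameStack) -> Volume:
    """Stack ordered frames into a Volume; frame k becomes ``voxels[:, :, k]``."""
    if len(stack) == 0:
        raise ValueError("cannot assemble a volume from an empty stack")
    voxels = np.stack(stack.frames, axis=2)
    g = stack.geometry
    return Volume(voxels=voxels, voxel_mm=(g.pixel_mm[0], g.pixel_mm[1], g.slice_spacing_mm))


def disassemble_volume(volume: Volume, geometry: AcquisitionGeometry | None = None) -> FrameStack:
    """Inverse of :func:`assemble_volume`; returns the original frames."""
    frames = [volume.voxels[:, :, k].copy() for k in range(volume.shape[2])]
    if geometry is None:
        # synthesize a geometry consistent with the volume's spacing
        geometry = AcquisitionGeometry(
            travel_mm=volume.voxel_mm[2] * volume.shape[2],
            scan_time_s=float(volume.shape[2]),
            frame_rate_hz=1.0,
            pixel_mm=(volume.voxel_mm[0], volume.voxel_mm[1]),
        )
    return FrameStack(frames=frames, geometry=geometry)


_ORIENTATIONS = ("axial", "sagittal", "coronal")


def extract_plane(
    volume: Volume | LabelVolume, orientation: str, index: int
) -> tuple[np.ndarray, tuple[float, float]]:
    """Axis-aligned multiplanar reformation.

    ``axial`` is the acquisition plane (``voxels[:, :, k]``); ``sagittal`` is
    the plane containing the elevational axis and the row axis
    (``voxels[:, j, :]``); ``coronal`` contains the elevational axis and the
    column axis (``voxels[i, :, :]``).  Returns the 2D image and its physical
    pixel sizes ``(row_mm, col_mm)`` of the returned image, which are
    anisotropic for the reformatted planes.
    """
    arr = volume.voxels if isinstance(volume, Volume) else volume.labels
    vr, vc, vs = volume.voxel_mm
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}")
    axis = {"axial": 2, "sagittal": 1, "coronal": 0}[orientation]
    if not (0 <= index < arr.shape[axis]):
        raise IndexError(
            f"{orientation} index {index} out of range [0, {arr.shape[axis]})"
        )
    if orientation == "axial":
        return arr[:, :, index].copy(), (vr, vc)
    if orientation == "sagittal":
        return arr[:, index, :].copy(), (vr, vs)
    return arr[index, :, :].copy(), (vc, vs)
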