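"""Reading and writing volumes (NIfTI) and frame stacks (TIFF/PNG + JSON sidecar).

Intensities live in [0, 1] in memory.  Integer storage maps the full dtype
range onto [0, 1] (``v / 65535`` for uint16), so a write/read round-trip is
exact on the integer grid; floating NIfTI storage round-trips to 1e-6 or
better.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .geometry import AcquisitionGeometry, FrameStack, LabelVolume, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_label_volume",
    "write_label_volume",
    "read_stack",
    "write_stack",
    "read_geometry",
    "write_geometry",
]

GEOMETRY_SIDECAR = "geometry.json"


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii") or path.name.endswith(".nii.gz")


def _nifti_affine(voxel_mm) -> np.ndarray:
    return np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write an intensity volume as float32 NIfTI; zooms carry voxel_mm."""
    path = Path(path)
    if not _is_nifti(path):
        raise ValueError(f"unsupported volume format: {path.name} (expected .nii/.nii.gz)")
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), _nifti_affine(volume.voxel_mm))
    img.header.set_zooms(volume.voxel_mm)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> Volume:
    path = Path(path)
    if not _is_nifti(path):
        raise ValueError(f"unsupported volume format: {path.name} (expected .nii/.nii.gz)")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(voxels=data, voxel_mm=zooms)


def write_label_volume(labels: LabelVolume, path: str | Path) -> Path:
    """Write a 4-class label volume as uint8 NIfTI."""
    path = Path(path)
    if not _is_nifti(path):
        raise ValueError(f"unsupported label format: {path.name} (expected .nii/.nii.gz)")
    img = nib.Nifti1Image(labels.labels.astype(np.uint8), _nifti_affine(labels.voxel_mm))
    img.header.set_zooms(labels.voxel_mm)
    nib.save(img, str(path))
    return path


def read_label_volume(path: str | Path) -> LabelVolume:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(labels=np.rint(data).astype(np.uint8), voxel_mm=zooms)


def write_geometry(geometry: AcquisitionGeometry, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(geometry.to_dict(), indent=2))
    return path


def read_geometry(path: str | Path) -> AcquisitionGeometry:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"geometry sidecar not found: {path}")
    return AcquisitionGeometry.from_dict(json.loads(path.read_text()))


def _to_uint16(frame: np.ndarray) -> np.ndarray:
    return np.rint(np.clip(frame, 0.0, 1.0) * 65535.0).astype(np.uint16)


def _from_int(arr: np.ndarray) -> np.ndarray:
    info = np.iinfo(arr.dtype)
    return arr.astype(float) / float(info.max)


def write_stack(
    stack: FrameStack,
    path_or_dir: str | Path,
    fmt: str = "tiff",
) -> Path:
    """Write a frame stack as uint16 multipage TIFF or numbered uint16 PNGs.

    The acquisition geometry goes to a ``geometry.json`` sidecar next to the
    stack (inside the directory for PNG series).
    """
    path = Path(path_or_dir)
    pages = np.stack([_to_uint16(f) for f in stack.frames], axis=0)
    if fmt == "tiff":
        if path.suffix.lower() not in (".tif", ".tiff"):
            path = path.with_suffix(".tiff")
        tifffile.imwrite(str(path), pages, photometric="minisblack")
        write_geometry(stack.geometry, path.parent / GEOMETRY_SIDECAR)
        return path
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(len(stack) - 1)))
        for k, page in enumerate(pages):
            iio.imwrite(path / f"frame_{k:0{width}d}.png", page)
        write_geometry(stack.geometry, path / GEOMETRY_SIDECAR)
        return path
    raise ValueError(f"unsupported stack format {fmt!r} (expected 'tiff' or 'png')")


_FRAME_RE = re.compile(r"(\d+)")


def _numeric_key(p: Path) -> tuple:
    m = _FRAME_RE.findall(p.stem)
    return (int(m[-1]) if m else 0, p.name)


def read_stack(path_or_dir: str | Path, geometry: AcquisitionGeometry | None = None) -> FrameStack:
    """Read a multipage TIFF or a directory of PNG/TIFF frames into a FrameStack.

    Integer pixel values are mapped to [0, 1] by full dtype range.  Geometry
    comes from the ``geometry.json`` sidecar unless given explicitly.
    """
    path = Path(path_or_dir)
    if path.is_dir():
        files = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")],
            key=_numeric_key,
        )
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in {path}")
        frames = [np.asarray(iio.imread(p)) for p in files]
        sidecar = path / GEOMETRY_SIDECAR
    elif path.suffix.lower() in (".tif", ".tiff"):
        pages = tifffile.imread(str(path))
        if pages.ndim == 2:
            pages = pages[None]
        frames = list(pages)
        sidecar = path.parent / GEOMETRY_SIDECAR
    else:
        raise ValueError(f"unsupported stack input: {path}")
    converted = []
    for f in frames:
        if f.ndim == 3:  # RGB(A) PNG — collapse identical channels
            f = f[..., 0]
        if np.issubdtype(f.dtype, np.integer):
            converted.append(_from_int(f))
        else:
            converted.append(np.asarray(f, dtype=float))
    if geometry is None:
        if not sidecar.exists():
            raise FileNotFoundError(
                f"missing geometry sidecar {sidecar}; pass geometry explicitly"
            )
        geometry = read_geometry(sidecar)
    return FrameStack(frames=converted, geometry=geometry)
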