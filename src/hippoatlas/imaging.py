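"""Volumetric data model, NIfTI I/O, binary masks and elementary volumetry.

All in-memory math is voxel-grid based: arrays are indexed ``[x, y, z]`` with
0-based indices, the NIfTI affine is carried along as opaque placement
metadata. Voxel spacing is in millimetres.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .atlas import VOISpec

__all__ = [
    "Volume3D",
    "BinaryMask",
    "ScoreMap",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "volume_of",
    "dice",
]


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclasses.dataclass
class Volume3D:
    """A 3-D scalar grid with voxel spacing (mm) and affine placement metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        if np.isnan(self.data).any():
            raise ValueError("volume contains NaN")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy_with(self, data: np.ndarray) -> "Volume3D":
        return Volume3D(np.asarray(data, dtype=np.float32), self.spacing, self.affine)


@dataclasses.dataclass
class BinaryMask:
    """A {0,1} label grid sharing shape and spacing with the volume it labels."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.data = arr.astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclasses.dataclass
class ScoreMap:
    """Classification scores in [0,1] on the voxel grid of one VOI."""

    data: np.ndarray
    voi: "VOISpec"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise ValueError("scores must lie in [0,1]")


def read_volume(path: str | Path) -> Volume3D:
    """Read a 3-D NIfTI image.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for a
    non-3-D image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D image, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asarray(data, dtype=np.float32), spacing, np.asarray(img.affine))


def write_volume(v: Volume3D, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), v.affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI label image, binarizing at > 0.5.

    The threshold tolerates interpolated / warped label images.
    """
    v = read_volume(path)
    return BinaryMask((v.data > 0.5).astype(np.uint8), v.spacing, v.affine)


def write_mask(m: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(m.data.astype(np.uint8), m.affine)
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))


def volume_of(mask: BinaryMask) -> float:
    """Mask volume in mm³: 1-voxel count times the voxel volume."""
    voxel_mm3 = float(np.prod(mask.spacing))
    return float(mask.data.sum()) * voxel_mm3


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks count as identical (1.0)."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na = int(a.data.sum())
    nb = int(b.data.sum())
    if na + nb == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)
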