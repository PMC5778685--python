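"""Peri-hippocampal VOI definition and optimal-atlas ranking.

The VOI is built from the warped training masks: the voxelwise label
probability map is thresholded at zero support and its bounding box, padded
and clipped to the template grid, becomes the common volume of interest.
Atlases are ranked by Pearson correlation between VOI intensity vectors.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .imaging import BinaryMask, Volume3D

__all__ = [
    "VOISpec",
    "AtlasRanking",
    "voi_probability_map",
    "define_voi",
    "extract_voi",
    "pearson_r",
    "rank_atlases",
]


@dataclasses.dataclass
class VOISpec:
    """Per-axis inclusive index ranges in template space."""

    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]
    side: str = "left"
    padding: int = 0

    def __post_init__(self) -> None:
        for rng in (self.x, self.y, self.z):
            if rng[0] > rng[1] or rng[0] < 0:
                raise ValueError(f"invalid VOI range {rng}")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (
            self.x[1] - self.x[0] + 1,
            self.y[1] - self.y[0] + 1,
            self.z[1] - self.z[0] + 1,
        )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def slices(self) -> tuple[slice, slice, slice]:
        return (
            slice(self.x[0], self.x[1] + 1),
            slice(self.y[0], self.y[1] + 1),
            slice(self.z[0], self.z[1] + 1),
        )

    def crop(self, data: np.ndarray) -> np.ndarray:
        if (
            self.x[1] >= data.shape[0]
            or self.y[1] >= data.shape[1]
            or self.z[1] >= data.shape[2]
        ):
            raise ValueError("VOI exceeds image bounds")
        return data[self.slices()]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_json(cls, path: str | Path) -> "VOISpec":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["x"]), tuple(d["y"]), tuple(d["z"]), d["side"], d["padding"])


@dataclasses.dataclass
class AtlasRanking:
    """Atlases ordered by correlation with the test scan, top-m selected."""

    ranked: list[tuple[str, float]]
    m: int

    def __post_init__(self) -> None:
        rs = [r for _, r in self.ranked]
        if any(r < -1 - 1e-12 or r > 1 + 1e-12 for r in rs):
            raise ValueError("correlations must lie in [-1, 1]")
        if any(rs[i] < rs[i + 1] - 1e-12 for i in range(len(rs) - 1)):
            raise ValueError("ranking must be sorted non-increasing")
        if self.m > len(self.ranked):
            raise ValueError("selected count exceeds available atlases")

    @property
    def selected(self) -> list[tuple[str, float]]:
        return self.ranked[: self.m]


def voi_probability_map(warped_masks: list[BinaryMask]) -> Volume3D:
    """Voxelwise mean of the warped training masks (label probability)."""
    if not warped_masks:
        raise ValueError("at least one mask is required")
    shape = warped_masks[0].shape
    for m in warped_masks:
        if m.shape != shape:
            raise ValueError("all masks must share a common shape")
    prob = np.mean([m.data.astype(np.float64) for m in warped_masks], axis=0)
    return Volume3D(prob.astype(np.float32), warped_masks[0].spacing, warped_masks[0].affine)


def define_voi(prob: Volume3D, padding: int = 2, side: str = "left") -> VOISpec:
    """Bounding box of strictly positive probability, padded and clipped.

    Guarantees the hippocampi of all contributing warped masks are contained
    within the VOI.
    """
    support = np.argwhere(prob.data > 0)
    if support.size == 0:
        raise ValueError("probability map has no positive support")
    lo = support.min(axis=0) - padding
    hi = support.max(axis=0) + padding
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(prob.shape) - 1)
    return VOISpec(
        (int(lo[0]), int(hi[0])),
        (int(lo[1]), int(hi[1])),
        (int(lo[2]), int(hi[2])),
        side=side,
        padding=padding,
    )


def extract_voi(v: Volume3D, voi: VOISpec) -> np.ndarray:
    """VOI intensities as a vector in fixed raster order (x fastest, then y, then z)."""
    return voi.crop(np.asarray(v.data)).ravel(order="F").astype(np.float64)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between two equally long intensity vectors.

    Computed in the one-pass product-moment form
    ``(N Σxy − Σx Σy) / sqrt[(N Σx² − (Σx)²)(N Σy² − (Σy)²)]``.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples")
    sx, sy = x.sum(), y.sum()
    sxx = float(x @ x)
    syy = float(y @ y)
    sxy = float(x @ y)
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        raise ValueError("correlation undefined for a constant vector")
    r = (n * sxy - sx * sy) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def rank_atlases(
    test_voi: np.ndarray,
    atlas_vois: dict[str, np.ndarray] | list[np.ndarray],
    m: int = 10,
) -> AtlasRanking:
    """Rank atlases by correlation with the test VOI; select the top m.

    Ties keep input order (stable sort); ``m`` is clipped to the number of
    available atlases. The default of 10 selected atlases follows the
    algorithm's published configuration.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if isinstance(atlas_vois, dict):
        items = list(atlas_vois.items())
    else:
        items = [(str(i), v) for i, v in enumerate(atlas_vois)]
    if not items:
        raise ValueError("empty atlas list")
    scored = [(aid, pearson_r(v, test_voi)) for aid, v in items]
    order = sorted(range(len(scored)), key=lambda i: -scored[i][1])
    ranked = [scored[i] for i in order]
    return AtlasRanking(ranked, min(m, len(ranked)))
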