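"""Voxel-wise statistical and textural features inside the VOI.

Three families are computed for every VOI voxel:

* central-moment statistics (mean, sd, skewness, excess kurtosis) on cubic
  neighbourhoods of configurable odd edge (default 3–9 voxels), with mirror
  padding at the VOI boundary;
* Haralick texture features from a symmetric gray-level co-occurrence matrix
  (GLCM) over the 13 unique 3-D unit offsets, quantized to equal-width bins
  spanning the whole-VOI intensity range, averaged over offsets;
* Haar-like box responses (three half-box differences plus
  center-minus-surround) evaluated in O(1) via an integral volume, with
  boundary boxes clipped and normalized by their actual voxel counts.

Feature rows are emitted in the same raster order as VOI extraction
(x fastest, then y, then z), which keeps voxel indices aligned across the
pipeline.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .atlas import VOISpec
from .imaging import Volume3D

__all__ = [
    "FeatureConfig",
    "FeatureScaler",
    "IntegralVolume",
    "build_integral",
    "moment_features",
    "haralick_features",
    "haar_features",
    "assemble_features",
]

# the 13 unique unit offsets of a 3-D 26-neighbourhood (one per +/- pair)
OFFSETS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

HARALICK_NAMES = ("energy", "contrast", "correlation", "homogeneity", "entropy")
HAAR_NAMES = ("lr", "ap", "si", "cs")
MOMENT_NAMES = ("mean", "sd", "skew", "kurt")


@dataclasses.dataclass
class FeatureConfig:
    moment_sizes: tuple[int, ...] = (3, 5, 7, 9)
    haralick_box: int = 5
    haralick_levels: int = 8
    haar_sizes: tuple[int, ...] = (3, 5, 7, 9)

    def __post_init__(self) -> None:
        for s in tuple(self.moment_sizes) + tuple(self.haar_sizes) + (self.haralick_box,):
            if s % 2 == 0 or s < 1:
                raise ValueError(f"box sizes must be odd and positive, got {s}")
        if self.haralick_levels < 2:
            raise ValueError("need at least 2 gray levels")

    def schema(self) -> list[str]:
        names: list[str] = []
        for s in self.moment_sizes:
            names += [f"moment_{m}_{s}" for m in MOMENT_NAMES]
        names += [f"haralick_{h}_{self.haralick_box}" for h in HARALICK_NAMES]
        for s in self.haar_sizes:
            names += [f"haar_{h}_{s}" for h in HAAR_NAMES]
        return names


# ---------------------------------------------------------------------------
# integral volume


class IntegralVolume:
    """3-D cumulative-sum grid answering axis-aligned box sums in O(1)."""

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError("expected a 3-D grid")
        self.shape = data.shape
        tab = np.zeros(tuple(n + 1 for n in data.shape), dtype=np.float64)
        tab[1:, 1:, 1:] = data.cumsum(0).cumsum(1).cumsum(2)
        self._tab = tab

    def box_sum(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """Sum over the inclusive box [lo, hi]; lo/hi have shape (..., 3).

        Bounds must already lie within the grid (empty boxes with
        lo > hi are allowed and return 0).
        """
        lo = np.asarray(lo, dtype=np.intp)
        hi = np.asarray(hi, dtype=np.intp)
        empty = (hi < lo).any(axis=-1)
        hi = np.maximum(hi, lo - 1)
        x0, y0, z0 = lo[..., 0], lo[..., 1], lo[..., 2]
        x1, y1, z1 = hi[..., 0] + 1, hi[..., 1] + 1, hi[..., 2] + 1
        t = self._tab
        s = (
            t[x1, y1, z1]
            - t[x0, y1, z1]
            - t[x1, y0, z1]
            - t[x1, y1, z0]
            + t[x0, y0, z1]
            + t[x0, y1, z0]
            + t[x1, y0, z0]
            - t[x0, y0, z0]
        )
        return np.where(empty, 0.0, s)


def build_integral(v: Volume3D | np.ndarray) -> IntegralVolume:
    data = v.data if isinstance(v, Volume3D) else v
    return IntegralVolume(data)


# ---------------------------------------------------------------------------
# moments


def _moment_maps(data: np.ndarray, size: int) -> np.ndarray:
    """Mean / sd / skewness / excess kurtosis maps for one cubic box size.

    Population moments; zero-variance neighbourhoods return 0 for the two
    standardized moments.
    """
    d = data.astype(np.float64)
    e1 = ndimage.uniform_filter(d, size, mode="mirror")
    e2 = ndimage.uniform_filter(d * d, size, mode="mirror")
    e3 = ndimage.uniform_filter(d**3, size, mode="mirror")
    e4 = ndimage.uniform_filter(d**4, size, mode="mirror")
    mu2 = np.maximum(e2 - e1 * e1, 0.0)
    mu3 = e3 - 3 * e1 * e2 + 2 * e1**3
    mu4 = e4 - 4 * e1 * e3 + 6 * e1 * e1 * e2 - 3 * e1**4
    sd = np.sqrt(mu2)
    ok = mu2 > 1e-18
    skew = np.zeros_like(d)
    kurt = np.zeros_like(d)
    np.divide(mu3, mu2**1.5, out=skew, where=ok)
    np.divide(mu4, mu2**2, out=kurt, where=ok)
    kurt[ok] -= 3.0
    kurt[~ok] = 0.0
    return np.stack([e1, sd, skew, kurt])


def moment_features(
    v: Volume3D | np.ndarray,
    voxel: tuple[int, int, int],
    sizes: tuple[int, ...] = (3, 5, 7, 9),
) -> np.ndarray:
    """Central-moment statistics of the cubic neighbourhoods of one voxel."""
    data = np.asarray(v.data if isinstance(v, Volume3D) else v, dtype=np.float64)
    _check_voxel(data, voxel)
    out = []
    for size in sizes:
        if size % 2 == 0:
            raise ValueError("box size must be odd")
        r = size // 2
        padded = np.pad(data, r, mode="reflect")
        patch = padded[
            voxel[0] : voxel[0] + size,
            voxel[1] : voxel[1] + size,
            voxel[2] : voxel[2] + size,
        ].ravel()
        mu = patch.mean()
        mu2 = ((patch - mu) ** 2).mean()
        if mu2 > 1e-18:
            sd = np.sqrt(mu2)
            skew = ((patch - mu) ** 3).mean() / mu2**1.5
            kurt = ((patch - mu) ** 4).mean() / mu2**2 - 3.0
        else:
            sd, skew, kurt = 0.0, 0.0, 0.0
        out += [mu, sd, skew, kurt]
    return np.asarray(out, dtype=np.float64)


def _check_voxel(data: np.ndarray, voxel: tuple[int, int, int]) -> None:
    if any(not (0 <= voxel[i] < data.shape[i]) for i in range(3)):
        raise ValueError(f"voxel {voxel} outside the VOI grid {data.shape}")


# ---------------------------------------------------------------------------
# Haralick


def quantize(data: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization over the whole-VOI intensity range."""
    d = np.asarray(data, dtype=np.float64)
    lo, hi = float(d.min()), float(d.max())
    if hi - lo <= 0:
        return np.zeros(d.shape, dtype=np.intp)
    q = np.floor((d - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def _glcm_features_from_counts(counts: np.ndarray, levels: int) -> np.ndarray:
    """Five features from a (levels, levels) symmetric co-occurrence count."""
    total = counts.sum()
    if total <= 0:
        return np.zeros(5)
    p = counts / total
    a = np.arange(levels, dtype=np.float64)
    diff2 = (a[:, None] - a[None, :]) ** 2
    energy = float((p**2).sum())
    contrast = float((p * diff2).sum())
    homogeneity = float((p / (1.0 + diff2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    marg = p.sum(axis=1)
    mu = float((a * marg).sum())
    var = float(((a - mu) ** 2 * marg).sum())
    if var > 1e-18:
        correlation = float(((a[:, None] * a[None, :] * p).sum() - mu * mu) / var)
    else:
        correlation = 0.0
    return np.array([energy, contrast, correlation, homogeneity, entropy])


def haralick_features(
    v: Volume3D | np.ndarray,
    voxel: tuple[int, int, int],
    box: int = 5,
    levels: int = 8,
    offsets: tuple[tuple[int, int, int], ...] = OFFSETS_13,
) -> np.ndarray:
    """GLCM texture features of one voxel's local patch.

    The patch (odd edge `box`) is clipped at the VOI boundary; a symmetric
    GLCM is built per offset from pairs whose two endpoints both fall inside
    the clipped patch, and the five features are averaged over offsets that
    produce at least one pair.
    """
    data = np.asarray(v.data if isinstance(v, Volume3D) else v, dtype=np.float64)
    _check_voxel(data, voxel)
    if box % 2 == 0:
        raise ValueError("box size must be odd")
    q = quantize(data, levels)
    r = box // 2
    lo = [max(voxel[i] - r, 0) for i in range(3)]
    hi = [min(voxel[i] + r, data.shape[i] - 1) for i in range(3)]
    patch = q[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    feats = np.zeros(5)
    n_used = 0
    for d in offsets:
        src = patch[
            max(0, -d[0]) : patch.shape[0] - max(0, d[0]),
            max(0, -d[1]) : patch.shape[1] - max(0, d[1]),
            max(0, -d[2]) : patch.shape[2] - max(0, d[2]),
        ]
        dst = patch[
            max(0, d[0]) : patch.shape[0] - max(0, -d[0]),
            max(0, d[1]) : patch.shape[1] - max(0, -d[1]),
            max(0, d[2]) : patch.shape[2] - max(0, -d[2]),
        ]
        if src.size == 0:
            continue
        counts = np.zeros((levels, levels), dtype=np.float64)
        np.add.at(counts, (src.ravel(), dst.ravel()), 1.0)
        counts = counts + counts.T  # symmetric GLCM
        feats += _glcm_features_from_counts(counts, levels)
        n_used += 1
    if n_used == 0:
        raise ValueError("patch too small for any co-occurrence pair")
    return feats / n_used


def _haralick_maps(data: np.ndarray, box: int, levels: int) -> np.ndarray:
    """Vectorized per-voxel GLCM features for the whole grid.

    For each offset the per-voxel pair count of a level pair (a, b) is a box
    sum of the indicator image [q(s)=a and q(s+d)=b] over a window derived
    from the clipped patch, evaluated with integral volumes.
    """
    q = quantize(data, levels)
    shape = data.shape
    r = box // 2
    vx, vy, vz = np.meshgrid(*(np.arange(n, dtype=np.intp) for n in shape), indexing="ij")
    centers = np.stack([vx, vy, vz], axis=-1)
    patch_lo = np.maximum(centers - r, 0)
    patch_hi = np.minimum(centers + r, np.asarray(shape) - 1)

    a_idx = np.arange(levels, dtype=np.float64)
    diff2 = (a_idx[:, None] - a_idx[None, :]) ** 2
    inv_diff2 = 1.0 / (1.0 + diff2)
    prod_ab = a_idx[:, None] * a_idx[None, :]

    feat_sum = np.zeros((5,) + shape, dtype=np.float64)
    used = np.zeros(shape, dtype=np.float64)

    for d in OFFSETS_13:
        dvec = np.asarray(d, dtype=np.intp)
        # src window such that src and src+d are both inside the clipped patch
        lo = patch_lo + np.maximum(0, -dvec)
        hi = patch_hi - np.maximum(0, dvec)
        # pair indicator volumes on the src grid
        src_sl = tuple(slice(max(0, -d[i]), shape[i] - max(0, d[i])) for i in range(3))
        dst_sl = tuple(slice(max(0, d[i]), shape[i] - max(0, -d[i])) for i in range(3))
        a_vol = np.full(shape, -1, dtype=np.intp)
        b_vol = np.full(shape, -1, dtype=np.intp)
        a_vol[src_sl] = q[src_sl]
        b_vol[src_sl] = q[dst_sl]

        counts = np.zeros((levels, levels) + shape, dtype=np.float64)
        for a in range(levels):
            for b in range(levels):
                ind = ((a_vol == a) & (b_vol == b)).astype(np.float64)
                if not ind.any():
                    continue
                iv = IntegralVolume(ind)
                counts[a, b] = iv.box_sum(lo, hi).reshape(shape)
        counts = counts + counts.transpose(1, 0, 2, 3, 4)
        total = counts.sum(axis=(0, 1))
        ok = total > 0
        p = np.zeros_like(counts)
        np.divide(counts, total, out=p, where=ok)

        energy = (p**2).sum(axis=(0, 1))
        contrast = (p * diff2[..., None, None, None]).sum(axis=(0, 1))
        homo = (p * inv_diff2[..., None, None, None]).sum(axis=(0, 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
        entropy = -(p * logp).sum(axis=(0, 1))
        marg = p.sum(axis=1)
        mu = (a_idx[:, None, None, None] * marg).sum(axis=0)
        var = ((a_idx[:, None, None, None] - mu) ** 2 * marg).sum(axis=0)
        corr_num = (p * prod_ab[..., None, None, None]).sum(axis=(0, 1)) - mu * mu
        corr = np.zeros(shape)
        np.divide(corr_num, var, out=corr, where=var > 1e-18)

        for i, f in enumerate((energy, contrast, corr, homo, entropy)):
            feat_sum[i][ok] += f[ok]
        used += ok

    out = np.zeros_like(feat_sum)
    np.divide(feat_sum, used, out=out, where=used > 0)
    return out


# ---------------------------------------------------------------------------
# Haar-like


def _clipped_box_mean(
    iv: IntegralVolume, lo: np.ndarray, hi: np.ndarray, shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean, count, sum) of the box [lo, hi] clipped to the grid."""
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, np.asarray(shape) - 1)
    sums = iv.box_sum(lo_c, hi_c)
    counts = np.prod(np.maximum(hi_c - lo_c + 1, 0), axis=-1).astype(np.float64)
    out = np.zeros_like(sums)
    np.divide(sums, counts, out=out, where=counts > 0)
    return out, counts, sums


def _haar_maps(data: np.ndarray, sizes: tuple[int, ...]) -> np.ndarray:
    shape = data.shape
    iv = IntegralVolume(data)
    vx, vy, vz = np.meshgrid(*(np.arange(n, dtype=np.intp) for n in shape), indexing="ij")
    centers = np.stack([vx, vy, vz], axis=-1)
    maps = []
    for size in sizes:
        r = size // 2
        lo = centers - r
        hi = centers + r
        for axis in range(3):  # left-right, anterior-posterior, superior-inferior
            lo_a, hi_a = lo.copy(), hi.copy()
            hi_a[..., axis] = centers[..., axis] - 1
            m1, c1, s1 = _clipped_box_mean(iv, lo_a, hi_a, shape)
            lo_b, hi_b = lo.copy(), hi.copy()
            lo_b[..., axis] = centers[..., axis] + 1
            m2, c2, s2 = _clipped_box_mean(iv, lo_b, hi_b, shape)
            maps.append(m1 - m2)
        # center minus surround
        rc = r - 1
        lo_c = centers - rc
        hi_c = centers + rc
        mc, cc, sc = _clipped_box_mean(iv, lo_c, hi_c, shape)
        mb, cb, sb = _clipped_box_mean(iv, lo, hi, shape)
        surr_cnt = cb - cc
        surr = np.zeros_like(mb)
        np.divide(sb - sc, surr_cnt, out=surr, where=surr_cnt > 0)
        maps.append(mc - surr)
    return np.stack(maps).reshape((len(sizes) * 4,) + shape)


def haar_features(
    iv: IntegralVolume | Volume3D | np.ndarray,
    voxel: tuple[int, int, int],
    sizes: tuple[int, ...] = (3, 5, 7, 9),
) -> np.ndarray:
    """Haar-like box responses for one voxel.

    Per size: three half-box mean differences (along x, y, z; the centre
    plane is excluded) and centre-minus-surround. Boundary boxes are clipped
    and normalized by the voxels actually covered.
    """
    if isinstance(iv, IntegralVolume):
        integral = iv
        shape = iv.shape
    else:
        data = iv.data if isinstance(iv, Volume3D) else np.asarray(iv)
        integral = IntegralVolume(data)
        shape = data.shape
    _check_voxel(np.empty(shape), voxel)
    center = np.asarray(voxel, dtype=np.intp)
    out = []
    for size in sizes:
        if size % 2 == 0:
            raise ValueError("box size must be odd")
        r = size // 2
        lo, hi = center - r, center + r
        for axis in range(3):
            lo_a, hi_a = lo.copy(), hi.copy()
            hi_a[axis] = center[axis] - 1
            m1, _, _ = _clipped_box_mean(integral, lo_a, hi_a, shape)
            lo_b, hi_b = lo.copy(), hi.copy()
            lo_b[axis] = center[axis] + 1
            m2, _, _ = _clipped_box_mean(integral, lo_b, hi_b, shape)
            out.append(float(m1 - m2))
        rc = r - 1
        mc, cc, sc = _clipped_box_mean(integral, center - rc, center + rc, shape)
        mb, cb, sb = _clipped_box_mean(integral, lo, hi, shape)
        surr_cnt = float(cb - cc)
        surr = float((sb - sc) / surr_cnt) if surr_cnt > 0 else 0.0
        out.append(float(mc) - surr)
    return np.asarray(out, dtype=np.float64)


# ---------------------------------------------------------------------------
# assembly and scaling


def assemble_features(
    v: Volume3D,
    voi: VOISpec,
    config: FeatureConfig | None = None,
    scaler: "FeatureScaler | None" = None,
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix with one row per VOI voxel in raster order.

    Raw features unless a fitted :class:`FeatureScaler` (training-set
    statistics) is supplied, in which case columns are z-scored and
    zero-variance columns dropped according to the scaler's schema.
    """
    config = config or FeatureConfig()
    data = voi.crop(np.asarray(v.data, dtype=np.float64))
    maps = []
    for size in config.moment_sizes:
        maps.append(_moment_maps(data, size))
    maps.append(_haralick_maps(data, config.haralick_box, config.haralick_levels))
    maps.append(_haar_maps(data, config.haar_sizes))
    stack = np.concatenate(maps, axis=0)
    matrix = np.stack([m.ravel(order="F") for m in stack], axis=1)
    schema = config.schema()
    if scaler is not None:
        matrix = scaler.transform(matrix)
        schema = list(scaler.schema)
    return matrix, schema


class FeatureScaler:
    """Column z-scoring with statistics accumulated from training VOIs only.

    Zero-variance columns are dropped (with a warning) and recorded in the
    schema so downstream models see a consistent layout.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None
        self.keep_: np.ndarray | None = None
        self.schema: list[str] = []
        self.dropped: list[str] = []

    def fit(self, matrices: list[np.ndarray], schema: list[str]) -> "FeatureScaler":
        stacked = np.concatenate(matrices, axis=0)
        mean = stacked.mean(axis=0)
        sd = stacked.std(axis=0)
        keep = sd > 1e-12
        if not keep.all():
            self.dropped = [n for n, k in zip(schema, keep) if not k]
            warnings.warn(
                f"dropping zero-variance feature columns: {self.dropped}",
                RuntimeWarning,
                stacklevel=2,
            )
        self.mean_, self.sd_, self.keep_ = mean, sd, keep
        self.schema = [n for n, k in zip(schema, keep) if k]
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        m = (matrix - self.mean_) / np.where(self.keep_, self.sd_, 1.0)
        return m[:, self.keep_]

    def to_dict(self) -> dict:
        return {
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "keep": self.keep_.astype(int).tolist(),
            "schema": self.schema,
            "dropped": self.dropped,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        sc = cls()
        sc.mean_ = np.asarray(d["mean"], dtype=np.float64)
        sc.sd_ = np.asarray(d["sd"], dtype=np.float64)
        sc.keep_ = np.asarray(d["keep"], dtype=bool)
        sc.schema = list(d["schema"])
        sc.dropped = list(d["dropped"])
        return sc
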