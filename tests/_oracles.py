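"""Independent brute-force oracles used to pin down the numeric operations.

Everything here is written as plain loops over definitions, deliberately
ignoring the vectorized implementations under test.
"""

from __future__ import annotations

import numpy as np

OFFSETS_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


def box_sum_brute(data: np.ndarray, lo, hi) -> float:
    total = 0.0
    for x in range(lo[0], hi[0] + 1):
        for y in range(lo[1], hi[1] + 1):
            for z in range(lo[2], hi[2] + 1):
                total += data[x, y, z]
    return total


def moments_brute(data: np.ndarray, voxel, size: int) -> list[float]:
    """Mean, population sd, skewness, excess kurtosis on a mirror-padded patch."""
    r = size // 2
    padded = np.pad(data, r, mode="reflect")
    vals = []
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                vals.append(padded[voxel[0] + r + dx, voxel[1] + r + dy, voxel[2] + r + dz])
    vals = np.asarray(vals, dtype=float)
    mu = vals.mean()
    mu2 = ((vals - mu) ** 2).mean()
    if mu2 <= 1e-18:
        return [mu, 0.0, 0.0, 0.0]
    return [
        mu,
        float(np.sqrt(mu2)),
        float(((vals - mu) ** 3).mean() / mu2**1.5),
        float(((vals - mu) ** 4).mean() / mu2**2 - 3.0),
    ]


def quantize_brute(data: np.ndarray, levels: int) -> np.ndarray:
    lo, hi = data.min(), data.max()
    if hi - lo <= 0:
        return np.zeros(data.shape, dtype=int)
    q = np.floor((data - lo) / (hi - lo) * levels).astype(int)
    q[q == levels] = levels - 1
    return q


def haralick_brute(data: np.ndarray, voxel, box: int, levels: int) -> np.ndarray:
    """Five GLCM features: energy, contrast, correlation, homogeneity, entropy.

    Symmetric GLCM per offset over pairs with both endpoints inside the
    clipped patch; features averaged over offsets with at least one pair.
    """
    q = quantize_brute(np.asarray(data, dtype=float), levels)
    r = box // 2
    shape = data.shape
    lo = [max(voxel[i] - r, 0) for i in range(3)]
    hi = [min(voxel[i] + r, shape[i] - 1) for i in range(3)]
    feats = np.zeros(5)
    used = 0
    for d in OFFSETS_13:
        glcm = np.zeros((levels, levels))
        n = 0
        for x in range(lo[0], hi[0] + 1):
            for y in range(lo[1], hi[1] + 1):
                for z in range(lo[2], hi[2] + 1):
                    x2, y2, z2 = x + d[0], y + d[1], z + d[2]
                    if lo[0] <= x2 <= hi[0] and lo[1] <= y2 <= hi[1] and lo[2] <= z2 <= hi[2]:
                        glcm[q[x, y, z], q[x2, y2, z2]] += 1
                        glcm[q[x2, y2, z2], q[x, y, z]] += 1
                        n += 1
        if n == 0:
            continue
        p = glcm / glcm.sum()
        energy = (p**2).sum()
        contrast = 0.0
        homo = 0.0
        ent = 0.0
        for a in range(levels):
            for b in range(levels):
                contrast += p[a, b] * (a - b) ** 2
                homo += p[a, b] / (1 + (a - b) ** 2)
                if p[a, b] > 0:
                    ent -= p[a, b] * np.log(p[a, b])
        marg = p.sum(axis=1)
        mu = sum(a * marg[a] for a in range(levels))
        var = sum((a - mu) ** 2 * marg[a] for a in range(levels))
        if var > 1e-18:
            corr = (sum(a * b * p[a, b] for a in range(levels) for b in range(levels)) - mu * mu) / var
        else:
            corr = 0.0
        feats += np.array([energy, contrast, corr, homo, ent])
        used += 1
    return feats / used


def haar_brute(data: np.ndarray, voxel, size: int) -> list[float]:
    """Half-box mean differences (x, y, z) and centre-minus-surround."""
    shape = data.shape
    r = size // 2

    def mean_box(lo, hi):
        lo = [max(v, 0) for v in lo]
        hi = [min(hi[i], shape[i] - 1) for i in range(3)]
        vals = []
        for x in range(lo[0], hi[0] + 1):
            for y in range(lo[1], hi[1] + 1):
                for z in range(lo[2], hi[2] + 1):
                    vals.append(data[x, y, z])
        return (float(np.mean(vals)), len(vals), float(np.sum(vals))) if vals else (0.0, 0, 0.0)

    v = list(voxel)
    out = []
    for axis in range(3):
        lo1 = [v[i] - r for i in range(3)]
        hi1 = [v[i] + r for i in range(3)]
        hi1[axis] = v[axis] - 1
        lo2 = [v[i] - r for i in range(3)]
        hi2 = [v[i] + r for i in range(3)]
        lo2[axis] = v[axis] + 1
        out.append(mean_box(lo1, hi1)[0] - mean_box(lo2, hi2)[0])
    rc = r - 1
    mc, cc, sc = mean_box([v[i] - rc for i in range(3)], [v[i] + rc for i in range(3)])
    mb, cb, sb = mean_box([v[i] - r for i in range(3)], [v[i] + r for i in range(3)])
    surr = (sb - sc) / (cb - cc) if cb > cc else 0.0
    out.append(mc - surr)
    return out


def pearson_two_pass(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook two-pass covariance form of the correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def auc_concordance(scores: np.ndarray, labels: np.ndarray) -> float:
    """All-pairs concordance count with ties half-weighted."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) from the closed-form normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope
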