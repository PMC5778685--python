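"""Intensity normalization, bias-field correction, template building and
spatial registration.

Registration here is a deliberately simple, fully self-contained scheme:
a multi-resolution Powell optimization of the mean squared intensity
difference over a 12-parameter affine, optionally followed by a
diffusion-regularized ("demons"-like) non-linear refinement. Transforms use
the *pull* (resampling) convention: they map fixed-space voxel coordinates
to moving-space voxel coordinates, so resampling the moving image at the
transformed coordinates produces the registered image on the fixed grid.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .imaging import BinaryMask, Volume3D

__all__ = [
    "AffineTransform",
    "RegistrationResult",
    "DisplacementField",
    "Template",
    "normalize_intensity",
    "correct_bias",
    "register_affine",
    "register_nonlinear",
    "resample",
    "resample_mask",
    "resample_with_field",
    "build_template",
]


# ---------------------------------------------------------------------------
# transforms


@dataclasses.dataclass
class AffineTransform:
    """12-parameter linear map in voxel units, pull convention.

    Maps a fixed-space coordinate x to the moving-space coordinate
    ``M @ (x - center) + center + translation``.
    """

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-8:
            raise ValueError("affine matrix is (near) singular")

    @classmethod
    def identity(cls, shape: tuple[int, int, int]) -> "AffineTransform":
        c = (np.asarray(shape, dtype=float) - 1.0) / 2.0
        return cls(np.eye(3), np.zeros(3), c)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map fixed-space points (..., 3) to moving-space points."""
        p = np.asarray(points, dtype=float)
        return (p - self.center) @ self.matrix.T + self.center + self.translation

    def matrix_offset(self) -> tuple[np.ndarray, np.ndarray]:
        """(matrix, offset) form for ``scipy.ndimage.affine_transform``."""
        offset = self.center + self.translation - self.matrix @ self.center
        return self.matrix, offset

    def inverse(self) -> "AffineTransform":
        # x -> M(x-c)+c+t inverts to y -> M^-1(y-c) + c - M^-1 t
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -(inv @ self.translation), self.center)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "center": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.array(d["matrix"]), np.array(d["translation"]), np.array(d["center"]))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclasses.dataclass
class RegistrationResult:
    """Outcome of a registration: transform plus convergence diagnostics.

    Non-convergence is flagged via ``converged`` rather than raised.
    """

    transform: AffineTransform
    converged: bool
    final_cost: float
    initial_cost: float
    message: str = ""


@dataclasses.dataclass
class DisplacementField:
    """Dense voxel displacement field (3, X, Y, Z) in fixed space, pull convention."""

    disp: np.ndarray

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=np.float32)
        if self.disp.ndim != 4 or self.disp.shape[0] != 3:
            raise ValueError("displacement field must have shape (3, X, Y, Z)")

    @property
    def max_magnitude(self) -> float:
        return float(np.sqrt((self.disp.astype(np.float64) ** 2).sum(axis=0)).max())

    def jacobian_determinant(self) -> np.ndarray:
        """det of d(x+u)/dx; > 0 everywhere means no folding."""
        grads = np.empty((3, 3) + self.disp.shape[1:], dtype=np.float64)
        for i in range(3):
            gx, gy, gz = np.gradient(self.disp[i].astype(np.float64))
            grads[i] = np.stack([gx, gy, gz])
        jac = grads.transpose(2, 3, 4, 0, 1) + np.eye(3)
        return np.linalg.det(jac)


@dataclasses.dataclass
class Template:
    """Population-average intensity image used as the common space."""

    volume: Volume3D
    provenance: list[str]
    iterations: int

    def __post_init__(self) -> None:
        d = self.volume.data
        if d.min() < -1e-6 or d.max() > 1 + 1e-6:
            raise ValueError("template intensities must lie in [0,1]")


# ---------------------------------------------------------------------------
# intensity operations


def normalize_intensity(v: Volume3D) -> Volume3D:
    """Linear rescale so the minimum maps to 0 and the maximum to 1.

    A constant image maps to all zeros (degenerate inputs must not poison
    downstream stages).
    """
    lo = float(v.data.min())
    hi = float(v.data.max())
    if hi - lo <= 0:
        return v.copy_with(np.zeros_like(v.data))
    return v.copy_with((v.data - lo) / (hi - lo))


def _poly_design(coords: np.ndarray, order: int) -> np.ndarray:
    """Monomial design matrix up to total degree `order` on coords in [-1,1]."""
    cols = []
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((x**i) * (y**j) * (z**k))
    return np.stack(cols, axis=1)


def correct_bias(
    v: Volume3D,
    order: int = 2,
    n_classes: int = 4,
    iterations: int = 2,
) -> Volume3D:
    """Remove a smooth multiplicative intensity inhomogeneity.

    Stand-in for a full N3-style correction: foreground log-intensities are
    decomposed into per-tissue-class means (1-D k-means on intensity) plus a
    low-order polynomial field; the exponentiated field (normalized to unit
    mean) is divided out and the image re-normalized to [0,1]. Removing the
    class means first keeps anatomy out of the field estimate, so a bias-free
    image passes through essentially unchanged.
    """
    data = np.asarray(v.data, dtype=np.float64)
    fg = data > 0
    if not fg.any():
        raise ValueError("all-zero image: nothing to correct")
    coords = np.argwhere(fg).astype(np.float64)
    scale = (np.asarray(v.shape, dtype=float) - 1.0)
    scale[scale == 0] = 1.0
    coords_n = coords / scale * 2.0 - 1.0
    design = _poly_design(coords_n, order)

    logv = np.log(np.clip(data[fg], 1e-8, None))
    log_field = np.zeros_like(logv)
    for _ in range(max(1, iterations)):
        corrected = logv - log_field
        centers = _kmeans_1d(corrected, n_classes)
        assign = np.argmin(np.abs(corrected[:, None] - centers[None, :]), axis=1)
        resid = logv - centers[assign]
        coef, *_ = np.linalg.lstsq(design, resid, rcond=None)
        log_field = design @ coef
        log_field -= log_field.mean()

    out = data.copy()
    out[fg] = data[fg] / np.exp(log_field)
    return normalize_intensity(v.copy_with(out))


def _lloyd_1d(values: np.ndarray, centers: np.ndarray, iters: int) -> tuple[np.ndarray, float]:
    centers = np.unique(centers)
    for _ in range(iters):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [values[assign == i].mean() if (assign == i).any() else centers[i] for i in range(centers.size)]
        )
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
    sse = float(((values - centers[assign]) ** 2).sum())
    return centers, sse


def _kmeans_1d(values: np.ndarray, k: int, iters: int = 25) -> np.ndarray:
    """Deterministic 1-D k-means; best of two seedings by within-cluster SSE.

    Farthest-point seeding never merges well-separated tissue modes; quantile
    seeding tracks the intensity mass when modes overlap. Running Lloyd from
    both and keeping the lower-SSE solution handles both regimes without
    randomness.
    """
    uniq = np.unique(values)
    fp = [float(np.median(values))]
    while len(fp) < min(k, uniq.size):
        dist = np.min(np.abs(uniq[:, None] - np.asarray(fp)[None, :]), axis=1)
        fp.append(float(uniq[np.argmax(dist)]))
    qs = np.linspace(0, 1, k + 2)[1:-1]
    candidates = [np.asarray(fp), np.quantile(values, qs)]
    best, best_sse = None, np.inf
    for init in candidates:
        centers, sse = _lloyd_1d(values, init, iters)
        if sse < best_sse - 1e-12:
            best, best_sse = centers, sse
    return best


# ---------------------------------------------------------------------------
# affine registration


def _params_to_transform(params: np.ndarray, center: np.ndarray) -> AffineTransform:
    """params = [tx,ty,tz, rx,ry,rz (deg), log-scales sx,sy,sz, shear xy,xz,yz]."""
    t = params[0:3]
    rx, ry, rz = np.deg2rad(params[3:6])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    S = np.diag(np.exp(params[6:9]))
    Sh = np.eye(3)
    Sh[0, 1], Sh[0, 2], Sh[1, 2] = params[9:12]
    M = Rz @ Ry @ Rx @ S @ Sh
    return AffineTransform(M, np.asarray(t, dtype=float), center)


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    sm = ndimage.gaussian_filter(data.astype(np.float64), sigma=factor / 2.0)
    return sm[::factor, ::factor, ::factor]


def _sample_grid(shape: tuple[int, ...], stride: int) -> np.ndarray:
    idx = np.meshgrid(*(np.arange(0, n, stride, dtype=float) for n in shape), indexing="ij")
    return np.stack([a.ravel() for a in idx], axis=1)


def _sample_cost(
    fixed: np.ndarray,
    moving: np.ndarray,
    transform: AffineTransform,
    stride: int,
    pts: np.ndarray | None = None,
    fvals: np.ndarray | None = None,
) -> float:
    if pts is None:
        pts = _sample_grid(fixed.shape, stride)
    if fvals is None:
        fvals = fixed[::stride, ::stride, ::stride].ravel()
    mpts = transform.apply(pts)
    vals = ndimage.map_coordinates(moving, mpts.T, order=1, mode="constant", cval=0.0)
    return float(np.mean((vals - fvals) ** 2))


def register_affine(
    moving: Volume3D,
    fixed: Volume3D,
    levels: int = 3,
    rigid_only: bool = False,
    max_fev_per_level: int = 800,
) -> RegistrationResult:
    """Multi-resolution affine registration by Powell search on the MSD.

    Returns a flagged :class:`RegistrationResult`; non-convergence is reported
    in ``converged``/``message`` rather than raised.
    """
    mov = np.asarray(moving.data, dtype=np.float64)
    fix = np.asarray(fixed.data, dtype=np.float64)
    n_params = 6 if rigid_only else 12
    params = np.zeros(12)
    factors = [2 ** (levels - 1 - i) for i in range(levels)]
    message = "ok"
    initial_cost = _sample_cost(fix, mov, AffineTransform.identity(fix.shape), 2)
    for factor in factors:
        fix_l = _downsample(fix, factor)
        mov_l = _downsample(mov, factor)
        center = (np.asarray(fix_l.shape, dtype=float) - 1.0) / 2.0
        stride = 1 if factor > 1 else 2
        pts = _sample_grid(fix_l.shape, stride)
        fvals = fix_l[::stride, ::stride, ::stride].ravel()

        def cost(p: np.ndarray) -> float:
            full = params.copy()
            full[:n_params] = p
            tr = _params_to_transform(full, center)
            return _sample_cost(fix_l, mov_l, tr, stride, pts, fvals)

        # translations live in level voxels: rescale from the previous level
        p0 = params[:n_params].copy()
        c0 = cost(p0)
        res = optimize.minimize(
            cost,
            p0,
            method="Powell",
            options={"maxfev": max_fev_per_level, "xtol": 1e-3, "ftol": 1e-7},
        )
        # accept only strict improvement: on flat cost landscapes (e.g.
        # constant images) Powell can wander without changing the cost
        if res.fun < c0 - 1e-15:
            params[:n_params] = res.x
        if not res.success:
            message = str(res.message)
        params[0:3] *= 2.0 if factor > 1 else 1.0  # to next (finer) level

    center_full = (np.asarray(fix.shape, dtype=float) - 1.0) / 2.0
    transform = _params_to_transform(params, center_full)
    final_cost = _sample_cost(fix, mov, transform, 2)
    # convergence = the optimization actually explained the initial mismatch
    converged = final_cost <= 0.5 * initial_cost or final_cost < 1e-6
    if not converged and message == "ok":
        message = "registration did not reduce the dissimilarity sufficiently"
    return RegistrationResult(transform, converged, final_cost, float(initial_cost), message)


def resample(moving: Volume3D, transform: AffineTransform, shape: tuple[int, int, int] | None = None, order: int = 1) -> Volume3D:
    """Resample the moving image onto the fixed grid (trilinear by default)."""
    shape = shape or moving.shape
    M, offset = transform.matrix_offset()
    out = ndimage.affine_transform(
        np.asarray(moving.data, dtype=np.float64), M, offset=offset, output_shape=shape, order=order, mode="constant", cval=0.0
    )
    return Volume3D(out.astype(np.float32), moving.spacing, moving.affine)


def resample_mask(mask: BinaryMask, transform: AffineTransform, shape: tuple[int, int, int] | None = None) -> BinaryMask:
    """Nearest-neighbour resampling for label images."""
    shape = shape or mask.shape
    M, offset = transform.matrix_offset()
    out = ndimage.affine_transform(
        mask.data.astype(np.float64), M, offset=offset, output_shape=shape, order=0, mode="constant", cval=0.0
    )
    return BinaryMask((out > 0.5).astype(np.uint8), mask.spacing, mask.affine)


def register_nonlinear(
    moving: Volume3D,
    fixed: Volume3D,
    smoothness: float = 1.5,
    iterations: int = 8,
    step: float = 1.5,
) -> DisplacementField:
    """Demons-like diffusion-regularized refinement after affine pre-alignment.

    Both images must already be on the same grid (apply the affine first).
    The returned field u maps fixed coordinates x to moving coordinates
    x + u(x). Zero iterations return a zero field.
    """
    fix = np.asarray(fixed.data, dtype=np.float64)
    mov = np.asarray(moving.data, dtype=np.float64)
    if fix.shape != mov.shape:
        raise ValueError("apply the affine pre-alignment before the non-linear step")
    disp = np.zeros((3,) + fix.shape, dtype=np.float64)
    base = np.stack(np.meshgrid(*(np.arange(n, dtype=float) for n in fix.shape), indexing="ij"))
    eps = 1e-6
    for _ in range(max(0, iterations)):
        coords = base + disp
        warped = ndimage.map_coordinates(mov, coords, order=1, mode="nearest")
        diff = fix - warped
        grad = np.stack(np.gradient(warped))
        gmag2 = (grad**2).sum(axis=0)
        denom = gmag2 + diff**2 + eps
        update = step * diff * grad / denom
        np.clip(update, -1.0, 1.0, out=update)
        for i in range(3):  # regularize the update, lightly diffuse the field
            update[i] = ndimage.gaussian_filter(update[i], sigma=smoothness)
        disp += update
        for i in range(3):
            disp[i] = ndimage.gaussian_filter(disp[i], sigma=0.5)
    return DisplacementField(disp.astype(np.float32))


def resample_with_field(
    moving: Volume3D,
    affine: AffineTransform,
    field: DisplacementField,
    shape: tuple[int, int, int],
    order: int = 1,
) -> Volume3D:
    """Sample the moving image at A(x + u(x)): one interpolation for the
    composed affine + displacement mapping."""
    base = np.stack(np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij"))
    coords = base + field.disp.astype(np.float64)
    pts = coords.reshape(3, -1).T
    mpts = affine.apply(pts)
    vals = ndimage.map_coordinates(np.asarray(moving.data, dtype=np.float64), mpts.T, order=order, mode="constant", cval=0.0)
    return Volume3D(vals.reshape(shape).astype(np.float32), moving.spacing, moving.affine)


# ---------------------------------------------------------------------------
# template


def build_template(scans: list[Volume3D], iterations: int = 2, levels: int = 3) -> Template:
    """Iterative population average: register every scan to the current
    reference and average the warped images.

    The initial reference is the voxelwise mean after rigid alignment to the
    first scan. All inputs must be normalized to [0,1].
    """
    if not scans:
        raise ValueError("at least one scan is required")
    for s in scans:
        if s.data.min() < -1e-6 or s.data.max() > 1 + 1e-6:
            raise ValueError("scans must be normalized to [0,1] before templating")
    if len(scans) == 1:
        return Template(scans[0], ["scan-0"], 0)

    shape = scans[0].shape
    warped = [scans[0].data.astype(np.float64)]
    for s in scans[1:]:
        res = register_affine(s, scans[0], levels=levels, rigid_only=True)
        warped.append(resample(s, res.transform, shape).data.astype(np.float64))
    reference = Volume3D(np.mean(warped, axis=0).astype(np.float32), scans[0].spacing, scans[0].affine)

    for _ in range(max(0, iterations)):
        warped = []
        for s in scans:
            res = register_affine(s, reference, levels=levels)
            warped.append(resample(s, res.transform, shape).data.astype(np.float64))
        reference = Volume3D(
            np.clip(np.mean(warped, axis=0), 0.0, 1.0).astype(np.float32), scans[0].spacing, scans[0].affine
        )
    return Template(reference, [f"scan-{i}" for i in range(len(scans))], iterations)
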