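"""Per-atlas voxel classifiers, Bayesian threshold and weighted label fusion.

One feed-forward network (a single hidden layer of ten sigmoid units,
trained by backpropagation / stochastic gradient descent on log-loss) is
trained per selected atlas to separate hippocampal from background voxels
inside the VOI. A test voxel's score is the correlation-weighted average of
the selected models' outputs; the binary segmentation keeps voxels whose
fused score strictly exceeds the posterior-probability threshold

    t = S·P(H) / (S·P(H) + (1 − s)·(1 − P(H)))

where S and s are the cross-validated training sensitivity and specificity
and P(H) the prior probability for a VOI voxel to belong to the hippocampus.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import atlas as atlas_mod
from . import preprocess as prep
from .atlas import VOISpec, extract_voi, rank_atlases
from .features import FeatureConfig, FeatureScaler, assemble_features
from .imaging import BinaryMask, ScoreMap, Volume3D, volume_of

__all__ = [
    "TrainingConfig",
    "VoxelModel",
    "ThresholdParams",
    "AtlasEntry",
    "TrainingContext",
    "train_voxel_model",
    "cv_sensitivity_specificity",
    "estimate_prior",
    "bayes_threshold",
    "fuse_scores",
    "binarize",
    "train_atlases",
    "segment_subject",
]


@dataclasses.dataclass
class TrainingConfig:
    """Hyperparameters of the per-atlas voxel networks (config-exposed)."""

    hidden_units: int = 10
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 50
    batch_size: int = 32
    max_train_voxels: int = 6000  # cap on the class-balanced sample per atlas


@dataclasses.dataclass
class VoxelModel:
    """Weights of a 1-hidden-layer sigmoid network plus its feature schema."""

    w1: np.ndarray  # (n_features, hidden)
    b1: np.ndarray
    w2: np.ndarray  # (hidden, 1)
    b2: np.ndarray
    schema: list[str]
    seed: int

    def score(self, features: np.ndarray) -> np.ndarray:
        """Class-1 probability for each row; strictly inside (0,1)."""
        h = _sigmoid(features @ self.w1 + self.b1)
        out = _sigmoid(h @ self.w2 + self.b2)
        return np.clip(out.ravel(), 1e-12, 1 - 1e-12)

    def to_dict(self) -> dict:
        return {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "schema": self.schema,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelModel":
        return cls(
            np.asarray(d["w1"]), np.asarray(d["b1"]),
            np.asarray(d["w2"]), np.asarray(d["b2"]),
            list(d["schema"]), int(d["seed"]),
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclasses.dataclass
class ThresholdParams:
    """Sensitivity S, specificity s, prior P(H) and the derived threshold t."""

    sensitivity: float
    specificity: float
    prior: float
    threshold: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "prior", "threshold"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val} outside [0,1]")

    @classmethod
    def from_estimates(cls, sensitivity: float, specificity: float, prior: float) -> "ThresholdParams":
        return cls(sensitivity, specificity, prior, bayes_threshold(sensitivity, specificity, prior))


def bayes_threshold(sensitivity: float, specificity: float, prior: float) -> float:
    """Posterior probability of hippocampus given a positive classifier call.

    t = S·P(H) / (S·P(H) + (1−s)·(1−P(H))). Strictly increasing in each of
    S, s and P(H) on the open unit cube.
    """
    S, s, p = float(sensitivity), float(specificity), float(prior)
    num = S * p
    den = num + (1.0 - s) * (1.0 - p)
    if den <= 0:
        raise ValueError("degenerate threshold: S*P(H)=0 with s=1")
    return num / den


def _balanced_subsample(
    features: np.ndarray, labels: np.ndarray, rng: np.random.Generator, cap: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """1:1 class-balanced subsample (background voxels dominate the VOI)."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n = min(pos.size, neg.size)
    if cap is not None:
        n = min(n, cap // 2)
    pos_sel = rng.choice(pos, size=n, replace=False) if pos.size > n else pos
    neg_sel = rng.choice(neg, size=n, replace=False) if neg.size > n else neg
    idx = np.concatenate([pos_sel, neg_sel])
    rng.shuffle(idx)
    return features[idx], labels[idx]


def _fit_mlp(
    features: np.ndarray, labels: np.ndarray, seed: int, hyper: TrainingConfig, schema: list[str] | None = None
) -> VoxelModel:
    """Minibatch SGD backpropagation on log-loss; deterministic given the seed."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).reshape(-1, 1)
    n, d = X.shape
    h = hyper.hidden_units
    rng = np.random.default_rng(seed)
    w1 = rng.normal(0.0, 1.0 / np.sqrt(d), (d, h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(h), (h, 1))
    b2 = np.zeros(1)
    lr = hyper.learning_rate
    mom = hyper.momentum
    bs = min(hyper.batch_size, n)
    idx = np.arange(n)
    vel = [np.zeros_like(p) for p in (w1, b1, w2, b2)]
    for _ in range(hyper.epochs):
        rng.shuffle(idx)
        for s in range(0, n, bs):
            b = idx[s : s + bs]
            Xb, yb = X[b], y[b]
            hidden = _sigmoid(Xb @ w1 + b1)
            out = _sigmoid(hidden @ w2 + b2)
            # gradient of the mean log-loss: (out - y) / batch
            dout = (out - yb) / len(b)
            dw2 = hidden.T @ dout
            db2 = dout.sum(axis=0)
            dh = (dout @ w2.T) * hidden * (1.0 - hidden)
            dw1 = Xb.T @ dh
            db1 = dh.sum(axis=0)
            for v, g in zip(vel, (dw1, db1, dw2, db2)):
                v *= mom
                v -= lr * g
            w1 += vel[0]
            b1 += vel[1]
            w2 += vel[2]
            b2 += vel[3]
    schema = schema or [f"f{i}" for i in range(d)]
    return VoxelModel(w1, b1, w2, b2, schema, seed)


def train_voxel_model(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    hyper: TrainingConfig | None = None,
    schema: list[str] | None = None,
) -> VoxelModel:
    """Train one voxel network on class-balanced resampled voxels.

    Deterministic given the seed. Raises on single-class labels.
    """
    hyper = hyper or TrainingConfig()
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least one positive and one negative voxel")
    rng = np.random.default_rng(seed)
    X, y = _balanced_subsample(np.asarray(features, dtype=np.float64), labels, rng, hyper.max_train_voxels)
    return _fit_mlp(X, y, seed, hyper, schema)


def cv_sensitivity_specificity(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    hyper: TrainingConfig | None = None,
) -> tuple[float, float]:
    """Repeated stratified k-fold estimate of sensitivity S and specificity s.

    Mean true-positive and true-negative rates at score threshold 0.5,
    averaged over folds and repeats. Deterministic given the seed.
    """
    hyper = hyper or TrainingConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError("too few samples in a class to stratify into folds")
    tprs, tnrs = [], []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 1000 * rep)
        for fold_i, (tr, te) in enumerate(skf.split(X, y)):
            model = _fit_mlp(X[tr], y[tr], seed + 7 * rep + fold_i, hyper)
            pred = model.score(X[te]) > 0.5
            pos = y[te] == 1
            tprs.append(float(pred[pos].mean()))
            tnrs.append(float((~pred[~pos]).mean()))
    return float(np.mean(tprs)), float(np.mean(tnrs))


def estimate_prior(training_masks: list[BinaryMask], voi: VOISpec) -> float:
    """Mean fraction of VOI voxels labelled hippocampus across training scans."""
    if not training_masks:
        raise ValueError("at least one training mask is required")
    if voi.n_voxels == 0:
        raise ValueError("empty VOI")
    fracs = [float(voi.crop(m.data).mean()) for m in training_masks]
    return float(np.mean(fracs))


def fuse_scores(score_maps: list[ScoreMap], weights: list[float] | np.ndarray) -> ScoreMap:
    """Voxelwise weighted mean of per-atlas score maps.

    Weights (the atlas correlations) must be positive; they are normalized to
    sum to one, so the fused map is a convex combination.
    """
    if not score_maps:
        raise ValueError("no score maps to fuse")
    w = np.asarray(weights, dtype=np.float64)
    if w.size != len(score_maps):
        raise ValueError("one weight per score map required")
    if (w <= 0).any():
        raise ValueError("non-positive weights: exclude non-positive-correlation atlases upstream")
    w = w / w.sum()
    fused = np.zeros_like(score_maps[0].data)
    for sm, wi in zip(score_maps, w):
        if sm.data.shape != fused.shape:
            raise ValueError("score maps must share a VOI")
        fused += wi * sm.data
    return ScoreMap(np.clip(fused, 0.0, 1.0), score_maps[0].voi)


def binarize(fused: ScoreMap, threshold: float) -> BinaryMask:
    """Voxels whose score strictly exceeds the threshold become hippocampus."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0,1]")
    return BinaryMask((fused.data > threshold).astype(np.uint8))


# ---------------------------------------------------------------------------
# training and end-to-end segmentation


@dataclasses.dataclass
class AtlasEntry:
    """A trained atlas: per-side VOI intensity vector, voxel model and CV rates."""

    atlas_id: str
    voi_vectors: dict[str, np.ndarray]
    models: dict[str, VoxelModel]
    cv_rates: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "atlas_id": self.atlas_id,
            "voi_vectors": {k: v.tolist() for k, v in self.voi_vectors.items()},
            "models": {k: m.to_dict() for k, m in self.models.items()},
            "cv_rates": {k: list(v) for k, v in self.cv_rates.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AtlasEntry":
        return cls(
            d["atlas_id"],
            {k: np.asarray(v) for k, v in d["voi_vectors"].items()},
            {k: VoxelModel.from_dict(m) for k, m in d["models"].items()},
            {k: (float(v[0]), float(v[1])) for k, v in d["cv_rates"].items()},
        )


@dataclasses.dataclass
class TrainingContext:
    """Everything segmentation needs besides the atlases themselves."""

    vois: dict[str, VOISpec]
    scalers: dict[str, FeatureScaler]
    priors: dict[str, float]
    feature_config: FeatureConfig

    def save(self, path: str | Path) -> None:
        d = {
            "vois": {k: dataclasses.asdict(v) for k, v in self.vois.items()},
            "scalers": {k: s.to_dict() for k, s in self.scalers.items()},
            "priors": self.priors,
            "feature_config": dataclasses.asdict(self.feature_config),
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path: str | Path) -> "TrainingContext":
        d = json.loads(Path(path).read_text())
        vois = {
            k: VOISpec(tuple(v["x"]), tuple(v["y"]), tuple(v["z"]), v["side"], v["padding"])
            for k, v in d["vois"].items()
        }
        fc = d["feature_config"]
        return cls(
            vois,
            {k: FeatureScaler.from_dict(s) for k, s in d["scalers"].items()},
            {k: float(v) for k, v in d["priors"].items()},
            FeatureConfig(
                tuple(fc["moment_sizes"]), fc["haralick_box"], fc["haralick_levels"], tuple(fc["haar_sizes"])
            ),
        )


@dataclasses.dataclass
class SegmentationConfig:
    """Knobs of the end-to-end segmentation chain."""

    m_atlases: int = 10
    voi_padding: int = 2
    feature_config: FeatureConfig = dataclasses.field(default_factory=FeatureConfig)
    training: TrainingConfig = dataclasses.field(default_factory=TrainingConfig)
    cv_folds: int = 5
    cv_repeats: int = 2
    bias_order: int = 2
    apply_bias_correction: bool = True
    registration_levels: int = 3
    nonlinear_iterations: int = 5
    nonlinear_smoothness: float = 1.5


def _preprocess_to_template(
    scan: Volume3D, template: prep.Template, cfg: SegmentationConfig
) -> tuple[Volume3D, prep.AffineTransform, prep.DisplacementField | None, bool]:
    """Normalize, bias-correct and spatially normalize a scan to the template."""
    v = prep.normalize_intensity(scan)
    if cfg.apply_bias_correction:
        v = prep.correct_bias(v, order=cfg.bias_order)
    res = prep.register_affine(v, template.volume, levels=cfg.registration_levels)
    warped = prep.resample(v, res.transform, template.volume.shape)
    field = None
    if cfg.nonlinear_iterations > 0:
        field = prep.register_nonlinear(
            warped, template.volume, smoothness=cfg.nonlinear_smoothness, iterations=cfg.nonlinear_iterations
        )
        warped = prep.resample_with_field(v, res.transform, field, template.volume.shape)
    return warped, res.transform, field, res.converged


def _warp_mask(
    mask: BinaryMask,
    transform: prep.AffineTransform,
    field: prep.DisplacementField | None,
    shape: tuple[int, int, int],
) -> BinaryMask:
    if field is None:
        return prep.resample_mask(mask, transform, shape)
    warped = prep.resample_with_field(
        Volume3D(mask.data.astype(np.float32), mask.spacing, mask.affine), transform, field, shape
    )
    return BinaryMask((warped.data > 0.5).astype(np.uint8), mask.spacing, mask.affine)


def train_atlases(
    scans: list[Volume3D],
    masks: dict[str, list[BinaryMask]],
    template: prep.Template,
    config: SegmentationConfig | None = None,
    seed: int = 0,
    atlas_ids: list[str] | None = None,
) -> tuple[list[AtlasEntry], TrainingContext]:
    """Warp training atlases to the template and train per-atlas voxel models.

    ``masks`` maps side ('left'/'right') to one mask per scan. Left and right
    hippocampi get separate VOIs and are processed independently.
    """
    config = config or SegmentationConfig()
    sides = list(masks.keys())
    n = len(scans)
    atlas_ids = atlas_ids or [f"atlas-{i:02d}" for i in range(n)]

    warped_scans: list[Volume3D] = []
    warped_masks: dict[str, list[BinaryMask]] = {s: [] for s in sides}
    for i, scan in enumerate(scans):
        warped, transform, field, _ = _preprocess_to_template(scan, template, config)
        warped_scans.append(warped)
        for side in sides:
            warped_masks[side].append(_warp_mask(masks[side][i], transform, field, template.volume.shape))

    vois: dict[str, VOISpec] = {}
    priors: dict[str, float] = {}
    scalers: dict[str, FeatureScaler] = {}
    entries = [AtlasEntry(atlas_ids[i], {}, {}, {}) for i in range(n)]

    for side in sides:
        prob = atlas_mod.voi_probability_map(warped_masks[side])
        voi = atlas_mod.define_voi(prob, padding=config.voi_padding, side=side)
        vois[side] = voi
        priors[side] = estimate_prior(warped_masks[side], voi)

        raw_feats = []
        for i in range(n):
            feats, schema = assemble_features(warped_scans[i], voi, config.feature_config)
            raw_feats.append(feats)
        scaler = FeatureScaler().fit(raw_feats, schema)
        scalers[side] = scaler

        for i in range(n):
            feats = scaler.transform(raw_feats[i])
            labels = voi.crop(warped_masks[side][i].data).ravel(order="F").astype(int)
            model_seed = seed + 101 * i + (0 if side == "left" else 50)
            model = train_voxel_model(feats, labels, seed=model_seed, hyper=config.training, schema=scaler.schema)
            rng = np.random.default_rng(model_seed + 1)
            Xb, yb = _balanced_subsample(feats, labels, rng, config.training.max_train_voxels)
            S, s = cv_sensitivity_specificity(
                Xb, yb, folds=config.cv_folds, repeats=config.cv_repeats, seed=model_seed, hyper=config.training
            )
            entries[i].voi_vectors[side] = extract_voi(warped_scans[i], voi)
            entries[i].models[side] = model
            entries[i].cv_rates[side] = (S, s)

    context = TrainingContext(vois, scalers, priors, config.feature_config)
    return entries, context


@dataclasses.dataclass
class SideResult:
    mask: BinaryMask
    volume_mm3: float
    ranking: atlas_mod.AtlasRanking
    threshold: ThresholdParams
    fused: ScoreMap


@dataclasses.dataclass
class SegmentationResult:
    left: SideResult
    right: SideResult
    registration_converged: bool
    transform: prep.AffineTransform | None = None
    field: prep.DisplacementField | None = None

    def mask_to_template(self, mask: BinaryMask, shape: tuple[int, int, int]) -> BinaryMask:
        """Carry a native-space mask (e.g. ground truth) into template space
        with the transform estimated for this subject."""
        return _warp_mask(mask, self.transform, self.field, shape)


def segment_subject(
    test: Volume3D,
    atlases: list[AtlasEntry],
    template: prep.Template,
    context: TrainingContext,
    config: SegmentationConfig | None = None,
) -> SegmentationResult:
    """Run the full segmentation chain on one test scan.

    normalize → bias-correct → register to template → per-side VOI extract →
    rank atlases by Pearson correlation → score with the m selected models →
    correlation-weighted fusion → Bayesian threshold → binarize → volume.
    """
    config = config or SegmentationConfig()
    warped, transform, field, converged = _preprocess_to_template(test, template, config)

    side_results: dict[str, SideResult] = {}
    for side in ("left", "right"):
        voi = context.vois[side]
        test_vec = extract_voi(warped, voi)
        ranking = rank_atlases(test_vec, {a.atlas_id: a.voi_vectors[side] for a in atlases}, m=config.m_atlases)
        selected = [(aid, r) for aid, r in ranking.selected if r > 0]
        if not selected:
            raise ValueError(f"no positively correlated atlas for side {side}")
        by_id = {a.atlas_id: a for a in atlases}

        feats, _ = assemble_features(warped, voi, context.feature_config, scaler=context.scalers[side])
        maps = []
        weights = []
        sens, spec = [], []
        for aid, r in selected:
            entry = by_id[aid]
            scores = entry.models[side].score(feats)
            maps.append(ScoreMap(scores.reshape(voi.shape, order="F"), voi))
            weights.append(r)
            S, s = entry.cv_rates[side]
            sens.append(S)
            spec.append(s)
        fused = fuse_scores(maps, weights)
        params = ThresholdParams.from_estimates(float(np.mean(sens)), float(np.mean(spec)), context.priors[side])
        voi_mask = binarize(fused, params.threshold)
        full = np.zeros(template.volume.shape, dtype=np.uint8)
        full[voi.slices()] = voi_mask.data
        mask = BinaryMask(full, test.spacing, template.volume.affine)
        side_results[side] = SideResult(mask, volume_of(mask), ranking, params, fused)

    return SegmentationResult(side_results["left"], side_results["right"], converged, transform, field)
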