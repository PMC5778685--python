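import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippoatlas.atlas import VOISpec
from hippoatlas.fusion import (
    SegmentationConfig,
    ThresholdParams,
    TrainingConfig,
    VoxelModel,
    bayes_threshold,
    binarize,
    cv_sensitivity_specificity,
    estimate_prior,
    fuse_scores,
    segment_subject,
    train_atlases,
    train_voxel_model,
)
from hippoatlas.imaging import BinaryMask, ScoreMap, dice
from hippoatlas.phantoms import PhantomSpec, make_phantom
from hippoatlas.preprocess import build_template, normalize_intensity


def _blobs(n=200, sep=3.0, seed=0):
    """Two Gaussian blobs separated by `sep` standard deviations."""
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.normal(0, 1, (n // 2, 4)), rng.normal(sep, 1, (n // 2, 4))])
    y = np.concatenate([np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)])
    return X, y


class TestBayesThreshold:
    def test_perfect_classifier_gives_one(self):
        assert bayes_threshold(1.0, 1.0, 0.3) == pytest.approx(1.0)

    def test_uninformative_classifier_returns_prior(self):
        for p in (0.1, 0.5, 0.9):
            assert bayes_threshold(0.5, 0.5, p) == pytest.approx(p)

    def test_worked_example(self):
        # 0.9*0.1 / (0.9*0.1 + 0.2*0.9) = 0.09/0.27 = 1/3
        assert bayes_threshold(0.9, 0.8, 0.1) == pytest.approx(1.0 / 3.0)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            bayes_threshold(0.0, 1.0, 0.0)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_strictly_increasing_in_each_argument(self, S, s, p):
        eps = 0.01
        t = bayes_threshold(S, s, p)
        assert 0 < t < 1
        assert bayes_threshold(S + eps, s, p) > t
        assert bayes_threshold(S, s + eps, p) > t
        assert bayes_threshold(S, s, p + eps) > t

    def test_threshold_params_validation(self):
        tp = ThresholdParams.from_estimates(0.9, 0.8, 0.1)
        assert tp.threshold == pytest.approx(1.0 / 3.0)
        with pytest.raises(ValueError):
            ThresholdParams(1.2, 0.5, 0.5, 0.5)


class TestVoxelModel:
    def test_separable_data_high_training_accuracy(self):
        X, y = _blobs()
        model = train_voxel_model(X, y, seed=3)
        acc = ((model.score(X) > 0.5).astype(int) == y).mean()
        assert acc >= 0.95

    def test_same_seed_bit_identical_weights(self):
        X, y = _blobs(seed=1)
        m1 = train_voxel_model(X, y, seed=7)
        m2 = train_voxel_model(X, y, seed=7)
        np.testing.assert_array_equal(m1.w1, m2.w1)
        np.testing.assert_array_equal(m1.w2, m2.w2)

    def test_scores_strictly_inside_unit_interval(self, rng):
        X, y = _blobs(seed=2)
        model = train_voxel_model(X, y, seed=0)
        extreme = rng.normal(0, 100, (50, 4))
        s = model.score(extreme)
        assert (s > 0).all() and (s < 1).all()

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            train_voxel_model(X, np.zeros(10, dtype=int))

    def test_serialization_round_trip(self):
        X, y = _blobs(n=60)
        m = train_voxel_model(X, y, seed=0)
        back = VoxelModel.from_dict(m.to_dict())
        np.testing.assert_allclose(back.score(X), m.score(X))


class TestCrossValidation:
    def test_separable_data_near_perfect_rates(self):
        X, y = _blobs(n=300, seed=4)
        S, s = cv_sensitivity_specificity(X, y, repeats=1, seed=0)
        assert S >= 0.95 and s >= 0.95

    def test_chance_level_when_labels_independent(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2000, 4))
        y = np.concatenate([np.zeros(1000, dtype=int), np.ones(1000, dtype=int)])
        hyper = TrainingConfig(epochs=15)
        S, s = cv_sensitivity_specificity(X, y, repeats=1, seed=0, hyper=hyper)
        assert 0.45 <= S <= 0.55
        assert 0.45 <= s <= 0.55

    def test_deterministic_given_seed(self):
        X, y = _blobs(n=120, sep=1.0, seed=6)
        r1 = cv_sensitivity_specificity(X, y, repeats=2, seed=9)
        r2 = cv_sensitivity_specificity(X, y, repeats=2, seed=9)
        assert r1 == r2

    def test_too_few_samples_rejected(self):
        X = np.zeros((6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError):
            cv_sensitivity_specificity(X, y, folds=5)


class TestPrior:
    def test_half_filled_voi(self):
        voi = VOISpec((0, 3), (0, 3), (0, 3))
        data = np.zeros((6, 6, 6), dtype=np.uint8)
        data[0:2, 0:4, 0:4] = 1  # 32 of 64 VOI voxels
        assert estimate_prior([BinaryMask(data)], voi) == pytest.approx(0.5)

    def test_count_ratio(self):
        voi = VOISpec((0, 4), (0, 4), (0, 3))  # 100 voxels
        data = np.zeros((6, 6, 6), dtype=np.uint8)
        data[0, 0, 0:2] = 1
        data[1, 1, 0:3] = 1
        data[2, 2, 0:2] = 1  # 7 labelled voxels inside the VOI
        assert estimate_prior([BinaryMask(data)], voi) == pytest.approx(0.07)

    def test_mean_over_scans(self):
        voi = VOISpec((0, 4), (0, 3), (0, 4))  # 100 voxels
        a = np.zeros((5, 5, 5), dtype=np.uint8)
        b = np.zeros((5, 5, 5), dtype=np.uint8)
        a[0, 0:2, 0:5] = 1  # 10 in-VOI voxels -> prior 0.1
        b[0:2, 0:3, 0:5] = 1  # 30 in-VOI voxels -> prior 0.3
        assert estimate_prior([BinaryMask(a), BinaryMask(b)], voi) == pytest.approx(0.2)


class TestFusion:
    def test_identical_maps_any_weights(self, rng):
        voi = VOISpec((0, 2), (0, 2), (0, 2))
        data = rng.random((3, 3, 3))
        maps = [ScoreMap(data.copy(), voi) for _ in range(3)]
        fused = fuse_scores(maps, [0.2, 1.0, 5.0])
        np.testing.assert_allclose(fused.data, data)

    def test_weighted_average_worked_example(self):
        voi = VOISpec((0, 0), (0, 0), (0, 0))
        a = ScoreMap(np.full((1, 1, 1), 0.2), voi)
        b = ScoreMap(np.full((1, 1, 1), 0.6), voi)
        fused = fuse_scores([a, b], [1.0, 3.0])
        assert fused.data[0, 0, 0] == pytest.approx(0.5)

    def test_single_atlas_passthrough(self, rng):
        voi = VOISpec((0, 1), (0, 1), (0, 1))
        m = ScoreMap(rng.random((2, 2, 2)), voi)
        np.testing.assert_allclose(fuse_scores([m], [0.7]).data, m.data)

    def test_nonpositive_weight_rejected(self, rng):
        voi = VOISpec((0, 1), (0, 1), (0, 1))
        m = ScoreMap(rng.random((2, 2, 2)), voi)
        with pytest.raises(ValueError):
            fuse_scores([m, m], [1.0, -0.2])

    def test_fused_bounded_by_inputs(self, rng):
        voi = VOISpec((0, 3), (0, 3), (0, 3))
        maps = [ScoreMap(rng.random((4, 4, 4)), voi) for _ in range(4)]
        w = rng.random(4) + 0.1
        fused = fuse_scores(maps, w)
        stack = np.stack([m.data for m in maps])
        assert (fused.data >= stack.min(axis=0) - 1e-12).all()
        assert (fused.data <= stack.max(axis=0) + 1e-12).all()


class TestBinarize:
    def test_strict_exceeding(self):
        voi = VOISpec((0, 2), (0, 0), (0, 0))
        m = ScoreMap(np.array([0.2, 0.4, 0.9]).reshape(3, 1, 1), voi)
        assert binarize(m, 0.4).data.sum() == 1  # score exactly t stays background

    def test_zero_threshold_all_positive_scores(self):
        voi = VOISpec((0, 1), (0, 1), (0, 1))
        m = ScoreMap(np.full((2, 2, 2), 0.01), voi)
        assert binarize(m, 0.0).data.sum() == 8

    def test_toy_count(self):
        voi = VOISpec((0, 2), (0, 0), (0, 0))
        m = ScoreMap(np.array([0.2, 0.5, 0.9]).reshape(3, 1, 1), voi)
        assert binarize(m, 0.4).data.sum() == 2


@pytest.fixture(scope="module")
def trained_small_pipeline():
    """Three small training atlases, trained end to end on a 32-voxel grid."""
    base = PhantomSpec(
        shape=(32, 32, 32), volume_left_mm3=700.0, volume_right_mm3=700.0,
        noise_sd=0.01, bias_amplitude=0.0, max_translation=1.0, max_rotation_deg=2.0,
    )
    phantoms = [make_phantom(dataclasses.replace(base, seed=s)) for s in (21, 22, 23)]
    scans = [normalize_intensity(p[0]) for p in phantoms]
    template = build_template(scans, iterations=1)
    cfg = SegmentationConfig(m_atlases=3, cv_repeats=1, apply_bias_correction=False, nonlinear_iterations=3)
    entries, ctx = train_atlases(
        [p[0] for p in phantoms],
        {"left": [p[1] for p in phantoms], "right": [p[2] for p in phantoms]},
        template, cfg, seed=0,
    )
    return base, template, cfg, entries, ctx


class TestSegmentSubject:
    def test_structural_contract_and_plausible_output(self, trained_small_pipeline):
        base, template, cfg, entries, ctx = trained_small_pipeline
        test_vol, truth_l, truth_r = make_phantom(dataclasses.replace(base, seed=77))
        res = segment_subject(test_vol, entries, template, ctx, cfg)
        for side_res in (res.left, res.right):
            assert side_res.mask.data.sum() > 0
            assert 0.0 < side_res.threshold.threshold < 1.0
        # left and right are produced independently: different VOIs
        assert ctx.vois["left"].x != ctx.vois["right"].x
        tl = res.mask_to_template(truth_l, template.volume.shape)
        tr = res.mask_to_template(truth_r, template.volume.shape)
        assert dice(res.left.mask, tl) > 0.5
        assert dice(res.right.mask, tr) > 0.5

    def test_deterministic(self, trained_small_pipeline):
        base, template, cfg, entries, ctx = trained_small_pipeline
        test_vol, _, _ = make_phantom(dataclasses.replace(base, seed=78))
        r1 = segment_subject(test_vol, entries, template, ctx, cfg)
        r2 = segment_subject(test_vol, entries, template, ctx, cfg)
        np.testing.assert_array_equal(r1.left.mask.data, r2.left.mask.data)
        assert r1.left.volume_mm3 == r2.left.volume_mm3
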