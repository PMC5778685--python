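import numpy as np
import pandas as pd
import pytest

from hippoatlas.diagnostics import (
    bootstrap_auc,
    detrend,
    fit_aging_model,
    hanley_mcneil_se,
    kruskal_wallis,
    naive_bayes_3class,
    precision_report,
    roc_auc,
    timepoint_correlations,
)
from hippoatlas.phantoms import CohortSpec, make_cohort

from _oracles import auc_concordance, ols_normal_equations


def _ctrl_table(ages, volumes):
    return pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(len(ages))],
            "age": ages,
            "group": "CTRL",
            "timepoint": "screening",
            "v_left_mm3": volumes,
            "v_right_mm3": volumes,
        }
    )


class TestPrecision:
    def test_identical_pairs(self):
        rep = precision_report([(2650.0, 2650.0)] * 5, 2650.0)
        assert rep.mean_residual == 0.0 and rep.sd_residual == 0.0

    def test_two_point_sd(self):
        rep = precision_report([(1.0, 2.0), (2.0, 1.0)], 100.0)
        assert rep.mean_residual == pytest.approx(0.0)
        assert rep.sd_residual == pytest.approx(np.sqrt(2.0))

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            precision_report([(1.0, 1.0)], 100.0)

    def test_sd_invariant_to_common_shift(self, rng):
        pairs = rng.normal(2650, 100, (50, 2))
        shifted = pairs + 500.0
        a = precision_report(pairs, 2650.0)
        b = precision_report(shifted, 2650.0)
        assert a.sd_residual == pytest.approx(b.sd_residual)


class TestTimepointCorrelations:
    def _table(self, vols_by_tp):
        rows = []
        for tp, vols in vols_by_tp.items():
            for i, v in enumerate(vols):
                rows.append({"id": f"s{i}", "age": 70, "group": "CTRL", "timepoint": tp,
                             "v_left_mm3": v, "v_right_mm3": v * 1.01})
        return pd.DataFrame(rows)

    def test_duplicated_volumes_give_unit_correlation(self, rng):
        v = rng.normal(2600, 200, 20)
        table = self._table({"screening": v, "repeat": v, "m12": v})
        corr = timepoint_correlations(table)
        np.testing.assert_allclose(corr["left"].to_numpy(), 1.0)

    def test_independent_volumes_near_zero(self, rng):
        table = self._table({"screening": rng.normal(0, 1, 200), "repeat": rng.normal(0, 1, 200)})
        corr = timepoint_correlations(table)["left"].to_numpy()
        assert abs(corr[0, 1]) < 0.2

    def test_symmetric_unit_diagonal(self, rng):
        table = self._table({tp: rng.normal(2600, 150, 15) for tp in ("screening", "repeat", "m12", "m24")})
        for mat in timepoint_correlations(table).values():
            arr = mat.to_numpy()
            np.testing.assert_allclose(arr, arr.T)
            np.testing.assert_allclose(np.diag(arr), 1.0)

    def test_missing_timepoint_column_rejected(self):
        with pytest.raises(ValueError):
            timepoint_correlations(pd.DataFrame({"id": [1], "v_left_mm3": [1.0], "v_right_mm3": [1.0]}))


class TestAgingModel:
    def test_noiseless_line_recovered_exactly(self):
        ages = np.array([60.0, 65.0, 70.0, 80.0, 85.0])
        vols = 3000.0 - 30.0 * (ages - ages.min())
        model = fit_aging_model(_ctrl_table(ages, vols))
        assert model.v0 == pytest.approx(3000.0)
        assert model.k == pytest.approx(-30.0)
        assert model.r2 == pytest.approx(1.0)
        assert model.t0 == 60.0

    def test_matches_normal_equations_oracle(self, rng):
        ages = rng.uniform(55, 90, 10)
        vols = rng.normal(2800, 300, 10)
        model = fit_aging_model(_ctrl_table(ages, vols))
        ic, sl = ols_normal_equations(ages - ages.min(), vols)
        assert model.v0 == pytest.approx(ic, abs=1e-10)
        assert model.k == pytest.approx(sl, abs=1e-10)

    def test_recovers_generating_coefficients_within_two_se(self):
        # CTRL cohort with total residual noise sd 84.3 mm^3 about the line
        per_source = 84.3 / np.sqrt(2)
        spec = CohortSpec(n_mci=0, n_ad=0, subject_sd=per_source, measurement_sd=per_source, seed=42)
        df = make_cohort(spec)
        model = fit_aging_model(df[df.group == "CTRL"], side="left", t0=df.age.min())
        assert abs(model.k - (-29.9)) <= 2 * model.se_k
        assert abs(model.v0 - 3173.0) <= 2 * model.se_v0

    def test_degenerate_ages_rejected(self):
        with pytest.raises(ValueError):
            fit_aging_model(_ctrl_table([70.0] * 5, [2000.0] * 5))


class TestDetrend:
    def test_on_model_line_gives_zero(self):
        ages = np.array([60.0, 70.0, 80.0])
        vols = 3000.0 - 30.0 * (ages - 60.0)
        model = fit_aging_model(_ctrl_table(ages, vols))
        np.testing.assert_allclose(detrend(vols, ages, model), 0.0, atol=1e-9)

    def test_worked_arithmetic(self):
        ages = np.array([60.0, 70.0, 80.0])
        vols = 3173.0 - 29.9 * (ages - 60.0)
        model = fit_aging_model(_ctrl_table(ages, vols))
        # age - t0 = 10, V = 2800: V_hat = 3173 - 299 = 2874, V_eff = 74
        assert detrend(2800.0, 70.0, model) == pytest.approx(74.0)
        # at the reference age, V = 3000: V_eff = 3173 - 3000 = 173
        assert detrend(3000.0, 60.0, model) == pytest.approx(173.0)

    def test_linear_in_volume_with_slope_minus_one(self):
        ages = np.array([60.0, 70.0, 80.0])
        vols = 3173.0 - 29.9 * (ages - 60.0)
        model = fit_aging_model(_ctrl_table(ages, vols))
        v = np.linspace(2000, 4000, 7)
        eff = detrend(v, 72.0, model)
        np.testing.assert_allclose(np.diff(eff) / np.diff(v), -1.0)


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc(np.array([1, 2, 3, 10, 11, 12]), np.array([0, 0, 0, 1, 1, 1]))
        assert res.auc == pytest.approx(1.0)
        assert res.fpr[0] == 0.0 and res.tpr[-1] == 1.0

    def test_all_ties_half_credit(self):
        res = roc_auc(np.ones(10), np.array([0, 1] * 5))
        assert res.auc == pytest.approx(0.5)

    def test_worked_example(self):
        res = roc_auc(np.array([0.0, 2.0, 1.0, 3.0]), np.array([0, 0, 1, 1]))
        assert res.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4, dtype=int))

    def test_matches_pair_concordance_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.linspace(0, 1, 20), n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(auc_concordance(scores, labels), abs=1e-12)


class TestHanleyMcNeil:
    def test_perfect_auc_zero_se(self):
        assert hanley_mcneil_se(1.0, 10, 10) == 0.0

    def test_half_auc_single_pair(self):
        assert hanley_mcneil_se(0.5, 1, 1) == pytest.approx(0.5)

    def test_worked_formula_example(self):
        assert hanley_mcneil_se(0.8, 10, 10) == pytest.approx(0.10198, abs=1e-4)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hanley_mcneil_se(0.8, 0, 10)


class TestBootstrap:
    def test_deterministic_given_seed(self, rng):
        scores = rng.normal(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        assert bootstrap_auc(scores, labels, n_boot=50, seed=4) == bootstrap_auc(scores, labels, n_boot=50, seed=4)

    def test_agrees_with_hanley_mcneil_on_gaussian_scores(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 100), rng.normal(1, 1, 100)])
        labels = np.concatenate([np.zeros(100, dtype=int), np.ones(100, dtype=int)])
        res = roc_auc(scores, labels)
        se_b = bootstrap_auc(scores, labels, n_boot=300, seed=0)
        assert abs(se_b - res.se_hanley_mcneil) <= 0.3 * res.se_hanley_mcneil

    def test_single_resample_warns_and_returns_zero(self, rng):
        scores = rng.normal(0, 1, 20)
        labels = np.array([0, 1] * 10)
        with pytest.warns(RuntimeWarning):
            assert bootstrap_auc(scores, labels, n_boot=1, seed=0) == 0.0


class TestKruskalWallis:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        h, p = kruskal_wallis([g, g, g])
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_rank_arithmetic_worked_example(self):
        h, p = kruskal_wallis([np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])])
        assert h == pytest.approx(32.0 / 7.0)

    def test_matches_textbook_formula_oracle(self, rng):
        groups = [rng.normal(i, 1, 12) for i in range(3)]
        h, _ = kruskal_wallis(groups)
        # textbook formula without ties: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)
        allv = np.concatenate(groups)
        ranks = allv.argsort().argsort() + 1.0
        n = len(allv)
        start = 0
        acc = 0.0
        for g in groups:
            r = ranks[start : start + len(g)]
            acc += r.sum() ** 2 / len(g)
            start += len(g)
        h_oracle = 12.0 / (n * (n + 1)) * acc - 3 * (n + 1)
        assert h == pytest.approx(h_oracle, abs=1e-6)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0, 2.0])])


def _nb_table(rng, means=(3200, 2900, 2500), n=100):
    rows = []
    for g, mu in zip(("CTRL", "MCI", "AD"), means):
        for i in range(n):
            v = rng.normal(mu, 80)
            rows.append({"id": f"{g}{i}", "age": 70, "group": g, "timepoint": "screening",
                         "v_left_mm3": v, "v_right_mm3": v + rng.normal(0, 40)})
    return pd.DataFrame(rows)


class TestNaiveBayes:
    def test_disjoint_ranges_high_accuracy(self, rng):
        res = naive_bayes_3class(_nb_table(rng), rounds=3, seed=0)
        assert res["accuracy"][0] >= 0.95

    def test_identical_distributions_chance_level(self, rng):
        table = _nb_table(rng, means=(2800, 2800, 2800))
        res = naive_bayes_3class(table, rounds=5, seed=0)
        assert res["accuracy"][0] == pytest.approx(1.0 / 3.0, abs=0.05)

    def test_missing_group_rejected(self, rng):
        table = _nb_table(rng)
        with pytest.raises(ValueError):
            naive_bayes_3class(table[table.group != "AD"])

    def test_ad_oriented_sensitivity_specificity(self, rng):
        res = naive_bayes_3class(_nb_table(rng), rounds=3, seed=1)
        assert res["sensitivity"][0] >= 0.9  # AD well separated in this toy
        assert res["specificity"][0] >= 0.9


class TestGroupSeparationOrdering:
    def test_auc_ordering_mirrors_atrophy_offsets(self):
        spec = CohortSpec(seed=11)  # defaults: delta_AD=500 > delta_MCI=250 > 0
        df = make_cohort(spec)
        ctrl = df[df.group == "CTRL"]
        model = fit_aging_model(ctrl, side="left", t0=df.age.min())
        veff = detrend(df["v_left_mm3"].to_numpy(), df["age"].to_numpy(), model)
        aucs = {}
        for pos in ("AD", "MCI"):
            sel = df.group.isin(["CTRL", pos]).to_numpy()
            labels = (df.group.to_numpy()[sel] == pos).astype(int)
            aucs[pos] = roc_auc(veff[sel], labels).auc
        assert aucs["AD"] > aucs["MCI"] > 0.5
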