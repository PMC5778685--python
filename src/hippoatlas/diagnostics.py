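"""Clinical evaluation of segmented hippocampal volumes.

Covers the volumetric analyses used to judge a segmentation algorithm's
clinical value: screening/repeat precision, cross-timepoint correlations,
linear age detrending of volumes fitted on the control cohort, ROC/AUC with
Hanley–McNeil and bootstrap standard errors, a Kruskal–Wallis group test,
and a three-class Gaussian Naive Bayes cross-validation.

Cohort tables are pandas DataFrames with columns
``id, age, group, timepoint, v_left_mm3, v_right_mm3`` where group is one of
CTRL/MCI/AD and timepoint one of screening/repeat/m12/m24.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

GROUPS = ("CTRL", "MCI", "AD")
TIMEPOINTS = ("screening", "repeat", "m12", "m24")

__all__ = [
    "AgingModel",
    "PrecisionReport",
    "ROCResult",
    "precision_report",
    "timepoint_correlations",
    "fit_aging_model",
    "detrend",
    "roc_auc",
    "hanley_mcneil_se",
    "bootstrap_auc",
    "kruskal_wallis",
    "naive_bayes_3class",
]


@dataclasses.dataclass
class AgingModel:
    """Linear normal-aging model V̂ = V0 + k·(t − t0) fitted on controls.

    V0 is the expected volume at the reference age t0 (the minimum age of
    the cohort); k is the annual atrophy slope in mm³/year.
    """

    v0: float
    k: float
    t0: float
    ci_k: tuple[float, float]
    r2: float
    se_k: float
    se_v0: float
    n: int

    def predict(self, age: float | np.ndarray) -> float | np.ndarray:
        return self.v0 + self.k * (np.asarray(age, dtype=float) - self.t0)


@dataclasses.dataclass
class PrecisionReport:
    n_pairs: int
    mean_residual: float
    sd_residual: float
    precision_percent: float
    p_zero_mean: float

    def __post_init__(self) -> None:
        if self.sd_residual < 0 or self.precision_percent < 0:
            raise ValueError("sd and percent must be non-negative")


@dataclasses.dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    se_hanley_mcneil: float
    se_bootstrap: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0,1]")


def precision_report(
    pairs: list[tuple[float, float]] | np.ndarray, reference_mean: float
) -> PrecisionReport:
    """Distribution of screening − repeat volume residuals.

    The residual standard deviation, expressed as a percentage of the
    reference mean volume, is the precision figure of merit; a one-sample
    t-test checks consistency with a null mean (no systematic bias).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (screening, repeat) pairs")
    residuals = arr[:, 0] - arr[:, 1]
    sd = float(residuals.std(ddof=1))
    if sd > 0:
        p = float(stats.ttest_1samp(residuals, 0.0).pvalue)
    else:
        p = 1.0
    return PrecisionReport(
        n_pairs=arr.shape[0],
        mean_residual=float(residuals.mean()),
        sd_residual=sd,
        precision_percent=sd / float(reference_mean) * 100.0,
        p_zero_mean=p,
    )


def timepoint_correlations(records: pd.DataFrame, sides: tuple[str, ...] = ("left", "right")) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson correlation of volumes across timepoints, per side.

    Subjects are matched by id; returns one symmetric matrix with unit
    diagonal per side.
    """
    if "timepoint" not in records.columns:
        raise ValueError("records table lacks a 'timepoint' column")
    out = {}
    for side in sides:
        col = f"v_{side}_mm3"
        wide = records.pivot(index="id", columns="timepoint", values=col)
        tps = [t for t in TIMEPOINTS if t in wide.columns]
        wide = wide[tps].dropna()
        if len(wide) < 3:
            raise ValueError("need at least 3 subjects with all requested timepoints")
        out[side] = wide.corr(method="pearson")
    return out


def fit_aging_model(ctrl: pd.DataFrame, side: str = "left", t0: float | None = None) -> AgingModel:
    """Ordinary least squares of CTRL volume on (age − t0).

    t0 defaults to the minimum age of the supplied table; pass the
    whole-cohort minimum explicitly when fitting on the CTRL subset of a
    larger cohort.
    """
    col = f"v_{side}_mm3"
    if len(ctrl) < 3:
        raise ValueError("need at least 3 control records")
    age = ctrl["age"].to_numpy(dtype=float)
    vol = ctrl[col].to_numpy(dtype=float)
    if np.ptp(age) <= 0:
        raise ValueError("degenerate fit: all subjects have the same age")
    t0 = float(age.min()) if t0 is None else float(t0)
    X = sm.add_constant(age - t0)
    fit = sm.OLS(vol, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return AgingModel(
        v0=float(fit.params[0]),
        k=float(fit.params[1]),
        t0=t0,
        ci_k=(float(ci[1][0]), float(ci[1][1])),
        r2=float(fit.rsquared),
        se_k=float(fit.bse[1]),
        se_v0=float(fit.bse[0]),
        n=len(ctrl),
    )


def detrend(volume: float | np.ndarray, age: float | np.ndarray, model: AgingModel):
    """Age-detrended (effective) volume V_eff = V̂(age) − V.

    V_eff is an atrophy *deficit*: larger values mean more missing volume
    relative to the normal-aging expectation, so V_eff is used directly as
    the disease-positive ROC score.
    """
    return model.predict(age) - np.asarray(volume, dtype=float)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve over a threshold sweep of the scores, AUC by trapezoid.

    Labels are binary with 1 = disease-positive; the convention is that
    positives score higher (use V_eff, or −V for raw volumes). The
    trapezoidal AUC equals the Mann–Whitney concordance with ties given
    half credit.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    se = hanley_mcneil_se(max(auc, 1e-12), n_pos, n_neg)
    return ROCResult(thr, tpr, fpr, auc, se)


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil closed-form standard error of an AUC.

    SE² = [A(1−A) + (n⁺−1)(Q1−A²) + (n⁻−1)(Q2−A²)] / (n⁺ n⁻)
    with Q1 = A/(2−A) and Q2 = 2A²/(1+A).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class counts must be positive")
    if not (0.0 < auc <= 1.0):
        raise ValueError("AUC must lie in (0, 1]")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    num = a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    return float(np.sqrt(max(num, 0.0) / (n_pos * n_neg)))


def bootstrap_auc(scores: np.ndarray, labels: np.ndarray, n_boot: int = 500, seed: int = 0) -> float:
    """Bootstrap standard error of the AUC, stratified by class.

    Resamples each class with replacement ``n_boot`` times; the SE is the
    sample standard deviation of the bootstrap AUCs.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, pos.size), rng.choice(neg, neg.size)])
        aucs[b] = roc_auc(s[idx], y[idx]).auc
    if n_boot < 2:
        warnings.warn("bootstrap with fewer than 2 resamples: SE reported as 0", RuntimeWarning, stacklevel=2)
        return 0.0
    return float(aucs.std(ddof=1))


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _nb_feature_matrix(records: pd.DataFrame, feature_set: str) -> np.ndarray:
    vl = records["v_left_mm3"].to_numpy(dtype=float)
    vr = records["v_right_mm3"].to_numpy(dtype=float)
    if feature_set == "both":
        return (vl + vr)[:, None]
    if feature_set == "left":
        return vl[:, None]
    if feature_set == "right":
        return vr[:, None]
    raise ValueError("feature_set must be one of 'both', 'left', 'right'")


def naive_bayes_3class(
    records: pd.DataFrame,
    feature_set: str = "both",
    folds: int = 10,
    rounds: int = 100,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Three-class (CTRL/MCI/AD) Gaussian Naive Bayes cross-validation.

    Accuracy is the fraction of correct labels over all three classes;
    sensitivity and specificity treat AD as positive and CTRL+MCI as
    negative. Returns mean ± sd over the cross-validation rounds.
    """
    present = set(records["group"].unique())
    if not set(GROUPS) <= present:
        raise ValueError(f"all three groups required, got {sorted(present)}")
    X = _nb_feature_matrix(records, feature_set)
    y = records["group"].to_numpy()
    accs, sens, specs = [], [], []
    for rnd in range(rounds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rnd)
        pred = np.empty(len(y), dtype=object)
        for tr, te in skf.split(X, y):
            clf = GaussianNB().fit(X[tr], y[tr])
            pred[te] = clf.predict(X[te])
        accs.append(float((pred == y).mean()))
        is_ad = y == "AD"
        sens.append(float((pred[is_ad] == "AD").mean()))
        specs.append(float((pred[~is_ad] != "AD").mean()))
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0  # noqa: E731
    return {
        "accuracy": (float(np.mean(accs)), sd(accs)),
        "sensitivity": (float(np.mean(sens)), sd(sens)),
        "specificity": (float(np.mean(specs)), sd(specs)),
    }
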