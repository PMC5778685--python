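"""Clinical-style analysis of a synthetic volumetric cohort.

Generates a 456-subject cohort (145 controls, 217 MCI, 94 AD) with
longitudinal timepoints, then runs the full diagnostics: screening/repeat
precision, the control aging model, age detrending, ROC/AUC for CTRL-AD and
CTRL-MCI, a Kruskal-Wallis group test and the 3-class Naive Bayes table.
"""

import numpy as np

from hippoatlas import (
    CohortSpec,
    detrend,
    fit_aging_model,
    kruskal_wallis,
    make_longitudinal,
    naive_bayes_3class,
    precision_report,
    roc_auc,
)

df = make_longitudinal(CohortSpec(seed=1))
screening = df[df.timepoint == "screening"].reset_index(drop=True)

# precision: screening vs repeat of the same subject
wide = df.pivot(index="id", columns="timepoint", values="v_left_mm3")
rep = precision_report(wide[["screening", "repeat"]].to_numpy(), reference_mean=2650.2)
print(f"precision: residual sd {rep.sd_residual:.1f} mm³ = {rep.precision_percent:.1f}% of the mean volume")

# aging model on controls, then age detrending
ctrl = screening[screening.group == "CTRL"]
model = fit_aging_model(ctrl, side="left", t0=df.age.min())
print(f"aging model: V0 = {model.v0:.1f} mm³, k = {model.k:.1f} mm³/yr, R² = {model.r2:.2f}")

veff = detrend(screening["v_left_mm3"].to_numpy(), screening["age"].to_numpy(), model)
for pos in ("AD", "MCI"):
    sel = screening.group.isin(["CTRL", pos]).to_numpy()
    labels = (screening.group.to_numpy()[sel] == pos).astype(int)
    res = roc_auc(veff[sel], labels)
    print(f"CTRL-{pos}: AUC = {res.auc:.3f} ± {res.se_hanley_mcneil:.3f} (Hanley-McNeil SE)")

groups = [screening[screening.group == g]["v_left_mm3"].to_numpy() for g in ("CTRL", "MCI", "AD")]
h, p = kruskal_wallis(groups)
print(f"Kruskal-Wallis: H = {h:.1f}, p = {p:.2e}")

nb = naive_bayes_3class(screening, feature_set="both", rounds=20, seed=0)
print(
    "3-class Naive Bayes (V_left + V_right): "
    f"accuracy {nb['accuracy'][0]:.2f} ± {nb['accuracy'][1]:.2f}, "
    f"sensitivity {nb['sensitivity'][0]:.2f}, specificity {nb['specificity'][0]:.2f}"
)

# Larger detrended volume = larger atrophy deficit, so AD (offset 500 mm³)
# separates from controls more cleanly than MCI (offset 250 mm³).
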