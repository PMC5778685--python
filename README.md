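# hippoatlas

Multi-atlas hippocampal segmentation with machine-learning label fusion, and
the volumetric statistics used to judge whether segmented volumes carry
clinical signal for Alzheimer's disease.

## What it does

Hippocampal atrophy is a supportive marker for probable Alzheimer's disease,
but manual hippocampus tracing is slow and rater-dependent. `hippoatlas`
implements an automated segmentation pipeline and its downstream volumetric
analysis:

1. **Spatial normalization** — intensity normalization to [0,1], removal of
   the smooth multiplicative bias field, and registration of every scan to a
   data-driven population template (multi-resolution 12-parameter affine plus
   an optional demons-like non-linear refinement).
2. **Atlas selection** — a peri-hippocampal volume of interest (VOI) is
   traced on the template from the warped training masks; candidate atlases
   are ranked by the Pearson correlation

   r = (N Σxⱼyⱼ − Σxⱼ Σyⱼ) / √[(N Σxⱼ² − (Σxⱼ)²)(N Σyⱼ² − (Σyⱼ)²)]

   between their VOI intensities xⱼ and the test scan's yⱼ; the ten most
   correlated atlases are kept.
3. **Voxel classification and label fusion** — for every VOI voxel,
   statistical moments (3³–9³ boxes), Haralick GLCM texture and Haar-like box
   features feed one feed-forward network per atlas (one hidden layer, ten
   sigmoid units, backpropagation). A test voxel's score is the
   correlation-weighted average of the selected models, and the binary
   segmentation keeps voxels whose score exceeds the Bayesian threshold

   t = S·P(H) / (S·P(H) + (1 − s)(1 − P(H)))

   built from the cross-validated sensitivity S, specificity s and the prior
   probability P(H) of a VOI voxel being hippocampus.
4. **Volumetric diagnostics** — screening/repeat precision (residual sd σ),
   cross-timepoint correlations, the control-cohort aging model
   V̂ = V₀ + k(t − t₀), the age-detrended (effective) volume
   V_eff = V̂ − V used as a disease score, ROC/AUC with Hanley–McNeil and
   bootstrap standard errors, Kruskal–Wallis group tests and a three-class
   Gaussian Naive Bayes cross-validation.

Real clinical scans are not required anywhere: a first-class synthetic module
generates 3-D brain phantoms with ground-truth hippocampus masks, and
volumetric cohorts (145 CTRL / 217 MCI / 94 AD by default) that follow the
linear aging model with group atrophy offsets, subject random effects and
per-scan measurement noise.

## Worked example

`examples/04_volumetric_diagnostics.py` generates a longitudinal synthetic
cohort and runs the full diagnostics:

```
precision: residual sd 84.8 mm³ = 3.2% of the mean volume
aging model: V0 = 3255.5 mm³, k = -34.0 mm³/yr, R² = 0.57
CTRL-AD: AUC = 0.994 ± 0.006 (Hanley-McNeil SE)
CTRL-MCI: AUC = 0.846 ± 0.020 (Hanley-McNeil SE)
Kruskal-Wallis: H = 166.5, p = 7.04e-37
3-class Naive Bayes (V_left + V_right): accuracy 0.62 ± 0.00, sensitivity 0.21, specificity 0.95
```

Reading the numbers: the screening−repeat residual sd is the segmentation
precision (here ~3% of the 2650 mm³ mean hippocampal volume); the aging model
recovers the generating atrophy slope of about −30 mm³/yr; detrended volumes
separate AD from controls almost perfectly (AUC 0.99) and MCI less cleanly
(AUC 0.85), mirroring the 500 vs 250 mm³ atrophy offsets the generator used;
the Kruskal–Wallis test confirms the three groups differ.

The other examples cover phantom generation/volumetry, atlas ranking and a
desk-scale end-to-end segmentation (`examples/01…03`). The same pipeline is
scriptable from the shell:

```bash
hippoatlas simulate  --out out --seed 7   # phantoms + cohort CSV
hippoatlas template  --out out            # population template
hippoatlas train     --out out            # warp atlases, train voxel nets
hippoatlas segment   --out out            # segment test scans -> masks + volumes.csv
hippoatlas diagnose  --out out            # cohort statistics -> diagnostic_report.json
```

All commands accept `--config run.yaml` (unknown keys are rejected, every
stochastic stage has a named seed, and re-runs are byte-identical).

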