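"""Pipeline orchestration: simulate → template → train → segment → diagnose.

Each command reads its prerequisites from disk, writes versioned artifacts
plus a machine-readable run log (seeds consumed, parameter hash, per-stage
timing) and is deterministic given the configuration seed. Missing
prerequisites raise :class:`PipelineError` naming the absent artifact.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as diag
from . import fusion, phantoms, preprocess
from .config import RunConfig
from .features import FeatureConfig
from .imaging import read_mask, read_volume, write_mask, write_volume

__all__ = ["PipelineError", "run_pipeline"]

COMMANDS = ("simulate", "template", "train", "segment", "diagnose")


class PipelineError(RuntimeError):
    """A stage prerequisite is missing or a stage failed."""


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise PipelineError(f"missing prerequisite artifact: {path} — run `{hint}` first")
    return path


def _segmentation_config(cfg: RunConfig) -> fusion.SegmentationConfig:
    seg = cfg.segmentation
    return fusion.SegmentationConfig(
        m_atlases=seg.m_atlases,
        voi_padding=seg.voi_padding,
        feature_config=FeatureConfig(
            tuple(seg.moment_sizes), seg.haralick_box, seg.haralick_levels, tuple(seg.haar_sizes)
        ),
        training=fusion.TrainingConfig(
            seg.hidden_units, seg.learning_rate, seg.epochs, seg.batch_size, seg.max_train_voxels
        ),
        cv_folds=seg.cv_folds,
        cv_repeats=seg.cv_repeats,
        bias_order=seg.bias_order,
        apply_bias_correction=seg.apply_bias_correction,
        registration_levels=seg.registration_levels,
        nonlinear_iterations=seg.nonlinear_iterations,
        nonlinear_smoothness=seg.nonlinear_smoothness,
    )


class _Log:
    def __init__(self, command: str, cfg: RunConfig):
        self.record = {
            "command": command,
            "parameter_hash": cfg.parameter_hash(),
            "seeds": {},
            "stages": [],
        }

    def seed(self, name: str, value: int) -> int:
        self.record["seeds"][name] = int(value)
        return int(value)

    def stage(self, name: str, t0: float) -> None:
        self.record["stages"].append({"name": name, "seconds": round(time.perf_counter() - t0, 3)})

    def write(self, outdir: Path, command: str) -> None:
        (outdir / f"run_log_{command}.json").write_text(json.dumps(self.record, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# stages


def _cmd_simulate(cfg: RunConfig, log: _Log) -> None:
    sim = cfg.simulate
    out = cfg.output_dir
    atlas_dir = cfg.atlas_dir
    test_dir = cfg.test_dir
    atlas_dir.mkdir(parents=True, exist_ok=True)
    test_dir.mkdir(parents=True, exist_ok=True)

    base = phantoms.PhantomSpec(
        shape=(sim.grid,) * 3,
        volume_left_mm3=sim.volume_mean_mm3,
        volume_right_mm3=sim.volume_mean_mm3,
        bias_amplitude=sim.bias_amplitude,
        noise_sd=sim.noise_sd,
        max_translation=sim.max_translation,
        max_rotation_deg=sim.max_rotation_deg,
    )
    t0 = time.perf_counter()
    train_set = phantoms.make_phantom_set(
        sim.n_atlases, seed=log.seed("simulate.atlases", cfg.seed), base=base, volume_sd_mm3=sim.volume_sd_mm3
    )
    truth_rows = []
    for i, (vol, ml, mr) in enumerate(train_set):
        write_volume(vol, atlas_dir / f"atlas-{i:02d}_scan.nii.gz")
        write_mask(ml, atlas_dir / f"atlas-{i:02d}_mask_left.nii.gz")
        write_mask(mr, atlas_dir / f"atlas-{i:02d}_mask_right.nii.gz")
        truth_rows.append({"id": f"atlas-{i:02d}", "set": "train"})
    test_set = phantoms.make_phantom_set(
        sim.n_test, seed=log.seed("simulate.test", cfg.seed + 10_000), base=base, volume_sd_mm3=sim.volume_sd_mm3
    )
    for i, (vol, ml, mr) in enumerate(test_set):
        write_volume(vol, test_dir / f"test-{i:02d}_scan.nii.gz")
        write_mask(ml, test_dir / f"test-{i:02d}_truth_left.nii.gz")
        write_mask(mr, test_dir / f"test-{i:02d}_truth_right.nii.gz")
    log.stage("phantoms", t0)

    t0 = time.perf_counter()
    cohort_spec = phantoms.CohortSpec(
        n_ctrl=sim.cohort_n_ctrl,
        n_mci=sim.cohort_n_mci,
        n_ad=sim.cohort_n_ad,
        seed=log.seed("simulate.cohort", cfg.seed + 20_000),
    )
    cohort = phantoms.make_longitudinal(cohort_spec)
    cohort.to_csv(cfg.cohort_csv, index=False, float_format="%.6f")
    log.stage("cohort", t0)


def _cmd_template(cfg: RunConfig, log: _Log) -> None:
    atlas_dir = _require(cfg.atlas_dir, "hippoatlas simulate")
    scans = sorted(atlas_dir.glob("*_scan.nii.gz"))
    if not scans:
        raise PipelineError(f"missing prerequisite artifact: no *_scan.nii.gz in {atlas_dir} — run `hippoatlas simulate` first")
    seg = _segmentation_config(cfg)
    t0 = time.perf_counter()
    volumes = []
    for p in scans:
        v = preprocess.normalize_intensity(read_volume(p))
        if seg.apply_bias_correction:
            v = preprocess.correct_bias(v, order=seg.bias_order)
        volumes.append(v)
    template = preprocess.build_template(
        volumes, iterations=cfg.segmentation.template_iterations, levels=seg.registration_levels
    )
    write_volume(template.volume, cfg.template_path)
    log.stage("template", t0)


def _cmd_train(cfg: RunConfig, log: _Log) -> None:
    atlas_dir = _require(cfg.atlas_dir, "hippoatlas simulate")
    template_path = _require(cfg.template_path, "hippoatlas template")
    scan_paths = sorted(atlas_dir.glob("*_scan.nii.gz"))
    if not scan_paths:
        raise PipelineError(f"missing prerequisite artifact: no *_scan.nii.gz in {atlas_dir} — run `hippoatlas simulate` first")
    template = preprocess.Template(read_volume(template_path), [], 0)
    scans, masks, ids = [], {"left": [], "right": []}, []
    for p in scan_paths:
        sid = p.name.replace("_scan.nii.gz", "")
        scans.append(read_volume(p))
        masks["left"].append(read_mask(atlas_dir / f"{sid}_mask_left.nii.gz"))
        masks["right"].append(read_mask(atlas_dir / f"{sid}_mask_right.nii.gz"))
        ids.append(sid)
    t0 = time.perf_counter()
    entries, context = fusion.train_atlases(
        scans, masks, template, _segmentation_config(cfg), seed=log.seed("train", cfg.seed + 30_000), atlas_ids=ids
    )
    log.stage("train", t0)
    model_dir = cfg.output_dir / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    (model_dir / "atlases.json").write_text(json.dumps([e.to_dict() for e in entries], sort_keys=True))
    context.save(model_dir / "context.json")


def _cmd_segment(cfg: RunConfig, log: _Log) -> None:
    template_path = _require(cfg.template_path, "hippoatlas template")
    model_dir = cfg.output_dir / "models"
    _require(model_dir / "atlases.json", "hippoatlas train")
    _require(model_dir / "context.json", "hippoatlas train")
    test_dir = _require(cfg.test_dir, "hippoatlas simulate")
    test_paths = sorted(test_dir.glob("*_scan.nii.gz"))
    if not test_paths:
        raise PipelineError(f"missing prerequisite artifact: no *_scan.nii.gz in {test_dir} — run `hippoatlas simulate` first")

    template = preprocess.Template(read_volume(template_path), [], 0)
    entries = [fusion.AtlasEntry.from_dict(d) for d in json.loads((model_dir / "atlases.json").read_text())]
    context = fusion.TrainingContext.load(model_dir / "context.json")
    seg_cfg = _segmentation_config(cfg)
    seg_dir = cfg.output_dir / "segmentations"
    seg_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for p in test_paths:
        sid = p.name.replace("_scan.nii.gz", "")
        t0 = time.perf_counter()
        result = fusion.segment_subject(read_volume(p), entries, template, context, seg_cfg)
        log.stage(f"segment:{sid}", t0)
        for side, res in (("left", result.left), ("right", result.right)):
            write_mask(res.mask, seg_dir / f"{sid}_seg_{side}.nii.gz")
            rows.append(
                {
                    "id": sid,
                    "side": side,
                    "volume_mm3": round(res.volume_mm3, 6),
                    "threshold_t": round(res.threshold.threshold, 6),
                    "weights_r": ";".join(f"{aid}:{r:.4f}" for aid, r in res.ranking.selected),
                    "registration_converged": result.registration_converged,
                }
            )
    pd.DataFrame(rows).to_csv(seg_dir / "volumes.csv", index=False)


def _cmd_diagnose(cfg: RunConfig, log: _Log) -> None:
    cohort_path = _require(cfg.cohort_csv, "hippoatlas simulate")
    records = pd.read_csv(cohort_path)
    t0 = time.perf_counter()
    report = build_diagnostic_report(
        records,
        n_boot=cfg.diagnostics.n_boot,
        nb_folds=cfg.diagnostics.nb_folds,
        nb_rounds=cfg.diagnostics.nb_rounds,
        seed=log.seed("diagnose", cfg.seed + 40_000),
    )
    log.stage("diagnose", t0)
    (cfg.output_dir / "diagnostic_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))


def build_diagnostic_report(
    records: pd.DataFrame,
    n_boot: int = 500,
    nb_folds: int = 10,
    nb_rounds: int = 100,
    seed: int = 0,
    reference_mean: float = 2650.2,
) -> dict:
    """Full volumetric analysis of a cohort table (see module docstring).

    Produces precision (screening vs repeat), cross-timepoint correlations,
    the control aging model, detrended-volume AUC per timepoint for both
    CTRL–AD and CTRL–MCI, a Kruskal–Wallis test, and the three-class Naive
    Bayes table.
    """
    report: dict = {}
    timepoints = [t for t in diag.TIMEPOINTS if t in set(records["timepoint"])]
    screening = records[records["timepoint"] == timepoints[0]].reset_index(drop=True)

    if "screening" in timepoints and "repeat" in timepoints:
        wide = records.pivot(index="id", columns="timepoint", values="v_left_mm3")
        pairs = wide[["screening", "repeat"]].dropna().to_numpy()
        rep = diag.precision_report(pairs, reference_mean)
        report["precision"] = {
            "n_pairs": rep.n_pairs,
            "mean_residual_mm3": rep.mean_residual,
            "sd_residual_mm3": rep.sd_residual,
            "precision_percent": rep.precision_percent,
            "p_zero_mean": rep.p_zero_mean,
        }
        corr = diag.timepoint_correlations(records)
        report["timepoint_correlations"] = {
            side: {"timepoints": list(mat.columns), "r": mat.to_numpy().round(6).tolist()}
            for side, mat in corr.items()
        }

    t0_cohort = float(records["age"].min())
    ctrl = screening[screening["group"] == "CTRL"]
    aging = {}
    auc_table: dict = {}
    for side in ("left", "right"):
        model = diag.fit_aging_model(ctrl, side=side, t0=t0_cohort)
        aging[side] = {
            "v0_mm3": model.v0,
            "k_mm3_per_year": model.k,
            "t0_years": model.t0,
            "ci_k": list(model.ci_k),
            "r2": model.r2,
        }
        for tp in timepoints:
            sub = records[records["timepoint"] == tp]
            veff = diag.detrend(sub[f"v_{side}_mm3"].to_numpy(), sub["age"].to_numpy(), model)
            for task, pos_group in (("CTRL-AD", "AD"), ("CTRL-MCI", "MCI")):
                sel = sub["group"].isin(["CTRL", pos_group]).to_numpy()
                labels = (sub["group"].to_numpy()[sel] == pos_group).astype(int)
                roc = diag.roc_auc(veff[sel], labels)
                se_boot = diag.bootstrap_auc(veff[sel], labels, n_boot=n_boot, seed=seed + 17)
                auc_table.setdefault(tp, {}).setdefault(task, {})[side] = {
                    "auc": roc.auc,
                    "se_hanley_mcneil": roc.se_hanley_mcneil,
                    "se_bootstrap": se_boot,
                }
    report["aging_model"] = aging
    report["auc_detrended"] = auc_table

    kw = {}
    for side in ("left", "right"):
        groups = [screening[screening["group"] == g][f"v_{side}_mm3"].to_numpy() for g in diag.GROUPS]
        h, p = diag.kruskal_wallis(groups)
        kw[side] = {"H": h, "p": p}
    report["kruskal_wallis"] = kw

    nb = {}
    for feature_set in ("both", "left", "right"):
        res = diag.naive_bayes_3class(screening, feature_set, folds=nb_folds, rounds=nb_rounds, seed=seed + 23)
        nb[feature_set] = {k: {"mean": v[0], "sd": v[1]} for k, v in res.items()}
    report["naive_bayes_3class"] = nb
    return report


def run_pipeline(command: str, config: RunConfig) -> int:
    """Execute one pipeline command; returns 0 on success.

    Raises :class:`PipelineError` on missing prerequisites or stage failure
    (the CLI converts this into a non-zero exit status).
    """
    if command not in COMMANDS:
        raise PipelineError(f"unknown command {command!r}; expected one of {COMMANDS}")
    config.output_dir.mkdir(parents=True, exist_ok=True)
    log = _Log(command, config)
    log.seed("base", config.seed)
    handlers = {
        "simulate": _cmd_simulate,
        "template": _cmd_template,
        "train": _cmd_train,
        "segment": _cmd_segment,
        "diagnose": _cmd_diagnose,
    }
    handlers[command](config, log)
    log.write(config.output_dir, command)
    return 0
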