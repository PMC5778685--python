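"""Run configuration: validated, defaulted, serializable as JSON or YAML.

Unknown keys are rejected (typos must fail loudly), every stochastic stage
draws from a named seed, and a saved configuration round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    output_dir: str = "out"
    template: str | None = None  # defaults to <output_dir>/template.nii.gz
    atlas_dir: str | None = None  # defaults to <output_dir>/atlases
    test_dir: str | None = None  # defaults to <output_dir>/test
    cohort_csv: str | None = None  # defaults to <output_dir>/cohort.csv


class SimulateConfig(_Strict):
    n_atlases: int = 10
    n_test: int = 5
    grid: int = 64
    volume_mean_mm3: float = 2650.2
    volume_sd_mm3: float = 150.0
    bias_amplitude: float = 0.2
    noise_sd: float = 0.02
    max_translation: float = 3.0
    max_rotation_deg: float = 5.0
    cohort_n_ctrl: int = 145
    cohort_n_mci: int = 217
    cohort_n_ad: int = 94


class SegmentationSettings(_Strict):
    m_atlases: int = 10
    voi_padding: int = 2
    moment_sizes: list[int] = Field(default_factory=lambda: [3, 5, 7, 9])
    haralick_box: int = 5
    haralick_levels: int = 8
    haar_sizes: list[int] = Field(default_factory=lambda: [3, 5, 7, 9])
    hidden_units: int = 10
    learning_rate: float = 0.01
    epochs: int = 50
    batch_size: int = 32
    max_train_voxels: int = 6000
    cv_folds: int = 5
    cv_repeats: int = 2
    bias_order: int = 2
    apply_bias_correction: bool = True
    template_iterations: int = 2
    registration_levels: int = 3
    nonlinear_iterations: int = 5
    nonlinear_smoothness: float = 1.5


class DiagnosticsConfig(_Strict):
    n_boot: int = 500
    nb_folds: int = 10
    nb_rounds: int = 100


class RunConfig(_Strict):
    paths: PathsConfig = Field(default_factory=PathsConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    segmentation: SegmentationSettings = Field(default_factory=SegmentationSettings)
    diagnostics: DiagnosticsConfig = Field(default_factory=DiagnosticsConfig)
    seed: int = 0

    # resolved path helpers -------------------------------------------------
    @property
    def output_dir(self) -> Path:
        return Path(self.paths.output_dir)

    @property
    def template_path(self) -> Path:
        return Path(self.paths.template) if self.paths.template else self.output_dir / "template.nii.gz"

    @property
    def atlas_dir(self) -> Path:
        return Path(self.paths.atlas_dir) if self.paths.atlas_dir else self.output_dir / "atlases"

    @property
    def test_dir(self) -> Path:
        return Path(self.paths.test_dir) if self.paths.test_dir else self.output_dir / "test"

    @property
    def cohort_csv(self) -> Path:
        return Path(self.paths.cohort_csv) if self.paths.cohort_csv else self.output_dir / "cohort.csv"

    def parameter_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON or YAML run configuration; an empty file means all defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
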