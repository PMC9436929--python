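"""Pipeline configuration: YAML-backed, validated, with study defaults.

Every analysis constant has a named, defaulted key: the QC window
(500-2500 UMI, 20% mito), the normalization scale, the age-gene thresholds
(CO 0.0019, FDR 5%), the 5% mode span threshold, the clock settings
(10 folds, 100 lambdas, elastic-net mixing 0.5, 500 trees with 100-
observation node floor) and the variant filters (TLOD 5.3, exome depth 10,
3 reads at > 50% within a UMI, 2-allele cap).  Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_cross: int = 16
    n_long: int = 8
    age_min: float = 0.0
    age_max: float = 90.0
    visits_per_long: int = 2
    visit_gap_mean: float = 9.0
    cells_per_visit: int = 120
    cell_age_jitter_sd: float = 5.0
    include_clock_panel: bool = True
    n_percentage_genes: int = 8
    n_expression_genes: int = 8
    n_both_genes: int = 4
    n_null_genes: int = 10
    n_background_genes: int = 140
    burden_rate0: float = 2.0
    burden_coef_log_umi: float = 0.4
    burden_coef_log_cell_cov: float = 0.3
    burden_coef_log_exome_cov: float = 0.2
    burden_coef_cell_age: float = 0.02
    variant_error_rate: float = 0.002

    @model_validator(mode="after")
    def _check(self):
        if self.age_max <= self.age_min:
            raise ValueError("age_max must exceed age_min")
        return self


class QCConfig(_Strict):
    umi_min: int = 500
    umi_max: int = 2500
    mito_max: float = 0.20
    norm_scale: float = 10000.0

    @model_validator(mode="after")
    def _check(self):
        if self.umi_min > self.umi_max:
            raise ValueError("umi_min must not exceed umi_max")
        if not 0 < self.mito_max <= 1:
            raise ValueError("mito_max must be in (0, 1]")
        if self.norm_scale <= 0:
            raise ValueError("norm_scale must be positive")
        return self


class AgeGenesConfig(_Strict):
    co_threshold: float = 0.0019
    q_threshold: float = 0.05
    min_detect_frac: float = 0.01


class ModesConfig(_Strict):
    span_threshold: float = 0.05
    relative_level: bool = True
    min_cells_per_donor_visit: int = 3


class ClockConfig(_Strict):
    learner: str = "meen"  # "meen" | "merf"
    l1_ratio: float = 0.5
    lam: float | None = None  # None -> tuned by CV
    n_folds: int = 10
    n_lambda: int = 100
    n_trees: int = 500
    min_node: int = 100
    tol: float = 1e-4
    max_iter: int = 50
    fold_mode: str = "cell"  # "cell" | "donor"

    @model_validator(mode="after")
    def _check(self):
        if self.learner not in ("meen", "merf"):
            raise ValueError("learner must be 'meen' or 'merf'")
        if self.fold_mode not in ("cell", "donor"):
            raise ValueError("fold_mode must be 'cell' or 'donor'")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        return self


class MutationsConfig(_Strict):
    tlod_min: float = 5.3
    exome_depth_min: int = 10
    snps_only: bool = True
    min_umi_reads: int = 3
    min_umi_fraction: float = 0.5
    max_alleles: int = 2


class PipelineConfig(_Strict):
    seed: int = 0
    out_dir: str = "tcellclock_run"
    simulate: SimulateConfig = SimulateConfig()
    qc: QCConfig = QCConfig()
    agegenes: AgeGenesConfig = AgeGenesConfig()
    modes: ModesConfig = ModesConfig()
    clock: ClockConfig = ClockConfig()
    mutations: MutationsConfig = MutationsConfig()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def default_config(**overrides) -> PipelineConfig:
    return PipelineConfig.model_validate(overrides)
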