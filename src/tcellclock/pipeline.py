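"""End-to-end seeded pipeline: simulate -> qc -> age genes -> modes ->
clock -> mutations, with TSV outputs and a JSON run manifest."""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clock, io, modes, mutations, qc, simulate
from .agegenes import detect_age_genes
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Run the full synthetic-to-result pipeline; returns a run report.

    Identical config + seed yields identical outputs.  Each stage failure
    aborts with a stage-tagged :class:`StageError`.
    """
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # ---- simulate -------------------------------------------------------
    name = stage("simulate")
    try:
        sc = config.simulate
        donors = simulate.generate_cohort(
            sc.n_cross, sc.n_long, (sc.age_min, sc.age_max),
            sc.visits_per_long, sc.visit_gap_mean, seed=config.seed,
        )
        panel = simulate.default_gene_panel(
            sc.n_percentage_genes, sc.n_expression_genes, sc.n_both_genes,
            sc.n_null_genes, sc.n_background_genes, seed=config.seed,
        )
        if sc.include_clock_panel:
            panel = panel + simulate.clock_gene_panel(
                n_background=0, seed=config.seed
            )
        sim = simulate.CellSimSpec(
            cells_per_visit=sc.cells_per_visit,
            subset_composition=simulate.default_subset_composition(),
            cell_age_jitter_sd=sc.cell_age_jitter_sd,
            subset_age_offsets=simulate.default_subset_age_offsets(),
            seed=config.seed,
        )
        adata = simulate.generate_counts(donors, panel, sim)
        burden_model = simulate.BurdenModel(
            rate0=sc.burden_rate0,
            coef_log_umi=sc.burden_coef_log_umi,
            coef_log_cell_cov=sc.burden_coef_log_cell_cov,
            coef_log_exome_cov=sc.burden_coef_log_exome_cov,
            coef_cell_age=sc.burden_coef_cell_age,
        )
        evidence = simulate.generate_variant_evidence(
            adata, burden_model, error_rate=sc.variant_error_rate,
            seed=config.seed,
        )
        report["stages"]["simulate"] = {
            "n_donors": len(donors),
            "n_cells": int(adata.n_obs),
            "n_genes": int(adata.n_vars),
            "n_evidence_records": len(evidence),
        }
        if write_outputs:
            io.write_matrix(adata, out / "raw_matrix")
            io.write_evidence(evidence, out / "variant_evidence.tsv")
    except Exception as err:
        raise StageError(name, err) from err

    # ---- qc -------------------------------------------------------------
    name = stage("qc")
    try:
        adata, qc_report = qc.filter_cells(
            adata, config.qc.umi_min, config.qc.umi_max, config.qc.mito_max
        )
        adata = qc.log2_normalize(adata, scale=config.qc.norm_scale)
        props = qc.subset_proportions(adata)
        trends = qc.proportion_trends(props)
        report["stages"]["qc"] = {
            "kept_cells": qc_report.n_kept,
            "removed": qc_report.n_input - qc_report.n_kept,
        }
        report["stages"]["proportion_trends"] = trends.set_index("subset")[
            "slope"
        ].to_dict()
        if write_outputs:
            qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t",
                                        index=False)
            props.to_csv(out / "subset_proportions.tsv", sep="\t", index=False)
            trends.to_csv(out / "proportion_trends.tsv", sep="\t", index=False)
    except Exception as err:
        raise StageError(name, err) from err

    # ---- age genes ------------------------------------------------------
    name = stage("agegenes")
    try:
        ag = detect_age_genes(
            adata, subset=None,
            co_threshold=config.agegenes.co_threshold,
            q_threshold=config.agegenes.q_threshold,
            min_detect_frac=config.agegenes.min_detect_frac,
        )
        sig = ag[ag["significant"]]
        report["stages"]["agegenes"] = {
            "tested": int(len(ag)),
            "significant": int(len(sig)),
            "up": int((sig["direction"] == "up").sum()),
            "down": int((sig["direction"] == "down").sum()),
        }
        if write_outputs:
            ag.to_csv(out / "age_genes.tsv", sep="\t")
    except Exception as err:
        raise StageError(name, err) from err

    # ---- modes ----------------------------------------------------------
    name = stage("modes")
    try:
        calls = modes.classify_modes(
            adata, list(sig.index), subset=None,
            span_threshold=config.modes.span_threshold,
            relative_level=config.modes.relative_level,
            min_cells=config.modes.min_cells_per_donor_visit,
        )
        summary = modes.mode_summary(calls)
        report["stages"]["modes"] = summary["n_genes"].to_dict()
        if write_outputs:
            calls.to_csv(out / "mode_calls.tsv", sep="\t")
            summary.to_csv(out / "mode_summary.tsv", sep="\t")
    except Exception as err:
        raise StageError(name, err) from err

    # ---- clock ----------------------------------------------------------
    name = stage("clock")
    try:
        cc = config.clock
        X, feats, y, groups = clock.make_features(adata)
        if cc.learner == "meen":
            lam = cc.lam
            if lam is None:
                lam, _ = clock.tune_meen(
                    X, y, groups, n_folds=cc.n_folds, n_lambda=cc.n_lambda,
                    l1_ratio=cc.l1_ratio, seed=config.seed,
                )
            learner = clock.ElasticNetSpec(lam=lam, l1_ratio=cc.l1_ratio)
        else:
            learner = clock.ForestSpec(
                n_trees=cc.n_trees, min_node=cc.min_node, seed=config.seed
            )
        preds, rmse, r = clock.cross_validate_clock(
            X, y, groups, learner, n_folds=cc.n_folds, seed=config.seed,
            tol=cc.tol, max_iter=cc.max_iter, fold_mode=cc.fold_mode,
            feature_names=feats,
        )
        preds.index = adata.obs_names
        model = clock.fit_mixed_ml(
            X, y, groups, learner, tol=cc.tol, max_iter=cc.max_iter,
            feature_names=feats,
        )
        naive_mask = adata.obs["subset"] == "Na"
        by_donor = (
            pd.DataFrame(
                {
                    "donor_id": adata.obs["donor_id"].to_numpy(),
                    "naive": naive_mask.to_numpy(),
                    "pred": preds["predicted_age"].to_numpy(),
                }
            )
            .groupby(["donor_id", "naive"], observed=True)["pred"]
            .mean()
            .unstack()
        )
        frac_naive_younger = float(
            (by_donor[True] < by_donor[False]).mean()
        ) if True in by_donor and False in by_donor else np.nan
        report["stages"]["clock"] = {
            "learner": cc.learner,
            "cv_rmse_years": rmse,
            "cv_pearson_r": r,
            "fraction_donors_naive_younger": frac_naive_younger,
        }
        if write_outputs:
            preds.to_csv(out / "cell_age_predictions.tsv", sep="\t")
            if cc.learner == "meen":
                clock.save_model(model, out / "clock_model.json")
                pd.DataFrame(
                    {"feature": feats, "coef": model.learner.coef_}
                ).to_csv(out / "clock_coefficients.tsv", sep="\t", index=False)
    except Exception as err:
        raise StageError(name, err) from err

    # ---- mutations ------------------------------------------------------
    name = stage("mutations")
    try:
        mc = config.mutations
        kept_evidence = [
            ev for ev in evidence if ev.cell_id in set(adata.obs_names)
        ]
        surviving = mutations.filter_pipeline(
            kept_evidence, mc.tlod_min, mc.exome_depth_min, mc.snps_only,
            mc.min_umi_reads, mc.min_umi_fraction, mc.max_alleles,
        )
        covs = pd.DataFrame(
            {
                "cell_umi_total": adata.obs["total_umi"].astype(float),
                "cell_coverage": adata.obs["cell_coverage"].astype(float),
                "donor_exome_coverage": adata.obs[
                    "donor_exome_coverage"
                ].astype(float),
            }
        )
        burden, nb_info = mutations.count_and_adjust(surviving, covs)
        slopes = mutations.burden_vs_predicted_age(
            burden, preds, adata.obs
        )
        report["stages"]["mutations"] = {
            "evidence_records": len(kept_evidence),
            "surviving_records": len(surviving),
            "nb_family": nb_info["family"],
            "burden_slopes": slopes.set_index("subset")["slope"].to_dict(),
            "burden_p_values": slopes.set_index("subset")[
                "p_value"
            ].to_dict(),
        }
        if write_outputs:
            burden.to_csv(out / "mutation_burden.tsv", sep="\t")
            slopes.to_csv(out / "burden_vs_age.tsv", sep="\t", index=False)
    except Exception as err:
        raise StageError(name, err) from err

    # ---- manifest -------------------------------------------------------
    manifest = {
        "tcellclock_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.model_dump(),
        "report": report,
    }
    if write_outputs:
        (out / "run_manifest.json").write_text(
            json.dumps(manifest, indent=1, default=float)
        )
        lines = ["tcellclock run summary", "======================"]
        for sname, vals in report["stages"].items():
            lines.append(f"[{sname}] {vals}")
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return manifest
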