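"""Classify age-associated genes by their mode of expression change.

A gene whose expression shifts with age can do so because more (or fewer)
cells express it at all, because expressing cells change their level, or
both.  For each gene and subset the two readouts are summarized per
donor-visit — the fraction of cells with a nonzero raw UMI count, and the
mean log2-normalized expression among those positive cells — and each is
regressed on age (with sex as a covariate and a donor random intercept).
The projected change over the cohort's age span is compared with a 5%
threshold: genes exceeding it in one readout are labeled ``percentage`` or
``expression``, in both ``both``, in neither ``unclassified``.

The level-change threshold is applied relative to the gene's cohort-mean
positive expression by default (the natural reading of "a 5% change in
expression level"); an absolute-scale variant is available via
``relative_level=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agegenes import fit_melr

logger = logging.getLogger(__name__)

SPAN_THRESHOLD = 0.05


@dataclass
class ModeCall:
    gene_id: str
    subset: str
    percent_slope: float  # proportion per year
    level_slope: float  # log2norm units per year
    percent_span_change: float  # proportion over the cohort span
    level_span_change_rel: float  # fraction of cohort-mean positive expr
    mode: str  # percentage | expression | both | unclassified
    n_donor_visits: int
    insufficient_data: bool = False


def per_donor_gene_summaries(
    adata,
    gene: str,
    subset: str | None = None,
    min_cells: int = 3,
    layer: str = "log2norm",
) -> pd.DataFrame:
    """Per donor-visit detection fraction and positive-cell mean expression.

    ``pct_expressing`` is the fraction of the donor-visit's subset cells
    with raw UMI > 0; ``mean_positive_expr`` the mean log2-normalized value
    over those cells (NaN when no cell is positive).  Donor-visits with
    fewer than ``min_cells`` subset cells are dropped (stability floor).
    """
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not in matrix")
    if layer not in adata.layers:
        raise ValueError("log2-normalized layer required")
    mask = (
        np.ones(adata.n_obs, bool)
        if subset is None
        else (adata.obs["subset"] == subset).to_numpy()
    )
    sub = adata[mask, gene]
    raw = np.asarray(
        sub.X.todense() if hasattr(sub.X, "todense") else sub.X
    ).ravel()
    expr = np.asarray(
        sub.layers[layer].todense()
        if hasattr(sub.layers[layer], "todense")
        else sub.layers[layer]
    ).ravel()
    df = pd.DataFrame(
        {
            "donor_id": sub.obs["donor_id"].to_numpy(),
            "visit_id": sub.obs["visit_id"].to_numpy(),
            "age_years": sub.obs["age_years"].to_numpy(dtype=float),
            "sex": sub.obs["sex"].to_numpy(),
            "group_id": sub.obs["group_id"].to_numpy(),
            "positive": raw > 0,
            "expr": expr,
        }
    )
    rows = []
    for (donor, visit), grp in df.groupby(
        ["donor_id", "visit_id"], observed=True, sort=True
    ):
        if len(grp) < min_cells:
            continue
        pos = grp.loc[grp["positive"], "expr"]
        rows.append(
            {
                "donor_id": donor,
                "visit_id": visit,
                "age_years": grp["age_years"].iloc[0],
                "sex": grp["sex"].iloc[0],
                "group_id": grp["group_id"].iloc[0],
                "n_cells": len(grp),
                "pct_expressing": grp["positive"].mean(),
                "mean_positive_expr": pos.mean() if len(pos) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def classify_mode(
    summaries: pd.DataFrame,
    cohort_age_span: float,
    gene_id: str = "",
    subset: str = "all",
    span_threshold: float = SPAN_THRESHOLD,
    relative_level: bool = True,
) -> ModeCall:
    """Assign the mode of age-related change from donor-visit summaries.

    Both measures are fit with ``measure ~ age + sex + (1|group)``; the
    absolute slope times ``cohort_age_span`` gives the span change.  The
    percentage span change is in proportion units; the level span change is
    divided by the cohort-mean positive expression when ``relative_level``.
    """
    n = len(summaries)
    level_rows = summaries.dropna(subset=["mean_positive_expr"])
    if n < 3 or len(level_rows) < 3:
        return ModeCall(
            gene_id=gene_id, subset=subset, percent_slope=np.nan,
            level_slope=np.nan, percent_span_change=np.nan,
            level_span_change_rel=np.nan, mode="unclassified",
            n_donor_visits=n, insufficient_data=True,
        )
    pct_fit = fit_melr(
        summaries["pct_expressing"], summaries["age_years"],
        summaries["sex"], summaries["group_id"],
    )
    lvl_fit = fit_melr(
        level_rows["mean_positive_expr"], level_rows["age_years"],
        level_rows["sex"], level_rows["group_id"],
    )
    pct_span = abs(pct_fit.age_slope) * cohort_age_span
    lvl_span = abs(lvl_fit.age_slope) * cohort_age_span
    if relative_level:
        ref = level_rows["mean_positive_expr"].mean()
        lvl_span_rel = lvl_span / ref if ref > 0 else np.nan
    else:
        lvl_span_rel = lvl_span
    pct_hit = pct_span >= span_threshold
    lvl_hit = np.isfinite(lvl_span_rel) and lvl_span_rel >= span_threshold
    if pct_hit and lvl_hit:
        mode = "both"
    elif pct_hit:
        mode = "percentage"
    elif lvl_hit:
        mode = "expression"
    else:
        mode = "unclassified"
    return ModeCall(
        gene_id=gene_id, subset=subset,
        percent_slope=pct_fit.age_slope, level_slope=lvl_fit.age_slope,
        percent_span_change=pct_span, level_span_change_rel=float(lvl_span_rel),
        mode=mode, n_donor_visits=n,
    )


def classify_modes(
    adata,
    genes,
    subset: str | None = None,
    span_threshold: float = SPAN_THRESHOLD,
    relative_level: bool = True,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Mode calls for a list of genes; every gene gets exactly one label."""
    ages = adata.obs["age_years"].to_numpy(dtype=float)
    span = float(np.ptp(ages))
    calls = []
    for gene in genes:
        summ = per_donor_gene_summaries(
            adata, gene, subset=subset, min_cells=min_cells
        )
        calls.append(
            classify_mode(
                summ, span, gene_id=gene,
                subset=subset if subset is not None else "all",
                span_threshold=span_threshold,
                relative_level=relative_level,
            )
        )
    return pd.DataFrame([c.__dict__ for c in calls]).set_index("gene_id")


def mode_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per mode (partition over the input genes)."""
    counts = (
        calls["mode"]
        .value_counts()
        .reindex(["percentage", "expression", "both", "unclassified"])
        .fillna(0)
        .astype(int)
    )
    return pd.DataFrame(
        {"n_genes": counts, "fraction": counts / max(counts.sum(), 1)}
    )
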