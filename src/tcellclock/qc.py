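"""Cell QC, depth normalization, composition trends, and cluster matching.

QC keeps cells whose UMI total lies inside an inclusive window (default
[500, 2500]) and whose mitochondrial fraction does not exceed 20%; the
window excludes shallow/broken cells below and likely doublets above.
Normalization is log2(1 + count / total_umi * scale) per cell.  Composition
trends fit per-subset percentages against donor age with the shared
random-intercept engine, and cluster matching compares marker profiles of
two cluster sets (e.g. flow cytometry vs scRNA-seq) by Spearman rank
correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .agegenes import fit_melr

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    n_input: int
    n_low_umi: int
    n_high_umi: int
    n_high_mito: int
    n_kept: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["input", "umi_low", "umi_high", "mito_high", "kept"],
                "cells": [
                    self.n_input, self.n_low_umi, self.n_high_umi,
                    self.n_high_mito, self.n_kept,
                ],
            }
        )


def filter_cells(
    adata: ad.AnnData,
    umi_min: int = 500,
    umi_max: int = 2500,
    mito_max: float = 0.20,
):
    """Remove low-quality cells; returns ``(filtered, QCReport)``.

    Retains cells with ``umi_min <= total_umi <= umi_max`` (bounds
    inclusive) and ``mito_frac <= mito_max`` (strictly greater is removed).
    Per-rule removal counts overlap when a cell fails several rules.
    """
    if adata.uns.get("normalized", False):
        raise ValueError("filter_cells expects a raw matrix")
    umi = adata.obs["total_umi"].to_numpy(dtype=float)
    mito = adata.obs["mito_frac"].to_numpy(dtype=float)
    low, high, dirty = umi < umi_min, umi > umi_max, mito > mito_max
    keep = ~(low | high | dirty)
    report = QCReport(
        n_input=adata.n_obs,
        n_low_umi=int(low.sum()),
        n_high_umi=int(high.sum()),
        n_high_mito=int(dirty.sum()),
        n_kept=int(keep.sum()),
    )
    if report.n_kept == 0:
        warnings.warn("QC removed every cell", stacklevel=2)
    return adata[keep].copy(), report


def log2_normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Add a ``log2norm`` layer: log2(1 + count / total_umi * scale)."""
    if adata.uns.get("normalized", False):
        raise ValueError("matrix is already normalized")
    totals = adata.obs["total_umi"].to_numpy(dtype=float)
    if (totals <= 0).any():
        raise ValueError("zero-total cell encountered; run QC first")
    X = adata.X
    dense = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    out = adata.copy()
    out.layers["log2norm"] = np.log2(
        1.0 + dense / totals[:, None] * scale
    )
    out.uns["normalized"] = True
    out.uns["norm_scale"] = float(scale)
    return out


def subset_proportions(adata: ad.AnnData) -> pd.DataFrame:
    """Per donor-visit subset percentages (summing to 100).

    Every observed subset gets a row for every donor-visit, including 0%
    rows for absent subsets.
    """
    obs = adata.obs
    key = ["donor_id", "visit_id", "age_years", "sex", "group_id"]
    counts = (
        obs.groupby(key + ["subset"], observed=False, sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    # complete the (donor-visit x subset) grid with zeros
    visits = obs[key].drop_duplicates()
    subsets = pd.DataFrame({"subset": sorted(obs["subset"].unique())})
    grid = visits.merge(subsets, how="cross")
    counts = grid.merge(counts, on=key + ["subset"], how="left").fillna(
        {"n_cells": 0}
    )
    totals = counts.groupby(["donor_id", "visit_id"], observed=True)[
        "n_cells"
    ].transform("sum")
    counts["percent"] = 100.0 * counts["n_cells"] / totals
    return counts.drop(columns="n_cells")


def proportion_trends(proportions: pd.DataFrame) -> pd.DataFrame:
    """Fit percent ~ age + sex + (1|group) per subset.

    Returns one row per subset with the slope (percentage points per year)
    and a two-sided t-test p-value (n - 2 df).  Subsets with fewer than 3
    donor-visits report the slope with ``p_value = nan`` (or nan slope when
    a fit is impossible).
    """
    rows = []
    for subset, grp in proportions.groupby("subset", observed=True):
        n = len(grp)
        if n < 3:
            slope = np.nan
            if n == 2:
                a, p = grp["age_years"].to_numpy(), grp["percent"].to_numpy()
                if a[1] != a[0]:
                    slope = (p[1] - p[0]) / (a[1] - a[0])
            rows.append(
                {
                    "subset": subset, "slope": slope, "p_value": np.nan,
                    "n_donor_visits": n,
                }
            )
            continue
        fit = fit_melr(
            grp["percent"], grp["age_years"], grp["sex"], grp["group_id"]
        )
        rows.append(
            {
                "subset": subset,
                "slope": fit.age_slope,
                "p_value": fit.p_value,
                "n_donor_visits": n,
            }
        )
    return pd.DataFrame(rows)


def match_subpopulations(
    marker_a: pd.DataFrame, marker_b: pd.DataFrame
):
    """Match clusters of two datasets by Spearman correlation of markers.

    ``marker_a`` / ``marker_b`` are clusters x markers tables sharing
    marker columns (e.g. mean flow-cytometry intensities vs mean gene
    expression for the 13 shared markers).  Returns
    ``(corr, matching, unmatched)`` where ``corr`` is the full Spearman
    matrix (rows = clusters of a, columns = clusters of b, ordered by
    average-linkage hierarchical clustering on 1 - rho), ``matching`` is a
    list of ``(cluster_a, cluster_b, rho)`` greedy best pairs, and
    ``unmatched`` lists leftover clusters from the larger side.
    """
    shared = [c for c in marker_a.columns if c in marker_b.columns]
    if len(shared) < 2:
        raise ValueError("need at least 2 shared marker columns")
    if len(marker_a) < 2 or len(marker_b) < 2:
        raise ValueError("need at least 2 clusters on each side")
    A = marker_a[shared].to_numpy(dtype=float)
    B = marker_b[shared].to_numpy(dtype=float)
    corr = np.full((len(A), len(B)), np.nan)
    for i in range(len(A)):
        if np.ptp(A[i]) == 0:
            warnings.warn(
                f"constant marker vector for cluster {marker_a.index[i]!r}",
                stacklevel=2,
            )
            continue
        for j in range(len(B)):
            if np.ptp(B[j]) == 0:
                continue
            corr[i, j] = stats.spearmanr(A[i], B[j]).statistic
    for j in range(len(B)):
        if np.ptp(B[j]) == 0:
            warnings.warn(
                f"constant marker vector for cluster {marker_b.index[j]!r}",
                stacklevel=2,
            )

    def leaf_order(dist_rows, n):
        if n < 3:
            return list(range(n))
        filled = np.nan_to_num(dist_rows, nan=2.0)
        # cluster the clusters by their correlation profiles
        Z = hierarchy.linkage(pdist(filled), method="average")
        return list(hierarchy.leaves_list(Z))

    order_a = leaf_order(1.0 - np.nan_to_num(corr, nan=-1.0), len(A))
    order_b = leaf_order(1.0 - np.nan_to_num(corr.T, nan=-1.0), len(B))
    corr_df = pd.DataFrame(
        corr, index=marker_a.index, columns=marker_b.index
    ).iloc[order_a, order_b]

    # greedy best-pair matching on the sorted matrix; ties by label order
    work = corr_df.copy()
    matching = []
    while work.shape[0] and work.shape[1] and work.notna().any().any():
        flat = work.stack()
        best = flat.idxmax()
        matching.append((best[0], best[1], float(flat.loc[best])))
        work = work.drop(index=best[0], columns=best[1])
    matched_a = {m[0] for m in matching}
    matched_b = {m[1] for m in matching}
    unmatched = [c for c in marker_a.index if c not in matched_a] + [
        c for c in marker_b.index if c not in matched_b
    ]
    return corr_df, matching, unmatched
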