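"""UMI-consensus variant filtering and mutation-burden adjustment.

Candidate somatic variants called per cell (e.g. by a Mutect2-style caller
run with the cell as "tumor" and the donor's exome as "normal") are
filtered in three stages:

1. **prefilter** — keep calls with TLOD > 5.3, exome depth > 10 and, by
   default, single-base ref/alt (SNPs only, indels removed);
2. **UMI consensus** — a variant is supported only if at least one UMI
   carries >= 3 alt reads making up strictly more than 50% of that UMI's
   reads (reads from one molecule should agree; split support marks a
   sequencing or amplification error);
3. **allele cap** — a diploid position can carry at most two alternate
   alleles, so positions in a cell with more than two distinct passing
   alts are dropped entirely.

The surviving per-cell counts are adjusted for technical covariates (cell
UMI total, cell coverage, donor exome coverage) with a log-link negative
binomial regression; the adjustment is the residual on the log2(count + 1)
scale, min-max rescaled back to [0, max raw count].  NB with a log link on
the raw counts is used rather than any model of log-transformed counts,
which would not be a coherent count model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .agegenes import fit_melr

logger = logging.getLogger(__name__)

TLOD_MIN = 5.3
EXOME_DEPTH_MIN = 10
MIN_UMI_READS = 3
MIN_UMI_FRACTION = 0.5
MAX_ALLELES = 2

COVARIATE_COLUMNS = ("cell_umi_total", "cell_coverage", "donor_exome_coverage")


@dataclass(frozen=True)
class VariantEvidence:
    """Per-cell candidate variant with UMI-resolution read support."""

    cell_id: str
    donor_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tlod: float
    exome_depth: int
    umi_support: tuple  # ((umi, alt_reads, total_reads), ...)

    def __post_init__(self):
        seen = set()
        for umi, alt_reads, total_reads in self.umi_support:
            if not 0 <= alt_reads <= total_reads:
                raise ValueError(
                    f"invalid read support {alt_reads}/{total_reads}"
                )
            if umi in seen:
                raise ValueError(f"duplicate UMI {umi!r} in record")
            seen.add(umi)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class MutationBurden:
    cell_id: str
    raw_count: int
    log2_count: float
    adjusted_count: float


def prefilter_variants(
    evidence,
    tlod_min: float = TLOD_MIN,
    exome_depth_min: int = EXOME_DEPTH_MIN,
    snps_only: bool = True,
) -> list:
    """Keep calls with tlod > tlod_min, depth > exome_depth_min, SNPs only."""
    return [
        ev
        for ev in evidence
        if ev.tlod > tlod_min
        and ev.exome_depth > exome_depth_min
        and (not snps_only or ev.is_snp)
    ]


def umi_consensus_filter(
    record: VariantEvidence,
    min_reads: int = MIN_UMI_READS,
    min_fraction: float = MIN_UMI_FRACTION,
) -> bool:
    """True iff some UMI has >= min_reads alt reads at a fraction > min_fraction.

    Zero-read UMIs are ignored with a warning.  Both conditions must hold
    within a single UMI: 3 alt of 4 reads passes, 2 of 2 fails (too few
    reads), 3 of 7 fails (43% is not a majority).
    """
    supported = False
    for umi, alt_reads, total_reads in record.umi_support:
        if total_reads == 0:
            warnings.warn(f"UMI {umi!r} has zero reads; ignored", stacklevel=2)
            continue
        if alt_reads >= min_reads and alt_reads / total_reads > min_fraction:
            supported = True
    return supported


def consensus_supported(
    evidence,
    min_reads: int = MIN_UMI_READS,
    min_fraction: float = MIN_UMI_FRACTION,
) -> list:
    return [
        ev
        for ev in evidence
        if umi_consensus_filter(ev, min_reads, min_fraction)
    ]


def position_allele_cap(supported, max_alleles: int = MAX_ALLELES) -> list:
    """Drop every record at a (cell, position) with > max_alleles distinct alts."""
    alts: dict = {}
    for ev in supported:
        alts.setdefault((ev.cell_id, ev.chrom, ev.pos), set()).add(ev.alt)
    return [
        ev
        for ev in supported
        if len(alts[(ev.cell_id, ev.chrom, ev.pos)]) <= max_alleles
    ]


def filter_pipeline(
    evidence,
    tlod_min: float = TLOD_MIN,
    exome_depth_min: int = EXOME_DEPTH_MIN,
    snps_only: bool = True,
    min_reads: int = MIN_UMI_READS,
    min_fraction: float = MIN_UMI_FRACTION,
    max_alleles: int = MAX_ALLELES,
) -> list:
    """Full filter chain: prefilter -> UMI consensus -> allele cap."""
    kept = prefilter_variants(evidence, tlod_min, exome_depth_min, snps_only)
    kept = consensus_supported(kept, min_reads, min_fraction)
    return position_allele_cap(kept, max_alleles)


# ---------------------------------------------------------------------------
# burden counting and covariate adjustment
# ---------------------------------------------------------------------------


def count_mutations(supported, cell_ids) -> pd.Series:
    """Surviving (cell, site, alt) records per cell, 0 for quiet cells."""
    counts = pd.Series(0, index=pd.Index(cell_ids, name="cell_id"), dtype=int)
    seen = set()
    for ev in supported:
        key = (ev.cell_id, ev.chrom, ev.pos, ev.alt)
        if key in seen:
            continue
        seen.add(key)
        if ev.cell_id in counts.index:
            counts.loc[ev.cell_id] += 1
    return counts


def count_and_adjust(
    supported,
    covariates: pd.DataFrame,
    rescale: bool = True,
):
    """Count mutations per cell and adjust for technical covariates.

    ``covariates`` is indexed by cell id with columns ``cell_umi_total``,
    ``cell_coverage`` and ``donor_exome_coverage``; every cell in the table
    is counted (cells with no surviving record get raw count 0), cells with
    missing covariates are dropped with a log entry.  The raw counts are
    regressed on the log covariates with a negative binomial (log link;
    Poisson fallback when the NB fit fails); the per-cell adjustment is
    ``log2(raw + 1) - log2(fitted + 1)``, min-max rescaled to
    ``[0, max raw count]`` when ``rescale``.

    Returns ``(burden, model_info)`` where ``burden`` is a DataFrame with
    ``raw_count``, ``log2_count``, ``expected_count`` and
    ``adjusted_count`` and ``model_info`` records the family, coefficients
    and dispersion.
    """
    missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariates missing columns: {missing}")
    cov = covariates[list(COVARIATE_COLUMNS)].astype(float)
    bad = cov.isna().any(axis=1) | (cov <= 0).any(axis=1)
    if bad.any():
        logger.info("dropping %d cells with missing/invalid covariates", bad.sum())
        cov = cov[~bad]
    if len(cov) < 10:
        raise ValueError("need at least 10 cells with covariates")
    raw = count_mutations(supported, cov.index)
    exog = sm.add_constant(np.log(cov.to_numpy()))
    endog = raw.to_numpy(dtype=float)

    family, fitted, params, alpha = "negative_binomial", None, None, np.nan
    if endog.var() == 0:
        # zero-variance counts: nothing to adjust, expected = observed mean
        warnings.warn(
            "mutation counts have zero variance; skipping regression",
            stacklevel=2,
        )
        family = "constant"
        fitted = np.full_like(endog, endog.mean())
        params = [float(endog.mean())]
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nb = sm.NegativeBinomial(endog, exog).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(nb.params)):
                raise ValueError("non-finite NB parameters")
            fitted = nb.predict(exog)
            params = nb.params[:-1]
            alpha = float(nb.params[-1])
        except Exception as err:  # separation, failed convergence, ...
            warnings.warn(
                f"negative binomial fit failed ({err}); "
                "falling back to Poisson",
                stacklevel=2,
            )
            family = "poisson"
            pois = sm.GLM(endog, exog, family=sm.families.Poisson()).fit()
            fitted = pois.predict(exog)
            params = pois.params

    log2_raw = np.log2(endog + 1.0)
    adj = log2_raw - np.log2(fitted + 1.0)
    max_raw = float(endog.max())
    if rescale:
        lo, hi = adj.min(), adj.max()
        adj = (
            (adj - lo) / (hi - lo) * max_raw
            if hi > lo
            else np.zeros_like(adj)
        )
    burden = pd.DataFrame(
        {
            "raw_count": raw,
            "log2_count": log2_raw,
            "expected_count": fitted,
            "adjusted_count": adj,
        },
        index=cov.index,
    )
    info = {
        "family": family,
        "coefficients": np.asarray(params, dtype=float).tolist(),
        "dispersion_alpha": alpha,
        "n_cells": int(len(cov)),
        "max_raw_count": max_raw,
    }
    return burden, info


def burden_vs_predicted_age(
    burden: pd.DataFrame,
    predictions: pd.DataFrame,
    cell_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-subset mixed regression of adjusted burden on predicted cell age.

    ``predictions`` must carry ``predicted_age`` and ``cell_meta`` the
    ``subset``, ``sex`` and ``group_id`` columns, all indexed by cell id.
    Returns one row per subset with slope, p (two-sided t, n - 2 df) and n;
    subsets with < 3 cells report NaN.
    """
    df = burden.join(predictions[["predicted_age"]], how="inner").join(
        cell_meta[["subset", "sex", "group_id"]], how="inner"
    )
    rows = []
    for subset, grp in df.groupby("subset", observed=True):
        if len(grp) < 3:
            rows.append(
                {
                    "subset": subset, "slope": np.nan, "p_value": np.nan,
                    "n_cells": len(grp),
                }
            )
            continue
        fit = fit_melr(
            grp["adjusted_count"], grp["predicted_age"], grp["sex"],
            grp["group_id"],
        )
        rows.append(
            {
                "subset": subset,
                "slope": fit.age_slope,
                "p_value": fit.p_value,
                "n_cells": len(grp),
            }
        )
    return pd.DataFrame(rows)
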