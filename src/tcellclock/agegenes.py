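"""Per-gene mixed-effect age regression (MELR) and significance calling.

The model is a random-intercept linear mixed model,

    expression ~ Age + Sex + (1 | group),

fit by restricted maximum likelihood.  For a single random intercept the
REML problem reduces to a one-dimensional profile over the variance ratio
theta = sigma_b^2 / sigma_e^2: for fixed theta the GLS estimates, the
profiled residual variance and the restricted log-likelihood are all
closed-form (the within-group covariance is compound-symmetric, so the
weighted cross-products need only per-group sums).  The solver therefore
scales to thousands of genes x thousands of cells.  With a single group the
random intercept is confounded with the fixed intercept and the fit reduces
exactly to ordinary least squares.

Significance of the age slope uses a two-sided t test with n - 2 degrees of
freedom; q-values are Benjamini-Hochberg within each subset, and a gene is
called significant when |CO| exceeds the effect-size floor (default 0.0019
log2-normalized units per year) and q < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: default effect-size floor on the age coefficient (log2norm units / year)
CO_THRESHOLD = 0.0019
#: default FDR threshold
Q_THRESHOLD = 0.05


@dataclass
class MelrFit:
    """Result of one random-intercept age regression."""

    intercept: float
    age_slope: float
    sex_coef: float
    slope_se: float
    p_value: float
    sigma_b2: float
    sigma_e2: float
    random_intercepts: dict
    n_obs: int
    n_groups: int
    singular: bool = False  # between-group variance hit the zero boundary
    constant_response: bool = False


def _group_sums(M, codes, n_groups):
    """Column-wise per-group sums of a 2-D array (groups x columns)."""
    out = np.zeros((n_groups, M.shape[1]))
    np.add.at(out, codes, M)
    return out


def fit_melr(y, age, sex, group) -> MelrFit:
    """Fit ``y ~ age + sex + (1 | group)`` by REML.

    Parameters
    ----------
    y, age : array-like of float
        Response and age (years), one entry per observation.
    sex : array-like
        0/1 (female/male) or "F"/"M" labels.
    group : array-like
        Random-effect group labels; all observations in one group reduce
        the model to OLS.

    Returns a :class:`MelrFit` with the fixed effects, the age-slope
    standard error and its two-sided t-test p-value on n - 2 degrees of
    freedom, the REML variance components, and the BLUP random intercepts.
    A constant response yields slope 0 with ``p_value = nan``.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "UOS":
        sex = (sex == "M").astype(float)
    sex = sex.astype(float)
    group = np.asarray(group)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    labels, codes = np.unique(group, return_inverse=True)
    q = labels.size

    if np.ptp(y) == 0.0:
        return MelrFit(
            intercept=float(y[0]), age_slope=0.0, sex_coef=0.0,
            slope_se=np.nan, p_value=np.nan, sigma_b2=0.0, sigma_e2=0.0,
            random_intercepts={g: 0.0 for g in labels}, n_obs=n,
            n_groups=q, singular=True, constant_response=True,
        )

    cols = [np.ones(n), age]
    has_sex = np.ptp(sex) > 0
    if has_sex:
        cols.append(sex)
    X = np.column_stack(cols)
    p = X.shape[1]

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    n_g = np.bincount(codes, minlength=q).astype(float)
    S = _group_sums(X, codes, q)  # q x p group sums of X
    t_g = np.bincount(codes, weights=y, minlength=q)  # group sums of y

    def weighted_parts(theta):
        c = theta / (1.0 + n_g * theta)  # shrink factor per group
        XtWX = XtX - (S * c[:, None]).T @ S
        XtWy = Xty - S.T @ (c * t_g)
        yWy = yty - float(c @ (t_g**2))
        return XtWX, XtWy, yWy

    def solve_beta(XtWX, XtWy):
        try:
            return np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]

    def neg2_reml(theta):
        XtWX, XtWy, yWy = weighted_parts(theta)
        beta = solve_beta(XtWX, XtWy)
        rss = max(yWy - float(beta @ XtWy), 1e-300)
        sign, logdet = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return (
            (n - p) * np.log(rss)
            + float(np.log1p(n_g * theta).sum())
            + logdet
        )

    if q == 1:
        theta_hat, singular = 0.0, True
    else:
        res = optimize.minimize_scalar(
            lambda u: neg2_reml(np.exp(u)),
            bounds=(-14.0, 14.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        theta_hat = float(np.exp(res.x))
        singular = False
        if neg2_reml(0.0) <= res.fun or theta_hat < 1e-10:
            theta_hat, singular = 0.0, True

    XtWX, XtWy, yWy = weighted_parts(theta_hat)
    beta = solve_beta(XtWX, XtWy)
    rss = max(yWy - float(beta @ XtWy), 0.0)
    sigma_e2 = rss / (n - p)
    sigma_b2 = theta_hat * sigma_e2

    # BLUPs: b_g = theta * n_g / (1 + theta * n_g) * mean residual in group
    resid = y - X @ beta
    r_g = np.bincount(codes, weights=resid, minlength=q)
    b = (theta_hat / (1.0 + n_g * theta_hat)) * r_g

    XtWX_inv = np.linalg.pinv(XtWX)
    slope_se = float(np.sqrt(max(sigma_e2 * XtWX_inv[1, 1], 0.0)))
    if slope_se > 0:
        tval = beta[1] / slope_se
        p_value = float(2.0 * stats.t.sf(abs(tval), df=n - 2))
    else:
        p_value = 0.0 if beta[1] != 0 else np.nan

    return MelrFit(
        intercept=float(beta[0]),
        age_slope=float(beta[1]),
        sex_coef=float(beta[2]) if has_sex else 0.0,
        slope_se=slope_se,
        p_value=p_value,
        sigma_b2=float(sigma_b2),
        sigma_e2=float(sigma_e2),
        random_intercepts={g: float(bi) for g, bi in zip(labels, b)},
        n_obs=n,
        n_groups=q,
        singular=singular,
    )


def detect_age_genes(
    adata,
    subset: str | None = None,
    co_threshold: float = CO_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
    min_detect_frac: float = 0.01,
    layer: str = "log2norm",
) -> pd.DataFrame:
    """Per-gene MELR age scan with BH-FDR significance calls.

    Restricts to ``subset`` cells (all cells when ``None``), fits
    ``expression ~ age + sex + (1|group)`` per gene on the log2-normalized
    layer, BH-adjusts the age-slope p-values across tested genes, and calls
    a gene significant when ``|CO| > co_threshold`` and ``q < q_threshold``.
    Genes detected (raw UMI > 0) in fewer than ``min_detect_frac`` of the
    subset's cells are skipped.

    Returns a DataFrame indexed by gene with columns ``co``, ``sex_coef``,
    ``p_value``, ``q_value``, ``n_cells``, ``detect_frac``, ``significant``
    and ``direction`` ("up"/"down"/"none").
    """
    if not adata.uns.get("normalized", False) or layer not in adata.layers:
        raise ValueError("matrix must carry a log2-normalized layer")
    mask = (
        np.ones(adata.n_obs, bool)
        if subset is None
        else (adata.obs["subset"] == subset).to_numpy()
    )
    sub = adata[mask]
    if sub.n_obs < 3:
        raise ValueError("need at least 3 cells in the subset")
    age = sub.obs["age_years"].to_numpy(dtype=float)
    sex = sub.obs["sex"].to_numpy()
    group = sub.obs["group_id"].to_numpy()
    raw = sub.X
    detect_frac = np.asarray((raw > 0).sum(axis=0)).ravel() / sub.n_obs
    Y = sub.layers[layer]
    Y = np.asarray(Y.todense()) if hasattr(Y, "todense") else np.asarray(Y)

    rows, skipped = [], 0
    for gi, gene in enumerate(sub.var_names):
        if detect_frac[gi] < min_detect_frac:
            skipped += 1
            continue
        fit = fit_melr(Y[:, gi], age, sex, group)
        rows.append(
            {
                "gene_id": gene,
                "subset": subset if subset is not None else "all",
                "co": fit.age_slope,
                "sex_coef": fit.sex_coef,
                "p_value": fit.p_value,
                "n_cells": fit.n_obs,
                "detect_frac": detect_frac[gi],
            }
        )
    if skipped:
        logger.info(
            "skipped %d genes below detection floor %.3g", skipped,
            min_detect_frac,
        )
    res = pd.DataFrame(rows).set_index("gene_id")
    if res.empty:
        res["q_value"] = res["significant"] = res["direction"] = []
        return res
    pvals = res["p_value"].to_numpy()
    ok = np.isfinite(pvals)
    q = np.full(pvals.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    res["q_value"] = q
    res["significant"] = (
        (res["co"].abs() > co_threshold) & (res["q_value"] < q_threshold)
    ).fillna(False)
    res["direction"] = np.where(
        res["significant"], np.where(res["co"] > 0, "up", "down"), "none"
    )
    return res
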