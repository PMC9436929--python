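"""Mixed-effect machine-learning cell-age clock (MEEN and MERF).

A cell's donor age is modeled as

    age = f(x) + b_g + eps,    b_g ~ N(0, sigma_b^2),  eps ~ N(0, sigma_e^2)

where ``x`` is the cell's log2-normalized expression vector plus a one-hot
sex covariate (1 = male, 0 = female), ``f`` is either an elastic-net linear
model (MEEN) or a random forest (MERF), and ``b_g`` is a random intercept
per donor group (all cross-sectional donors form one group; each
longitudinal donor is its own group).  Fitting alternates, EM-style:

1. subtract current random intercepts from the response;
2. refit the fixed-part learner on the adjusted response;
3. update the BLUPs ``b_g = sigma_b^2 n_g / (sigma_e^2 + n_g sigma_b^2)
   * mean(residual in g)``;
4. update the variance components from the current residuals and BLUPs;
5. stop when the generalized log-likelihood changes by less than ``tol``.

With a single group the random intercept is confounded with the learner's
intercept, so the fit short-circuits to the plain learner.  After
convergence the random intercepts are mean-centered, the mean being folded
into a fixed offset, which keeps the decomposition identifiable.

The elastic-net penalty weight (lambda) is tuned by random cell-level
10-fold cross-validation over a log-spaced path descending from the
smallest lambda that zeroes every coefficient, choosing the
minimum-mean-squared-error point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElasticNetSpec:
    """MEEN fixed part: ``l1_ratio`` is the L1/L2 mixing alpha, ``lam`` the
    penalty weight lambda."""

    lam: float = 0.1
    l1_ratio: float = 0.5

    def build(self):
        return ElasticNet(
            alpha=self.lam, l1_ratio=self.l1_ratio, max_iter=5000
        )


@dataclass(frozen=True)
class ForestSpec:
    """MERF fixed part: bootstrap forest, min observations per node split."""

    n_trees: int = 500
    min_node: int = 100
    seed: int = 0

    def build(self):
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            min_samples_split=self.min_node,
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass
class ClockModel:
    kind: str  # "MEEN" | "MERF"
    learner: object  # fitted sklearn regressor
    feature_names: list  # gene order + "sex", fixed at fit time
    random_intercepts: dict  # group_id -> b_g (years), mean-centered
    fixed_offset: float  # mean of raw BLUPs folded out of b_g
    sigma_b2: float
    sigma_e2: float
    tuning: dict
    converged: bool
    n_iter: int
    gll_trace: list = field(default_factory=list)

    def fixed_predict(self, X) -> np.ndarray:
        return self.learner.predict(np.asarray(X)) + self.fixed_offset


def make_features(adata, layer: str = "log2norm"):
    """Feature matrix for the clock: genes + one-hot sex (1=male).

    Returns ``(X, feature_names, y, groups)`` with ``y`` the donor age in
    years and ``groups`` the random-effect labels.
    """
    Y = adata.layers[layer]
    Y = np.asarray(Y.todense()) if hasattr(Y, "todense") else np.asarray(Y)
    sex = (adata.obs["sex"].to_numpy() == "M").astype(float)
    X = np.column_stack([Y, sex])
    names = list(adata.var_names) + ["sex"]
    return (
        X,
        names,
        adata.obs["age_years"].to_numpy(dtype=float),
        adata.obs["group_id"].to_numpy(),
    )


def _generalized_ll(resid_by_group, b, sigma_e2, sigma_b2):
    se2 = max(sigma_e2, 1e-12)
    sb2 = max(sigma_b2, 1e-12)
    gll = 0.0
    for g, eps in resid_by_group.items():
        gll += float(eps @ eps) / se2 + eps.size * np.log(se2)
        gll += b[g] ** 2 / sb2 + np.log(sb2)
    return gll


def fit_mixed_ml(
    X,
    y,
    groups,
    learner,
    tol: float = 1e-4,
    max_iter: int = 50,
    feature_names=None,
) -> ClockModel:
    """Fit the mixed-effect clock by EM-style alternation (see module doc).

    ``learner`` is an :class:`ElasticNetSpec` or :class:`ForestSpec`.  With
    one group the result is exactly the plain learner fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    kind = "MEEN" if isinstance(learner, ElasticNetSpec) else "MERF"
    labels, codes = np.unique(groups, return_inverse=True)
    q = labels.size
    n_g = np.bincount(codes).astype(float)

    if q == 1:
        est = learner.build().fit(X, y)
        return ClockModel(
            kind=kind, learner=est, feature_names=list(feature_names),
            random_intercepts={labels[0]: 0.0}, fixed_offset=0.0,
            sigma_b2=0.0,
            sigma_e2=float(np.mean((y - est.predict(X)) ** 2)),
            tuning=learner.__dict__.copy(), converged=True, n_iter=1,
        )

    b = np.zeros(q)
    sigma_b2, sigma_e2 = 1.0, 1.0
    est = learner.build()
    gll_prev, gll_trace, converged = None, [], False
    n = y.size
    for it in range(1, max_iter + 1):
        y_star = y - b[codes]
        est = clone(est).fit(X, y_star)
        f = est.predict(X)
        r = y - f
        if not np.all(np.isfinite(r)):
            raise FloatingPointError("non-finite residuals in EM")
        r_sum = np.bincount(codes, weights=r, minlength=q)
        shrink = sigma_b2 * n_g / (sigma_e2 + n_g * sigma_b2)
        b = shrink * (r_sum / n_g)
        eps = r - b[codes]
        sse = np.bincount(codes, weights=eps**2, minlength=q)
        trace_term = sigma_e2 * n_g * sigma_b2 / (sigma_e2 + n_g * sigma_b2)
        sigma_e2 = float((sse + trace_term).sum() / n)
        post_var = sigma_b2 * sigma_e2 / (sigma_e2 + n_g * sigma_b2)
        sigma_b2 = float((b**2 + post_var).sum() / q)
        resid_by_group = {
            g: eps[codes == gi] for gi, g in enumerate(labels)
        }
        gll = _generalized_ll(
            resid_by_group, dict(zip(labels, b)), sigma_e2, sigma_b2
        )
        gll_trace.append(gll)
        if gll_prev is not None and abs(gll - gll_prev) < tol:
            converged = True
            break
        gll_prev = gll

    center = float(b.mean())
    b = b - center
    return ClockModel(
        kind=kind, learner=est, feature_names=list(feature_names),
        random_intercepts={g: float(bi) for g, bi in zip(labels, b)},
        fixed_offset=center, sigma_b2=float(sigma_b2),
        sigma_e2=float(sigma_e2), tuning=learner.__dict__.copy(),
        converged=converged, n_iter=it, gll_trace=gll_trace,
    )


# ---------------------------------------------------------------------------
# elastic-net tuning
# ---------------------------------------------------------------------------


def lambda_path(X, y, l1_ratio: float, n_lambda: int = 100, decades: float = 4.0):
    """Log-spaced lambda path descending from lambda_max.

    ``lambda_max`` is the smallest penalty at which every coefficient is
    zero: max |x_j' y_c| / (n * l1_ratio) on centered data.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(Xc.T @ yc)) / (X.shape[0] * max(l1_ratio, 1e-3)))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max) - decades, n_lambda
    )


def tune_meen(
    X,
    y,
    groups=None,
    n_folds: int = 10,
    n_lambda: int = 100,
    l1_ratio: float = 0.5,
    seed: int = 0,
):
    """Choose the elastic-net lambda by random cell-level K-fold CV.

    Cells are shuffled into ``n_folds`` folds; for each fold a coefficient
    path over ``n_lambda`` log-spaced penalties (descending from
    lambda_max) is fit on the training 90% and scored on the held-out 10%.
    Returns ``(lambda_star, cv_curve)`` with the minimum-mean-MSE penalty
    and the full CV curve (lambda, mean_mse, se_mse).
    """
    from sklearn.linear_model import enet_path

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    lams = lambda_path(X, y, l1_ratio, n_lambda)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_mse = []
    for tr, te in kf.split(X):
        y_tr = y[tr]
        if np.ptp(y_tr) == 0:
            logger.warning("skipping degenerate fold with constant response")
            continue
        mu_x, mu_y = X[tr].mean(axis=0), y_tr.mean()
        _, coefs, _ = enet_path(
            X[tr] - mu_x, y_tr - mu_y, l1_ratio=l1_ratio, alphas=lams
        )
        pred = (X[te] - mu_x) @ coefs + mu_y  # n_test x n_lambda
        fold_mse.append(((y[te][:, None] - pred) ** 2).mean(axis=0))
    if not fold_mse:
        raise ValueError("all folds degenerate")
    M = np.vstack(fold_mse)
    curve = pd.DataFrame(
        {
            "lam": lams,
            "mean_mse": M.mean(axis=0),
            "se_mse": M.std(axis=0, ddof=1) / np.sqrt(M.shape[0]),
        }
    )
    lam_star = float(curve.loc[curve["mean_mse"].idxmin(), "lam"])
    return lam_star, curve


# ---------------------------------------------------------------------------
# prediction and evaluation
# ---------------------------------------------------------------------------


def predict_cell_age(
    model: ClockModel, X: pd.DataFrame, groups=None
) -> pd.DataFrame:
    """Predict cell ages; columns are aligned to the model's feature order.

    ``X`` is a cells x features DataFrame.  Features the model knows but
    ``X`` lacks are imputed as 0 (logged); extra columns are dropped; more
    than 50% missing raises.  ``groups`` (optional, per cell) adds the
    trained random intercept for cells whose group was seen in training.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X), columns=model.feature_names)
    missing = [f for f in model.feature_names if f not in X.columns]
    if len(missing) > 0.5 * len(model.feature_names):
        raise ValueError(
            f"{len(missing)}/{len(model.feature_names)} model features "
            "missing from input"
        )
    if missing:
        logger.info("imputing %d missing model features as 0", len(missing))
        X = X.copy()
        for f in missing:
            X[f] = 0.0
    Xa = X[model.feature_names].to_numpy(dtype=float)
    pred = model.fixed_predict(Xa)
    used = np.zeros(len(X), dtype=bool)
    if groups is not None:
        groups = np.asarray(groups)
        for g, bg in model.random_intercepts.items():
            hit = groups == g
            pred[hit] += bg
            used |= hit
    return pd.DataFrame(
        {"predicted_age": pred, "used_random_effect": used}, index=X.index
    )


def cross_validate_clock(
    X,
    y,
    groups,
    learner,
    n_folds: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 50,
    fold_mode: str = "cell",
    feature_names=None,
):
    """K-fold CV of the mixed clock; returns ``(predictions, rmse, r)``.

    ``fold_mode='cell'`` shuffles cells into folds (a donor's cells can
    appear in both train and test, so held-out cells usually get their
    group's random intercept); ``'donor'`` holds out whole groups for a
    leakage-free read, predicting with the fixed part only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n = y.size
    pred = np.full(n, np.nan)
    fold_id = np.full(n, -1)
    used_re = np.zeros(n, dtype=bool)
    if fold_mode == "cell":
        splits = KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(
            np.arange(n)
        )
    elif fold_mode == "donor":
        from sklearn.model_selection import GroupKFold

        uniq = np.unique(groups)
        splits = GroupKFold(n_splits=min(n_folds, uniq.size)).split(
            np.arange(n), groups=groups
        )
    else:
        raise ValueError("fold_mode must be 'cell' or 'donor'")
    for k, (tr, te) in enumerate(splits):
        model = fit_mixed_ml(
            X[tr], y[tr], groups[tr], learner, tol=tol, max_iter=max_iter,
            feature_names=feature_names,
        )
        p = model.fixed_predict(X[te])
        for g, bg in model.random_intercepts.items():
            hit = groups[te] == g
            p[hit] += bg
            used_re[te[hit]] = True
        pred[te] = p
        fold_id[te] = k
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    r = float(np.corrcoef(pred, y)[0, 1])
    out = pd.DataFrame(
        {
            "predicted_age": pred,
            "true_age": y,
            "fold_id": fold_id,
            "used_random_effect": used_re,
        }
    )
    return out, rmse, r


def permutation_importance(
    model: ClockModel, X, y, n_repeats: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Permutation feature importance: mean MSE increase over baseline.

    Each feature column is shuffled within the evaluation set
    ``n_repeats`` times; importance is the mean increase of the fixed-part
    prediction MSE.  Sorted descending.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    base = float(np.mean((model.fixed_predict(X) - y) ** 2))
    rows = []
    for j, name in enumerate(model.feature_names):
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas.append(
                float(np.mean((model.fixed_predict(Xp) - y) ** 2)) - base
            )
        rows.append(
            {
                "feature": name,
                "importance": float(np.mean(deltas)),
                "importance_se": float(
                    np.std(deltas, ddof=1) / np.sqrt(n_repeats)
                )
                if n_repeats > 1
                else np.nan,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("importance", ascending=False)
        .reset_index(drop=True)
    )


def compare_groups(preds_a, preds_b, elapsed_years: float = 0.0):
    """Mean predicted-age difference (b - a) net of elapsed time, Welch p.

    Subtracting ``elapsed_years`` from the second group removes the
    expected chronological increase, isolating excess aging.  Returns
    ``(delta, p_value)``; ``p_value`` is NaN when either group has < 2
    observations.
    """
    a = np.asarray(preds_a, dtype=float)
    b = np.asarray(preds_b, dtype=float) - elapsed_years
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    delta = float(b.mean() - a.mean())
    if a.size < 2 or b.size < 2:
        return delta, np.nan
    if delta == 0.0 and np.array_equal(np.sort(a), np.sort(b)):
        return delta, 1.0
    p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
    return delta, p


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: ClockModel, path):
    """Serialize a MEEN model to versioned JSON (MERF is not portable)."""
    if model.kind != "MEEN":
        raise ValueError("only MEEN models serialize to JSON")
    payload = {
        "format_version": 1,
        "kind": model.kind,
        "feature_names": model.feature_names,
        "coef": model.learner.coef_.tolist(),
        "intercept": float(model.learner.intercept_),
        "fixed_offset": model.fixed_offset,
        "random_intercepts": model.random_intercepts,
        "sigma_b2": model.sigma_b2,
        "sigma_e2": model.sigma_e2,
        "tuning": model.tuning,
        "converged": model.converged,
        "n_iter": model.n_iter,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> ClockModel:
    with open(path) as fh:
        payload = json.load(fh)
    spec = ElasticNetSpec(**payload["tuning"])
    est = spec.build()
    est.coef_ = np.asarray(payload["coef"], dtype=float)
    est.intercept_ = payload["intercept"]
    est.n_features_in_ = len(payload["feature_names"])
    return ClockModel(
        kind=payload["kind"], learner=est,
        feature_names=payload["feature_names"],
        random_intercepts=payload["random_intercepts"],
        fixed_offset=payload["fixed_offset"], sigma_b2=payload["sigma_b2"],
        sigma_e2=payload["sigma_e2"], tuning=payload["tuning"],
        converged=payload["converged"], n_iter=payload["n_iter"],
    )
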