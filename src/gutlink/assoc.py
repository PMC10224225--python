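"""Covariate-adjusted regression, correlation and multiple testing.

This is the statistical backbone every screen calls: a compact IRLS
logistic solver (tens of thousands of per-feature fits are run in the
calibration suites, so the fit must be cheap), OLS via statsmodels,
partial Spearman correlation on rank residuals, Benjamini-Hochberg FDR,
HIV-stratified/interaction models, quartile grouping and covariate-
adjusted group means.

Effect sizes follow the epidemiological convention: logistic fits report
beta (log-odds), OR = exp(beta) and Wald 95% CI = exp(beta +/- 1.96 se).
Exposures are NOT standardized inside ``fit_logistic``; screens that
report "per SD" effects standardize before calling.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AssociationRecord, ValidationError

__all__ = [
    "build_design",
    "fit_logistic",
    "fit_linear",
    "partial_spearman",
    "bh_fdr",
    "interaction_test",
    "quartile_groups",
    "adjusted_group_means",
]

_Z95 = 1.959963984540054  # Phi^-1(0.975)


def build_design(covariates: Optional[pd.DataFrame]) -> Optional[np.ndarray]:
    """Expand a covariate frame to a numeric design (no intercept).

    Categorical/object columns are reference-coded with the most frequent
    level as reference; numeric columns pass through unchanged.
    """
    if covariates is None:
        return None
    covariates = pd.DataFrame(covariates)
    if covariates.shape[1] == 0:
        return None
    blocks = []
    for col in covariates.columns:
        series = covariates[col]
        if series.dtype.kind in "ifub" and series.nunique() > 2:
            blocks.append(series.astype(float).to_frame(col))
        elif series.dtype.kind in "ifub":
            blocks.append(series.astype(float).to_frame(col))
        else:
            counts = series.value_counts()
            reference = counts.index[0]
            levels = [lv for lv in sorted(counts.index.astype(str)) if lv != str(reference)]
            dummies = pd.DataFrame(
                {f"{col}[{lv}]": (series.astype(str) == lv).astype(float) for lv in levels},
                index=series.index)
            blocks.append(dummies)
    return pd.concat(blocks, axis=1).to_numpy(dtype=float)


def _stack(exposure: np.ndarray, covariates) -> np.ndarray:
    cols = [np.ones_like(exposure), exposure]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    return np.column_stack(cols)


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                   tol: float = 1e-10):
    """Newton/IRLS maximum likelihood for logistic regression.

    Returns (beta, se, converged, message). Quasi-separation is reported
    via the converged flag rather than raised.
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    message = ""
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            message = "degenerate weights"
            break
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
        converged = False
        message = message or "singular information matrix"
    if converged and (np.abs(beta).max() > 15 or np.max(se[np.isfinite(se)], initial=0) > 50):
        converged = False
        message = "possible separation (extreme estimates)"
    if not converged and not message:
        message = "IRLS did not converge"
    return beta, se, converged, message


def fit_logistic(outcome, exposure, covariates=None,
                 feature_id: str = "exposure",
                 model_tag: str = "model1") -> AssociationRecord:
    """Covariate-adjusted logistic regression of a binary outcome on one
    exposure; Wald CI on the OR scale.  Separation or non-convergence is
    flagged on the record, not raised."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome has a single class")
    if np.std(x) == 0:
        raise ValidationError(f"constant exposure {feature_id!r}")
    X = _stack(x, covariates)
    beta, se, converged, message = _irls_logistic(X, y)
    b, s = float(beta[1]), float(se[1])
    p = 2 * stats.norm.sf(abs(b) / s) if s > 0 and np.isfinite(s) else np.nan
    with np.errstate(over="ignore"):
        or_value = float(np.exp(b))
        ci_low = float(np.exp(b - _Z95 * s))
        ci_high = float(np.exp(b + _Z95 * s))
    return AssociationRecord(
        feature_id=feature_id, model_tag=model_tag, beta=b, se=s, p=float(p),
        or_value=or_value, ci_low=ci_low, ci_high=ci_high,
        converged=converged, note=message)


def fit_linear(response, exposure, covariates=None,
               feature_id: str = "exposure",
               model_tag: str = "model1") -> AssociationRecord:
    """OLS of a continuous response on one exposure plus covariates;
    t-based p, CI fields hold beta +/- 1.96 se (no OR)."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(exposure, dtype=float)
    X = _stack(x, covariates)
    n, k = X.shape
    if n <= k:
        raise ValidationError("more parameters than observations")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # identify aliased columns via pivoted QR diagnostics
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        aliased = [i for i, d in enumerate(diag) if d < 1e-8 * diag.max()]
        raise ValidationError(f"rank-deficient design; aliased column indices {aliased}")
    model = sm.OLS(y, X).fit()
    b, s = float(model.params[1]), float(model.bse[1])
    return AssociationRecord(
        feature_id=feature_id, model_tag=model_tag, beta=b, se=s,
        p=float(model.pvalues[1]),
        ci_low=b - _Z95 * s, ci_high=b + _Z95 * s, converged=True)


def _residual_ranks(v: np.ndarray, covariates) -> np.ndarray:
    ranks = stats.rankdata(v)
    if covariates is None:
        return ranks - ranks.mean()
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    design = np.column_stack([np.ones(len(v)), C])
    coef, *_ = np.linalg.lstsq(design, ranks, rcond=None)
    return ranks - design @ coef


def partial_spearman(x, y, covariates=None) -> dict:
    """Partial Spearman correlation: rank x and y (average ranks),
    residualize each on the covariates, Pearson-correlate the residuals;
    p from t with n - 2 - k degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant input to partial_spearman")
    k = 0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        k = 1 if C.ndim == 1 else C.shape[1]
    n = len(x)
    if n < k + 3:
        raise ValidationError("too few samples for the covariate count")
    rx = _residual_ranks(x, covariates)
    ry = _residual_ranks(y, covariates)
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    rho = float((rx * ry).sum() / denom)
    df = n - 2 - k
    rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
    t = rho_c * np.sqrt(df / (1 - rho_c ** 2))
    p = float(2 * stats.t.sf(abs(t), df)) if abs(rho) < 1 else 0.0
    return {"rho": rho, "p": p, "n": n}


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def interaction_test(outcome, exposure, modifier, covariates=None,
                     feature_id: str = "exposure") -> dict:
    """Effect-modification test: logistic model with an exposure x
    modifier product term (Wald p), plus per-stratum records."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(modifier, dtype=float)
    levels = np.unique(m)
    if levels.size != 2:
        raise ValidationError("modifier must be binary with both levels present")
    for lv in levels:
        stratum_y = y[m == lv]
        if len(np.unique(stratum_y)) < 2:
            raise ValidationError(f"stratum {lv} lacks both outcome classes")
    base_cols = [np.ones_like(x), x, m, x * m]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        base_cols.extend(C.T)
    X = np.column_stack(base_cols)
    beta, se, converged, message = _irls_logistic(X, y)
    z = beta[3] / se[3] if se[3] > 0 else np.nan
    p_int = float(2 * stats.norm.sf(abs(z)))
    strata = {}
    for lv in levels:
        mask = m == lv
        cov_s = None
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            cov_s = C[mask]
            cov_s = cov_s[:, np.std(cov_s, axis=0) > 0]
        strata[float(lv)] = fit_logistic(y[mask], x[mask], cov_s,
                                         feature_id=feature_id,
                                         model_tag=f"stratum_{lv:g}")
    return {"p_interaction": p_int, "converged": converged,
            "note": message, "stratum_records": strata}


def quartile_groups(values) -> np.ndarray:
    """Label values low (quartile 1), medium (quartiles 2-3), high
    (quartile 4); ties at a quartile boundary go to the lower group."""
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 4:
        raise ValidationError("need >= 4 distinct values for quartile groups")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    labels = np.where(v <= q1, "low", np.where(v <= q3, "medium", "high"))
    return labels


def adjusted_group_means(response, groups, covariates=None,
                         conf_level: float = 0.95) -> pd.DataFrame:
    """Covariate-adjusted group means: linear model on group indicators
    plus covariates, predicted at the covariate means, CI from the
    prediction standard error."""
    y = np.asarray(response, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if (counts == 0).any() or labels.size < 2:
        raise ValidationError("every group must be non-empty (>= 2 groups)")
    G = np.column_stack([(groups == lv).astype(float) for lv in labels])
    cols = [G]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("group indicators aliased with covariates")
    model = sm.OLS(y, X).fit()
    rows = []
    zq = stats.norm.ppf(0.5 + conf_level / 2)
    for i, lv in enumerate(labels):
        at = np.zeros(X.shape[1])
        at[i] = 1.0
        if covariates is not None:
            at[labels.size:] = np.asarray(covariates, dtype=float).reshape(len(y), -1).mean(axis=0)
        pred = model.get_prediction(at[None, :])
        mean = float(pred.predicted_mean[0])
        se = float(pred.se_mean[0])
        rows.append({"group": lv, "n": int(counts[i]), "mean": mean,
                     "ci_low": mean - zq * se, "ci_high": mean + zq * se})
    return pd.DataFrame(rows).set_index("group")
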