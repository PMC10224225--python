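"""Cross-omics integration: correlation screens, conditional selection,
the weighted gut-microbiota score, EC-category enrichment, and
sequential-adjustment attenuation.

The score construction follows the two-stage design: (1) screen all
species against the target microbial metabolite (Spearman, BH FDR);
(2) enter every correlated species into one joint "mutual adjustment"
linear model; species with joint-model p < alpha are declared
independently associated and their joint betas become the score weights.
The per-sample score is the weighted sum of INT-CLR species abundances,
optionally standardized to unit SD so downstream ORs read "per SD of the
score".
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .assoc import bh_fdr, fit_logistic, partial_spearman
from .containers import (AssociationRecord, AttenuationReport,
                         EnrichmentRecord, MicrobiotaScore,
                         TransformedMatrix, ValidationError, records_to_frame)

__all__ = ["correlation_screen", "GutMicrobiotaScore", "conditional_selection",
           "build_gmb_score", "ec_enrichment", "attenuation_analysis"]


def _frame(x) -> pd.DataFrame:
    if isinstance(x, TransformedMatrix):
        return x.data
    if hasattr(x, "data") and isinstance(getattr(x, "data"), pd.DataFrame):
        return x.data
    return pd.DataFrame(x)


def _residualize(R: np.ndarray, covariates) -> np.ndarray:
    if covariates is None:
        return R - R.mean(axis=0, keepdims=True)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    design = np.column_stack([np.ones(R.shape[0]), C])
    coef, *_ = np.linalg.lstsq(design, R, rcond=None)
    return R - design @ coef


def correlation_screen(features, targets, covariates=None,
                       fdr: float = 0.10, model_tag: str = "spearman") -> pd.DataFrame:
    """All feature x target (partial) Spearman correlations with a single
    BH adjustment across the screen.

    Returns a DataFrame (feature_id, target_id, rho, p, q, significant)
    where significant means q < ``fdr``.  With ``covariates`` the
    correlations are partial (rank-residual) Spearman; the vectorised
    computation matches elementwise :func:`gutlink.assoc.partial_spearman`.
    """
    F = _frame(features)
    T = _frame(targets)
    shared = F.index.intersection(T.index)
    if len(shared) == 0:
        raise ValidationError("no shared samples between features and targets")
    if len(shared) < 10:
        raise ValidationError("need >= 10 shared samples for the screen")
    F = F.loc[shared]
    T = T.loc[shared]
    n = len(shared)
    k = 0
    if covariates is not None:
        C = np.asarray(pd.DataFrame(covariates).loc[shared], dtype=float)
        k = C.shape[1]
    else:
        C = None
    RF = _residualize(np.apply_along_axis(sps.rankdata, 0, F.to_numpy(float)), C)
    RT = _residualize(np.apply_along_axis(sps.rankdata, 0, T.to_numpy(float)), C)
    RF = RF / np.sqrt((RF ** 2).sum(axis=0, keepdims=True))
    RT = RT / np.sqrt((RT ** 2).sum(axis=0, keepdims=True))
    rho = RF.T @ RT  # features x targets
    df = n - 2 - k
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = rho_c * np.sqrt(df / (1 - rho_c ** 2))
    p = 2 * sps.t.sf(np.abs(t), df)
    rows = pd.DataFrame({
        "feature_id": np.repeat(F.columns.to_numpy(), T.shape[1]),
        "target_id": np.tile(T.columns.to_numpy(), F.shape[1]),
        "rho": rho.ravel(),
        "p": p.ravel(),
    })
    rows["q"] = bh_fdr(rows["p"].to_numpy())
    rows["significant"] = rows["q"] < fdr
    rows["model_tag"] = model_tag
    return rows


class GutMicrobiotaScore(BaseEstimator):
    """Mutual-adjustment species selection plus the weighted score.

    ``fit(X, y, covariates=...)`` takes candidate species columns (INT-CLR
    scale) and the target metabolite; one joint OLS over all candidates
    plus covariates is fitted and candidates with joint-model p < alpha
    are selected.  ``transform(X)`` returns the per-sample weighted sum
    of the selected columns (standardized to unit SD by default).

    Fitted attributes: ``species_ids_``, ``weights_`` (joint-model
    betas), ``joint_model_`` (full per-candidate result frame),
    ``dropped_`` (candidates removed as aliased).
    """

    def __init__(self, alpha: float = 0.05, standardize: bool = True):
        self.alpha = alpha
        self.standardize = standardize

    def fit(self, X, y, covariates=None):
        X = _frame(X)
        y = np.asarray(y, dtype=float)
        candidates = list(X.columns)
        n = X.shape[0]
        k_cov = 0
        C = None
        if covariates is not None:
            C = np.asarray(pd.DataFrame(covariates), dtype=float)
            k_cov = C.shape[1]
        if n <= len(candidates) + k_cov + 1:
            raise ValidationError(
                f"n={n} too small for {len(candidates)} candidates "
                f"+ {k_cov} covariates")
        self.dropped_ = []
        while True:
            cols = [np.ones(n)] + [X[c].to_numpy(float) for c in candidates]
            if C is not None:
                cols.extend(C.T)
            D = np.column_stack(cols)
            rank = np.linalg.matrix_rank(D)
            if rank == D.shape[1]:
                break
            # drop the aliased candidate with the smallest QR pivot
            _, R = np.linalg.qr(D)
            diag = np.abs(np.diag(R))
            cand_diag = diag[1:1 + len(candidates)]
            worst = candidates[int(np.argmin(cand_diag))]
            warnings.warn(f"dropping aliased candidate {worst!r}")
            self.dropped_.append(worst)
            candidates.remove(worst)
            if not candidates:
                raise ValidationError("all candidates aliased")
        model = sm.OLS(y, D).fit()
        betas = model.params[1:1 + len(candidates)]
        pvals = model.pvalues[1:1 + len(candidates)]
        joint = pd.DataFrame({"feature_id": candidates, "beta": betas,
                              "se": model.bse[1:1 + len(candidates)],
                              "p": pvals})
        joint["selected"] = joint["p"] < self.alpha
        self.joint_model_ = joint
        self.species_ids_ = list(joint.loc[joint["selected"], "feature_id"])
        self.weights_ = joint.loc[joint["selected"], "beta"].to_numpy()
        return self

    def transform(self, X) -> pd.Series:
        X = _frame(X)
        missing = [s for s in self.species_ids_ if s not in X.columns]
        if missing:
            raise ValidationError(f"matrix missing selected species: {missing}")
        raw = X[self.species_ids_].to_numpy(float) @ self.weights_ \
            if self.species_ids_ else np.zeros(X.shape[0])
        score = pd.Series(raw, index=X.index, name="gmb_score")
        if self.standardize and score.std(ddof=1) > 0:
            score = score / score.std(ddof=1)
        return score

    def to_score(self, X) -> MicrobiotaScore:
        return MicrobiotaScore(species_ids=self.species_ids_,
                               weights=self.weights_,
                               scores=self.transform(X),
                               standardized=self.standardize)


def conditional_selection(target, candidate_species, covariates=None,
                          alpha: float = 0.05) -> GutMicrobiotaScore:
    """Joint mutual-adjustment fit; returns the fitted selector."""
    return GutMicrobiotaScore(alpha=alpha).fit(candidate_species, target,
                                               covariates=covariates)


def build_gmb_score(species_ids, betas, abundance, standardize: bool = True
                    ) -> MicrobiotaScore:
    """Weighted sum of INT-CLR abundances for a given species/weight set."""
    X = _frame(abundance)
    species_ids = list(species_ids)
    betas = np.asarray(betas, dtype=float)
    missing = [s for s in species_ids if s not in X.columns]
    if missing:
        raise ValidationError(f"abundance matrix missing species: {missing}")
    raw = X[species_ids].to_numpy(float) @ betas if species_ids \
        else np.zeros(X.shape[0])
    score = pd.Series(raw, index=X.index, name="gmb_score")
    if standardize and score.std(ddof=1) > 0:
        score = score / score.std(ddof=1)
    return MicrobiotaScore(species_ids=species_ids, weights=betas,
                           scores=score, standardized=standardize)


def ec_enrichment(enzyme_records, ec_map, alpha_feature: float = 0.05,
                  fdr: float = 0.10) -> pd.DataFrame:
    """Hypergeometric over-representation of significant enzymes within
    EC level-III categories.

    ``enzyme_records`` is a list of AssociationRecords (or a frame with
    feature_id and p); ``ec_map`` maps enzyme id -> category id.  Per
    category with K members of which k are significant (out of n
    significant among N tested): p = P(X >= k | N, K, n) upper tail;
    BH across categories, enriched when q < ``fdr``.
    """
    if isinstance(enzyme_records, pd.DataFrame):
        frame = enzyme_records[["feature_id", "p"]].copy()
    else:
        frame = records_to_frame(enzyme_records)[["feature_id", "p"]]
    ec_map = dict(ec_map)
    unmapped = [f for f in frame["feature_id"] if f not in ec_map]
    if unmapped:
        raise ValidationError(f"enzymes without EC category: {unmapped[:5]}")
    frame["category"] = frame["feature_id"].map(ec_map)
    N = len(frame)
    sig = frame["p"] < alpha_feature
    n_sig = int(sig.sum())
    rows = []
    for cat, sub in frame.groupby("category", sort=True):
        K = len(sub)
        k = int((sub["p"] < alpha_feature).sum())
        p = float(sps.hypergeom.sf(k - 1, N, K, n_sig)) if n_sig > 0 else 1.0
        rows.append({"category_id": cat, "category_size": K, "hits": k,
                     "significant_total": n_sig, "universe": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["enriched"] = out["q"] < fdr
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def attenuation_analysis(outcome, exposure, covariates, extra_adjusters,
                         feature_id: str = "exposure",
                         adjustment_tag: str = "plus_adjusters") -> AttenuationReport:
    """Base vs augmented logistic fit; percent attenuation of |log-odds|.

    percent_attenuation = 100 (|beta_base| - |beta_adj|) / |beta_base|.
    An adjuster nearly collinear with the exposure (|r| > 0.99) sets a
    warning flag on the report.
    """
    x = np.asarray(exposure, dtype=float)
    A = np.asarray(pd.DataFrame(extra_adjusters), dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    collinear = False
    for j in range(A.shape[1]):
        if np.std(A[:, j]) > 0 and abs(np.corrcoef(x, A[:, j])[0, 1]) > 0.99:
            collinear = True
            warnings.warn("adjuster nearly collinear with the exposure")
    cov_base = None if covariates is None else np.asarray(
        pd.DataFrame(covariates), dtype=float)
    base = fit_logistic(outcome, x, cov_base, feature_id=feature_id,
                        model_tag="base")
    cov_aug = A if cov_base is None else np.column_stack([cov_base, A])
    adjusted = fit_logistic(outcome, x, cov_aug, feature_id=feature_id,
                            model_tag=adjustment_tag)
    if base.beta == 0:
        pct = 0.0 if adjusted.beta == 0 else float("nan")
    else:
        pct = 100.0 * (abs(base.beta) - abs(adjusted.beta)) / abs(base.beta)
    return AttenuationReport(feature_id=feature_id,
                             adjustment_tag=adjustment_tag,
                             base=base, adjusted=adjusted,
                             percent_attenuation=pct,
                             collinearity_warning=collinear)
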