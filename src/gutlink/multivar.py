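"""PLS-DA over the inflammatory-marker panel, and PERMANOVA.

The discriminant analysis is PLS1 (NIPALS) with the binary plaque status
as the single response: for two classes this is equivalent to the
two-column dummy PLS2 formulation and is deterministic.  Component
scores feed covariate-adjusted logistic models; loadings rank each
component's contributing markers (default: top five of eight
components).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression

from .assoc import fit_logistic
from .containers import ValidationError

__all__ = ["PLSDiscriminant", "plsda_fit", "top_contributors",
           "pc_outcome_association", "permanova"]


class PLSDiscriminant(BaseEstimator):
    """Partial least squares discriminant analysis (PLS1, NIPALS).

    ``fit(X, y)`` column-standardizes X (error on a constant column) and
    centers the 0/1 response internally.  Fitted attributes:

    x_weights_, x_loadings_ : (features x components)
    scores_                 : (samples x components) DataFrame, mutually
                              orthogonal columns
    y_loadings_             : (components,) regression of y on scores
    explained_x_variance_   : per-component fraction of X variance
    """

    def __init__(self, n_components: int = 8):
        self.n_components = n_components

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValidationError("y must be coded 0/1")
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = list(sd.index[sd == 0])
            raise ValidationError(f"constant feature column(s): {bad}")
        Z = (X - X.mean(axis=0)) / sd
        rank = np.linalg.matrix_rank(Z.to_numpy())
        if self.n_components > rank:
            raise ValidationError(
                f"n_components={self.n_components} exceeds rank {rank} of X")
        pls = PLSRegression(n_components=self.n_components, scale=False)
        pls.fit(Z.to_numpy(), y - y.mean())
        self.feature_ids_ = list(X.columns)
        self.x_weights_ = pls.x_weights_
        self.x_loadings_ = pls.x_loadings_
        self.y_loadings_ = pls.y_loadings_.ravel()
        comp_ids = [f"PC{i + 1}" for i in range(self.n_components)]
        self.scores_ = pd.DataFrame(pls.x_scores_, index=X.index, columns=comp_ids)
        total = (Z.to_numpy() ** 2).sum()
        t = pls.x_scores_
        p = pls.x_loadings_
        self.explained_x_variance_ = np.array(
            [(t[:, a] ** 2).sum() * (p[:, a] ** 2).sum() / total
             for a in range(self.n_components)])
        self._pls = pls
        self._center = X.mean(axis=0)
        self._scale = sd
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        Z = (X[self.feature_ids_] - self._center) / self._scale
        comp_ids = list(self.scores_.columns)
        return pd.DataFrame(self._pls.transform(Z.to_numpy()),
                            index=X.index, columns=comp_ids)

    def top_contributors(self, k: int = 5) -> dict:
        """Per component, the k features with largest |loading| (signed
        loadings reported; exact ties broken lexicographically by id)."""
        if k > len(self.feature_ids_):
            raise ValidationError("k exceeds the number of features")
        out = {}
        for a, comp in enumerate(self.scores_.columns):
            loadings = pd.Series(self.x_loadings_[:, a], index=self.feature_ids_)
            ranked = loadings.reindex(
                sorted(loadings.index, key=lambda f: (-abs(loadings[f]), f)))
            out[comp] = [(f, float(v)) for f, v in ranked.head(k).items()]
        return out


def plsda_fit(X, y, n_components: int = 8) -> PLSDiscriminant:
    return PLSDiscriminant(n_components=n_components).fit(X, y)


def top_contributors(model: PLSDiscriminant, k: int = 5) -> dict:
    return model.top_contributors(k)


def pc_outcome_association(model: PLSDiscriminant, outcome, covariates=None,
                           model_tag: str = "model1") -> list:
    """Covariate-adjusted logistic fit of the outcome on each component
    score (standardized to unit SD, so ORs are per SD of the score)."""
    records = []
    for comp in model.scores_.columns:
        score = model.scores_[comp].to_numpy()
        if np.std(score) == 0:
            raise ValidationError(f"degenerate component {comp}")
        z = (score - score.mean()) / score.std(ddof=1)
        records.append(fit_logistic(outcome, z, covariates,
                                    feature_id=comp, model_tag=model_tag))
    return records


def _ss_within(d2: np.ndarray, groups: np.ndarray, labels) -> float:
    ss = 0.0
    for lv in labels:
        mask = groups == lv
        n_g = int(mask.sum())
        ss += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ss


def permanova(d, groups, n_permutations: int = 999, seed: int = 0) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F from the among/within partition of squared distances,
    R^2 = SS_among / SS_total, and an add-one permutation p-value
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    D = d.to_numpy() if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValidationError("distance matrix must be square and symmetric")
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2 or (counts < 2).any():
        raise ValidationError("need >= 2 groups with >= 2 samples each")
    n = D.shape[0]
    a = labels.size
    d2 = D ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    def pseudo_f(g):
        ss_w = _ss_within(d2, g, labels)
        ss_a = ss_total - ss_w
        return (ss_a / (a - 1)) / (ss_w / (n - a)), ss_a
    f_obs, ss_among = pseudo_f(groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        f_perm, _ = pseudo_f(rng.permutation(groups))
        if f_perm >= f_obs:
            exceed += 1
    return {"pseudo_F": float(f_obs),
            "R2": float(ss_among / ss_total),
            "p": (1 + exceed) / (1 + n_permutations),
            "n_permutations": n_permutations}
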