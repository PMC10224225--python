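"""Feature filtering, compositional/rank transforms, QC and diversity.

The transforms are scikit-learn style transformers operating on pandas
DataFrames (samples x features); thin module-level functions wrap them
for one-shot use on :class:`~gutlink.containers.CountTable` /
:class:`~gutlink.containers.OmicsMatrix` containers.

Conventions
-----------
* CLR: clr_ij = ln(x_ij) - mean_j ln(x_ij) on zero-replaced relative
  abundances; scale-invariant per sample, rows sum to zero.
* Inverse-normal transform: Blom offset c = 3/8, average ranks for ties,
  value of rank r among n maps to Phi^-1((r - c) / (n - 2c + 1)).
* Prevalence: fraction of samples with abundance strictly > 0; a feature
  is dropped when prevalence < min_prevalence (strict, i.e. exactly-at-
  threshold features survive) or mean relative abundance < the abundance
  floor.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountTable, OmicsMatrix, TransformedMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PrevalenceAbundanceFilter",
    "CLRTransformer",
    "InverseNormalTransformer",
    "HalfMinImputer",
    "OmicsQCFilter",
    "filter_features",
    "clr_transform",
    "int_transform",
    "int_clr_transform",
    "qc_filter",
    "impute_half_min",
    "alpha_diversity",
    "distance_matrix",
    "branch_profile",
]


def _as_frame(X) -> pd.DataFrame:
    return X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)


class PrevalenceAbundanceFilter(BaseEstimator, TransformerMixin):
    """Drop rare features: prevalence < ``min_prevalence`` or mean relative
    abundance < ``min_mean_relative_abundance``.

    Both rules are strict inequalities (a feature sitting exactly on a
    threshold is retained).  Fitted attributes: ``support_`` (boolean per
    feature), ``prevalence_``, ``mean_relative_abundance_``.
    """

    def __init__(self, min_prevalence: float = 0.20,
                 min_mean_relative_abundance: float = 1e-5):
        self.min_prevalence = min_prevalence
        self.min_mean_relative_abundance = min_mean_relative_abundance

    def fit(self, X, y=None):
        if not (0.0 <= self.min_prevalence <= 1.0) or not (
                0.0 <= self.min_mean_relative_abundance <= 1.0):
            raise ValidationError("filter thresholds must lie in [0, 1]")
        X = _as_frame(X)
        if X.shape[0] == 0 or X.shape[1] == 0:
            raise ValidationError("empty table")
        totals = X.sum(axis=1)
        rel = X.div(totals.where(totals > 0, np.nan), axis=0).fillna(0.0)
        self.prevalence_ = (X > 0).mean(axis=0)
        self.mean_relative_abundance_ = rel.mean(axis=0)
        self.support_ = (
            (self.prevalence_ >= self.min_prevalence)
            & (self.mean_relative_abundance_ >= self.min_mean_relative_abundance)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_frame(X)
        kept = self.support_.index[self.support_]
        out = X.loc[:, kept]
        if out.shape[1] == 0:
            warnings.warn("no features survive the prevalence/abundance filter")
        logger.info("feature filter: kept %d of %d features (prev>=%g, abund>=%g)",
                    out.shape[1], X.shape[1],
                    self.min_prevalence, self.min_mean_relative_abundance)
        return out


class CLRTransformer(BaseEstimator, TransformerMixin):
    """Centered log-ratio transform with zero replacement.

    ``zero_replacement`` is either the string ``"half_min_nonzero"`` (delta
    = half the smallest nonzero relative abundance in the fitted table) or
    a positive pseudocount added on the relative-abundance scale.
    """

    def __init__(self, zero_replacement="half_min_nonzero"):
        self.zero_replacement = zero_replacement

    def _close(self, X: pd.DataFrame) -> pd.DataFrame:
        totals = X.sum(axis=1)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise ValidationError(f"sample {bad!r} has an all-zero composition")
        return X.div(totals, axis=0)

    def fit(self, X, y=None):
        X = _as_frame(X)
        rel = self._close(X)
        vals = rel.to_numpy()
        if self.zero_replacement == "half_min_nonzero":
            nonzero = vals[vals > 0]
            self.delta_ = 0.5 * nonzero.min()
        else:
            delta = float(self.zero_replacement)
            if delta <= 0:
                raise ValidationError("pseudocount must be positive")
            self.delta_ = delta
        return self

    def transform(self, X):
        X = _as_frame(X)
        rel = self._close(X).to_numpy()
        rel = np.where(rel > 0, rel, self.delta_)
        logs = np.log(rel)
        clr = logs - logs.mean(axis=1, keepdims=True)
        return pd.DataFrame(clr, index=X.index, columns=X.columns)


class InverseNormalTransformer(BaseEstimator, TransformerMixin):
    """Rank-based inverse normal transform, column-wise.

    Maps the value of (average) rank r among n to the normal quantile
    Phi^-1((r - c)/(n - 2c + 1)) with Blom offset c = 3/8 by default.
    This is a within-cohort rank transform: ``transform`` re-ranks the
    matrix it is given, so fit/transform on the same cohort matrix.
    """

    def __init__(self, offset_c: float = 0.375):
        self.offset_c = offset_c

    def fit(self, X, y=None):
        X = _as_frame(X)
        n_distinct = X.nunique(axis=0)
        if (n_distinct < 2).any():
            bad = list(n_distinct.index[n_distinct < 2])
            raise ValidationError(f"constant column(s) cannot be rank-normalized: {bad}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_frame(X)
        c = self.offset_c
        n = X.shape[0]
        ranks = np.apply_along_axis(stats.rankdata, 0, X.to_numpy())
        quantiles = (ranks - c) / (n - 2 * c + 1)
        out = stats.norm.ppf(quantiles)
        return pd.DataFrame(out, index=X.index, columns=X.columns)


class HalfMinImputer(BaseEstimator, TransformerMixin):
    """Replace missing entries of each feature by half its minimum
    observed value (the convention for below-detection metabolites)."""

    def fit(self, X, y=None):
        X = _as_frame(X)
        observed = X.notna().sum(axis=0)
        if (observed == 0).any():
            bad = list(observed.index[observed == 0])
            raise ValidationError(f"feature(s) with no observed values: {bad}")
        self.fill_values_ = 0.5 * X.min(axis=0, skipna=True)
        return self

    def transform(self, X):
        X = _as_frame(X)
        return X.fillna(self.fill_values_)


class OmicsQCFilter(BaseEstimator, TransformerMixin):
    """QC feature filter for continuous omics layers.

    ``kind="protein"``: keep features detected (non-missing) in strictly
    more than ``min_detection`` of samples.
    ``kind="metabolite"``: keep features with coefficient of variation
    (SD/mean on observed values) strictly below ``max_cv`` AND missing
    rate strictly below ``max_missing``.
    """

    def __init__(self, kind: str = "protein", min_detection: float = 0.75,
                 max_cv: float = 0.30, max_missing: float = 0.20):
        self.kind = kind
        self.min_detection = min_detection
        self.max_cv = max_cv
        self.max_missing = max_missing

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.shape[1] == 0:
            raise ValidationError("empty matrix")
        detection = X.notna().mean(axis=0)
        if self.kind == "protein":
            self.support_ = detection > self.min_detection
        elif self.kind == "metabolite":
            mean = X.mean(axis=0, skipna=True)
            sd = X.std(axis=0, skipna=True, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                cv = (sd / mean.abs()).replace([np.inf, -np.inf], np.nan)
            missing = 1.0 - detection
            self.cv_ = cv
            self.support_ = (cv.fillna(np.inf) < self.max_cv) & (missing < self.max_missing)
        else:
            raise ValidationError(f"unknown QC kind {self.kind!r}")
        self.detection_ = detection
        return self

    def transform(self, X):
        X = _as_frame(X)
        kept = self.support_.index[self.support_]
        out = X.loc[:, kept]
        if out.shape[1] == 0:
            warnings.warn(f"no {self.kind} features survive QC")
        return out


# ---------------------------------------------------------------------------
# one-shot functional wrappers over the transformers
# ---------------------------------------------------------------------------

def filter_features(table: CountTable, min_prevalence: float = 0.20,
                    min_mean_relative_abundance: float = 1e-5) -> CountTable:
    """Apply the prevalence/mean-abundance feature filter to a CountTable."""
    filt = PrevalenceAbundanceFilter(min_prevalence, min_mean_relative_abundance)
    data = filt.fit_transform(table.data)
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = table.taxonomy.loc[data.columns]
    return CountTable(data=data, feature_kind=table.feature_kind,
                      relative=False, taxonomy=taxonomy)


def clr_transform(table: CountTable,
                  zero_replacement="half_min_nonzero") -> TransformedMatrix:
    tf = CLRTransformer(zero_replacement=zero_replacement)
    data = tf.fit_transform(table.data)
    return TransformedMatrix(data=data, transform_tag="CLR",
                             parameters={"delta": float(tf.delta_)})


def int_transform(matrix, offset_c: float = 0.375) -> TransformedMatrix:
    X = matrix.data if hasattr(matrix, "data") else _as_frame(matrix)
    tf = InverseNormalTransformer(offset_c=offset_c)
    data = tf.fit_transform(X)
    tag = "INT_CLR" if getattr(matrix, "transform_tag", None) == "CLR" else "INT"
    return TransformedMatrix(data=data, transform_tag=tag,
                             parameters={"offset_c": offset_c})


def int_clr_transform(table: CountTable,
                      zero_replacement="half_min_nonzero",
                      offset_c: float = 0.375) -> TransformedMatrix:
    """INT-CLR: inverse-normal transform applied feature-wise to CLR
    abundances (the scale the gut-microbiota score is built on)."""
    return int_transform(clr_transform(table, zero_replacement), offset_c=offset_c)


def qc_filter(matrix: OmicsMatrix, kind: str, **thresholds) -> OmicsMatrix:
    filt = OmicsQCFilter(kind=kind, **thresholds)
    return OmicsMatrix(data=filt.fit_transform(matrix.data), scale_tag=matrix.scale_tag)


def impute_half_min(matrix: OmicsMatrix) -> OmicsMatrix:
    imp = HalfMinImputer()
    return OmicsMatrix(data=imp.fit_transform(matrix.data), scale_tag=matrix.scale_tag)


# ---------------------------------------------------------------------------
# diversity and distances
# ---------------------------------------------------------------------------

def _shannon(counts: np.ndarray) -> float:
    p = counts[counts > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def _simpson(counts: np.ndarray) -> float:
    p = counts[counts > 0]
    p = p / p.sum()
    return float(1.0 - (p ** 2).sum())


def _chao1(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    s_obs = counts.size
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 ** 2 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_diversity(table: CountTable, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity (shannon, simpson on natural log /
    probability scale; chao1 requires integer counts)."""
    values = table.data.to_numpy(dtype=float)
    if metric == "chao1":
        if table.relative or not np.allclose(values, np.round(values)):
            raise ValidationError("chao1 requires integer counts")
        fn = _chao1
    elif metric == "shannon":
        fn = _shannon
    elif metric == "simpson":
        fn = _simpson
    else:
        raise ValidationError(f"unknown alpha-diversity metric {metric!r}")
    out = np.array([fn(row) for row in values])
    return pd.Series(out, index=table.data.index, name=metric)


def branch_profile(tree, feature_ids: Iterable[str]):
    """Branch lengths and leaf-membership incidence for a rooted tree.

    Returns ``(lengths, incidence, leaf_order)`` where ``incidence`` is a
    branches x features 0/1 matrix marking which leaves descend through
    each branch.  Root branch (if any length) is excluded: it carries the
    full mass of both samples and cancels in weighted UniFrac.
    """
    import skbio

    if not isinstance(tree, skbio.TreeNode):
        tree = skbio.TreeNode.read([str(tree)])
    feature_ids = list(feature_ids)
    tip_names = {t.name for t in tree.tips()}
    missing = [f for f in feature_ids if f not in tip_names]
    if missing:
        raise ValidationError(f"tree is missing leaves: {missing}")
    pos = {f: i for i, f in enumerate(feature_ids)}
    lengths = []
    rows = []
    for node in tree.postorder(include_self=False):
        length = node.length or 0.0
        if length <= 0:
            raise ValidationError(f"non-positive branch length at {node.name!r}")
        row = np.zeros(len(feature_ids))
        for tip in node.tips(include_self=True):
            if tip.name in pos:
                row[pos[tip.name]] = 1.0
        lengths.append(length)
        rows.append(row)
    return np.asarray(lengths), np.asarray(rows), feature_ids


def _weighted_unifrac_matrix(rel: np.ndarray, lengths: np.ndarray,
                             incidence: np.ndarray) -> np.ndarray:
    # P[s, b]: proportion of sample s descending through branch b
    P = rel @ incidence.T
    n = rel.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(P[i] - P[i + 1:]) @ lengths
        tot = (P[i] + P[i + 1:]) @ lengths
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / tot, 0.0)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return D


def distance_matrix(table: CountTable, method: str = "bray_curtis",
                    tree=None) -> pd.DataFrame:
    """Pairwise sample distances: Bray-Curtis or normalized weighted
    UniFrac (|pA - pB| branch sum over (pA + pB) branch sum)."""
    if method == "bray_curtis":
        D = squareform(pdist(table.data.to_numpy(dtype=float), metric="braycurtis"))
    elif method == "weighted_unifrac":
        if tree is None:
            raise ValidationError("weighted UniFrac requires a rooted tree")
        lengths, incidence, _ = branch_profile(tree, table.feature_ids)
        rel = table.relative_abundance().to_numpy()
        D = _weighted_unifrac_matrix(rel, lengths, incidence)
    else:
        raise ValidationError(f"unknown distance method {method!r}")
    return pd.DataFrame(D, index=table.data.index, columns=table.data.index)
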