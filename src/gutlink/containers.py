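"""Lightweight typed containers shared across the pipeline.

All tabular data live in pandas DataFrames with samples as rows and
features as columns; the dataclasses here carry the DataFrame plus the
small amount of provenance (feature kind, transform tag, scale) that the
downstream statistics need to validate their inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a container or operation input violates its contract."""


def _check_unique(ids: Sequence, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class CountTable:
    """Sample-by-feature abundance matrix (species, enzymes or genes).

    ``data`` holds non-negative counts or relative abundances; rows are
    samples, columns features.  ``relative`` marks row-closed relative
    abundances (rows sum to 1).
    """

    data: pd.DataFrame
    feature_kind: str = "species"  # species | enzyme | gene
    relative: bool = False
    taxonomy: Optional[pd.Series] = None  # per-feature lineage strings

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "feature ids")
        values = self.data.to_numpy()
        if values.size and np.nanmin(values) < 0:
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        if self.relative and values.size:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.index[np.argmax(np.abs(sums - 1.0))]
                raise ValidationError(f"relative-abundance row {bad!r} does not sum to 1")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Row-closed relative abundances (no-op if already relative)."""
        if self.relative:
            return self.data.copy()
        totals = self.data.sum(axis=1)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise ValidationError(f"sample {bad!r} has zero total abundance")
        return self.data.div(totals, axis=0)

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each feature has abundance > 0."""
        return (self.data > 0).mean(axis=0)


@dataclass
class OmicsMatrix:
    """Continuous omics layer (protein NPX on log2 scale, or metabolite
    intensities); missing values allowed as NaN."""

    data: pd.DataFrame
    scale_tag: str = "intensity"  # NPX_log2 | intensity

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "feature ids")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    def missing_rate(self) -> pd.Series:
        return self.data.isna().mean(axis=0)


@dataclass
class TransformedMatrix:
    """Real matrix after CLR / inverse-normal / z-score transformation."""

    data: pd.DataFrame
    transform_tag: str  # CLR | INT | INT_CLR | zscore
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "feature ids")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)


@dataclass
class AssociationRecord:
    """Per-feature covariate-adjusted effect estimate.

    ``beta`` is on the model's natural scale (log-odds for logistic fits,
    raw slope for linear fits); ``or_value``/CI are filled for logistic
    fits only.  ``q`` is populated by screen-level BH adjustment.
    """

    feature_id: str
    model_tag: str
    beta: float
    se: float
    p: float
    or_value: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    q: Optional[float] = None
    converged: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Stack AssociationRecords into the canonical result table."""
    cols = ["feature_id", "model_tag", "beta", "se", "or_value",
            "ci_low", "ci_high", "p", "q", "converged", "note"]
    frame = pd.DataFrame([r.to_dict() for r in records])
    return frame.reindex(columns=cols)


@dataclass
class MicrobiotaScore:
    """Weighted gut-microbiota score: per-sample weighted sum of INT-CLR
    abundances of the selected species."""

    species_ids: list
    weights: np.ndarray
    scores: pd.Series
    standardized: bool

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.species_ids) != self.weights.size:
            raise ValidationError("weights and species_ids length mismatch")


@dataclass
class EnrichmentRecord:
    """Hypergeometric over-representation result for one EC level-III class."""

    category_id: str
    category_size: int   # K: enzymes annotated to the category
    hits: int            # k: significant enzymes in the category
    significant_total: int  # n: significant enzymes overall
    universe: int        # N: all tested enzymes
    p: float
    q: Optional[float] = None


@dataclass
class AttenuationReport:
    """Change in a species-plaque log-odds after adding adjusters."""

    feature_id: str
    adjustment_tag: str
    base: AssociationRecord
    adjusted: AssociationRecord
    percent_attenuation: float
    collinearity_warning: bool = False


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic cohort (for recovery tests)."""

    seed: int
    species_ids: list
    species_plaque_effects: np.ndarray
    producer_set: list
    producer_weights: np.ndarray
    carrier_set: list
    carrier_weights: np.ndarray
    mediator_loadings: dict  # protein id -> {driver id: loading}
    covariate_effects: dict
    plaque_intercept: float
    target_metabolite: str
    carrier_enzyme: str

    def __post_init__(self) -> None:
        self.species_plaque_effects = np.asarray(self.species_plaque_effects, float)
        self.producer_weights = np.asarray(self.producer_weights, float)
        self.carrier_weights = np.asarray(self.carrier_weights, float)
        known = set(self.species_ids)
        for s in list(self.producer_set) + list(self.carrier_set):
            if s not in known:
                raise ValidationError(f"truth set member {s!r} not a species id")

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        for key in ("species_plaque_effects", "producer_weights", "carrier_weights"):
            payload[key] = list(map(float, payload[key]))
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        return cls(**payload)


@dataclass
class CohortSummary:
    """Counts/percentages describing the analysis cohort, including viral
    suppression among ART users at each cutoff."""

    n_total: int
    n_cases: int
    n_controls: int
    suppression: pd.DataFrame  # columns: cutoff, numerator, denominator, percent
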