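"""TSV / newick / JSON / YAML readers and writers.

Canonical table layout: TSV with a header row of feature ids and the
sample id in the first column (samples as rows).  A features-as-rows
dialect is accepted through the ``orientation`` flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import CountTable, OmicsMatrix, SyntheticTruth, ValidationError

__all__ = ["read_feature_table", "write_feature_table", "read_omics_matrix",
           "write_omics_matrix", "read_metadata", "write_metadata",
           "read_truth", "write_truth", "PipelineConfig"]


def _read_tsv(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed TSV {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate row ids {dups[:5]}")
    if frame.columns.has_duplicates:
        dups = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate column ids {dups[:5]}")
    return frame


def read_feature_table(path, orientation: str = "samples_as_rows",
                       feature_kind: str = "species") -> CountTable:
    """Read an abundance TSV into a CountTable; rejects duplicates,
    non-numeric bodies and negative entries (naming row and column)."""
    frame = _read_tsv(path)
    if orientation == "features_as_rows":
        frame = frame.T
    elif orientation != "samples_as_rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric entries ({exc})") from exc
    if frame.isna().any().any():
        col = frame.columns[frame.isna().any()][0]
        raise ValidationError(f"{path}: missing value in column {col!r}")
    values = frame.to_numpy()
    if values.size and values.min() < 0:
        r, c = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{path}: negative entry at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r}")
    return CountTable(data=frame, feature_kind=feature_kind)


def write_feature_table(table, path) -> None:
    frame = table.data if hasattr(table, "data") else pd.DataFrame(table)
    frame.to_csv(path, sep="\t", index_label="sample_id")


def read_omics_matrix(path, scale_tag: str = "intensity") -> OmicsMatrix:
    frame = _read_tsv(path).astype(float)
    return OmicsMatrix(data=frame, scale_tag=scale_tag)


def write_omics_matrix(matrix, path) -> None:
    frame = matrix.data if hasattr(matrix, "data") else pd.DataFrame(matrix)
    frame.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path, required: Sequence[str] = ("plaque",)) -> pd.DataFrame:
    frame = _read_tsv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata column(s) {missing}")
    if "plaque" in frame.columns:
        vals = set(frame["plaque"].dropna().unique().tolist())
        if vals - {0, 1, 0.0, 1.0}:
            raise ValidationError(f"{path}: plaque must be binary 0/1")
    return frame


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_truth(path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())


def write_truth(truth: SyntheticTruth, path) -> None:
    Path(path).write_text(truth.to_json())


@dataclass
class PipelineConfig:
    """All thresholds and paths of the end-to-end analysis.

    Paths left as None mean "simulate this layer" (the synthetic cohort
    generator runs with ``seed`` and the ``generator`` overrides).
    """

    seed: int = 0
    outdir: str = "gutlink_out"
    # input paths (None -> synthetic)
    species_path: Optional[str] = None
    enzymes_path: Optional[str] = None
    proteins_path: Optional[str] = None
    metabolites_path: Optional[str] = None
    metadata_path: Optional[str] = None
    tree_path: Optional[str] = None
    ec_map_path: Optional[str] = None
    # thresholds (the printed analysis defaults)
    min_prevalence: float = 0.20
    min_mean_abundance: float = 1e-5
    protein_detection: float = 0.75
    metabolite_cv: float = 0.30
    metabolite_missing: float = 0.20
    fdr: float = 0.10
    alpha: float = 0.05
    lda_cutoff: float = 3.0
    ancom_detection: float = 0.6
    plsda_components: int = 8
    top_k: int = 5
    n_permutations: int = 999
    target_metabolite: str = "met_ImP"
    carrier_enzyme: str = "enz_hutH"
    suppression_cutoffs: tuple = (20.0, 200.0)
    covariates_model1: tuple = ("age", "hiv", "art", "site")
    covariates_model2_extra: tuple = ()
    generator: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("min_prevalence", "min_mean_abundance", "protein_detection",
                     "metabolite_cv", "metabolite_missing", "fdr", "alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.plsda_components < 1 or self.top_k < 1:
            raise ValidationError("plsda_components and top_k must be >= 1")
        for name in ("species_path", "enzymes_path", "proteins_path",
                     "metabolites_path", "metadata_path", "tree_path",
                     "ec_map_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name}: file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        for name in ("suppression_cutoffs", "covariates_model1",
                     "covariates_model2_extra"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        for name in ("suppression_cutoffs", "covariates_model1",
                     "covariates_model2_extra"):
            payload[name] = list(payload[name])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
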