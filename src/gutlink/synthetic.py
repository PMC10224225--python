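"""Synthetic multi-omics cohort generator.

Emulates the statistical structure the analysis assumes, at the scale of
the study it mirrors: ~320 women, ~316 sparse gut species profiled by
shallow shotgun sequencing, 74 inflammatory-protein NPX columns, 378
metabolite intensities with left-censored missingness, a KEGG-style
enzyme layer, and a binary carotid-plaque outcome drawn from a logistic
model over species CLR abundances and covariates.

Planted structure (all recorded in :class:`SyntheticTruth`):

* six species carry plaque log-odds effects per SD of CLR abundance
  (default magnitudes ln 1.47 and ln 0.64...0.82, one risk species and
  five protective ones);
* a producer set (8 positive + 9 negative species) drives one target
  metabolite ("ImP-like") through its CLR abundances;
* a carrier set drives one functional-gene column ("hutH-like") through
  relative abundances;
* a subset of protein columns loads on the plaque species and on the
  target metabolite (the mediator path the attenuation analysis probes).

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (CohortSummary, CountTable, OmicsMatrix,
                         SyntheticTruth, ValidationError)

__all__ = ["GeneratorConfig", "generate_cohort", "generate_tree"]

# default planted plaque ORs: one enriched, five depleted species
_DEFAULT_PLAQUE_ORS = (1.47, 0.64, 0.75, 0.71, 0.70, 0.82)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults are the emulated cohort
    design's conditions (sample size, layer widths, ~26% outcome prevalence,
    65% HIV seropositivity, shallow-shotgun depth)."""

    n_samples: int = 320
    n_species: int = 316
    n_enzymes: int = 1634
    n_proteins: int = 74
    n_metabolites: int = 378
    seed: int = 0
    sequencing_depth: int = 100_000
    # latent log-scale abundance distribution (None: drawn from the seed)
    species_log_mean: Optional[Sequence[float]] = None
    species_log_sd: Optional[Sequence[float]] = None
    max_structural_zero_fraction: float = 0.8
    # outcome model
    plaque_intercept: Optional[float] = None   # None: calibrated to prevalence
    outcome_prevalence: float = 84 / 320
    species_plaque_effects: Optional[Sequence[float]] = None
    covariate_effects: dict = field(default_factory=lambda: {
        "age_per_10y": 0.30, "hiv": 0.40, "site_B": 0.10, "site_C": -0.10})
    # cross-layer structure
    n_producers_positive: int = 8
    n_producers_negative: int = 9
    producer_weights: Optional[Sequence[float]] = None
    carrier_weights: Optional[Sequence[float]] = None
    noise_sd: dict = field(default_factory=lambda: {
        "metabolite": 1.0, "protein": 1.0, "enzyme": 0.5})
    missing_rate_metabolites: float = 0.05

    def validate(self) -> None:
        for name in ("n_samples", "n_species", "n_enzymes", "n_proteins",
                     "n_metabolites", "sequencing_depth"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 <= self.missing_rate_metabolites < 1):
            raise ValidationError("missing_rate_metabolites must lie in [0, 1)")
        if self.species_plaque_effects is not None and \
                len(self.species_plaque_effects) != self.n_species:
            raise ValidationError("species_plaque_effects length != n_species")
        for vec in ("species_log_mean", "species_log_sd"):
            v = getattr(self, vec)
            if v is not None and len(v) != self.n_species:
                raise ValidationError(f"{vec} length != n_species")
        if self.n_producers_positive + self.n_producers_negative + 6 > self.n_species:
            raise ValidationError("not enough species for the planted sets")
        if self.n_producers_negative < 5:
            raise ValidationError(
                "need >= 5 negative producers (the protective plaque species)")


def _clr_latent(comp: np.ndarray) -> np.ndarray:
    """CLR of latent compositions with a per-feature detection floor.

    A structurally absent species is treated as "below detection" for that
    feature (half its smallest nonzero abundance), not as astronomically
    rare: a global floor would put absent samples many SDs below the data
    range and let arbitrary zero-replacement magnitudes dominate the
    planted cross-layer signals.
    """
    col_min = np.where(comp > 0, comp, np.inf).min(axis=0)
    col_min = np.where(np.isfinite(col_min), col_min, 1.0)
    filled = np.where(comp > 0, comp, 0.5 * col_min[None, :])
    logs = np.log(filled)
    return logs - logs.mean(axis=1, keepdims=True)


def _standardize(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (M - M.mean(axis=0)) / sd


def _calibrate_intercept(lp: np.ndarray, prevalence: float) -> float:
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        mean_p = float(np.mean(1.0 / (1.0 + np.exp(-(mid + lp)))))
        if mean_p < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: GeneratorConfig) -> dict:
    """Generate one synthetic cohort; returns a dict with keys
    species, enzymes, proteins, metabolites, metadata, ec_map, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_species

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    species_ids = [f"sp{j + 1:04d}" for j in range(m)]

    # --- latent species abundances: log-normal with structural zeros ----
    n_planted = 6 + config.n_producers_positive + config.n_producers_negative - 5
    if config.species_log_mean is not None:
        mu = np.asarray(config.species_log_mean, float)
    else:
        mu = rng.normal(0.0, 2.0, m)
        # planted species are the cohort's well-quantified commensals: keep
        # their mean log abundance in the range the sequencing depth resolves
        mu[:n_planted] = rng.uniform(0.5, 3.0, n_planted)
    sigma = (np.asarray(config.species_log_sd, float)
             if config.species_log_sd is not None else np.ones(m))
    zero_prob = rng.uniform(0.0, config.max_structural_zero_fraction, m)
    # planted species (plaque set + producer sets) are prevalent commensals:
    # they must comfortably survive the 20%-prevalence filter, so their
    # structural-zero fraction is capped well below it
    zero_prob[:n_planted] = np.minimum(zero_prob[:n_planted], 0.3)
    latent = np.exp(mu + sigma * rng.standard_normal((n, m)))
    latent *= rng.random((n, m)) >= zero_prob
    # guard: no all-zero sample
    dead = latent.sum(axis=1) == 0
    if dead.any():
        latent[dead, rng.integers(0, m, int(dead.sum()))] = np.exp(mu[0])
    comp = latent / latent.sum(axis=1, keepdims=True)

    counts = rng.multinomial(config.sequencing_depth, comp)
    species = CountTable(
        data=pd.DataFrame(counts, index=sample_ids, columns=species_ids),
        feature_kind="species")

    z_clr = _standardize(_clr_latent(comp))

    # --- covariates ----------------------------------------------------
    age = rng.normal(50.0, 10.0, n)
    hiv = rng.binomial(1, 0.65, n)
    site = rng.choice(["A", "B", "C"], size=n, p=[0.40, 0.35, 0.25])
    art = np.where(hiv == 1, rng.binomial(1, 0.92, n), 0)
    viral_load = np.full(n, np.nan)
    on_art = (art == 1)
    u = rng.random(n)
    viral_load[on_art & (u < 0.764)] = rng.uniform(0, 20, int((on_art & (u < 0.764)).sum()))
    mid = on_art & (u >= 0.764) & (u < 0.92)
    viral_load[mid] = rng.uniform(21, 200, int(mid.sum()))
    high = on_art & (u >= 0.92)
    viral_load[high] = rng.uniform(201, 10_000, int(high.sum()))
    off_art = (hiv == 1) & ~on_art
    viral_load[off_art] = rng.uniform(1_000, 100_000, int(off_art.sum()))

    ce = config.covariate_effects
    cov_lp = (ce.get("age_per_10y", 0.0) * (age - 50.0) / 10.0
              + ce.get("hiv", 0.0) * hiv
              + ce.get("site_B", 0.0) * (site == "B")
              + ce.get("site_C", 0.0) * (site == "C"))

    # --- outcome --------------------------------------------------------
    if config.species_plaque_effects is not None:
        effects = np.asarray(config.species_plaque_effects, float)
    else:
        effects = np.zeros(m)
        effects[:6] = np.log(_DEFAULT_PLAQUE_ORS)
    lp = z_clr @ effects + cov_lp
    intercept = (config.plaque_intercept if config.plaque_intercept is not None
                 else _calibrate_intercept(lp, config.outcome_prevalence))
    plaque = rng.binomial(1, 1.0 / (1.0 + np.exp(-(intercept + lp))))

    metadata = pd.DataFrame({
        "plaque": plaque, "age": age, "hiv": hiv, "art": art,
        "site": site, "viral_load": viral_load}, index=sample_ids)

    # --- target metabolite and the metabolite layer ---------------------
    pos = list(range(6, 6 + config.n_producers_positive))
    neg = list(range(1, 6)) + list(
        range(6 + config.n_producers_positive,
              6 + config.n_producers_positive + config.n_producers_negative - 5))
    producer_idx = pos + neg
    if config.producer_weights is not None:
        p_weights = np.asarray(config.producer_weights, float)
        if p_weights.size != len(producer_idx):
            raise ValidationError("producer_weights length mismatch")
    else:
        # every planted producer sits above the screen's detection floor at
        # the emulated sample size (the study's producers were all both
        # screen-significant and jointly significant), hence the narrow range
        p_weights = np.concatenate([rng.uniform(0.3, 0.5, len(pos)),
                                    -rng.uniform(0.3, 0.5, len(neg))])
    signal = z_clr[:, producer_idx] @ p_weights
    sd_sig = signal.std(ddof=1)
    if sd_sig > 0:
        p_weights = p_weights / sd_sig
        signal = signal / sd_sig
    target_z = signal + config.noise_sd["metabolite"] * rng.standard_normal(n)

    met_ids = ["met_ImP"] + [f"met_{j + 1:04d}" for j in range(config.n_metabolites - 1)]
    base = rng.uniform(1.0, 3.0, config.n_metabolites - 1)
    others_z = base + 0.2 * rng.standard_normal((n, config.n_metabolites - 1))
    met_log = np.column_stack([
        1.0 + 0.25 * (target_z - target_z.mean()) / max(target_z.std(ddof=1), 1e-12),
        others_z])
    met_intensity = np.exp(met_log)
    # left-censor the lowest fraction of each non-target metabolite
    if config.missing_rate_metabolites > 0:
        k_censor = int(np.floor(config.missing_rate_metabolites * n))
        for j in range(1, config.n_metabolites):
            if k_censor > 0:
                cut = np.argsort(met_intensity[:, j])[:k_censor]
                met_intensity[cut, j] = np.nan
    metabolites = OmicsMatrix(
        data=pd.DataFrame(met_intensity, index=sample_ids, columns=met_ids),
        scale_tag="intensity")

    # --- proteins: mediator loadings on species CLR and the metabolite --
    prot_ids = [f"prot_{j + 1:03d}" for j in range(config.n_proteins)]
    P = config.noise_sd["protein"] * rng.standard_normal((n, config.n_proteins))
    loadings: dict = {}
    n_species_driven = min(10, config.n_proteins)
    z_target = (target_z - target_z.mean()) / max(target_z.std(ddof=1), 1e-12)
    for j in range(n_species_driven):
        s_idx = j % 6
        load = 0.8 * np.sign(effects[s_idx]) if effects[s_idx] != 0 else 0.8
        P[:, j] += load * z_clr[:, s_idx]
        loadings[prot_ids[j]] = {species_ids[s_idx]: float(load)}
    for j in range(n_species_driven, min(n_species_driven + 5, config.n_proteins)):
        P[:, j] += 0.8 * z_target
        loadings[prot_ids[j]] = {"met_ImP": 0.8}
    proteins = OmicsMatrix(
        data=pd.DataFrame(P, index=sample_ids, columns=prot_ids),
        scale_tag="NPX_log2")

    # --- enzyme layer ----------------------------------------------------
    enz_ids = ["enz_hutH"] + [f"enz_{j + 1:04d}" for j in range(config.n_enzymes - 1)]
    rel = counts / counts.sum(axis=1, keepdims=True)
    carrier_idx = pos  # ImP producers carry the hutH-like gene
    if config.carrier_weights is not None:
        c_weights = np.asarray(config.carrier_weights, float)
        if c_weights.size != len(carrier_idx):
            raise ValidationError("carrier_weights length mismatch")
    else:
        c_weights = rng.uniform(0.5, 1.5, len(carrier_idx))
    hut_signal = rel[:, carrier_idx] @ c_weights
    hut_sd = max(hut_signal.std(ddof=1), 1e-12)
    hut = hut_signal + config.noise_sd["enzyme"] * hut_sd * rng.standard_normal(n)
    E = np.empty((n, config.n_enzymes))
    E[:, 0] = np.clip(hut, 0.0, None)
    mix_idx = rng.integers(0, m, size=(config.n_enzymes - 1, 3))
    mix_w = rng.uniform(0.5, 1.5, size=(config.n_enzymes - 1, 3))
    for j in range(config.n_enzymes - 1):
        sig = (rel[:, mix_idx[j]] * mix_w[j]).sum(axis=1)
        sd = max(sig.std(ddof=1), 1e-12)
        E[:, j + 1] = np.clip(
            sig + config.noise_sd["enzyme"] * sd * rng.standard_normal(n), 0.0, None)
    enzymes = CountTable(
        data=pd.DataFrame(E, index=sample_ids, columns=enz_ids),
        feature_kind="enzyme")

    # EC level-III category map (~one category per 12 enzymes)
    n_cat = max(3, config.n_enzymes // 12)
    cats = [f"EC {rng.integers(1, 7)}.{i % 9 + 1}.{i % 20 + 1}" for i in range(n_cat)]
    cats = list(dict.fromkeys(cats))
    ec_map = pd.Series(rng.choice(cats, size=config.n_enzymes), index=enz_ids,
                       name="ec_level3")

    truth = SyntheticTruth(
        seed=config.seed,
        species_ids=species_ids,
        species_plaque_effects=effects,
        producer_set=[species_ids[i] for i in producer_idx],
        producer_weights=p_weights,
        carrier_set=[species_ids[i] for i in carrier_idx],
        carrier_weights=c_weights,
        mediator_loadings=loadings,
        covariate_effects=dict(ce),
        plaque_intercept=float(intercept),
        target_metabolite="met_ImP",
        carrier_enzyme="enz_hutH")

    return {"species": species, "enzymes": enzymes, "proteins": proteins,
            "metabolites": metabolites, "metadata": metadata,
            "ec_map": ec_map, "truth": truth}


def generate_tree(feature_ids: Sequence[str], seed: int = 0) -> str:
    """Random rooted binary tree over the features as a newick string;
    strictly positive branch lengths, n-1 internal nodes."""
    ids = list(feature_ids)
    if len(ids) < 2:
        raise ValidationError("need >= 2 feature ids")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate feature ids")
    rng = np.random.default_rng(seed)
    nodes = list(ids)
    lengths = {name: None for name in nodes}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        li = rng.uniform(0.05, 1.0)
        lj = rng.uniform(0.05, 1.0)
        merged = f"({nodes[i]}:{li:.6f},{nodes[j]}:{lj:.6f})"
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0] + ";"
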