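"""End-to-end orchestration: simulate/load -> preprocess -> differential
abundance -> PLS-DA -> integration -> report.

Each stage reads the artifacts of the previous stage from the working
directory and writes its own TSV/JSON outputs, so the CLI subcommands
can re-run any stage in isolation.  Re-running with the same config is
byte-identical: every random step is seeded from ``config.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, diffabund, integrate, multivar, preprocess
from .containers import CohortSummary, CountTable, OmicsMatrix, ValidationError, records_to_frame
from .io import (PipelineConfig, read_feature_table, read_metadata,
                 read_omics_matrix, write_feature_table, write_metadata,
                 write_omics_matrix, write_truth)
from .synthetic import GeneratorConfig, generate_cohort, generate_tree

logger = logging.getLogger(__name__)

__all__ = ["summarize_cohort", "run_pipeline",
           "stage_simulate", "stage_preprocess", "stage_diffabund",
           "stage_plsda", "stage_integrate", "stage_report"]


def _round_half_up_1dp(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cohort(metadata: pd.DataFrame,
                     suppression_cutoffs=(20.0, 200.0)) -> CohortSummary:
    """Cohort counts plus viral suppression among ART users at each
    cutoff; percentages rounded half-up to one decimal.  A zero
    denominator yields an undefined (NaN) percentage, never 0."""
    if "art" not in metadata.columns or "viral_load" not in metadata.columns:
        raise ValidationError("metadata needs 'art' and 'viral_load' columns")
    plaque = metadata.get("plaque")
    n_total = len(metadata)
    n_cases = int(plaque.sum()) if plaque is not None else 0
    on_art = metadata["art"] == 1
    denom = int(on_art.sum())
    rows = []
    for cutoff in suppression_cutoffs:
        num = int(((metadata.loc[on_art, "viral_load"] <= cutoff)).sum())
        pct = _round_half_up_1dp(100.0 * num / denom) if denom > 0 else float("nan")
        rows.append({"cutoff": cutoff, "numerator": num,
                     "denominator": denom, "percent": pct})
    return CohortSummary(n_total=n_total, n_cases=n_cases,
                         n_controls=n_total - n_cases,
                         suppression=pd.DataFrame(rows))


def _design(metadata: pd.DataFrame, columns) -> np.ndarray:
    return assoc.build_design(metadata[list(columns)])


def stage_simulate(config: PipelineConfig, workdir: Path) -> None:
    gen_cfg = GeneratorConfig(seed=config.seed, **config.generator)
    cohort = generate_cohort(gen_cfg)
    write_feature_table(cohort["species"], workdir / "species.tsv")
    write_feature_table(cohort["enzymes"], workdir / "enzymes.tsv")
    write_omics_matrix(cohort["proteins"], workdir / "proteins.tsv")
    write_omics_matrix(cohort["metabolites"], workdir / "metabolites.tsv")
    write_metadata(cohort["metadata"], workdir / "metadata.tsv")
    cohort["ec_map"].to_csv(workdir / "ec_map.tsv", sep="\t",
                            index_label="enzyme_id")
    (workdir / "tree.nwk").write_text(
        generate_tree(cohort["species"].feature_ids, seed=config.seed))
    write_truth(cohort["truth"], workdir / "truth.json")


def _load_inputs(config: PipelineConfig, workdir: Path) -> dict:
    paths = {
        "species": config.species_path or workdir / "species.tsv",
        "enzymes": config.enzymes_path or workdir / "enzymes.tsv",
        "proteins": config.proteins_path or workdir / "proteins.tsv",
        "metabolites": config.metabolites_path or workdir / "metabolites.tsv",
        "metadata": config.metadata_path or workdir / "metadata.tsv",
        "tree": config.tree_path or workdir / "tree.nwk",
        "ec_map": config.ec_map_path or workdir / "ec_map.tsv",
    }
    return {
        "species": read_feature_table(paths["species"], feature_kind="species"),
        "enzymes": read_feature_table(paths["enzymes"], feature_kind="enzyme"),
        "proteins": read_omics_matrix(paths["proteins"], scale_tag="NPX_log2"),
        "metabolites": read_omics_matrix(paths["metabolites"]),
        "metadata": read_metadata(paths["metadata"],
                                  required=("plaque", "art", "viral_load")
                                  + tuple(c for c in config.covariates_model1
                                          if c not in ("art",))),
        "tree": Path(paths["tree"]).read_text().strip(),
        "ec_map": pd.read_csv(paths["ec_map"], sep="\t", index_col=0).iloc[:, 0],
    }


def stage_preprocess(config: PipelineConfig, workdir: Path) -> None:
    data = _load_inputs(config, workdir)
    species = preprocess.filter_features(
        data["species"], config.min_prevalence, config.min_mean_abundance)
    write_feature_table(species, workdir / "species_filtered.tsv")
    clr = preprocess.clr_transform(species)
    write_feature_table(clr, workdir / "species_clr.tsv")
    intclr = preprocess.int_clr_transform(species)
    write_feature_table(intclr, workdir / "species_intclr.tsv")

    alpha = pd.DataFrame({m: preprocess.alpha_diversity(data["species"], m)
                          for m in ("shannon", "chao1", "simpson")})
    alpha.to_csv(workdir / "alpha_diversity.tsv", sep="\t", index_label="sample_id")

    dist = preprocess.distance_matrix(species, "weighted_unifrac", tree=data["tree"])
    perm = multivar.permanova(dist, data["metadata"]["plaque"].to_numpy(),
                              n_permutations=config.n_permutations,
                              seed=config.seed)
    (workdir / "permanova.json").write_text(json.dumps(perm, indent=1))

    prot_qc = preprocess.qc_filter(data["proteins"], "protein",
                                   min_detection=config.protein_detection)
    prot_int = preprocess.int_transform(prot_qc)
    write_omics_matrix(prot_int, workdir / "proteins_int.tsv")

    met_qc = preprocess.qc_filter(data["metabolites"], "metabolite",
                                  max_cv=config.metabolite_cv,
                                  max_missing=config.metabolite_missing)
    met_imp = preprocess.impute_half_min(met_qc)
    met_log = OmicsMatrix(np.log(met_imp.data), scale_tag="log_intensity")
    write_omics_matrix(met_log, workdir / "metabolites_log.tsv")

    logger.info("preprocess: %d/%d species kept, %d proteins, %d metabolites",
                species.n_features, data["species"].n_features,
                prot_int.data.shape[1], met_log.data.shape[1])


def stage_diffabund(config: PipelineConfig, workdir: Path) -> None:
    data = _load_inputs(config, workdir)
    species = read_feature_table(workdir / "species_filtered.tsv")
    clr = pd.read_csv(workdir / "species_clr.tsv", sep="\t", index_col=0)
    metadata = data["metadata"]
    outcome = metadata["plaque"].to_numpy()
    cov = _design(metadata, config.covariates_model1)

    rel = species.relative_abundance()
    lefse = diffabund.lefse_lda_scores(rel, outcome, alpha=config.alpha,
                                       threshold=config.lda_cutoff,
                                       seed=config.seed)
    lefse.to_csv(workdir / "lefse.tsv", sep="\t", index=False)

    delta = 0.5 * rel.to_numpy()[rel.to_numpy() > 0].min()
    filled = rel.where(rel > 0, delta)
    ancom = diffabund.ancom_w(filled, outcome, covariates=cov, alpha=config.alpha)
    ancom.to_csv(workdir / "ancom.tsv", sep="\t", index=False)

    records = []
    for feature in clr.columns:
        x = clr[feature].to_numpy()
        z = (x - x.mean()) / x.std(ddof=1)
        records.append(assoc.fit_logistic(outcome, z, cov, feature_id=feature,
                                          model_tag="model1"))
    table = records_to_frame(records)
    table["q"] = assoc.bh_fdr(table["p"].to_numpy())
    table.to_csv(workdir / "species_logistic.tsv", sep="\t", index=False)


def stage_plsda(config: PipelineConfig, workdir: Path) -> None:
    data = _load_inputs(config, workdir)
    prot_int = pd.read_csv(workdir / "proteins_int.tsv", sep="\t", index_col=0)
    metadata = data["metadata"]
    outcome = metadata["plaque"].to_numpy()
    model = multivar.plsda_fit(prot_int, outcome,
                               n_components=config.plsda_components)
    model.scores_.to_csv(workdir / "plsda_scores.tsv", sep="\t",
                         index_label="sample_id")
    contributors = model.top_contributors(config.top_k)
    payload = {"explained_x_variance": model.explained_x_variance_.tolist(),
               "top_contributors": contributors}
    (workdir / "plsda_contributors.json").write_text(json.dumps(payload, indent=1))
    cov = _design(metadata, config.covariates_model1)
    records = multivar.pc_outcome_association(model, outcome, cov)
    records_to_frame(records).to_csv(workdir / "plsda_pc_logistic.tsv",
                                     sep="\t", index=False)


def stage_integrate(config: PipelineConfig, workdir: Path) -> None:
    data = _load_inputs(config, workdir)
    metadata = data["metadata"]
    outcome = metadata["plaque"].to_numpy()
    cov = _design(metadata, config.covariates_model1)
    intclr = pd.read_csv(workdir / "species_intclr.tsv", sep="\t", index_col=0)
    met_log = pd.read_csv(workdir / "metabolites_log.tsv", sep="\t", index_col=0)
    scores = pd.read_csv(workdir / "plsda_scores.tsv", sep="\t", index_col=0)

    # enzyme screen (CLR-transformed) + EC level-III enrichment
    enz = preprocess.filter_features(data["enzymes"], min_prevalence=0.2,
                                     min_mean_relative_abundance=0.0)
    enz_clr = preprocess.clr_transform(enz).data
    enz_records = []
    for feature in enz_clr.columns:
        x = enz_clr[feature].to_numpy()
        sd = x.std(ddof=1)
        if sd == 0:
            continue
        enz_records.append(assoc.fit_linear(outcome, (x - x.mean()) / sd, cov,
                                            feature_id=feature))
    enz_table = records_to_frame(enz_records)
    enz_table["q"] = assoc.bh_fdr(enz_table["p"].to_numpy())
    enz_table.to_csv(workdir / "enzyme_screen.tsv", sep="\t", index=False)
    enrich = integrate.ec_enrichment(enz_table, data["ec_map"].to_dict(),
                                     alpha_feature=config.alpha, fdr=config.fdr)
    enrich.to_csv(workdir / "ec_enrichment.tsv", sep="\t", index=False)

    # species <-> target metabolite screen and mutual adjustment
    if config.target_metabolite not in met_log.columns:
        raise ValidationError(
            f"target metabolite {config.target_metabolite!r} absent after QC")
    target = preprocess.int_transform(
        met_log[[config.target_metabolite]]).data.iloc[:, 0]
    screen = integrate.correlation_screen(intclr, target.to_frame(),
                                          fdr=config.fdr)
    screen.to_csv(workdir / "imp_screen.tsv", sep="\t", index=False)
    candidates = list(screen.loc[screen["significant"], "feature_id"])
    k_cov = cov.shape[1] if cov is not None else 0
    max_cand = intclr.shape[0] - k_cov - 2
    if len(candidates) > max_cand:
        logger.warning("capping candidates at %d (of %d) for the joint model",
                       max_cand, len(candidates))
        order = screen.set_index("feature_id").loc[candidates, "q"]
        candidates = list(order.sort_values().index[:max_cand])
    selector = integrate.conditional_selection(target.to_numpy(),
                                               intclr[candidates], cov,
                                               alpha=config.alpha)
    selector.joint_model_.to_csv(workdir / "gmb_selection.tsv", sep="\t",
                                 index=False)
    score = selector.transform(intclr)
    score.to_frame().to_csv(workdir / "gmb_score.tsv", sep="\t",
                            index_label="sample_id")

    results = {}
    if score.std(ddof=1) > 0:
        rec = assoc.fit_logistic(outcome, score.to_numpy(), cov,
                                 feature_id="gmb_score")
        results["score_outcome"] = rec.to_dict()
        results["score_metabolite"] = assoc.fit_linear(
            target.to_numpy(), score.to_numpy(), cov,
            feature_id="gmb_score").to_dict()
        hut = data["enzymes"].data.get(config.carrier_enzyme)
        if hut is not None and hut.std(ddof=1) > 0:
            z_hut = (hut - hut.mean()) / hut.std(ddof=1)
            results["score_carrier_enzyme"] = assoc.fit_linear(
                z_hut.to_numpy(), score.to_numpy(), cov,
                feature_id="gmb_score").to_dict()
        groups = assoc.quartile_groups(score.to_numpy())
        results["adjusted_target_by_score_group"] = assoc.adjusted_group_means(
            target.to_numpy(), groups, cov).to_dict("index")
    (workdir / "gmb_outcome.json").write_text(json.dumps(results, indent=1))

    # sequential-adjustment attenuation for the leading risk species
    clr = pd.read_csv(workdir / "species_clr.tsv", sep="\t", index_col=0)
    lead = clr.columns[0]
    x = clr[lead].to_numpy()
    z = (x - x.mean()) / x.std(ddof=1)
    top = scores.iloc[:, :config.top_k].to_numpy()
    atten = {
        "plus_metabolite": integrate.attenuation_analysis(
            outcome, z, cov, target.to_frame(), feature_id=lead,
            adjustment_tag="plus_metabolite"),
        "plus_PCs": integrate.attenuation_analysis(
            outcome, z, cov, top, feature_id=lead, adjustment_tag="plus_PCs"),
        "plus_both": integrate.attenuation_analysis(
            outcome, z, cov, np.column_stack([top, target.to_numpy()]),
            feature_id=lead, adjustment_tag="plus_both"),
    }
    payload = {tag: {"percent_attenuation": rep.percent_attenuation,
                     "beta_base": rep.base.beta,
                     "beta_adjusted": rep.adjusted.beta,
                     "collinearity_warning": rep.collinearity_warning}
               for tag, rep in atten.items()}
    (workdir / "attenuation.json").write_text(json.dumps(payload, indent=1))


def stage_report(config: PipelineConfig, workdir: Path) -> None:
    data = _load_inputs(config, workdir)
    summary = summarize_cohort(data["metadata"], config.suppression_cutoffs)
    payload = {"n_total": summary.n_total, "n_cases": summary.n_cases,
               "n_controls": summary.n_controls,
               "suppression": summary.suppression.to_dict("records")}
    (workdir / "cohort_summary.json").write_text(json.dumps(payload, indent=1))
    lines = ["gutlink run log"]
    for f in dataclasses.fields(config):
        lines.append(f"{f.name} = {getattr(config, f.name)!r}")
    (workdir / "run_log.txt").write_text("\n".join(lines) + "\n")


_STAGES = (stage_simulate, stage_preprocess, stage_diffabund,
           stage_plsda, stage_integrate, stage_report)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; aborts on the first failing stage with
    its name in the error, keeping partial outputs."""
    config.validate()
    workdir = Path(config.outdir)
    workdir.mkdir(parents=True, exist_ok=True)
    for stage in _STAGES:
        if stage is stage_simulate and config.species_path is not None:
            continue
        try:
            stage(config, workdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage.__name__} failed: {exc}") from exc
    return workdir
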