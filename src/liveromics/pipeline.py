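"""End-to-end orchestration: read (or simulate) a cohort, run every
stage in dependency order, and write a report bundle of TSV tables plus
a JSON summary of the counts at each step.

A single global seed fans out to per-stage seeds by fixed offsets, so a
stage re-run in isolation reproduces its table exactly. Stages whose
inputs are absent (e.g. no methylation matrix) are skipped with a
logged reason and marked in the summary, so partial-omics cohorts still
produce the remaining sections.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlation, io as omics_io, methylation, pas, preprocess, subgroups, survival
from .datatypes import ValidationError

log = logging.getLogger(__name__)

# fixed per-stage seed offsets (stage reproducibility under one global seed)
SEED_OFFSETS = {"cluster": 101, "pas": 202, "gmm": 303}


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run."""

    protein: str
    mrna: str
    clinical: str
    pathways: str
    methylation: str | None = None
    regions: str | None = None
    gene_model: str | None = None
    out_dir: str = "results"
    seed: int = 0
    # stage parameters (defaults match the individual stages)
    max_missing_fraction: float = 0.5
    impute_method: str = "half_min"
    knn_k: int = 5
    variance_fraction: float = 0.25
    variance_metric: str = "mad"
    corr_method: str = "spearman"
    corr_alpha: float = 0.01
    ks_min_members: int = 5
    k_range: tuple = (2, 6)
    n_resamples: int = 1000
    subsample_fraction: float = 0.8
    K_fixed: int | None = None
    de_alpha: float = 0.05
    pas_permutations: int = 999
    pas_alpha: float = 0.05
    dmr_alpha: float = 0.05
    dmr_min_delta: float = 0.1
    promoter_window: int = 1500
    horizon_months: float = 24.0
    cox_covariates: tuple = ("tnm_stage", "afp_high", "thrombus")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("k_range", "cox_covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        for key in ("protein", "mrna", "clinical", "pathways",
                    "methylation", "regions", "gene_model"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"config path for {key!r} does not exist: {p}")
        return cfg


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict (also written as
    summary.json in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"counts": {}, "skipped": {}}

    protein = omics_io.read_matrix(config.protein)
    mrna = omics_io.read_matrix(config.mrna)
    clinical = omics_io.read_clinical(config.clinical)
    pathways = omics_io.read_gmt(config.pathways)
    summary["counts"]["proteins_identified"] = protein.n_features
    summary["counts"]["samples"] = protein.n_samples

    # --- preprocess
    filtered = preprocess.filter_missing(protein, config.max_missing_fraction)
    imputed = preprocess.impute(filtered, config.impute_method, config.knn_k)
    variable = preprocess.select_variable(
        imputed, config.variance_fraction, config.variance_metric
    )
    summary["counts"]["proteins_after_missing_filter"] = filtered.n_features
    summary["counts"]["variable_proteins"] = variable.n_features
    log.info("proteins: %d identified -> %d after filtering -> %d variable",
             protein.n_features, filtered.n_features, variable.n_features)

    # --- mRNA-protein correlation + KS enrichment (pairwise-complete,
    # on the filtered but un-imputed matrix)
    paired = correlation.pair_genes(filtered, mrna)
    records, corr_summary = correlation.correlate(
        paired, config.corr_method, config.corr_alpha
    )
    _write(records, out / "correlation.tsv")
    summary["correlation"] = corr_summary
    scores = records.set_index("gene")["rho"]
    enrich = correlation.ks_pathway_enrichment(scores, pathways,
                                               config.ks_min_members)
    _write(enrich, out / "ks_enrichment.tsv")
    summary["counts"]["pairs_tested"] = corr_summary["n_tested"]
    summary["counts"]["significant_positive_pairs"] = corr_summary[
        "n_significant_positive"]

    # --- subgroup discovery
    assign = subgroups.consensus_cluster(
        variable, K_range=config.k_range, n_resamples=config.n_resamples,
        subsample_fraction=config.subsample_fraction,
        seed=config.seed + SEED_OFFSETS["cluster"], K_fixed=config.K_fixed,
    )
    assign.labels.rename_axis("sample").to_frame().to_csv(
        out / "subgroup_labels.tsv", sep="\t")
    assign.consensus.to_csv(out / "consensus_matrix.tsv", sep="\t")
    _write(assign.selection_trace, out / "consensus_selection.tsv")
    summary["counts"]["selected_K"] = assign.K
    summary["counts"]["subgroup_sizes"] = (
        assign.labels.value_counts().sort_index().to_dict()
    )

    de = subgroups.kw_differential(imputed, assign.labels, config.de_alpha)
    _write(de, out / "differential_expression.tsv")
    summary["counts"]["de_proteins"] = int(de["significant"].sum())

    assoc = subgroups.clinical_association(assign.labels, clinical)
    _write(assoc, out / "clinical_association.tsv")

    # --- pathway activity
    pas_res = pas.pathway_activity_score(
        imputed, assign.labels, pathways, B=config.pas_permutations,
        alpha=config.pas_alpha, seed=config.seed + SEED_OFFSETS["pas"],
    )
    _write(pas_res, out / "pas.tsv")
    pas.pas_heatmap_table(pas_res, config.pas_alpha).to_csv(
        out / "pas_matrix.tsv", sep="\t", na_rep="NA")
    summary["counts"]["significant_pas_cells"] = int(pas_res["significant"].sum())

    # --- survival
    flags = survival.early_relapse_flag(clinical, config.horizon_months)
    labs = assign.labels
    prop = survival.relapse_proportion_test(flags, labs)
    _write(prop, out / "early_relapse_fisher.tsv")
    curves, logrank = survival.km_logrank(clinical.subset(labs.index), labs,
                                          config.horizon_months)
    pd.concat(
        [c.assign(group=g) for g, c in curves.items()], ignore_index=True
    ).to_csv(out / "km_curves.tsv", sep="\t", index=False)
    summary["survival"] = {"logrank_chi2": logrank["chi2"],
                           "logrank_p": logrank["p"]}
    try:
        cox = survival.cox_multivariable(
            clinical.subset(labs.index), labels=labs,
            covariates=config.cox_covariates)
        cox.rename_axis("covariate").reset_index().to_csv(
            out / "cox_multivariable.tsv", sep="\t", index=False)
    except ValidationError as err:
        summary["skipped"]["cox"] = str(err)
        log.warning("Cox stage skipped: %s", err)

    de_sig = set(de.loc[de["significant"], "feature"])
    sig_pos = set(records.loc[records["significant_positive"], "gene"])

    # --- methylation branch (optional inputs)
    atten_genes: set = set()
    if config.methylation and config.regions and config.gene_model:
        meth = omics_io.read_matrix(config.methylation, value_domain="beta")
        regions = omics_io.read_regions(config.regions)
        gene_model = omics_io.read_gene_model(config.gene_model)
        dmrs = methylation.call_dmrs(meth, regions, labs, config.dmr_alpha,
                                     config.dmr_min_delta)
        annotated = methylation.annotate_regions(regions, gene_model,
                                                 config.promoter_window)
        dmrs = dmrs.merge(
            annotated[["region_id", "annotation", "annotated_gene"]],
            on="region_id", how="left")
        _write(dmrs, out / "dmrs.tsv")
        summary["counts"]["dmrs"] = int(dmrs["is_dmr"].sum())
        summary["counts"]["dmr_annotation"] = (
            dmrs.loc[dmrs["is_dmr"], "annotation"].value_counts().to_dict()
        )
        links = dmrs.loc[
            dmrs["is_dmr"] & dmrs["annotation"].isin(["promoter", "gene_body"]),
            ["region_id", "annotated_gene"],
        ].rename(columns={"annotated_gene": "gene"})
        try:
            atten, fit = methylation.attenuation_gmm(
                meth, mrna, imputed, links,
                seed=config.seed + SEED_OFFSETS["gmm"])
            _write(atten, out / "attenuation.tsv")
            n_att = int(atten["attenuated"].sum())
            summary["attenuation"] = {
                "n_analyzed": len(atten),
                "n_attenuated": n_att,
                "pct_attenuated": round(100.0 * n_att / len(atten), 1),
                "degenerate_fit": fit.degenerate,
            }
            atten_genes = set(atten.loc[atten["attenuated"], "gene"])
            ora = methylation.attenuated_ora(
                atten_genes, set(atten["gene"]), pathways)
            _write(ora, out / "attenuated_ora.tsv")
        except ValidationError as err:
            summary["skipped"]["attenuation"] = str(err)
            log.warning("attenuation stage skipped: %s", err)
    else:
        summary["skipped"]["methylation"] = "methylation inputs not provided"
        log.info("methylation branch skipped: inputs not provided")

    # --- cross-omics overlap report
    overlap = subgroups.overlap_summary({
        "de_proteins": de_sig,
        "positive_correlation": sig_pos,
        "methylation_attenuated": atten_genes,
    })
    _write(overlap, out / "overlap_summary.tsv")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
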