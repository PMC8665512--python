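"""Synthetic multi-omics cohort generator.

Emulates a 77-sample noncancerous-liver cohort with three latent
proteomic subgroups, a metabolic gene subset with planted positive
mRNA-protein correlation against a near-zero background, a planted
fraction of methylation-attenuated genes (methylation reaches the
transcript but not the protein), subgroup-dependent pathway activation,
and subgroup-dependent relapse hazards — so that every downstream stage
of the pipeline has ground truth to be scored against.

Generative model (log2 scale), per gene g and sample i in subgroup c:

    meth latent  z_ri   = mu_r + d_rc + a_ri          (beta = sigmoid(z))
    mRNA_gi      = b_g - k_g * (z_r(g),i - mean_i z)  + e_gi
    protein_gi   = b_g + u_gc + w_g * s_gi + f_gi

where s_gi is the mRNA signal component (its deviation from baseline),
w_g is tuned analytically so planted genes reach an expected Spearman
correlation of ``target_rho_pos`` while background genes sit near 0,
k_g > 0 only for attenuated genes (their protein noise is independent
of methylation), and u_gc is a mean shift applied to the member genes of
each subgroup's active pathways (this creates both the clusterable
subgroup structure and pathway activity scores > 1). Recurrence times
are exponential with subgroup-specific hazards and exponential
censoring. Protein entries go missing completely at random plus an
extra intensity-dependent mass on the lowest abundance decile, the
pattern typical of isobaric-label mass spectrometry.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as omics_io
from .datatypes import ClinicalTable, OmicsMatrix, PathwayDB, ValidationError

N_AUTOSOMES = 22
GENE_LENGTH = 10_000
GENE_SPACING = 50_000
PROMOTER_HALF = 200


class ParameterError(ValidationError):
    """Infeasible cohort specification."""


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort; defaults are the study
    conditions the pipeline is validated under."""

    n_samples: int = 77
    n_genes: int = 2000
    n_regions: int = 2500
    n_pathways: int = 20
    subgroup_proportions: tuple = (0.40, 0.34, 0.26)
    corr_gene_fraction: float = 0.16
    target_rho_pos: float = 0.6
    attenuated_fraction: float = 0.20
    hazard_by_subgroup: tuple = (0.02, 0.09, 0.03)  # events / month
    censor_rate: float = 0.01
    thrombus_prob_by_subgroup: tuple = (0.15, 0.25, 0.55)
    missing_rate_protein: float = 0.05
    seed: int = 0
    # noise / effect-size calibration
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    mrna_noise_sd: float = 1.0
    protein_noise_sd: float = 1.0
    subgroup_shift: float = 2.0  # log2 units, in within-group noise SDs
    meth_mu_sd: float = 1.0
    meth_latent_sd: float = 1.0
    meth_dmr_shift: float = 1.2  # latent shift for subgroup-variable regions
    dmr_region_fraction: float = 0.15
    meth_effect: float = 1.0  # k_g for attenuated genes
    low_abundance_missing_extra: float = 0.20
    genes_per_pathway: int = 40
    n_active_pathways_per_subgroup: int = 2
    n_corr_enriched_pathways: int = 2  # pathways drawn from the planted
    # positively-correlated genes (metabolic-style enrichment signal)
    afp_prob_by_subgroup: tuple = (0.20, 0.30, 0.60)
    mi_prob_by_subgroup: tuple = (0.20, 0.65, 0.45)
    phenotype_missing_prob: float = 0.05

    def validate(self) -> None:
        if abs(sum(self.subgroup_proportions) - 1.0) > 1e-12:
            raise ParameterError("subgroup_proportions must sum to 1")
        if len(self.subgroup_proportions) != 3:
            raise ParameterError("exactly 3 subgroups are supported")
        for name in ("n_samples", "n_genes", "n_regions", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("corr_gene_fraction", "attenuated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0,1]")
        if not 0.0 <= self.missing_rate_protein < 1.0:
            raise ParameterError("missing_rate_protein must lie in [0,1)")
        if not 0.0 < self.target_rho_pos <= 1.0:
            raise ParameterError("target_rho_pos must lie in (0,1]")
        if any(h <= 0 for h in self.hazard_by_subgroup) or self.censor_rate <= 0:
            raise ParameterError("hazards and censor_rate must be positive")
        for p in (*self.thrombus_prob_by_subgroup, *self.afp_prob_by_subgroup,
                  *self.mi_prob_by_subgroup):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("subgroup probabilities must lie in [0,1]")
        if int(self.corr_gene_fraction * self.n_genes) < 1:
            raise ParameterError(
                "corr_gene_fraction * n_genes < 1: no gene can be planted"
            )
        if self.n_regions < self.n_genes:
            raise ParameterError(
                "n_regions must be >= n_genes (one promoter region per gene)"
            )
        n_corr = int(round(self.corr_gene_fraction * self.n_genes))
        n_atten = int(round(self.attenuated_fraction * self.n_genes))
        n_active = (3 * self.n_active_pathways_per_subgroup
                    * self.genes_per_pathway)
        if n_corr + n_atten + n_active > self.n_genes:
            raise ParameterError(
                "planted gene sets (correlated + attenuated + active-pathway) "
                "exceed n_genes"
            )
        if self.n_pathways < (3 * self.n_active_pathways_per_subgroup
                              + self.n_corr_enriched_pathways):
            raise ParameterError("too few pathways for the active and "
                                 "correlation-enriched assignments")
        if (self.n_corr_enriched_pathways > 0
                and self.genes_per_pathway > n_corr):
            raise ParameterError(
                "genes_per_pathway exceeds the planted correlated gene count"
            )


@dataclass
class GroundTruth:
    subgroup_of_sample: pd.Series
    positively_correlated_genes: frozenset
    attenuated_genes: frozenset
    active_pathways_by_subgroup: dict
    corr_enriched_pathways: frozenset
    dmr_regions: frozenset
    expected_missing_rate: float


@dataclass
class Cohort:
    """Bundle of everything :func:`simulate_cohort` emits."""

    protein: OmicsMatrix
    mrna: OmicsMatrix
    methylation: OmicsMatrix
    regions: pd.DataFrame
    gene_model: pd.DataFrame
    clinical: ClinicalTable
    pathways: PathwayDB
    truth: GroundTruth


def _spearman_to_pearson(rho_s: float) -> float:
    """Invert the bivariate-normal identity rho_s = (6/pi) asin(rho_p/2)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate one cohort. Same spec (incl. seed) -> identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    genes = _gene_names(g)
    samples = [f"S{i:03d}" for i in range(n)]

    # --- subgroup labels: deterministic counts, shuffled assignment
    counts = np.floor(np.asarray(spec.subgroup_proportions) * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(np.asarray(spec.subgroup_proportions) * n - counts))] += 1
    labels = np.repeat([1, 2, 3], counts)
    rng.shuffle(labels)
    subgroup = pd.Series(labels, index=samples, name="subgroup")

    # --- planted gene sets (disjoint by construction)
    n_corr = int(round(spec.corr_gene_fraction * g))
    n_atten = int(round(spec.attenuated_fraction * g))
    perm = rng.permutation(g)
    corr_idx = perm[:n_corr]
    atten_idx = perm[n_corr:n_corr + n_atten]
    active_pool = perm[n_corr + n_atten:]

    # --- pathways; the first 3 * n_active are subgroup-active and draw
    # their members from the untouched background pool
    n_active_total = 3 * spec.n_active_pathways_per_subgroup
    pathway_names = [f"PW{j:03d}" for j in range(spec.n_pathways)]
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    active_by_subgroup: dict[int, set] = {1: set(), 2: set(), 3: set()}
    corr_enriched_pathways: set = set()
    shift_gene_subgroup = np.zeros(g, dtype=int)  # 0 = no shift
    cursor = 0
    for j, name in enumerate(pathway_names):
        if j < n_active_total:
            member_idx = active_pool[cursor:cursor + spec.genes_per_pathway]
            cursor += spec.genes_per_pathway
            c = j // spec.n_active_pathways_per_subgroup + 1
            active_by_subgroup[c].add(name)
            shift_gene_subgroup[member_idx] = c
            desc = f"synthetic metabolic pathway, active in subgroup S{c}"
        elif j < n_active_total + spec.n_corr_enriched_pathways:
            member_idx = rng.choice(corr_idx, size=spec.genes_per_pathway,
                                    replace=False)
            corr_enriched_pathways.add(name)
            desc = ("synthetic metabolic pathway, enriched for positive "
                    "mRNA-protein correlation")
        else:
            member_idx = rng.choice(g, size=spec.genes_per_pathway, replace=False)
            desc = "synthetic background pathway"
        sets[name] = (desc, frozenset(genes[i] for i in member_idx))
    pathways = PathwayDB(sets=sets)

    # --- gene model on 22 autosomes
    chrom = np.array([f"chr{(i % N_AUTOSOMES) + 1}" for i in range(g)])
    rank_on_chrom = np.arange(g) // N_AUTOSOMES
    gstart = 100_000 + rank_on_chrom * GENE_SPACING
    gend = gstart + GENE_LENGTH
    strand = np.where(np.arange(g) % 2 == 0, "+", "-")
    tss = np.where(strand == "+", gstart, gend - 1)
    gene_model = pd.DataFrame(
        {"gene": genes, "chrom": chrom, "tss": tss, "strand": strand,
         "start": gstart, "end": gend}
    )

    # --- regions: one promoter region per gene, the rest intergenic
    n_extra = spec.n_regions - g
    reg_rows = []
    for i in range(g):
        reg_rows.append((chrom[i], int(tss[i] - PROMOTER_HALF),
                         int(tss[i] + PROMOTER_HALF), f"R{i:05d}", genes[i]))
    for j in range(n_extra):
        i = j % g
        s = int(gstart[i] - 25_000)
        reg_rows.append((chrom[i], s, s + 500, f"R{g + j:05d}", "."))
    regions = pd.DataFrame(
        reg_rows, columns=["chrom", "start", "end", "region_id", "linked_gene"]
    )
    region_ids = list(regions["region_id"])

    # --- methylation latents; a fraction of regions vary by subgroup
    n_reg = spec.n_regions
    mu_r = rng.normal(0.0, spec.meth_mu_sd, size=n_reg)
    n_dmr = int(round(spec.dmr_region_fraction * n_reg))
    dmr_idx = rng.choice(n_reg, size=n_dmr, replace=False)
    dmr_dir = rng.choice([-1.0, 1.0], size=n_dmr)
    dmr_sub = rng.integers(1, 4, size=n_dmr)
    d_rc = np.zeros((n_reg, 3))
    d_rc[dmr_idx, dmr_sub - 1] = dmr_dir * spec.meth_dmr_shift
    z = (mu_r[:, None] + d_rc[:, labels - 1]
         + rng.normal(0.0, spec.meth_latent_sd, size=(n_reg, n)))
    beta = 1.0 / (1.0 + np.exp(-z))
    methylation = OmicsMatrix(
        pd.DataFrame(beta, index=region_ids, columns=samples), value_domain="beta"
    )

    # --- mRNA
    b_g = rng.normal(spec.baseline_mean, spec.baseline_sd, size=g)
    k_g = np.zeros(g)
    k_g[atten_idx] = spec.meth_effect
    z_gene = z[:g]  # promoter region of gene i is region i
    z_centered = z_gene - z_gene.mean(axis=1, keepdims=True)
    e = rng.normal(0.0, spec.mrna_noise_sd, size=(g, n))
    s_signal = -k_g[:, None] * z_centered + e
    mrna_vals = b_g[:, None] + s_signal
    mrna = OmicsMatrix(
        pd.DataFrame(mrna_vals, index=genes, columns=samples),
        value_domain="log-abundance",
    )

    # --- protein
    w_g = np.zeros(g)
    sigma_s = np.sqrt(k_g**2 * spec.meth_latent_sd**2 + spec.mrna_noise_sd**2)
    if spec.target_rho_pos >= 1.0 and spec.protein_noise_sd == 0.0:
        w_g[corr_idx] = 1.0
    else:
        rho_p = _spearman_to_pearson(spec.target_rho_pos)
        if rho_p >= 1.0:
            raise ParameterError("target_rho_pos = 1 requires protein_noise_sd = 0")
        w_g[corr_idx] = (rho_p / math.sqrt(1.0 - rho_p**2)
                         * spec.protein_noise_sd / sigma_s[corr_idx])
    u_gc = np.zeros((g, 3))
    for c in (1, 2, 3):
        idx = np.where(shift_gene_subgroup == c)[0]
        u_gc[idx, c - 1] = spec.subgroup_shift * max(spec.protein_noise_sd, 1e-12)
    f = rng.normal(0.0, spec.protein_noise_sd, size=(g, n))
    prot_vals = b_g[:, None] + u_gc[:, labels - 1] + w_g[:, None] * s_signal + f

    # --- missingness: MCAR plus extra mass on the lowest abundance decile
    u1 = rng.random(size=(g, n))
    u2 = rng.random(size=(g, n))
    decile = np.quantile(prot_vals, 0.10)
    miss = (u1 < spec.missing_rate_protein) | (
        (prot_vals <= decile) & (u2 < spec.low_abundance_missing_extra)
    )
    prot_missing = prot_vals.copy()
    prot_missing[miss] = np.nan
    protein = OmicsMatrix(
        pd.DataFrame(prot_missing, index=genes, columns=samples),
        value_domain="log-abundance",
    )
    expected_missing = (spec.missing_rate_protein
                        + 0.10 * spec.low_abundance_missing_extra
                        * (1.0 - spec.missing_rate_protein))

    # --- clinical
    hz = np.asarray(spec.hazard_by_subgroup)[labels - 1]
    t_event = rng.exponential(1.0 / hz)
    t_cens = rng.exponential(1.0 / spec.censor_rate, size=n)
    rfs = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    rfs = np.maximum(np.round(rfs, 1), 0.1)
    tnm_probs = {
        1: (0.45, 0.35, 0.15, 0.05),
        2: (0.35, 0.35, 0.20, 0.10),
        3: (0.10, 0.20, 0.40, 0.30),
    }
    stages = np.array(
        [rng.choice(4, p=tnm_probs[c]) for c in labels]
    )
    tnm = np.array(["I", "II", "III", "IV"])[stages]
    afp = (rng.random(n) < np.asarray(spec.afp_prob_by_subgroup)[labels - 1]).astype(int)
    thrombus = (
        rng.random(n) < np.asarray(spec.thrombus_prob_by_subgroup)[labels - 1]
    ).astype(int)
    mi = rng.random(n) < np.asarray(spec.mi_prob_by_subgroup)[labels - 1]
    phenotype = np.where(mi, "MI", "MA").astype(object)
    phenotype[rng.random(n) < spec.phenotype_missing_prob] = np.nan
    clinical = ClinicalTable(pd.DataFrame({
        "sample": samples,
        "rfs_months": rfs,
        "rfs_event": event,
        "tnm_stage": tnm,
        "afp_high": afp,
        "thrombus": thrombus,
        "phenotype": phenotype,
    }))

    truth = GroundTruth(
        subgroup_of_sample=subgroup,
        positively_correlated_genes=frozenset(genes[i] for i in corr_idx),
        attenuated_genes=frozenset(genes[i] for i in atten_idx),
        active_pathways_by_subgroup={c: frozenset(v) for c, v in
                                     active_by_subgroup.items()},
        corr_enriched_pathways=frozenset(corr_enriched_pathways),
        dmr_regions=frozenset(region_ids[i] for i in dmr_idx),
        expected_missing_rate=expected_missing,
    )
    return Cohort(protein=protein, mrna=mrna, methylation=methylation,
                  regions=regions, gene_model=gene_model, clinical=clinical,
                  pathways=pathways, truth=truth)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(cohort: Cohort, directory) -> pd.DataFrame:
    """Write every cohort file into ``directory``; returns the manifest
    (file, role, sha256), which is also written as ``manifest.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    plan = [
        ("protein.tsv", "protein matrix",
         lambda p: omics_io.write_matrix(cohort.protein, p)),
        ("mrna.tsv", "mRNA matrix",
         lambda p: omics_io.write_matrix(cohort.mrna, p)),
        ("methylation.tsv", "methylation beta matrix",
         lambda p: omics_io.write_matrix(cohort.methylation, p)),
        ("regions.bed", "region table",
         lambda p: omics_io.write_regions(cohort.regions, p)),
        ("gene_model.tsv", "gene model",
         lambda p: omics_io.write_gene_model(cohort.gene_model, p)),
        ("clinical.csv", "clinical table",
         lambda p: omics_io.write_clinical(cohort.clinical, p)),
        ("pathways.gmt", "pathway gene sets",
         lambda p: omics_io.write_gmt(cohort.pathways, p)),
        ("truth_subgroups.tsv", "ground-truth subgroup labels",
         lambda p: cohort.truth.subgroup_of_sample.rename_axis("sample")
         .to_frame().to_csv(p, sep="\t")),
    ]
    rows = []
    for fname, role, writer in plan:
        path = directory / fname
        writer(path)
        rows.append({"file": fname, "role": role, "sha256": _sha256(path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return manifest
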