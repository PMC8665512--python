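"""Differential methylation, genomic annotation, and the Gaussian-mixture
classification of methylation-attenuated proteins.

DMR calling: regions (autosomes only) are tested across subgroups with
Kruskal-Wallis on M-values (logit of beta, clipped away from 0/1), BH
adjusted, and called when additionally the largest pairwise mean-beta
difference reaches ``min_delta``.

Attenuation: per gene, methylation (mean beta over its linked DMRs) is
rank-correlated with mRNA and with protein across samples. The
attenuation score r_meth_protein - r_meth_mrna is high for genes where
methylation's (negative) effect reaches the transcript but is damped at
the protein — the construction used for copy-number attenuation in
tumor proteogenomics, transported to methylation. Scores across genes
are modelled as a two-component univariate Gaussian mixture fitted by
EM; the component with the larger mean is the attenuated class, and a
gene is called attenuated when its posterior for that component is at
least 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import OmicsMatrix, PathwayDB, ValidationError
from .stats import bh_adjust, hypergeom_ora, rowwise_spearman

log = logging.getLogger(__name__)

SEX_CHROMS = {"chrX", "chrY", "X", "Y", "chrM", "MT"}
BETA_CLIP = (0.001, 0.999)


def m_values(beta: np.ndarray) -> np.ndarray:
    """M = log2(beta / (1 - beta)) with beta clipped to [0.001, 0.999]."""
    b = np.clip(beta, *BETA_CLIP)
    return np.log2(b / (1.0 - b))


def call_dmrs(
    meth: OmicsMatrix,
    regions: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    min_delta: float = 0.1,
) -> pd.DataFrame:
    """Kruskal-Wallis DMR calling across subgroups on M-values.

    Sex-chromosome regions are dropped (with a log line) so calls cover
    autosomes only. A region is a DMR iff BH-adjusted p < alpha AND the
    max pairwise |Delta mean beta| >= min_delta. Returns all tested
    regions with an ``is_dmr`` flag plus coordinates.
    """
    labels = labels.loc[meth.sample_ids]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValidationError("need >= 2 subgroups for DMR calling")
    reg = regions.set_index("region_id")
    shared = [r for r in meth.feature_ids if r in reg.index]
    if not shared:
        raise ValidationError("no region in the matrix matches the region table")
    autosomal = [r for r in shared if reg.loc[r, "chrom"] not in SEX_CHROMS]
    n_dropped = len(shared) - len(autosomal)
    if n_dropped:
        log.info("dropped %d sex-chromosome regions", n_dropped)
    beta = meth.values.loc[autosomal].to_numpy(dtype=float)
    if np.isnan(beta).any():
        raise ValidationError("methylation matrix must be complete")
    mvals = m_values(beta)
    idx_by_group = [np.where((labels == c).to_numpy())[0] for c in groups]
    hs = np.empty(len(autosomal))
    ps = np.empty(len(autosomal))
    for i in range(len(autosomal)):
        chunks = [mvals[i, idx] for idx in idx_by_group]
        if np.ptp(mvals[i]) == 0:
            hs[i], ps[i] = 0.0, 1.0
            continue
        hs[i], ps[i] = sps.kruskal(*chunks)
    adj = bh_adjust(ps)
    group_means = np.stack([beta[:, idx].mean(axis=1) for idx in idx_by_group], axis=1)
    max_delta = group_means.max(axis=1) - group_means.min(axis=1)
    # signed: difference between the extreme groups
    sign = np.sign(np.argmax(group_means, axis=1) - np.argmin(group_means, axis=1))
    out = pd.DataFrame({
        "region_id": autosomal,
        "chrom": reg.loc[autosomal, "chrom"].to_numpy(),
        "start": reg.loc[autosomal, "start"].to_numpy(),
        "end": reg.loc[autosomal, "end"].to_numpy(),
        "H": hs,
        "p": ps,
        "adj_p": adj,
        "max_delta_beta": max_delta * np.where(sign == 0, 1, sign),
    })
    out["is_dmr"] = (out["adj_p"] < alpha) & (max_delta >= min_delta)
    return out


def annotate_regions(
    regions: pd.DataFrame, gene_model: pd.DataFrame, promoter_window: int = 1500
) -> pd.DataFrame:
    """Annotate regions as promoter / gene_body / intergenic.

    All coordinates 0-based half-open; overlap = any shared base.
    Promoter = overlap with [TSS - w, TSS + w) (strand-aware TSS),
    taking precedence over gene_body = overlap with [start, end).
    Multi-gene hits resolve to the gene with the nearest TSS.
    """
    if (regions["start"] >= regions["end"]).any():
        raise ValidationError("region with start >= end")
    gm = gene_model
    ann, linked = [], []
    by_chrom = {c: sub for c, sub in gm.groupby("chrom")}
    for _, row in regions.iterrows():
        sub = by_chrom.get(row["chrom"])
        if sub is None:
            ann.append("intergenic")
            linked.append(None)
            continue
        rs, re_ = int(row["start"]), int(row["end"])
        tss = sub["tss"].to_numpy()
        prom_hit = (rs < tss + promoter_window) & (re_ > tss - promoter_window)
        body_hit = (rs < sub["end"].to_numpy()) & (re_ > sub["start"].to_numpy())
        mid = (rs + re_ - 1) / 2.0
        if prom_hit.any():
            cand = np.where(prom_hit)[0]
            best = cand[int(np.argmin(np.abs(tss[cand] - mid)))]
            ann.append("promoter")
            linked.append(sub["gene"].iloc[best])
        elif body_hit.any():
            cand = np.where(body_hit)[0]
            best = cand[int(np.argmin(np.abs(tss[cand] - mid)))]
            ann.append("gene_body")
            linked.append(sub["gene"].iloc[best])
        else:
            ann.append("intergenic")
            linked.append(None)
    out = regions.copy()
    out["annotation"] = ann
    out["annotated_gene"] = linked
    return out


@dataclass
class GMMFit:
    means: np.ndarray  # (2,)
    sds: np.ndarray  # (2,)
    weight: float  # weight of component 0
    loglik_trace: list
    converged: bool
    degenerate: bool


def fit_two_component_gmm(
    scores: np.ndarray, tol: float = 1e-8, max_iter: int = 1000, seed: int = 0
) -> GMMFit:
    """EM fit of a 1-D two-component Gaussian mixture.

    Initialised from the means of the two extreme quartiles of the data
    (a deterministic k-means-style split), equal weights, pooled SD.
    The log-likelihood is asserted non-decreasing at every step.
    Degenerate fits (component weight < 0.01 or sd < 1e-6) are flagged.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 20:
        raise ValidationError("mixture unidentifiable with < 20 scores")
    q = np.quantile(x, [0.25, 0.75])
    lo, hi = x[x <= q[0]], x[x >= q[1]]
    means = np.array([lo.mean(), hi.mean()])
    sds = np.array([x.std(ddof=0)] * 2)
    if sds[0] == 0:
        return GMMFit(means=np.array([x.mean(), x.mean()]), sds=np.array([0.0, 0.0]),
                      weight=1.0, loglik_trace=[], converged=True, degenerate=True)
    w = 0.5
    prev_ll = -np.inf
    trace = []
    converged = False
    for _ in range(max_iter):
        log_pdf0 = sps.norm.logpdf(x, means[0], max(sds[0], 1e-12))
        log_pdf1 = sps.norm.logpdf(x, means[1], max(sds[1], 1e-12))
        a = np.log(w) + log_pdf0
        b = np.log1p(-w) + log_pdf1
        m_ = np.maximum(a, b)
        ll = float(np.sum(m_ + np.log(np.exp(a - m_) + np.exp(b - m_))))
        if ll + 1e-9 < prev_ll:
            raise AssertionError("EM log-likelihood decreased")
        trace.append(ll)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        r0 = np.exp(a - m_) / (np.exp(a - m_) + np.exp(b - m_))
        n0 = r0.sum()
        n1 = x.size - n0
        if n0 < 1e-9 or n1 < 1e-9:
            break
        means = np.array([(r0 * x).sum() / n0, ((1 - r0) * x).sum() / n1])
        sds = np.sqrt(np.array([
            (r0 * (x - means[0]) ** 2).sum() / n0,
            ((1 - r0) * (x - means[1]) ** 2).sum() / n1,
        ]))
        w = n0 / x.size
    degenerate = (min(w, 1 - w) < 0.01) or (sds.min() < 1e-6)
    return GMMFit(means=means, sds=sds, weight=float(w),
                  loglik_trace=trace, converged=converged, degenerate=degenerate)


def attenuation_gmm(
    meth: OmicsMatrix,
    mrna: OmicsMatrix,
    protein: OmicsMatrix,
    dmr_gene_links: pd.DataFrame,
    seed: int = 0,
) -> tuple[pd.DataFrame, GMMFit]:
    """Score and classify methylation-attenuated genes.

    ``dmr_gene_links`` needs columns region_id and gene (promoter or
    gene-body links). Per gene: methylation summary = mean beta over
    linked regions; r_meth_rna / r_meth_prot = Spearman across shared
    samples; atten_score = r_meth_prot - r_meth_rna. The mixture fit
    (see :func:`fit_two_component_gmm`) classifies genes; on a
    degenerate fit nothing is called attenuated and the fit is flagged.
    """
    samples = sorted(set(meth.sample_ids) & set(mrna.sample_ids)
                     & set(protein.sample_ids))
    if len(samples) < 5:
        raise ValidationError("need >= 5 shared samples across the three omics")
    links = dmr_gene_links.dropna(subset=["gene"])
    genes = sorted(
        set(links["gene"]) & set(mrna.feature_ids) & set(protein.feature_ids)
    )
    region_set = set(meth.feature_ids)
    meth_rows, kept = [], []
    links_by_gene = links.groupby("gene")["region_id"].apply(list)
    for gg in genes:
        regs = [r for r in links_by_gene.get(gg, []) if r in region_set]
        if not regs:
            continue
        meth_rows.append(meth.values.loc[regs, samples].mean(axis=0).to_numpy())
        kept.append(gg)
    if len(kept) < 20:
        raise ValidationError("fewer than 20 genes with linked DMRs; "
                              "mixture unidentifiable")
    meth_mat = np.vstack(meth_rows)
    rna_mat = mrna.values.loc[kept, samples].to_numpy(dtype=float)
    prot_mat = protein.values.loc[kept, samples].to_numpy(dtype=float)
    if np.isnan(rna_mat).any() or np.isnan(prot_mat).any():
        raise ValidationError("mRNA/protein matrices must be complete (imputed)")
    r_rna = rowwise_spearman(meth_mat, rna_mat)
    r_prot = rowwise_spearman(meth_mat, prot_mat)
    score = r_prot - r_rna
    ok = ~np.isnan(score)
    fit = fit_two_component_gmm(score[ok], seed=seed)
    post_att = np.full(len(kept), np.nan)
    if not fit.degenerate:
        att_comp = int(np.argmax(fit.means))
        weights = np.array([fit.weight, 1.0 - fit.weight])
        pdf = np.stack([
            weights[0] * sps.norm.pdf(score[ok], fit.means[0], fit.sds[0]),
            weights[1] * sps.norm.pdf(score[ok], fit.means[1], fit.sds[1]),
        ])
        post_att[ok] = pdf[att_comp] / pdf.sum(axis=0)
    else:
        post_att[ok] = 0.0
    result = pd.DataFrame({
        "gene": kept,
        "r_meth_rna": r_rna,
        "r_meth_prot": r_prot,
        "atten_score": score,
        "posterior_attenuated": post_att,
        "attenuated": post_att >= 0.5,
    })
    return result, fit


def attenuated_ora(attenuated: set, universe: set, pathways: PathwayDB
                   ) -> pd.DataFrame:
    """Hypergeometric over-representation of the attenuated gene set
    against the analyzed-gene universe, BH adjusted."""
    return hypergeom_ora(attenuated, universe, pathways)
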