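"""Per-gene mRNA-protein correlation and KS pathway enrichment.

A gene's transcript and protein abundances are correlated across
samples (Spearman by default — robust to the monotone distortions that
differ between RNA-seq and TMT quantification), p-values are BH
adjusted across all testable genes, and "significant positive" means
adjusted p below alpha with rho > 0. Pathway-level signal is assessed
by a two-sample Kolmogorov-Smirnov test of member vs non-member
correlations over the correlation-ranked gene list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import OmicsMatrix, PathwayDB, ValidationError
from .stats import bh_adjust, percent


@dataclass
class PairedOmics:
    genes: list[str]
    samples: list[str]
    protein: pd.DataFrame  # genes x samples, aligned
    mrna: pd.DataFrame


def pair_genes(protein: OmicsMatrix, mrna: OmicsMatrix) -> PairedOmics:
    """Align the two omics on the intersection of genes and samples
    (both sorted); mRNA-protein pairing is by exact symbol match."""
    genes = sorted(set(protein.feature_ids) & set(mrna.feature_ids))
    samples = sorted(set(protein.sample_ids) & set(mrna.sample_ids))
    if not genes:
        raise ValidationError("no shared genes between protein and mRNA matrices")
    if not samples:
        raise ValidationError("no shared samples between protein and mRNA matrices")
    return PairedOmics(
        genes=genes,
        samples=samples,
        protein=protein.values.loc[genes, samples],
        mrna=mrna.values.loc[genes, samples],
    )


def correlate(
    paired: PairedOmics, method: str = "spearman", alpha: float = 0.01
) -> tuple[pd.DataFrame, dict]:
    """Per-gene cross-omic correlation with BH control.

    Returns (records, summary). Records columns: gene, n_pairs, rho, p,
    adj_p, significant_positive. Correlations use pairwise-complete
    observations, so per-gene ``n_pairs`` can differ when entries are
    missing; genes with < 3 complete pairs or a constant vector are
    flagged (rho = NaN) and excluded from the BH denominator. The
    summary reports the median rho and the significant-positive count
    and percentage (one decimal), mirroring how such screens are
    conventionally reported.
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown correlation method {method!r}")
    prot = paired.protein.to_numpy(dtype=float)
    mrna = paired.mrna.to_numpy(dtype=float)
    if prot.shape[1] < 3:
        raise ValidationError("need >= 3 shared samples to correlate")
    n_genes = prot.shape[0]
    rho = np.full(n_genes, np.nan)
    p = np.full(n_genes, np.nan)
    n_pairs = np.zeros(n_genes, dtype=int)
    complete = ~(np.isnan(prot) | np.isnan(mrna))
    for i in range(n_genes):
        obs = complete[i]
        n_pairs[i] = int(obs.sum())
        if n_pairs[i] < 3:
            continue
        a, b = prot[i, obs], mrna[i, obs]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        if method == "spearman":
            res = sps.spearmanr(a, b)
        else:
            res = sps.pearsonr(a, b)
        rho[i], p[i] = float(res.statistic), float(res.pvalue)
    adj = bh_adjust(p)
    records = pd.DataFrame({
        "gene": paired.genes,
        "n_pairs": n_pairs,
        "rho": rho,
        "p": p,
        "adj_p": adj,
        "significant_positive": (adj < alpha) & (rho > 0),
    })
    records["significant_positive"] = records["significant_positive"].fillna(False)
    n_tested = int(np.sum(~np.isnan(p)))
    n_sig = int(records["significant_positive"].sum())
    summary = {
        "n_pairs": len(paired.genes),
        "n_tested": n_tested,
        "median_rho": float(np.nanmedian(rho)) if n_tested else float("nan"),
        "n_significant_positive": n_sig,
        "pct_significant_positive": percent(n_sig, n_tested) if n_tested else float("nan"),
        "alpha": alpha,
    }
    return records, summary


def discordant_genes(records: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Genes with significant discordant (negative) cross-omic correlation."""
    sel = (records["adj_p"] < alpha) & (records["rho"] < 0)
    return records.loc[sel.fillna(False)].copy()


def ks_pathway_enrichment(
    scores: pd.Series, pathways: PathwayDB, min_members: int = 5
) -> pd.DataFrame:
    """Two-sample KS enrichment of per-gene scores by pathway.

    ``scores`` is indexed by gene (e.g. the mRNA-protein rho). For each
    pathway with at least ``min_members`` scored genes and a non-empty
    complement, member scores are compared to non-member scores;
    direction is the sign of (mean member - mean non-member). Pathways
    failing the size requirement are skipped (listed in the output with
    status "skipped").
    """
    scores = scores.dropna()
    if not np.isfinite(scores.to_numpy()).all():
        raise ValidationError("scores must be finite")
    all_genes = set(scores.index)
    rows = []
    for name, (_desc, genes) in pathways.items():
        members = genes & all_genes
        non_members = all_genes - members
        if len(members) < min_members or len(non_members) == 0:
            rows.append({"pathway": name, "n_members": len(members),
                         "mean_rho": np.nan, "ks_stat": np.nan, "p": np.nan,
                         "direction": 0, "status": "skipped"})
            continue
        mv = scores.loc[sorted(members)].to_numpy()
        nv = scores.loc[sorted(non_members)].to_numpy()
        ks = sps.ks_2samp(mv, nv, method="auto")
        rows.append({
            "pathway": name,
            "n_members": len(members),
            "mean_rho": float(mv.mean()),
            "ks_stat": float(ks.statistic),
            "p": float(ks.pvalue),
            "direction": int(np.sign(mv.mean() - nv.mean())),
            "status": "tested",
        })
    df = pd.DataFrame(rows, columns=["pathway", "n_members", "mean_rho",
                                     "ks_stat", "p", "direction", "status"])
    df["adj_p"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df
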