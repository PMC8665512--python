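"""Pathway activity score (PAS) with a label-permutation null.

A gene's relative abundance in a sample is its linear-scale value
divided by the gene's mean over all samples; PAS of pathway j in
subgroup c is the mean, over the pathway's measured genes, of the
gene's mean relative abundance within the subgroup. PAS = 1 is
cohort-average activity. Significance comes from permuting subgroup
labels (which preserves gene-gene covariance): the two-sided
permutation p is

    p = (1 + #{b : |PAS_b - 1| >= |PAS_obs - 1|}) / (B + 1).

Input matrices on a log scale are exponentiated first — ratios of log
values are not meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import OmicsMatrix, PathwayDB, ValidationError


def _linear_values(m: OmicsMatrix, log_base: float | None) -> np.ndarray:
    vals = m.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("PAS requires a complete (imputed) matrix")
    if log_base is not None:
        vals = np.power(log_base, vals)
    if (vals < 0).any():
        raise ValidationError("linear-scale abundances must be non-negative")
    return vals


def _group_matrix(labels: np.ndarray, groups: list) -> np.ndarray:
    """samples x groups column-normalised membership (means operator)."""
    M = np.zeros((labels.size, len(groups)))
    for j, c in enumerate(groups):
        idx = labels == c
        M[idx, j] = 1.0 / idx.sum()
    return M


def pathway_activity_score(
    m: OmicsMatrix,
    labels: pd.Series,
    pathways: PathwayDB,
    B: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    log_base: float | None = 2.0,
) -> pd.DataFrame:
    """Long-format PAS results: pathway, subgroup, n_genes, pas, perm_p,
    significant.

    ``log_base`` — base used to de-log the matrix (None if already
    linear). Pathways with no measured genes are skipped; subgroups of
    size < 3 raise.
    """
    labels = labels.loc[m.sample_ids]
    groups = sorted(labels.unique())
    labs = labels.to_numpy()
    for c in groups:
        if (labs == c).sum() < 3:
            raise ValidationError(f"subgroup {c} has fewer than 3 samples")
    vals = _linear_values(m, log_base)
    gene_mean = vals.mean(axis=1, keepdims=True)
    if (gene_mean == 0).any():
        raise ValidationError("gene with zero mean abundance")
    rel = vals / gene_mean  # relative abundance, rows average to 1

    feature_pos = {fid: i for i, fid in enumerate(m.feature_ids)}
    path_rows = []
    A_rows = []
    for name, (_desc, genes) in pathways.items():
        idx = [feature_pos[gg] for gg in sorted(genes) if gg in feature_pos]
        if not idx:
            continue
        row = np.zeros(m.n_features)
        row[idx] = 1.0 / len(idx)
        path_rows.append((name, len(idx)))
        A_rows.append(row)
    if not path_rows:
        raise ValidationError("no pathway has measured genes")
    A = np.vstack(A_rows)  # pathways x genes
    AR = A @ rel  # pathways x samples: per-pathway mean relative abundance

    M_obs = _group_matrix(labs, groups)
    pas_obs = AR @ M_obs  # pathways x groups
    dev_obs = np.abs(pas_obs - 1.0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(pas_obs)
    for _ in range(B):
        perm = rng.permutation(labs)
        pas_b = AR @ _group_matrix(perm, groups)
        exceed += np.abs(pas_b - 1.0) >= dev_obs - 1e-12
    perm_p = (1.0 + exceed) / (B + 1.0)

    rows = []
    for i, (name, n_genes) in enumerate(path_rows):
        for j, c in enumerate(groups):
            rows.append({
                "pathway": name, "subgroup": c, "n_genes": n_genes,
                "pas": float(pas_obs[i, j]), "perm_p": float(perm_p[i, j]),
                "significant": bool(perm_p[i, j] <= alpha),
            })
    return pd.DataFrame(rows)


def pas_heatmap_table(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pathway x subgroup PAS matrix with non-significant cells masked
    (NaN), the conventional blank-cell heatmap layout."""
    wide = results.pivot(index="pathway", columns="subgroup", values="pas")
    pmat = results.pivot(index="pathway", columns="subgroup", values="perm_p")
    return wide.where(pmat <= alpha)
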