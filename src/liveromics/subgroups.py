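"""Unsupervised proteomic subgroup discovery and subgroup statistics.

Consensus clustering: features are z-scored, samples are compared with a
1 - Spearman-correlation distance, and for each candidate K the cohort
is repeatedly subsampled (80% by default) and partitioned with
k-medoids. Co-clustering frequencies among co-sampled pairs form the
consensus matrix; final labels come from an average-linkage cut of
1 - consensus, and K is selected by the maximal relative gain in the
area under the consensus CDF (Monti-style delta-area).

Differential expression between subgroups uses the Kruskal-Wallis test
(tie-corrected, chi-square reference) with BH control; with two groups
it coincides with the tie-corrected Wilcoxon rank-sum chi-square, which
is asserted in the test-suite as a consistency contract.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import (ClinicalTable, OmicsMatrix, PathwayDB,
                        SubgroupAssignment, ValidationError)
from .stats import bh_adjust, fisher_exact_rxc

log = logging.getLogger(__name__)


def _spearman_distance(values: np.ndarray) -> np.ndarray:
    """1 - Spearman correlation between columns (samples)."""
    ranks = sps.rankdata(values, axis=0)
    ranks = ranks - ranks.mean(axis=0, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=0))
    norms[norms == 0] = 1.0
    corr = (ranks.T @ ranks) / np.outer(norms, norms)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _kmedoids(dist: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int = 100) -> np.ndarray:
    """Voronoi-iteration k-medoids on a precomputed distance matrix."""
    n = dist.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    assign = np.argmin(dist[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.where(assign == j)[0]
            if members.size == 0:
                # re-seed an empty cluster at the point farthest from its medoid
                far = int(np.argmax(dist[np.arange(n), medoids[assign]]))
                new_medoids[j] = far
                continue
            within = dist[np.ix_(members, members)].sum(axis=0)
            new_medoids[j] = members[int(np.argmin(within))]
        new_assign = np.argmin(dist[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_assign, assign):
            break
        medoids, assign = new_medoids, new_assign
    return assign


def _consensus_for_k(dist: np.ndarray, k: int, n_resamples: int,
                     subsample_fraction: float, rng: np.random.Generator
                     ) -> np.ndarray:
    n = dist.shape[0]
    m = max(k + 1, int(round(subsample_fraction * n)))
    hits = np.zeros((n, n))
    both = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        assign = _kmedoids(dist[np.ix_(idx, idx)], k, rng)
        both[np.ix_(idx, idx)] += 1.0
        for j in range(k):
            members = idx[assign == j]
            hits[np.ix_(members, members)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(both > 0, hits / np.maximum(both, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    return (consensus + consensus.T) / 2.0


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries;
    equals 1 - mean(consensus) for values on [0, 1]."""
    iu = np.triu_indices_from(consensus, k=1)
    return float(1.0 - consensus[iu].mean())


def consensus_cluster(
    m: OmicsMatrix,
    K_range=(2, 6),
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    K_fixed: int | None = None,
) -> SubgroupAssignment:
    """Consensus k-medoids clustering of samples; see module docstring.

    ``K_range`` is inclusive. With ``K_fixed`` the CDF-area selection is
    bypassed and only that K is resampled.
    """
    if m.mask.to_numpy().any():
        raise ValidationError("consensus_cluster requires a complete matrix")
    n = m.n_samples
    k_lo, k_hi = int(K_range[0]), int(K_range[1])
    if k_lo < 2 or k_hi > n - 1 or k_lo > k_hi:
        raise ValidationError(f"K range [{k_lo},{k_hi}] outside [2,{n - 1}]")
    vals = m.values.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd
    dist = _spearman_distance(z)
    rng = np.random.default_rng(seed)

    ks = [K_fixed] if K_fixed is not None else list(range(k_lo, k_hi + 1))
    consensus_by_k: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    for k in ks:
        consensus_by_k[k] = _consensus_for_k(dist, k, n_resamples,
                                             subsample_fraction, rng)
        areas[k] = _cdf_area(consensus_by_k[k])
    deltas: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else areas[k]
    if K_fixed is not None:
        chosen = K_fixed
    else:
        # the consensus-CDF area grows mechanically with K; the signal is
        # how long the relative gain stays substantial. Select the largest
        # K whose relative delta-area is still >= min_gain (Monti-style
        # elbow); below the floor extra clusters only fragment stable ones.
        min_gain = 0.15
        qualifying = [k for k in ks if deltas[k] >= min_gain]
        chosen = max(qualifying) if qualifying else ks[0]

    cons = consensus_by_k[chosen]
    condensed = squareform(np.clip(1.0 - cons, 0.0, None), checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=chosen, criterion="maxclust")
    # relabel clusters 1..K by decreasing size (stable, order-free labels)
    sizes = pd.Series(raw).value_counts()
    remap = {old: new + 1 for new, old in enumerate(
        sorted(sizes.index, key=lambda c: (-sizes[c], c)))}
    labels = pd.Series([remap[c] for c in raw], index=m.sample_ids, name="subgroup")
    trace = pd.DataFrame({
        "K": ks,
        "cdf_area": [areas[k] for k in ks],
        "delta_area": [deltas[k] for k in ks],
        "selected": [k == chosen for k in ks],
    })
    return SubgroupAssignment(
        labels=labels, K=int(chosen),
        consensus=pd.DataFrame(cons, index=m.sample_ids, columns=m.sample_ids),
        selection_trace=trace,
    )


def kw_differential(m: OmicsMatrix, labels: pd.Series, alpha: float = 0.05
                    ) -> pd.DataFrame:
    """Kruskal-Wallis differential expression across subgroups.

    Returns per-feature H, p, BH-adjusted p, per-group medians, and the
    significance flag at ``alpha``. Requires >= 2 groups of >= 2 samples.
    """
    labels = labels.loc[m.sample_ids]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    idx_by_group = {c: np.where((labels == c).to_numpy())[0] for c in groups}
    for c, idx in idx_by_group.items():
        if idx.size < 2:
            raise ValidationError(f"group {c} has fewer than 2 samples")
    vals = m.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("kw_differential requires a complete matrix")
    hs = np.empty(m.n_features)
    ps = np.empty(m.n_features)
    for i in range(m.n_features):
        samples = [vals[i, idx] for idx in idx_by_group.values()]
        if np.ptp(np.concatenate(samples)) == 0:
            hs[i], ps[i] = 0.0, 1.0  # constant feature: H = 0 by definition
            continue
        h, p = sps.kruskal(*samples)
        hs[i], ps[i] = h, p
    adj = bh_adjust(ps)
    out = pd.DataFrame({"feature": m.feature_ids, "H": hs, "p": ps, "adj_p": adj})
    for c, idx in idx_by_group.items():
        out[f"median_g{c}"] = np.median(vals[:, idx], axis=1)
    out["significant"] = out["adj_p"] < alpha
    return out


def clinical_association(labels: pd.Series, clinical: ClinicalTable,
                         variables=("tnm_stage", "afp_high", "thrombus",
                                    "phenotype")) -> pd.DataFrame:
    """Fisher's exact association between subgroup and each categorical
    clinical variable (R x C exact by enumeration when feasible)."""
    df = clinical.frame.set_index("sample")
    common = [s for s in labels.index if s in df.index]
    labs = labels.loc[common]
    rows = []
    for var in variables:
        col = df.loc[common, var].dropna()
        cats = sorted(col.unique())
        if len(cats) < 2:
            log.info("clinical variable %s has a single category; skipped", var)
            rows.append({"variable": var, "n_categories": len(cats),
                         "p": np.nan, "method": "skipped"})
            continue
        table = pd.crosstab(labs.loc[col.index], col).to_numpy()
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        res = fisher_exact_rxc(table)
        rows.append({"variable": var, "n_categories": len(cats),
                     "p": res["p"], "method": res["method"]})
    return pd.DataFrame(rows)


def signature_scores(mrna: OmicsMatrix, signatures: PathwayDB) -> pd.DataFrame:
    """Per-sample mean-z signature scores plus immune / stroma /
    microenvironment aggregates.

    A signature's score for a sample is the mean z-score (across
    samples, per gene) of its measured member genes. Cell types whose
    GMT description contains the tag "immune" contribute to the immune
    score, "stromal"/"stroma" to the stroma score; microenvironment is
    their sum. Signatures with no measured genes are skipped.
    """
    vals = mrna.values.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd
    zf = pd.DataFrame(z, index=mrna.feature_ids, columns=mrna.sample_ids)
    scores = {}
    immune, stromal = [], []
    for name, (desc, genes) in signatures.items():
        members = sorted(genes & set(mrna.feature_ids))
        if not members:
            log.info("signature %s has no measured genes; skipped", name)
            continue
        scores[name] = zf.loc[members].mean(axis=0)
        tag = desc.lower()
        if "immune" in tag:
            immune.append(name)
        elif "stroma" in tag:
            stromal.append(name)
    out = pd.DataFrame(scores)
    out["immune_score"] = out[immune].sum(axis=1) if immune else 0.0
    out["stroma_score"] = out[stromal].sum(axis=1) if stromal else 0.0
    out["microenvironment_score"] = out["immune_score"] + out["stroma_score"]
    out.index.name = "sample"
    return out


def overlap_summary(named_sets: dict) -> pd.DataFrame:
    """Exact Venn-partition sizes for up to a handful of named sets.

    Returns one row per non-empty membership pattern (2^k - 1 rows),
    with a 0/1 column per set name and the exclusive region size.
    """
    names = list(named_sets)
    sets = {n: set(s) for n, s in named_sets.items()}
    rows = []
    for pattern in itertools.product([1, 0], repeat=len(names)):
        if not any(pattern):
            continue
        inside = [n for n, bit in zip(names, pattern) if bit]
        outside = [n for n, bit in zip(names, pattern) if not bit]
        region = set.intersection(*(sets[n] for n in inside))
        for n in outside:
            region -= sets[n]
        rows.append({**{n: b for n, b in zip(names, pattern)}, "size": len(region)})
    return pd.DataFrame(rows)
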