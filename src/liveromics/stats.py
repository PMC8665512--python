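"""Shared statistical utilities: BH adjustment, exact contingency tests,
over-representation, and vectorised rank correlation."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untestable features) are excluded from the multiplicity
    denominator and returned as NaN. Output order matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        bad = p[finite][(p[finite] < 0) | (p[finite] > 1)][0]
        raise ValidationError(f"p-value outside [0,1]: {bad}")
    out = np.full_like(p, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Share as a percentage rounded to the printed precision."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


def _log_table_prob(table: np.ndarray, lgamma_cache=math.lgamma) -> float:
    """Log probability of an R x C table under fixed margins
    (multivariate hypergeometric)."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lp = (
        sum(lgamma_cache(r + 1) for r in rows)
        + sum(lgamma_cache(c + 1) for c in cols)
        - lgamma_cache(n + 1)
        - sum(lgamma_cache(x + 1) for x in table.ravel())
    )
    return lp


def fisher_exact_rxc(table, max_total: int = 500,
                     max_tables: int = 500_000) -> dict:
    """Fisher's exact test for an R x C contingency table.

    2x2 tables use scipy's exact test. Larger tables are enumerated
    exactly over all tables with the observed margins when the grand
    total is <= ``max_total`` and the enumeration space is tractable
    (at most ~``max_tables`` candidate tables); otherwise a chi-square
    approximation is used and flagged in the returned ``method`` field.

    Returns dict with keys ``p``, ``method`` ("exact" | "chi2_approx").
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or (t < 0).any():
        raise ValidationError("contingency table must be a non-negative 2-D array")
    if t.shape == (2, 2):
        _, p = sps.fisher_exact(t, alternative="two-sided")
        return {"p": float(p), "method": "exact"}
    n = int(t.sum())
    # upper bound on the enumeration space: product over free cells
    bound = 1.0
    for i in range(t.shape[0] - 1):
        for j in range(t.shape[1] - 1):
            bound *= min(t[i].sum(), t[:, j].sum()) + 1
    if n > max_total or bound > max_tables:
        chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
        return {"p": float(p), "method": "chi2_approx"}

    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    obs_lp = _log_table_prob(t)
    tol = 1e-7  # tables as-or-less probable, with float slack
    total_p = 0.0

    ncols = len(cols)

    def recurse(row_idx: int, remaining_cols: tuple, acc_rows: list):
        nonlocal total_p
        if row_idx == len(rows) - 1:
            last = np.array(remaining_cols)
            if (last < 0).any():
                return
            cand = np.vstack(acc_rows + [last])
            lp = _log_table_prob(cand)
            if lp <= obs_lp + tol:
                total_p += math.exp(lp)
            return
        r = rows[row_idx]

        def fill(col_idx: int, left: int, row_acc: list):
            if col_idx == ncols - 1:
                if left <= remaining_cols[col_idx]:
                    row = row_acc + [left]
                    new_cols = tuple(
                        remaining_cols[j] - row[j] for j in range(ncols)
                    )
                    recurse(row_idx + 1, new_cols, acc_rows + [np.array(row)])
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                fill(col_idx + 1, left - v, row_acc + [v])

        fill(0, int(r), [])

    recurse(0, tuple(int(c) for c in cols), [])
    return {"p": float(min(total_p, 1.0)), "method": "exact"}


def hypergeom_ora(
    hits: set, universe: set, pathways, min_overlap: int = 1
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per pathway.

    ``hits`` must be a subset of ``universe``. Pathway membership is
    intersected with the universe before testing. Returns a frame with
    pathway, n_universe_members, n_hits, p, adj_p.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise ValidationError("hit set is not a subset of the universe")
    N, K = len(universe), len(hits)
    rows = []
    for name, (_desc, genes) in pathways.items():
        members = genes & universe
        m = len(members)
        if m == 0:
            continue
        k = len(members & hits)
        # P(X >= k), X ~ Hypergeom(N, m, K)
        p = float(sps.hypergeom.sf(k - 1, N, m, K)) if k >= min_overlap else 1.0
        rows.append({"pathway": name, "n_members": m, "n_hits": k, "p": p})
    df = pd.DataFrame(rows, columns=["pathway", "n_members", "n_hits", "p"])
    df["adj_p"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def rowwise_rank(a: np.ndarray) -> np.ndarray:
    """Average ranks along axis 1 (ties averaged)."""
    return sps.rankdata(a, axis=1)


def rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho between matching rows of two (features x samples)
    arrays; rows with zero variance yield NaN."""
    ra = rowwise_rank(a)
    rb = rowwise_rank(b)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / den
    rho[den == 0] = np.nan
    return rho


def spearman_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation (n >= 4)."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho**2, 1e-300, None))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    p[np.isnan(rho)] = np.nan
    return np.clip(p, 0.0, 1.0)
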