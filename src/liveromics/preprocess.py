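"""Protein-matrix preprocessing: missingness filter, imputation, and
high-variance feature selection.

The filter removes a protein when it is missing in strictly more than
``max_missing_fraction`` of the samples (50% by default). Imputation
default is shifted-minimum (one log2 unit below the per-feature observed
minimum), reflecting the abundance-biased missingness of isobaric-label
MS data; a correlation-kNN alternative is provided. Feature selection
keeps the top fraction of proteins ranked by a robust spread statistic
(MAD by default).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import OmicsMatrix, ValidationError


def filter_missing(m: OmicsMatrix, max_missing_fraction: float = 0.5) -> OmicsMatrix:
    """Keep features with missing_count / n_samples <= threshold
    (strictly-greater removal); feature order preserved."""
    if not 0.0 < max_missing_fraction <= 1.0:
        raise ValidationError("max_missing_fraction must lie in (0,1]")
    frac = m.mask.mean(axis=1)
    keep = frac <= max_missing_fraction
    if not keep.any():
        raise ValidationError("missingness filter removed every feature")
    return m.copy_with(m.values.loc[keep])


def impute_half_min(m: OmicsMatrix, shift: float = 1.0) -> OmicsMatrix:
    """Replace each missing entry with (per-feature observed minimum) - shift."""
    vals = m.values.to_numpy(dtype=float).copy()
    miss = np.isnan(vals)
    n_obs = (~miss).sum(axis=1)
    if (n_obs == 0).any():
        feat = m.feature_ids[int(np.argmax(n_obs == 0))]
        raise ValidationError(f"feature {feat!r} has no observed values")
    fill = np.nanmin(vals, axis=1) - shift
    vals[miss] = np.broadcast_to(fill[:, None], vals.shape)[miss]
    return m.copy_with(pd.DataFrame(vals, index=m.values.index, columns=m.values.columns))


def impute_knn(m: OmicsMatrix, k: int = 5) -> OmicsMatrix:
    """Correlation-kNN imputation.

    For a missing entry (g, i), the k features most correlated with g
    over shared observed samples (and observed at sample i) each predict
    the value through the affine map matching g's observed mean/sd
    (sign-aware); the imputed value is the mean prediction. Falls back
    to the feature mean when no correlated neighbour is available.
    """
    if k < 1:
        raise ValidationError("knn_k must be >= 1")
    vals = m.values.to_numpy(dtype=float)
    miss = np.isnan(vals)
    if (np.sum(~miss, axis=1) == 0).any():
        raise ValidationError("feature with no observed values")
    out = vals.copy()
    if not miss.any():
        return m.copy_with(m.values.copy())
    # pairwise Pearson over shared samples via masked arrays
    ma = np.ma.masked_invalid(vals)
    corr = np.ma.corrcoef(ma).filled(np.nan)
    np.fill_diagonal(corr, np.nan)
    means = np.nanmean(vals, axis=1)
    sds = np.nanstd(vals, axis=1, ddof=0)
    for gi in np.unique(np.where(miss)[0]):
        order = np.argsort(-np.abs(corr[gi]))  # NaNs sort last
        for si in np.where(miss[gi])[0]:
            preds = []
            for nb in order:
                if len(preds) >= k or np.isnan(corr[gi, nb]):
                    break
                if np.isnan(vals[nb, si]) or sds[nb] == 0:
                    continue
                zn = (vals[nb, si] - means[nb]) / sds[nb]
                preds.append(means[gi] + math.copysign(1.0, corr[gi, nb]) * zn * sds[gi])
            out[gi, si] = np.mean(preds) if preds else means[gi]
    return m.copy_with(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))


def impute(m: OmicsMatrix, method: str = "half_min", knn_k: int = 5) -> OmicsMatrix:
    """Dispatch to the chosen imputation; observed entries never change."""
    if method == "half_min":
        return impute_half_min(m)
    if method == "knn":
        return impute_knn(m, k=knn_k)
    raise ValidationError(f"unknown imputation method {method!r}")


def select_variable(
    m: OmicsMatrix, variance_fraction: float = 0.25, variance_metric: str = "mad"
) -> OmicsMatrix:
    """Keep the ceil(fraction x n_features) most variable features.

    Ties broken by feature ID (lexicographic), making selection
    deterministic. Requires a fully observed matrix.
    """
    if m.mask.to_numpy().any():
        raise ValidationError("select_variable requires an imputed (complete) matrix")
    if not 0.0 < variance_fraction <= 1.0:
        raise ValidationError("variance_fraction must lie in (0,1]")
    vals = m.values.to_numpy(dtype=float)
    if variance_metric == "mad":
        metric = sps.median_abs_deviation(vals, axis=1)
    elif variance_metric == "sd":
        metric = vals.std(axis=1, ddof=1)
    else:
        raise ValidationError(f"unknown variance_metric {variance_metric!r}")
    n_keep = math.ceil(variance_fraction * m.n_features)
    order = sorted(range(m.n_features), key=lambda i: (-metric[i], m.feature_ids[i]))
    keep_ids = sorted(m.feature_ids[i] for i in order[:n_keep])
    # preserve original row order among the kept features
    keep = [fid for fid in m.feature_ids if fid in set(keep_ids)]
    return m.copy_with(m.values.loc[keep])
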