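"""Recurrence-free survival analyses: early-relapse tests, Kaplan-Meier /
log-rank, multivariable Cox adjustment, and the supervised prognostic
marker screen.

Early relapse is a recurrence event within 24 months of surgery. A
patient censored before the horizon without an event is indeterminate —
their early-relapse status is unknowable — and is excluded from
proportion tests. Kaplan-Meier and log-rank use administrative
censoring at the horizon; the multivariable Cox model (Efron tie
handling) adjusts subgroup effects for TNM stage, AFP and tumor
thrombus.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from .datatypes import ClinicalTable, OmicsMatrix, ValidationError
from .stats import bh_adjust

log = logging.getLogger(__name__)

TNM_ORDINAL = {"I": 1, "II": 2, "III": 3, "IV": 4}


def early_relapse_flag(clinical: ClinicalTable, horizon_months: float = 24.0
                       ) -> pd.Series:
    """1 = event within the horizon, 0 = known relapse-free through the
    horizon (event later, or censored at/after it), NaN = indeterminate
    (censored before the horizon without an event)."""
    df = clinical.frame
    flag = pd.Series(np.nan, index=df["sample"], name="early_relapse")
    event_within = (df["rfs_event"] == 1) & (df["rfs_months"] <= horizon_months)
    known_free = ((df["rfs_event"] == 1) & (df["rfs_months"] > horizon_months)) | (
        (df["rfs_event"] == 0) & (df["rfs_months"] >= horizon_months)
    )
    flag[event_within.to_numpy()] = 1.0
    flag[known_free.to_numpy()] = 0.0
    return flag


def relapse_proportion_test(
    flags: pd.Series,
    labels: pd.Series,
    pairs=((2, 1), (2, 3)),
    strata: pd.Series | None = None,
) -> pd.DataFrame:
    """Fisher's exact test of early-relapse proportions per subgroup pair.

    Indeterminate samples (NaN flags) are excluded. With ``strata``
    (e.g. TNM stage) each pair is tested within each stratum; empty or
    single-group strata are skipped with a log line.
    """
    common = flags.index.intersection(labels.index)
    flags = flags.loc[common]
    labels = labels.loc[common]
    strata_iter = (
        [(None, pd.Series(True, index=common))]
        if strata is None
        else [(lvl, strata.loc[common] == lvl) for lvl in sorted(strata.dropna().unique())]
    )
    rows = []
    for stratum, in_stratum in strata_iter:
        for a, b in pairs:
            sel = in_stratum & flags.notna() & labels.isin([a, b])
            sub_f = flags[sel]
            sub_l = labels[sel]
            table = np.array([
                [(sub_f[sub_l == g] == 1).sum(), (sub_f[sub_l == g] == 0).sum()]
                for g in (a, b)
            ])
            if (table.sum(axis=1) == 0).any():
                log.info("relapse test %s vs %s in stratum %s: empty group, skipped",
                         a, b, stratum)
                rows.append({"stratum": stratum, "group_a": a, "group_b": b,
                             "n": int(table.sum()), "p": np.nan,
                             "status": "skipped"})
                continue
            _, p = sps.fisher_exact(table, alternative="two-sided")
            rows.append({
                "stratum": stratum, "group_a": a, "group_b": b,
                "n": int(table.sum()),
                "prop_a": float(table[0, 0] / table[0].sum()),
                "prop_b": float(table[1, 0] / table[1].sum()),
                "p": float(p), "status": "tested",
            })
    return pd.DataFrame(rows)


def _administrative_censor(df: pd.DataFrame, horizon: float | None
                           ) -> tuple[np.ndarray, np.ndarray]:
    t = df["rfs_months"].to_numpy(dtype=float)
    e = df["rfs_event"].to_numpy(dtype=int)
    if horizon is not None:
        e = np.where(t <= horizon, e, 0)
        t = np.minimum(t, horizon)
    return t, e


def km_logrank(
    clinical: ClinicalTable,
    labels: pd.Series,
    horizon_months: float | None = None,
) -> tuple[dict, dict]:
    """Kaplan-Meier curve per group plus the K-group log-rank test.

    Returns (curves, test) where curves maps group -> DataFrame with
    columns time, survival, at_risk, and test has chi2, df, p.
    """
    df = clinical.frame.set_index("sample").loc[labels.index].reset_index()
    t, e = _administrative_censor(df, horizon_months)
    if e.sum() == 0:
        raise ValidationError("no events observed; log-rank undefined")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    curves = {}
    for g in groups:
        sel = (labels == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], event_observed=e[sel], label=str(g))
        tab = kmf.event_table
        curves[g] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": tab["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
        })
    res = multivariate_logrank_test(t, labels.to_numpy(), e)
    test = {"chi2": float(res.test_statistic), "df": len(groups) - 1,
            "p": float(res.p_value)}
    return curves, test


def cox_score_test(time, event, x) -> dict:
    """Score test of a single covariate at beta = 0 in the Cox partial
    likelihood (Breslow risk sets; with no tied event times this equals
    the log-rank chi-square)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    xv = np.asarray(x, dtype=float)
    order = np.argsort(t, kind="stable")
    t, e, xv = t[order], e[order], xv[order]
    U = 0.0
    V = 0.0
    for i in np.where(e == 1)[0]:
        risk = t >= t[i]
        xr = xv[risk]
        mean = xr.mean()
        U += xv[i] - mean
        V += ((xr - mean) ** 2).mean()
    if V == 0:
        raise ValidationError("degenerate covariate in score test")
    return {"U": float(U), "V": float(V), "chi2": float(U * U / V),
            "p": float(sps.chi2.sf(U * U / V, df=1))}


def cox_multivariable(
    clinical: ClinicalTable,
    labels: pd.Series | None = None,
    covariates=("tnm_stage", "afp_high", "thrombus"),
    extra: pd.DataFrame | None = None,
    horizon_months: float | None = None,
) -> pd.DataFrame:
    """Multivariable Cox PH fit (Efron ties) of RFS on proteomic
    subgroups plus clinicopathologic covariates.

    Subgroup enters as indicator columns against the first (reference)
    subgroup; TNM stage is encoded ordinally I..IV -> 1..4. ``extra``
    may add numeric per-sample covariates (indexed by sample). Returns
    the coefficient table (coef, HR, se, p) and raises on perfect
    separation / non-convergence.
    """
    df = clinical.frame.set_index("sample").copy()
    t, e = _administrative_censor(df.reset_index(), horizon_months)
    X = pd.DataFrame(index=df.index)
    X["time"] = t
    X["event"] = e
    for cov in covariates:
        if cov == "tnm_stage":
            X["tnm_stage"] = df["tnm_stage"].map(TNM_ORDINAL)
        else:
            X[cov] = pd.to_numeric(df[cov])
    if labels is not None:
        labs = labels.loc[df.index]
        ref = sorted(labs.unique())[0]
        for g in sorted(labs.unique())[1:]:
            X[f"subgroup_{g}"] = (labs == g).astype(int)
    if extra is not None:
        for col in extra.columns:
            X[col] = extra.loc[df.index, col]
    X = X.dropna()
    cph = CoxPHFitter()
    try:
        cph.fit(X, duration_col="time", event_col="event")
    except Exception as err:  # lifelines ConvergenceError and friends
        raise ValidationError(f"Cox fit failed (separation or collinearity): {err}")
    # monotone likelihood (perfect separation) shows up as an exploding
    # coefficient / standard error rather than an exception
    bad = cph.summary[(cph.summary["se(coef)"] > 100)
                      | (cph.summary["coef"].abs() > 15)]
    if len(bad):
        raise ValidationError(
            f"monotone likelihood (perfect separation) for covariate "
            f"{bad.index[0]!r}")
    out = cph.summary[["coef", "exp(coef)", "se(coef)", "p"]].copy()
    out.columns = ["coef", "hazard_ratio", "se", "p"]
    out["converged"] = True
    return out


def marker_screen(
    protein: OmicsMatrix,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    covariates=("tnm_stage", "afp_high", "thrombus"),
) -> pd.DataFrame:
    """Three-stage supervised prognostic marker screen.

    Stage 1: per protein, Wilcoxon rank-sum between MI and MA samples,
    BH adjusted. Stage 2 (stage-1 hits): dichotomize at the median
    (ties to the low group) and log-rank on RFS. Stage 3: multivariable
    Cox of the high/low indicator adjusted for clinicopathologic
    covariates. A marker passes when significant at ``alpha`` in all
    three stages. Markers whose median split leaves a group empty are
    skipped.
    """
    df = clinical.frame.set_index("sample")
    pheno = df["phenotype"]
    mi = pheno[pheno == "MI"].index
    ma = pheno[pheno == "MA"].index
    mi = [s for s in mi if s in protein.sample_ids]
    ma = [s for s in ma if s in protein.sample_ids]
    if len(mi) < 5 or len(ma) < 5:
        raise ValidationError("need >= 5 samples in each phenotype group")
    vals = protein.values
    ps = []
    for g in protein.feature_ids:
        a = vals.loc[g, mi].dropna()
        b = vals.loc[g, ma].dropna()
        if len(a) < 2 or len(b) < 2 or np.ptp(np.concatenate([a, b])) == 0:
            ps.append(np.nan)
            continue
        ps.append(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    adj = bh_adjust(np.asarray(ps, dtype=float))
    out_rows = []
    clin_samples = [s for s in protein.sample_ids if s in df.index]
    for g, p_ph, ap in zip(protein.feature_ids, ps, adj):
        row = {"protein": g, "phenotype_p": p_ph, "phenotype_adj_p": ap,
               "cutoff": np.nan, "logrank_p": np.nan, "cox_adj_p": np.nan,
               "is_marker": False, "status": "phenotype_ns"}
        if not (np.isfinite(ap) and ap < alpha):
            out_rows.append(row)
            continue
        x = vals.loc[g, clin_samples]
        med = float(x.median())
        high = (x > med).astype(int)  # ties assigned to the low group
        if high.sum() == 0 or high.sum() == len(high):
            row["status"] = "degenerate_median_split"
            log.info("marker %s: median split degenerate; skipped", g)
            out_rows.append(row)
            continue
        row["cutoff"] = med
        sub_clin = clinical.subset(clin_samples)
        try:
            _, lr = km_logrank(sub_clin, high)
        except ValidationError:
            row["status"] = "no_events"
            out_rows.append(row)
            continue
        row["logrank_p"] = lr["p"]
        if lr["p"] >= alpha:
            row["status"] = "logrank_ns"
            out_rows.append(row)
            continue
        try:
            cox = cox_multivariable(sub_clin, covariates=covariates,
                                    extra=high.to_frame("marker_high"))
            row["cox_adj_p"] = float(cox.loc["marker_high", "p"])
        except (ValidationError, KeyError):
            row["status"] = "cox_failed"
            out_rows.append(row)
            continue
        row["is_marker"] = bool(row["cox_adj_p"] < alpha)
        row["status"] = "marker" if row["is_marker"] else "cox_ns"
        out_rows.append(row)
    return pd.DataFrame(out_rows)
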