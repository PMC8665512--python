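import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from liveromics import survival
from liveromics.datatypes import ClinicalTable, ValidationError

from conftest import make_clinical, make_matrix


def clinical_from(times, events, samples=None, **extra):
    n = len(times)
    samples = samples or [f"S{i:03d}" for i in range(n)]
    base = {
        "sample": samples,
        "rfs_months": times,
        "rfs_event": events,
        "tnm_stage": ["I"] * n,
        "afp_high": [0] * n,
        "thrombus": [0] * n,
        "phenotype": ["MA"] * n,
    }
    base.update(extra)
    return ClinicalTable(pd.DataFrame(base))


class TestEarlyRelapse:
    def test_flag_semantics(self):
        clin = clinical_from([12, 30, 10, 24, 25], [1, 0, 0, 1, 1])
        f = survival.early_relapse_flag(clin)
        assert f.iloc[0] == 1          # event at 12 months
        assert f.iloc[1] == 0          # censored at 30, no event
        assert np.isnan(f.iloc[2])     # censored at 10: indeterminate
        assert f.iloc[3] == 1          # event exactly at the horizon
        assert f.iloc[4] == 0          # event after the horizon


class TestProportionTest:
    def test_balanced_equal_tables_p_near_one(self):
        flags = pd.Series([1, 1, 0, 0] * 4, index=[f"S{i}" for i in range(16)])
        labels = pd.Series([1, 2] * 8, index=flags.index)
        res = survival.relapse_proportion_test(flags, labels, pairs=((1, 2),))
        assert res["p"].iloc[0] >= 0.99

    def test_8_2_table_matches_enumeration(self):
        # group A: 8 relapse / 2 free; group B: 2 / 8
        flags = pd.Series([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8,
                          index=[f"S{i}" for i in range(20)])
        labels = pd.Series([1] * 10 + [2] * 10, index=flags.index)
        res = survival.relapse_proportion_test(flags, labels, pairs=((1, 2),))
        # brute force over all 2x2 tables with margins (10, 10) x (10, 10)
        pmf = sps.hypergeom(20, 10, 10).pmf
        p_obs = pmf(8)
        total = sum(pmf(k) for k in range(11) if pmf(k) <= p_obs * (1 + 1e-9))
        assert res["p"].iloc[0] == pytest.approx(total, rel=1e-9)
        assert res["p"].iloc[0] == pytest.approx(0.023, abs=5e-4)

    def test_indeterminate_excluded(self):
        flags = pd.Series([1, np.nan, 0, 1, np.nan, 0],
                          index=[f"S{i}" for i in range(6)])
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=flags.index)
        res = survival.relapse_proportion_test(flags, labels, pairs=((1, 2),))
        assert res["n"].iloc[0] == 4

    def test_empty_stratum_skipped(self):
        flags = pd.Series([1, 0, 1, 0], index=[f"S{i}" for i in range(4)])
        labels = pd.Series([1, 1, 2, 2], index=flags.index)
        strata = pd.Series(["I", "I", "I", "I"], index=flags.index)
        strata.iloc[2:] = "II"  # stratum I has no group-2 samples
        res = survival.relapse_proportion_test(flags, labels, pairs=((1, 2),),
                                               strata=strata)
        assert (res["status"] == "skipped").all()


class TestKMLogrank:
    def test_no_events_raises(self):
        clin = clinical_from([10, 20, 30, 40], [0, 0, 0, 0])
        labels = pd.Series([1, 1, 2, 2], index=clin.frame["sample"])
        with pytest.raises(ValidationError, match="no events"):
            survival.km_logrank(clin, labels)

    def test_identical_groups_chi2_zero(self):
        clin = clinical_from([5, 10, 15, 5, 10, 15], [1, 1, 1, 1, 1, 1])
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=clin.frame["sample"])
        # identical event patterns in both groups
        clin.frame.loc[3:, "rfs_months"] = [5, 10, 15]
        curves, test = survival.km_logrank(clin, labels)
        assert test["chi2"] == pytest.approx(0.0, abs=1e-10)
        assert test["p"] == pytest.approx(1.0)

    def test_toy_table_hand_computation(self):
        # A events at 1,2,3; B events at 4,5,6; no censoring
        clin = clinical_from([1, 2, 3, 4, 5, 6], [1] * 6)
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=clin.frame["sample"])
        curves, test = survival.km_logrank(clin, labels)
        # hand-computed log-rank table (observed-minus-expected for A):
        # t=1: E=3/6, V=(1*5/5)*(3/6)(3/6)=0.25 ; t=2: E=2/5, V=0.24
        # t=3: E=1/4, V=0.1875 ; t=4,5,6: A risk set empty, E=V=0
        E = 3 / 6 + 2 / 5 + 1 / 4
        V = 0.25 + 0.24 + 0.1875
        chi2 = (3 - E) ** 2 / V
        assert test["chi2"] == pytest.approx(chi2, abs=1e-10)

    def test_km_equals_empirical_survival_without_censoring(self, rng):
        times = np.round(rng.exponential(20, size=40), 1).clip(min=0.1)
        clin = clinical_from(times, [1] * 40)
        labels = pd.Series([1] * 20 + [2] * 20, index=clin.frame["sample"])
        curves, _ = survival.km_logrank(clin, labels)
        for g, idx in ((1, slice(0, 20)), (2, slice(20, 40))):
            t_g = times[idx]
            for _, row in curves[g].iterrows():
                emp = np.mean(t_g > row["time"])
                assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_group_relabeling_invariance(self, rng):
        clin = make_clinical(40, rng)
        labels = pd.Series(rng.integers(1, 3, size=40),
                           index=clin.frame["sample"])
        _, t1 = survival.km_logrank(clin, labels)
        _, t2 = survival.km_logrank(clin, 3 - labels)
        assert t1["chi2"] == pytest.approx(t2["chi2"], abs=1e-12)

    def test_administrative_censoring_never_adds_events(self, rng):
        clin = make_clinical(60, rng)
        labels = pd.Series([1] * 30 + [2] * 30, index=clin.frame["sample"])
        full_events = clin.frame["rfs_event"].sum()
        t, e = survival._administrative_censor(clin.frame, 24.0)
        assert e.sum() <= full_events


class TestCox:
    def test_score_test_matches_logrank(self):
        rng = np.random.default_rng(0)
        n = 30
        times = rng.exponential(10, size=n) + rng.random(n) * 1e-6  # no ties
        events = rng.random(n) < 0.8
        group = rng.integers(0, 2, size=n)
        st_res = survival.cox_score_test(times, events.astype(int), group)
        clin = clinical_from(times, events.astype(int))
        labels = pd.Series(group + 1, index=clin.frame["sample"])
        _, lr = survival.km_logrank(clin, labels)
        assert st_res["chi2"] == pytest.approx(lr["chi2"], abs=1e-8)

    def test_null_covariate_coefficient_near_zero(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 500
            clin = make_clinical(n, rng)
            extra = pd.DataFrame(
                {"noise": rng.normal(size=n)},
                index=clin.frame["sample"])
            fit = survival.cox_multivariable(clin, covariates=(), extra=extra)
            hits += abs(fit.loc["noise", "coef"]) < 0.1
        assert hits >= 9

    def test_duplicating_subjects_leaves_coefficient_unchanged(self, rng):
        clin = make_clinical(60, rng)
        extra = pd.DataFrame({"x": rng.normal(size=60)},
                             index=clin.frame["sample"])
        fit1 = survival.cox_multivariable(clin, covariates=(), extra=extra)
        dup = clin.frame.copy()
        dup["sample"] = dup["sample"] + "d"
        clin2 = ClinicalTable(pd.concat([clin.frame, dup], ignore_index=True))
        extra2 = pd.concat([extra, extra.set_axis(dup["sample"])])
        fit2 = survival.cox_multivariable(clin2, covariates=(), extra=extra2)
        # exact under Breslow risk sets; Efron tie handling perturbs the
        # duplicated (now tied) event times slightly
        assert fit1.loc["x", "coef"] == pytest.approx(
            fit2.loc["x", "coef"], abs=0.05)

    def test_perfect_separation_raises(self):
        # covariate = event indicator with covariate-sorted times:
        # monotone likelihood
        times = np.array([1., 2, 3, 4, 50, 60, 70, 80])
        events = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        clin = clinical_from(times, events)
        extra = pd.DataFrame({"sep": events.astype(float)},
                             index=clin.frame["sample"])
        with pytest.raises(ValidationError):
            survival.cox_multivariable(clin, covariates=(), extra=extra)


class TestMarkerScreen:
    def planted_cohort(self, seed=0, n=77, n_prot=40):
        rng = np.random.default_rng(seed)
        pheno = rng.choice(["MI", "MA"], size=n)
        is_mi = pheno == "MI"
        vals = rng.normal(8, 1, size=(n_prot, n))
        vals[0, is_mi] += 2.0  # marker: higher in MI
        hazard = np.where(vals[0] > np.median(vals[0]), 0.12, 0.03)
        t_ev = rng.exponential(1 / hazard)
        t_c = rng.exponential(100, size=n)
        clin = clinical_from(
            np.round(np.minimum(t_ev, t_c), 1).clip(min=0.1),
            (t_ev <= t_c).astype(int),
            phenotype=list(pheno),
            tnm_stage=list(rng.choice(["I", "II", "III"], size=n)),
            afp_high=list(rng.integers(0, 2, size=n)),
            thrombus=list(rng.integers(0, 2, size=n)),
        )
        prot = make_matrix(vals, features=[f"P{i}" for i in range(n_prot)],
                           samples=list(clin.frame["sample"]))
        return prot, clin

    def test_constant_protein_skipped(self, rng):
        prot, clin = self.planted_cohort()
        vals = prot.values.copy()
        vals.iloc[5] = 3.0
        prot2 = prot.copy_with(vals)
        res = survival.marker_screen(prot2, clin).set_index("protein")
        assert not res.loc["P5", "is_marker"]

    def test_planted_marker_recovered_with_power(self):
        hits = 0
        n_sim = 20
        for seed in range(n_sim):
            prot, clin = self.planted_cohort(seed)
            res = survival.marker_screen(prot, clin).set_index("protein")
            hits += bool(res.loc["P0", "is_marker"])
        assert hits / n_sim >= 0.7

    def test_null_calibration_no_false_markers(self):
        """With phenotype-independent proteins, BH keeps the expected
        false-marker count at or below ~1 per 1,000 null proteins."""
        rng = np.random.default_rng(1)
        n = 77
        clin_base = make_clinical(n, rng)
        vals = rng.normal(size=(1000, n))
        prot = make_matrix(vals, features=[f"P{i}" for i in range(1000)],
                           samples=list(clin_base.frame["sample"]))
        res = survival.marker_screen(prot, clin_base)
        assert res["is_marker"].sum() <= 1
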