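import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from liveromics import subgroups
from liveromics.datatypes import PathwayDB, ValidationError

from conftest import make_clinical, make_matrix


def blob_matrix(rng, n=77, n_feat=60, sep=2.0, props=(0.4, 0.34, 0.26)):
    counts = [int(round(p * n)) for p in props]
    counts[-1] = n - sum(counts[:-1])
    labels = np.repeat([1, 2, 3], counts)
    rng.shuffle(labels)
    centers = rng.normal(0, sep, size=(3, n_feat))
    vals = centers[labels - 1].T + rng.normal(0, 1.0, size=(n_feat, n))
    return make_matrix(vals), labels


class TestConsensusCluster:
    def test_planted_partition_recovery(self, rng):
        m, truth = blob_matrix(rng)
        a = subgroups.consensus_cluster(m, (2, 5), n_resamples=100, seed=3)
        assert a.K == 3
        assert adjusted_rand_score(truth, a.labels.to_numpy()) >= 0.9

    def test_same_seed_identical_labels(self, rng):
        m, _ = blob_matrix(rng)
        a = subgroups.consensus_cluster(m, (2, 4), n_resamples=40, seed=9)
        b = subgroups.consensus_cluster(m, (2, 4), n_resamples=40, seed=9)
        assert a.labels.equals(b.labels)
        assert np.array_equal(a.consensus.to_numpy(), b.consensus.to_numpy())

    def test_duplicate_samples_always_cocluster(self, rng):
        m, _ = blob_matrix(rng, n=30, n_feat=40)
        dup = m.values.copy()
        dup.columns = [f"{c}x" for c in dup.columns]
        both = make_matrix(np.hstack([m.values, dup]),
                           features=m.feature_ids,
                           samples=list(m.sample_ids) + list(dup.columns))
        a = subgroups.consensus_cluster(both, (2, 3), n_resamples=50, seed=1,
                                        K_fixed=3)
        cons = a.consensus
        for s in m.sample_ids:
            assert cons.loc[s, f"{s}x"] == pytest.approx(1.0)

    def test_sample_order_invariance_of_structure(self, rng):
        m, _ = blob_matrix(rng)
        perm = rng.permutation(m.n_samples)
        shuffled = make_matrix(m.values.to_numpy()[:, perm],
                               features=m.feature_ids,
                               samples=[m.sample_ids[i] for i in perm])
        a = subgroups.consensus_cluster(m, (2, 4), n_resamples=80, seed=2)
        b = subgroups.consensus_cluster(shuffled, (2, 4), n_resamples=80, seed=2)
        common = sorted(m.sample_ids)
        ari = adjusted_rand_score(a.labels.loc[common], b.labels.loc[common])
        assert ari >= 0.9

    def test_k_range_validation(self, rng):
        m, _ = blob_matrix(rng, n=10)
        with pytest.raises(ValidationError):
            subgroups.consensus_cluster(m, (1, 3))
        with pytest.raises(ValidationError):
            subgroups.consensus_cluster(m, (2, 10))

    def test_consensus_entries_bounded(self, rng):
        m, _ = blob_matrix(rng, n=25)
        a = subgroups.consensus_cluster(m, (2, 3), n_resamples=30, seed=4)
        c = a.consensus.to_numpy()
        assert c.min() >= 0 and c.max() <= 1


class TestKWDifferential:
    def test_hand_rank_formula(self):
        # ranks {1..9} in thirds: H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2 = 7.2
        m = make_matrix([[1, 2, 3, 4, 5, 6, 7, 8, 9.0]])
        labels = pd.Series([1, 1, 1, 2, 2, 2, 3, 3, 3],
                           index=m.sample_ids)
        res = subgroups.kw_differential(m, labels)
        assert res["H"].iloc[0] == pytest.approx(7.2, abs=1e-10)

    def test_identical_values_H_zero(self):
        m = make_matrix([[5.0] * 9])
        labels = pd.Series([1, 1, 1, 2, 2, 2, 3, 3, 3], index=m.sample_ids)
        res = subgroups.kw_differential(m, labels)
        assert res["H"].iloc[0] == 0.0

    def test_two_group_equals_tie_corrected_ranksum(self, rng):
        vals = np.round(rng.normal(size=(6, 24)), 1)  # rounding forces ties
        m = make_matrix(vals)
        labels = pd.Series([1] * 10 + [2] * 14, index=m.sample_ids)
        res = subgroups.kw_differential(m, labels)
        for i in range(6):
            x = vals[i]
            ranks = sps.rankdata(x)
            W = ranks[:10].sum()
            n1, n2, N = 10, 14, 24
            _, counts = np.unique(x, return_counts=True)
            tie_term = ((counts**3 - counts).sum()) / (N * (N - 1))
            var = n1 * n2 / 12 * ((N + 1) - tie_term)
            z = (W - n1 * (N + 1) / 2) / np.sqrt(var)
            assert res["H"].iloc[i] == pytest.approx(z**2, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=(5, 20))
        m1 = make_matrix(vals)
        m2 = make_matrix(np.exp(vals))
        labels = pd.Series([1] * 7 + [2] * 7 + [3] * 6, index=m1.sample_ids)
        r1 = subgroups.kw_differential(m1, labels)
        r2 = subgroups.kw_differential(m2, labels)
        assert np.allclose(r1["H"], r2["H"], atol=1e-12)

    def test_small_group_rejected(self, rng):
        m = make_matrix(rng.normal(size=(2, 5)))
        labels = pd.Series([1, 1, 1, 1, 2], index=m.sample_ids)
        with pytest.raises(ValidationError):
            subgroups.kw_differential(m, labels)

    def test_null_fdr_control(self, rng):
        """On null data the mean count of adj_p<0.05 calls stays below
        0.05 x features tested."""
        counts = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            m = make_matrix(r.normal(size=(50, 30)))
            labels = pd.Series(r.integers(1, 4, size=30), index=m.sample_ids)
            if labels.value_counts().min() < 2:
                continue
            res = subgroups.kw_differential(m, labels)
            counts.append(res["significant"].sum())
        assert np.mean(counts) <= 0.05 * 50


class TestClinicalAssociation:
    def test_runs_on_synthetic_cohort(self, small_cohort):
        truth = small_cohort.truth.subgroup_of_sample
        res = subgroups.clinical_association(truth, small_cohort.clinical)
        tested = res[res["method"] != "skipped"]
        assert set(tested["variable"]) == {"tnm_stage", "afp_high", "thrombus",
                                           "phenotype"}
        assert tested["p"].between(0, 1).all()

    def test_single_category_skipped(self, rng):
        clin = make_clinical(20, rng)
        clin.frame["thrombus"] = 0
        labels = pd.Series([1] * 10 + [2] * 10, index=clin.frame["sample"])
        res = subgroups.clinical_association(labels, clin,
                                             variables=("thrombus",))
        assert res["method"].iloc[0] == "skipped"


class TestSignatureScores:
    def sig_db(self):
        return PathwayDB({
            "Tcell": ("immune cell type", frozenset({"g0", "g1"})),
            "Fibro": ("stromal cell type", frozenset({"g2", "g3"})),
        })

    def test_all_constant_expression_zero_scores(self):
        m = make_matrix(np.zeros((4, 6)), features=[f"g{i}" for i in range(4)])
        out = subgroups.signature_scores(m, self.sig_db())
        assert np.allclose(out.to_numpy(), 0.0)

    def test_locality_of_perturbation(self, rng):
        vals = rng.normal(size=(4, 6))
        m = make_matrix(vals, features=[f"g{i}" for i in range(4)])
        base = subgroups.signature_scores(m, self.sig_db())
        vals2 = vals.copy()
        vals2[0, 3] += 5.0  # raise Tcell gene g0 in sample S3
        m2 = make_matrix(vals2, features=[f"g{i}" for i in range(4)])
        bumped = subgroups.signature_scores(m2, self.sig_db())
        assert bumped.loc["S3", "Tcell"] > base.loc["S3", "Tcell"]
        # stromal score of that sample is driven by other genes only
        assert bumped.loc["S3", "Fibro"] == pytest.approx(
            base.loc["S3", "Fibro"], abs=0.5)

    def test_microenvironment_is_immune_plus_stroma(self, rng):
        m = make_matrix(rng.normal(size=(4, 8)),
                        features=[f"g{i}" for i in range(4)])
        out = subgroups.signature_scores(m, self.sig_db())
        assert np.allclose(out["microenvironment_score"],
                           out["immune_score"] + out["stroma_score"])

    def test_planted_immune_hot_subgroup_detected(self, rng):
        n = 60
        labels = pd.Series(np.repeat([1, 2, 3], 20),
                           index=[f"S{i}" for i in range(n)])
        vals = rng.normal(size=(10, n))
        vals[:3, labels.to_numpy() == 2] += 2.0  # immune genes hot in group 2
        m = make_matrix(vals, features=[f"g{i}" for i in range(10)],
                        samples=list(labels.index))
        db = PathwayDB({"NK": ("immune cells", frozenset({"g0", "g1", "g2"}))})
        scores = subgroups.signature_scores(m, db)
        h, p = sps.kruskal(*[scores.loc[labels == c, "immune_score"]
                             for c in (1, 2, 3)])
        assert p < 0.01


class TestOverlapSummary:
    def test_disjoint_sets(self):
        out = subgroups.overlap_summary({"a": {1, 2}, "b": {3}})
        full = out[(out["a"] == 1) & (out["b"] == 1)]["size"].iloc[0]
        assert full == 0

    def test_identical_sets_all_in_intersection(self):
        out = subgroups.overlap_summary({"a": {1, 2}, "b": {1, 2}})
        assert out[(out["a"] == 1) & (out["b"] == 1)]["size"].iloc[0] == 2
        assert out[(out["a"] == 1) & (out["b"] == 0)]["size"].iloc[0] == 0

    def test_random_sets_against_brute_force(self, rng):
        universe = list(range(50))
        sets = {n: set(rng.choice(universe, size=rng.integers(5, 30),
                                  replace=False).tolist())
                for n in ("x", "y", "z")}
        out = subgroups.overlap_summary(sets)
        assert len(out) == 7
        for _, row in out.iterrows():
            count = sum(
                1 for e in universe
                if all((e in sets[n]) == bool(row[n]) for n in sets)
            )
            assert row["size"] == count
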