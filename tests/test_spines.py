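"""Spine dynamics, clustering rules, permutation nulls and enrichment."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import mutual_info_score

from linklab.spines import (
    NewSpineSet,
    SpineMap,
    addition_mutual_information,
    addition_spearman,
    chance_clustering_resample,
    clustering_ratio,
    colocalization_enrichment,
    cross_session_coallocation,
    extract_dynamics,
    fisher_compare,
    mutual_information,
    nn_coclustering,
    subsample_statistic,
)
from linklab.synth import SpineSimConfig, gen_spine_maps


def _map(positions, present, lengths=(50.0,), dendrite=None, sessions=("s0", "s1")):
    positions = np.asarray(positions, float)
    dendrite = np.zeros(len(positions), int) if dendrite is None else np.asarray(dendrite)
    return SpineMap(
        lengths=np.asarray(lengths, float),
        spine_dendrite=dendrite,
        positions=positions,
        presence=np.asarray(present, bool),
        sessions=list(sessions),
    )


class TestDynamics:
    def test_identical_sessions_no_change(self):
        m = _map([10, 20], [[1, 1], [1, 1]])
        d = extract_dynamics(m, "s0", "s1")
        assert d["gained"].sum() == 0 and d["lost"].sum() == 0

    def test_close_new_spines_clustered(self):
        m = _map([10, 13], [[0, 1], [0, 1]])
        d = extract_dynamics(m, "s0", "s1")
        assert d["new"].clustered.tolist() == [True, True]

    def test_exactly_5um_not_clustered(self):
        m = _map([10.0, 15.0], [[0, 1], [0, 1]])
        d = extract_dynamics(m, "s0", "s1")
        assert not d["new"].clustered.any()

    def test_cross_dendrite_not_clustered(self):
        m = _map([10.0, 11.0], [[0, 1], [0, 1]],
                 lengths=(50.0, 50.0), dendrite=[0, 1])
        d = extract_dynamics(m, "s0", "s1")
        assert not d["new"].clustered.any()

    def test_unknown_session_rejected(self):
        m = _map([10], [[1, 1]])
        with pytest.raises(KeyError):
            extract_dynamics(m, "s0", "nope")


class TestClusteringRatio:
    def test_half_clustered(self):
        n = NewSpineSet(np.zeros(4, int), np.array([0.0, 3.0, 20.0, 40.0]),
                        np.arange(4), 1)
        assert clustering_ratio(n) == pytest.approx(0.5)

    def test_single_new_spine_zero(self):
        n = NewSpineSet(np.zeros(1, int), np.array([7.0]), np.arange(1), 1)
        assert clustering_ratio(n) == 0.0

    def test_tight_stretch_all_clustered(self):
        n = NewSpineSet(np.zeros(3, int), np.array([1.0, 2.5, 4.0]),
                        np.arange(3), 1)
        assert clustering_ratio(n) == 1.0

    def test_zero_new_spines_rejected(self):
        n = NewSpineSet(np.zeros(0, int), np.zeros(0), np.zeros(0, int), 1)
        with pytest.raises(ValueError):
            clustering_ratio(n)

    def test_reflection_and_relabel_invariance(self, rng):
        pos = rng.uniform(0, 50, 12)
        dend = rng.integers(0, 3, 12)
        n1 = NewSpineSet(dend, pos, np.arange(12), 3)
        n2 = NewSpineSet(dend, 50.0 - pos, np.arange(12), 3)
        perm = np.array([2, 0, 1])
        n3 = NewSpineSet(perm[dend], pos, np.arange(12), 3)
        assert clustering_ratio(n1) == clustering_ratio(n2) == clustering_ratio(n3)


class TestChanceClustering:
    def test_seed_reproducible(self, rng):
        m, _ = gen_spine_maps(SpineSimConfig(), np.random.default_rng(0))
        d = extract_dynamics(m, "s0", "s1")
        r1 = chance_clustering_resample(m, d["new"], reps=50,
                                        rng=np.random.default_rng(3))
        r2 = chance_clustering_resample(m, d["new"], reps=50,
                                        rng=np.random.default_rng(3))
        assert np.array_equal(r1["null"], r2["null"])

    def test_biased_generator_detected(self):
        rng = np.random.default_rng(8)
        m, _ = gen_spine_maps(SpineSimConfig(pi_clust=0.8), rng)
        d = extract_dynamics(m, "s0", "s1")
        r = chance_clustering_resample(m, d["new"], reps=200, rng=rng)
        assert r["percentile"] > 97.5


class TestSpearman:
    def test_identical_counts(self, rng):
        a = rng.poisson(2, 30)
        a[0] += 1  # break possible constancy
        out = addition_spearman(a, a, n_perm=200, rng=rng)
        assert out["rho"] == pytest.approx(1.0)
        assert out["p"] < 0.05

    def test_antimonotone_hand_example(self, rng):
        a = np.array([1, 2, 3, 4, 5])
        b = np.array([5, 4, 3, 2, 1])
        out = addition_spearman(a, b, n_perm=100, rng=rng)
        assert out["rho"] == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self, rng):
        a = rng.poisson(1.5, 40)
        b = rng.poisson(1.5, 40)
        a[0] += 1; b[1] += 1
        out = addition_spearman(a, b, n_perm=10, rng=rng)
        assert out["rho"] == pytest.approx(stats.spearmanr(a, b).statistic)

    def test_constant_counts_flagged(self, rng):
        with pytest.warns(UserWarning):
            out = addition_spearman(np.ones(10), rng.poisson(2, 10),
                                    n_perm=10, rng=rng)
        assert np.isnan(out["rho"])


class TestMutualInformation:
    def test_constant_vector_zero_mi(self):
        assert mutual_information(np.full(20, 3), np.arange(20)) == \
            pytest.approx(0.0)

    def test_matches_sklearn_oracle(self, rng):
        a = rng.poisson(1.5, 60)
        b = rng.poisson(1.5, 60)
        ours = mutual_information(a, b)
        ref = mutual_info_score(np.minimum(a, 4), np.minimum(b, 4))
        assert ours == pytest.approx(ref)

    def test_identical_counts_significant(self, rng):
        a = rng.poisson(2.0, 45)
        while len(np.unique(np.minimum(a, 4))) < 3:
            a = rng.poisson(2.0, 45)
        out = addition_mutual_information(a, a, n_perm=500, rng=rng)
        assert out["z"] > 2 and out["significant"]

    def test_null_z_reproducible(self, rng):
        a = rng.poisson(2.0, 45)
        b = rng.poisson(2.0, 45)
        o1 = addition_mutual_information(a, b, n_perm=100,
                                         rng=np.random.default_rng(1))
        o2 = addition_mutual_information(a, b, n_perm=100,
                                         rng=np.random.default_rng(1))
        assert o1["z"] == o2["z"]


class TestFisher:
    def test_equal_correlations(self):
        out = fisher_compare(0.4, 30, 0.4, 25)
        assert out["Z"] == 0.0 and out["p"] == pytest.approx(0.5)

    def test_antisymmetry(self):
        a = fisher_compare(0.5, 40, 0.1, 45)
        b = fisher_compare(0.1, 45, 0.5, 40)
        assert a["Z"] == pytest.approx(-b["Z"])

    def test_tail_against_high_precision_cdf(self):
        from mpmath import erfc, mp, mpf, sqrt
        mp.dps = 30
        out = fisher_compare(0.37, 45, 0.09, 45)
        expect = float(erfc(mpf(out["Z"]) / sqrt(2)) / 2)
        assert out["p"] == pytest.approx(expect, rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_compare(1.0, 30, 0.2, 30)
        with pytest.raises(ValueError):
            fisher_compare(0.5, 3, 0.2, 30)


class TestCoallocation:
    def test_forced_identical_segments_extreme(self, rng):
        # both transitions gain clustered spines on the same segments
        dend = np.repeat(np.arange(5), 2)
        pos = np.tile([10.0, 12.0], 5)
        n1 = NewSpineSet(dend, pos, np.arange(10), 20)
        n2 = NewSpineSet(dend, pos + 1.0, np.arange(10), 20)
        out = cross_session_coallocation(n1, n2, n_perm=400, rng=rng)
        assert out["observed"] == 100.0
        assert out["percentile"] >= 97.5

    def test_seed_reproducible(self, rng):
        m, _ = gen_spine_maps(SpineSimConfig(pi_clust=0.5),
                              np.random.default_rng(4))
        d0 = extract_dynamics(m, "s0", "s1")
        d1 = extract_dynamics(m, "s1", "s2")
        r1 = cross_session_coallocation(d0["new"], d1["new"], m.animals,
                                        n_perm=100, rng=np.random.default_rng(2))
        r2 = cross_session_coallocation(d0["new"], d1["new"], m.animals,
                                        n_perm=100, rng=np.random.default_rng(2))
        assert np.array_equal(r1["null"], r2["null"])

    def test_no_clustered_spines_rejected(self, rng):
        empty = NewSpineSet(np.array([0]), np.array([5.0]), np.array([0]), 3)
        with pytest.raises(ValueError):
            cross_session_coallocation(empty, empty, n_perm=10, rng=rng)


class TestNNCoclustering:
    def test_identical_positions(self):
        n1 = NewSpineSet(np.zeros(3, int), np.array([5., 20., 40.]),
                         np.arange(3), 1)
        n2 = NewSpineSet(np.zeros(3, int), np.array([5., 20., 40.]),
                         np.arange(3), 1)
        out = nn_coclustering(n1, n2)
        assert np.all(out["distances"] == 0)
        assert out["co_clustered_pct"] == 100.0

    def test_far_pair_not_coclustered(self):
        n1 = NewSpineSet(np.zeros(1, int), np.array([0.0]), np.arange(1), 1)
        n2 = NewSpineSet(np.zeros(1, int), np.array([10.0]), np.arange(1), 1)
        out = nn_coclustering(n1, n2)
        assert out["co_clustered_pct"] == 0.0

    def test_fallback_uses_segment_length(self):
        n1 = NewSpineSet(np.zeros(0, int), np.zeros(0), np.zeros(0, int), 2)
        n2 = NewSpineSet(np.array([1]), np.array([3.0]), np.array([0]), 2)
        lengths = np.array([30.0, 44.0])
        out = nn_coclustering(n1, n2, lengths=lengths, fallback=True)
        assert out["distances"].tolist() == [44.0]
        with pytest.raises(ValueError):
            nn_coclustering(n1, n2)  # default mode: no eligible pairs


class TestSubsample:
    def test_degenerate_population(self, rng):
        a = rng.poisson(2, 40).astype(float)
        b = rng.poisson(2, 40).astype(float)
        stat = lambda x, y: float(np.corrcoef(x, y)[0, 1])
        out = subsample_statistic((a, b), (a, b), stat,
                                  n_dendrites=40, reps=20, rng=rng)
        assert np.allclose(out["exp"], out["exp"][0])

    def test_identical_conditions_symmetric_p(self, rng):
        a = rng.poisson(2, 80).astype(float)
        b = rng.poisson(2, 80).astype(float)
        stat = lambda x, y: float(np.mean(x) - np.mean(y))
        out = subsample_statistic((a, b), (a, b), stat,
                                  n_dendrites=40, reps=2000, rng=rng)
        assert out["p"] == pytest.approx(0.5, abs=0.07)

    def test_seed_reproducible(self, rng):
        a = np.arange(50, dtype=float)
        stat = lambda x: float(x.mean())
        o1 = subsample_statistic((a,), (a,), stat, n_dendrites=40, reps=50,
                                 rng=np.random.default_rng(7))
        o2 = subsample_statistic((a,), (a,), stat, n_dendrites=40, reps=50,
                                 rng=np.random.default_rng(7))
        assert np.array_equal(o1["exp"], o2["exp"])


class TestColocalization:
    def test_full_coverage(self):
        out = colocalization_enrichment(100, 100, 37, 100)
        assert out["chance"] == pytest.approx(1.0)
        assert out["enrichment"] == pytest.approx(0.37)

    def test_zero_overlap(self):
        out = colocalization_enrichment(10, 10, 0, 100)
        assert out["enrichment"] == 0.0

    def test_independent_masks_enrichment_one(self, rng):
        vals = []
        for _ in range(100):
            n = 10_000
            a = rng.random(n) < 0.2
            b = rng.random(n) < 0.3
            out = colocalization_enrichment(
                a.sum(), b.sum(), (a & b).sum(), n)
            vals.append(out["enrichment"])
        assert np.mean(vals) == pytest.approx(1.0, abs=0.02)

    def test_inconsistent_volumes_rejected(self):
        with pytest.raises(ValueError):
            colocalization_enrichment(10, 10, 20, 100)
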