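"""Cross-session ensemble statistics: overlap, rates, decoding, coactivity."""

import numpy as np
import pytest

from linklab.ensemble import (
    MatchedSessions,
    SessionEvents,
    connectivity_distance,
    firing_rates,
    nb_classifier_auc,
    population_vector_correlation,
    pwc_map,
    pwc_stability,
    rank_auc,
    reactivated_rate_correlation,
    session_overlap,
    top_decile_reactivation,
)


def _session(events, fr=15.5, **kw):
    return SessionEvents(events=np.asarray(events, np.uint8), frame_rate=fr, **kw)


def _identity_map(n):
    return np.column_stack([np.arange(n)] * 2)


class TestSessionOverlap:
    def test_identical_sessions_full_map(self, rng):
        ev = (rng.random((200, 30)) < 0.1).astype(np.uint8)
        ev[:, 0] = 1  # ensure non-empty
        s = _session(ev)
        assert session_overlap(MatchedSessions(s, s, _identity_map(30))) == \
            pytest.approx(100.0)

    def test_empty_id_map(self, rng):
        ev = np.ones((10, 5), np.uint8)
        m = MatchedSessions(_session(ev), _session(ev), np.empty((0, 2)))
        assert session_overlap(m) == 0.0

    def test_average_normalization(self):
        # 100 and 60 active cells sharing 40 matched -> 100*40/80 = 50%
        ev1 = np.zeros((10, 120), np.uint8)
        ev1[0, :100] = 1
        ev2 = np.zeros((10, 120), np.uint8)
        ev2[0, :40] = 1
        ev2[0, 100:120] = 1
        id_map = _identity_map(120)
        m = MatchedSessions(_session(ev1), _session(ev2), id_map)
        assert session_overlap(m) == pytest.approx(50.0)

    def test_symmetry(self, rng):
        a = (rng.random((100, 40)) < 0.2).astype(np.uint8)
        b = (rng.random((100, 40)) < 0.2).astype(np.uint8)
        a[0, 0] = b[0, 0] = 1
        m12 = MatchedSessions(_session(a), _session(b), _identity_map(40))
        m21 = MatchedSessions(_session(b), _session(a), _identity_map(40))
        assert session_overlap(m12) == pytest.approx(session_overlap(m21))


class TestFiringRates:
    def test_limits(self):
        ev = np.zeros((100, 2), np.uint8)
        ev[:, 1] = 1
        r = firing_rates(_session(ev, fr=10.0))
        assert r[0] == 0.0 and r[1] == pytest.approx(10.0)

    def test_ten_minute_session_arithmetic(self):
        # 93 active frames in a 10-min session at 15.5 Hz -> 0.155 Hz
        n_frames = int(600 * 15.5)
        ev = np.zeros((n_frames, 1), np.uint8)
        ev[:93, 0] = 1
        assert firing_rates(_session(ev))[0] == pytest.approx(0.155)


class TestPVC:
    def test_identity_and_scale_invariance(self):
        r = np.array([1.0, 2.0, 5.0, 0.5, 3.0])
        assert population_vector_correlation(r, r) == pytest.approx(1.0)
        assert population_vector_correlation(r, 2 * r) == pytest.approx(1.0)

    def test_hand_example_against_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        expect = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean())**2) * np.sum((y - y.mean())**2)))
        assert population_vector_correlation(x, y) == pytest.approx(expect)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            out = population_vector_correlation(
                np.ones(5), np.array([1.0, 2, 3, 4, 5]))
        assert np.isnan(out)


class TestNBClassifier:
    def test_disjoint_populations_perfectly_separable(self, rng):
        n = int(120 * 15.5)
        ev1 = np.zeros((n, 40), np.uint8)
        ev1[:, :20] = rng.random((n, 20)) < 0.05
        ev2 = np.zeros((n, 40), np.uint8)
        ev2[:, 20:] = rng.random((n, 20)) < 0.05
        res = nb_classifier_auc(_session(ev1), _session(ev2),
                                np.array([2.0]), rng=rng)
        assert res["mean_auc"] > 0.95

    def test_rank_auc_equals_pair_counting_oracle(self, rng):
        pos = rng.normal(0.5, 1.0, 37)
        neg = rng.normal(0.0, 1.0, 43)
        neg[:5] = pos[:5]  # inject ties
        brute = np.mean([
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a in pos for b in neg
        ])
        assert rank_auc(pos, neg) == pytest.approx(brute)

    def test_label_shuffle_is_chance(self, rng):
        # one Bernoulli model, two independent draws: AUC ~ 0.5
        n = int(300 * 15.5)
        p = rng.uniform(0.005, 0.05, 50)
        aucs = []
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            e1 = (r2.random((n, 50)) < p).astype(np.uint8)
            e2 = (r2.random((n, 50)) < p).astype(np.uint8)
            res = nb_classifier_auc(_session(e1), _session(e2),
                                    np.array([1.0, 5.0]), rng=r2)
            aucs.extend(res["auc"])
        assert abs(np.nanmean(aucs) - 0.5) < 0.07


class TestPWC:
    def test_duplicated_cell_unit_entry(self, rng):
        n = int(700 * 15.5)
        base = (rng.random(n) < 0.05).astype(np.uint8)
        other = (rng.random(n) < 0.05).astype(np.uint8)
        ev = np.column_stack([base, base, other])
        m = pwc_map(_session(ev))
        assert m[0, 1] == pytest.approx(1.0)
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.allclose(np.diag(m), 1.0)

    def test_independent_cells_near_zero(self, rng):
        n_bins = 6000
        fpb = max(1, int(round(0.1 * 15.5)))
        ev = (rng.random((n_bins * fpb, 20)) < 0.03).astype(np.uint8)
        m = pwc_map(_session(ev))
        off = m[np.triu_indices(20, 1)]
        assert np.nanmean(np.abs(off)) < 0.05

    def test_stability_self_is_one(self, rng):
        ev = (rng.random((8000, 15)) < 0.05).astype(np.uint8)
        m = pwc_map(_session(ev))
        v = pwc_stability(m, m, subsample_n=10, reps=20, rng=rng)
        assert v == pytest.approx(1.0)

    def test_independent_sessions_near_zero(self, rng):
        m1 = pwc_map(_session((rng.random((9000, 15)) < 0.05).astype(np.uint8)))
        m2 = pwc_map(_session((rng.random((9000, 15)) < 0.05).astype(np.uint8)))
        v = pwc_stability(m1, m2, subsample_n=10, reps=200, rng=rng)
        assert abs(v) < 0.1

    def test_excluded_pairs_absent(self, rng):
        # two cells marked as footprint-overlapping are perfectly
        # correlated; with exclusion the stability must ignore them
        n = 8000
        base = (rng.random(n) < 0.05).astype(np.uint8)
        ev = np.column_stack(
            [base, base] + [(rng.random(n) < 0.05).astype(np.uint8)
                            for _ in range(10)])
        fo = np.zeros((12, 12), bool)
        fo[0, 1] = fo[1, 0] = True
        m1 = pwc_map(_session(ev))
        m2 = pwc_map(_session(np.column_stack(
            [base, base] + [(rng.random(n) < 0.05).astype(np.uint8)
                            for _ in range(10)])))
        with_excl = pwc_stability(m1, m2, footprint_overlap=fo,
                                  subsample_n=12, reps=50, rng=np.random.default_rng(0))
        without = pwc_stability(m1, m2, subsample_n=12, reps=50,
                                rng=np.random.default_rng(0))
        # the duplicated pair's r=1 entry dominates the unexcluded version
        assert without > with_excl


class TestConnectivityDistance:
    def test_identical_maps_zero(self, rng):
        m = rng.random((8, 8))
        m = (m + m.T) / 2
        assert connectivity_distance(m, m, exclude_top_frac=0.0) == 0.0

    def test_hand_example_vector_norm(self):
        m1 = np.array([[1, .2, .3, .1], [.2, 1, .4, .5],
                       [.3, .4, 1, .6], [.1, .5, .6, 1]])
        m2 = np.zeros_like(m1)
        expect = np.linalg.norm(m1[np.triu_indices(4, 1)])
        assert connectivity_distance(m1, m2, exclude_top_frac=0.0) == \
            pytest.approx(expect)

    def test_exclusion_drops_top_rate_cells(self):
        m1 = np.eye(10) + 0.5
        m2 = np.eye(10)
        rates = np.arange(10.0)
        full = connectivity_distance(m1, m2, exclude_top_frac=0.0)
        part = connectivity_distance(m1, m2, rates=rates, exclude_top_frac=0.2)
        assert part < full

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            connectivity_distance(np.eye(4), np.eye(4), exclude_top_frac=1.0)


class TestTopDecile:
    def test_all_reactivated(self, rng):
        ev = (rng.random((500, 20)) < 0.2).astype(np.uint8)
        ev[0] = 1
        s = _session(ev)
        m = MatchedSessions(s, s, _identity_map(20))
        assert top_decile_reactivation(m) == 1.0

    def test_none_matched(self, rng):
        ev = (rng.random((500, 20)) < 0.2).astype(np.uint8)
        ev[0] = 1
        s = _session(ev)
        m = MatchedSessions(s, s, np.empty((0, 2)))
        assert top_decile_reactivation(m) == 0.0


class TestReactivatedRateCorrelation:
    def test_perfect_linear_relation(self, rng):
        x = rng.uniform(0, 1, 60)
        pairs = np.column_stack([x, x])
        res = reactivated_rate_correlation(pairs, reps=50, rng=rng)
        assert np.allclose(res["correlations"], 1.0)
        assert res["slope"] == pytest.approx(1.0)

    def test_independent_centered_at_zero(self, rng):
        pairs = rng.normal(0, 1, (200, 2))
        res = reactivated_rate_correlation(pairs, reps=400, rng=rng)
        assert abs(np.nanmean(res["correlations"])) < 0.1

    def test_seed_reproducible(self):
        pairs = np.random.default_rng(0).normal(0, 1, (60, 2))
        r1 = reactivated_rate_correlation(pairs, reps=100,
                                          rng=np.random.default_rng(5))
        r2 = reactivated_rate_correlation(pairs, reps=100,
                                          rng=np.random.default_rng(5))
        assert np.array_equal(r1["correlations"], r2["correlations"])
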