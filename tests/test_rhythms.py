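"""JTK statistic, exact null, BH correction, overlap and scaling."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chronoscreen.rhythms import (benjamini_hochberg, jtk_exact_pvalue,
                                  jtk_mc_pvalue, jtk_screen, jtk_statistic,
                                  overlap_summary, zscale_features)
from chronoscreen.synth import OmicsSimConfig, generate_omics


def _brute_S(zts, values, lag):
    ref = np.cos(2 * np.pi * (np.asarray(zts, float) - lag) / 24)
    s = 0
    for i, j in itertools.combinations(range(len(values)), 2):
        s += np.sign(values[i] - values[j]) * np.sign(round(ref[i], 9) - round(ref[j], 9))
    return int(s)


class TestStatistic:
    def test_perfect_concordance_and_discordance(self):
        # cos(2*pi*(t-12)/24) is strictly increasing on (0, 12): no ref ties
        zts = [1, 3, 5, 7, 9, 11]
        inc = [10, 20, 30, 40, 50, 60]
        assert jtk_statistic(zts, inc, lag=12).tau == pytest.approx(1.0)
        assert jtk_statistic(zts, inc[::-1], lag=12).tau == pytest.approx(-1.0)

    def test_small_example_matches_pair_enumeration(self):
        zts, values = [0, 8, 16], [3, 1, 2]
        st_ = jtk_statistic(zts, values, lag=0)
        assert st_.S == _brute_S(zts, values, 0)
        # the lag-0 reference ties ZT8 with ZT16: n0=3, n2=1 tied pair
        assert st_.tau == pytest.approx(st_.S / math.sqrt(3 * (3 - 1)))

    def test_replicates_share_reference_value(self):
        # both observations at ZT0 are tied in the reference
        zts = [0, 0, 6, 12]
        st_ = jtk_statistic(zts, [5, 1, 3, 2], lag=0)
        assert st_.S == _brute_S(zts, [5, 1, 3, 2], 0)

    def test_constant_series_flagged(self):
        st_ = jtk_statistic([0, 4, 8, 12], [2, 2, 2, 2])
        assert st_.tau == 0.0 and st_.constant

    @given(st.lists(st.integers(0, 1000), min_size=6, max_size=6, unique=True),
           st.sampled_from([0.0, 4.0, 8.0]))
    def test_antipodal_lag_negates_S(self, values, lag):
        """Shifting the reference by half a period negates S (tie-free data)."""
        zts = [0, 4, 8, 12, 16, 20]
        s1 = jtk_statistic(zts, values, lag=lag).S
        s2 = jtk_statistic(zts, values, lag=lag + 12).S
        assert s1 == -s2


class TestExactPvalue:
    def test_n3_maximum_S_is_one_sixth(self):
        """All 3! orderings vs a strictly ordered reference: max S has p=1/6."""
        assert jtk_exact_pvalue(3, [1, 1, 1]) == pytest.approx(1 / 6)

    def test_minimum_S_has_p_one(self):
        assert jtk_exact_pvalue(-3, [1, 1, 1]) == 1.0
        assert jtk_exact_pvalue(-13, [1, 2, 2, 1]) == 1.0

    def test_dp_equals_enumeration_with_reference_ties(self):
        """n=4, tied reference [0,0,6,12]: DP tail matches 4! enumeration."""
        zts = [0, 0, 6, 12]
        all_S = [
            _brute_S(zts, perm, 0)
            for perm in itertools.permutations([1, 2, 3, 4])
        ]
        for S in sorted(set(all_S)):
            enum_p = Fraction(sum(s >= S for s in all_S), len(all_S))
            dp_p = jtk_exact_pvalue(S, [2, 1, 1])
            assert dp_p == pytest.approx(float(enum_p), abs=1e-15)

    def test_mc_fallback_approximates_exact(self):
        zts = [0, 4, 8, 12, 16, 20]
        values = [3, 6, 5, 1, 2, 4]
        S = jtk_statistic(zts, values, lag=0).S
        exact = jtk_exact_pvalue(S, [1, 2, 2, 1])
        mc = jtk_mc_pvalue(S, zts, values, lag=0, n_perm=20000, seed=1)
        assert mc == pytest.approx(exact, abs=0.01)


class TestBenjaminiHochberg:
    def test_worked_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_empty(self):
        assert benjamini_hochberg([1.0]) == pytest.approx([1.0])
        assert benjamini_hochberg([]).size == 0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    def test_order_isotonic_and_bounded(self, ps):
        q = benjamini_hochberg(ps)
        assert ((q > 0) & (q <= 1)).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestScreen:
    def test_all_constant_matrix_yields_no_calls(self, tiny_matrix):
        m = tiny_matrix
        m.values.iloc[:, :] = 5.0
        screen = jtk_screen(m, "g")
        assert screen.significant_ids == set()
        assert all(r.p_value == 1.0 for r in screen.results)

    def test_recovers_planted_rhythms(self):
        cfg = OmicsSimConfig(
            n_features=40, reps_per_group={"g": 5},
            rhythmic_sets={"g": {f"met{i:03d}" for i in range(1, 9)}},
            amplitude_rel={"g": 0.5}, noise_cv={"g": 0.1}, seed=21,
        )
        matrix, truth = generate_omics(cfg)
        screen = jtk_screen(matrix, "g", q_threshold=0.2, seed=21)
        called = screen.significant_ids
        true = truth.rhythmic_sets["g"]
        assert len(called & true) >= 7
        # best lag tracks the planted phase to grid resolution
        by_id = {r.feature_id: r for r in screen.results}
        for f in true:
            phase = truth.phase_hours[f]
            dist = min(abs(by_id[f].lag_hours - phase) % 24,
                       (-(by_id[f].lag_hours - phase)) % 24)
            assert dist <= 4.0

    def test_perfect_cosine_reaches_dp_minimum(self):
        """A noise-free cosine (rank ties broken by an infinitesimal jitter so
        the exact null applies) attains the design's smallest DP p-value."""
        cfg = OmicsSimConfig(
            n_features=2, reps_per_group={"g": 5},
            rhythmic_sets={"g": {"met001"}}, amplitude_rel={"g": 0.5},
            phase_hours={"met001": 0.0}, noise_cv={"g": 0.0}, seed=0,
        )
        matrix, _ = generate_omics(cfg)
        n = matrix.values.shape[1]
        jitter = np.linspace(0, 1e-9, n) * matrix.values.loc["met001"].mean()
        matrix.values.loc["met001"] = matrix.values.loc["met001"].to_numpy() + jitter
        matrix.values.loc["met002"] = matrix.values.loc["met002"].to_numpy() + jitter
        screen = jtk_screen(matrix, "g")
        res = {r.feature_id: r for r in screen.results}
        assert res["met001"].method == "exact"
        # smallest attainable p for this design, times the 6-lag correction
        p_floor = jtk_exact_pvalue(res["met001"].kendall_S, [5, 10, 10, 5])
        assert res["met001"].p_min_lag == pytest.approx(p_floor)
        assert res["met001"].p_value == pytest.approx(min(1.0, 6 * p_floor))

    def test_null_calibration(self):
        """Pure noise: the fraction of q<0.2 calls stays at or below 0.25."""
        fracs = []
        for seed in range(20):
            cfg = OmicsSimConfig(n_features=60, reps_per_group={"g": 5},
                                 noise_cv={"g": 0.1}, seed=seed)
            matrix, _ = generate_omics(cfg)
            screen = jtk_screen(matrix, "g", seed=seed)
            fracs.append(len(screen.significant_ids) / 60)
        assert np.mean(fracs) <= 0.25


class TestOverlapAndScaling:
    def _screen_with(self, ids, sig, label="a"):
        from chronoscreen.rhythms import JTKResult, RhythmScreen
        results = [
            JTKResult(f, 24.0, 0.0, 0, 0.0, 0.5,
                      q_value=0.01 if f in sig else 0.9)
            for f in ids
        ]
        return RhythmScreen(group=label, results=results, q_threshold=0.2)

    def test_venn_partition_17_17_4(self):
        ids = [f"m{i}" for i in range(159)]
        a = self._screen_with(ids, set(ids[:17]), "young")
        b = self._screen_with(ids, set(ids[13:30]), "old")
        ov = overlap_summary(a, b)
        assert ov.counts == (13, 4, 13)

    def test_identical_and_disjoint_screens(self):
        ids = ["x", "y", "z"]
        a = self._screen_with(ids, {"x", "y"})
        assert overlap_summary(a, a).counts == (0, 2, 0)
        b = self._screen_with(ids, {"z"})
        assert overlap_summary(a, b).shared == set()

    def test_mismatched_universes_rejected(self):
        a = self._screen_with(["x"], set())
        b = self._screen_with(["y"], set())
        with pytest.raises(ValueError):
            overlap_summary(a, b)

    def test_zscale_row_moments_and_idempotence(self, tiny_matrix):
        scaled, flags = zscale_features(tiny_matrix)
        v = scaled.values.to_numpy()
        assert np.allclose(v.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(v.std(axis=1), 1, atol=1e-12)
        assert not flags.any()
        twice, _ = zscale_features(scaled)
        assert np.allclose(twice.values.to_numpy(), v, atol=1e-12)

    def test_zscale_constant_row_flagged(self, tiny_matrix):
        m = tiny_matrix
        m.values.iloc[0, :] = 3.0
        scaled, flags = zscale_features(m)
        assert flags.iloc[0]
        assert (scaled.values.iloc[0] == 0).all()
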