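"""DAM parsing, artifact filtering, sleep scoring, FFT, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chronoscreen.behavior import (ActivityTable, LightSchedule,
                                   compare_groups, exclude_dead,
                                   fft_rhythm_power, filter_artifacts,
                                   read_dam, score_sleep, summarize_sleep)


def _dam_line(i, ts, counts, status=1):
    fields = [str(i), ts.strftime("%d %b %y"), ts.strftime("%H:%M:%S"),
              str(status)] + ["0"] * 6 + [str(c) for c in counts]
    return "\t".join(fields)


def _table(cols: dict, lights_on=8, mode="LD"):
    n = len(next(iter(cols.values())))
    idx = pd.date_range(pd.Timestamp("2023-01-02") + pd.Timedelta(hours=lights_on),
                        periods=n, freq="min")
    return ActivityTable(counts=pd.DataFrame(cols, index=idx),
                         schedule=LightSchedule(mode=mode, lights_on=lights_on))


class TestReadDam:
    def test_three_line_fixture(self, tmp_path):
        path = tmp_path / "Monitor3.txt"
        t0 = pd.Timestamp("2023-05-01 08:00:00")
        lines = []
        for i, c1 in enumerate([0, 5, 2]):
            counts = [c1] + [0] * 31
            lines.append(_dam_line(i + 1, t0 + pd.Timedelta(minutes=i), counts))
        path.write_text("\n".join(lines) + "\n")
        table = read_dam(path, monitor_id="M3")
        assert list(table.counts["M3_c01"]) == [0, 5, 2]
        assert table.counts.shape[1] == 32

    def test_status_error_row_flagged_and_excluded(self, tmp_path):
        path = tmp_path / "Monitor4.txt"
        t0 = pd.Timestamp("2023-05-01 08:00:00")
        lines = [
            _dam_line(1, t0, [1] * 32),
            _dam_line(2, t0 + pd.Timedelta(minutes=1), [9] * 32, status=51),
            _dam_line(3, t0 + pd.Timedelta(minutes=2), [2] * 32),
        ]
        path.write_text("\n".join(lines) + "\n")
        table = read_dam(path)
        assert len(table.counts) == 2
        assert table.bad_rows is not None and len(table.bad_rows) == 1
        assert table.gaps  # the dropped minute shows up as a gap

    def test_malformed_lines_rejected(self, tmp_path):
        path = tmp_path / "Monitor5.txt"
        path.write_text("1\t01 May 23\t08:00:00\t1\n")
        with pytest.raises(ValueError, match="line 1"):
            read_dam(path)
        path.write_text(_dam_line(1, pd.Timestamp("2023-05-01"),
                                  ["x"] + [0] * 31) + "\n")
        with pytest.raises(ValueError, match="non-integer"):
            read_dam(path)


class TestFilterArtifacts:
    def test_spike_replaced_by_neighbor_average(self):
        base = [2, 3] * 100
        series = base[:2] + [500] + base[2:]
        table = _table({"f1": series})
        nz = np.array([v for v in series if v > 0], float)
        assert 500 >= nz.mean() + 6 * nz.std()  # fixture sanity
        filtered, log = filter_artifacts(table)
        assert filtered.counts["f1"].iloc[2] == pytest.approx((3 + 2) / 2)
        assert len(log) == 1 and log["original"].iloc[0] == 500

    def test_no_outliers_identity(self):
        table = _table({"f1": [2, 3, 2, 3, 2, 3]})
        filtered, log = filter_artifacts(table)
        assert log.empty
        assert filtered.counts.equals(table.counts)

    def test_edge_spike_uses_single_neighbor(self):
        series = [500] + [2, 3] * 100
        table = _table({"f1": series})
        filtered, log = filter_artifacts(table)
        assert filtered.counts["f1"].iloc[0] == 2  # following minute alone
        assert len(log) == 1

    def test_consecutive_spikes_use_flanking_values(self):
        base = [2, 3] * 120
        series = base[:10] + [600, 700] + base[10:]
        table = _table({"f1": series})
        filtered, _ = filter_artifacts(table)
        expected = (series[9] + series[12]) / 2
        assert filtered.counts["f1"].iloc[10] == pytest.approx(expected)
        assert filtered.counts["f1"].iloc[11] == pytest.approx(expected)

    def test_pooled_statistics_across_flies(self):
        """The threshold pools non-zero counts over every fly."""
        quiet = [1, 1] * 150
        loud = [30, 40] * 150
        table = _table({"quiet": quiet, "loud": loud})
        _, log = filter_artifacts(table)
        # 40 is normal for the pooled distribution: nothing replaced
        assert log.empty


class TestScoreSleep:
    def test_full_day_asleep(self):
        rec = score_sleep([0] * 1440)
        assert rec.sleep.sum() == 1440
        assert rec.bouts == [(0, 1440)]

    def test_short_gaps_are_wake(self):
        rec = score_sleep([1] + [0] * 4 + [1] * 10)
        assert rec.sleep.sum() == 0

    def test_worked_example_two_bouts(self):
        rec = score_sleep([1] + [0] * 10 + [1] + [0] * 5 + [1])
        assert rec.sleep.sum() == 15
        assert [L for _, L in rec.bouts] == [10, 5]

    @given(st.lists(st.integers(0, 5), min_size=20, max_size=200))
    def test_pure_function_of_zero_pattern(self, counts):
        """Sleep depends only on where counts are zero, not their size."""
        rec1 = score_sleep(counts)
        rec2 = score_sleep([c * 17 for c in counts])
        assert np.array_equal(rec1.sleep, rec2.sleep)
        assert rec1.bouts == rec2.bouts


class TestSummarizeSleep:
    def test_hand_built_single_day(self):
        day = [0] * 360 + [4] * 360 + [0] * 600 + [2] * 120
        table = _table({"f1": day})
        rec = score_sleep(day)
        summ = summarize_sleep(rec, np.array(day, float), table.schedule,
                               table.counts.index)
        row = summ.per_day.iloc[0]
        assert row["total_sleep"] == 960
        assert row["day_sleep"] == 360
        assert row["night_sleep"] == 600
        assert row["total_activity"] == 4 * 360 + 2 * 120
        assert row["waking_activity"] == pytest.approx(row["total_activity"] / 480)
        assert row["total_sleep"] + row["total_activity"] / row["waking_activity"] == 1440

    def test_all_sleep_day_waking_activity_missing(self):
        day = [0] * 1440
        table = _table({"f1": day})
        summ = summarize_sleep(score_sleep(day), np.array(day, float),
                               table.schedule, table.counts.index)
        assert summ.per_day["total_sleep"].iloc[0] == 1440
        assert np.isnan(summ.per_day["waking_activity"].iloc[0])

    def test_partial_leading_day_skipped(self):
        # 100 leading minutes before lights-on, then 2 full days
        idx = pd.date_range("2023-01-02 06:20:00", periods=100 + 2 * 1440,
                            freq="min")
        counts = np.ones(len(idx))
        table = ActivityTable(counts=pd.DataFrame({"f1": counts}, index=idx),
                              schedule=LightSchedule(lights_on=8))
        summ = summarize_sleep(score_sleep(counts), counts, table.schedule,
                               table.counts.index, window_days=4)
        assert summ.window_days == 2  # only the full days count

    def test_no_full_day_errors(self):
        day = [1] * 100
        table = _table({"f1": day})
        with pytest.raises(ValueError):
            summarize_sleep(score_sleep(day), np.array(day, float),
                            table.schedule, table.counts.index)

    def test_dead_fly_exclusion(self):
        alive = [1, 0] * (2 * 1440 // 2)
        dead = [1] * 1440 + [0] * 1440
        table = _table({"alive": alive, "dead": dead})
        kept, excluded = exclude_dead(table)
        assert excluded == ["dead"]
        assert list(kept.counts.columns) == ["alive"]


class TestFFT:
    def test_pure_24h_sinusoid(self):
        t = np.arange(5 * 1440)
        p = fft_rhythm_power(10 + 5 * np.cos(2 * np.pi * t / 1440))
        assert p.peak_period_h == pytest.approx(24.0, abs=24 / 5)
        assert p.power_24h > 0.9 and p.rhythmic

    def test_pure_12h_sinusoid_has_no_circadian_band_power(self):
        t = np.arange(5 * 1440)
        p = fft_rhythm_power(10 + 5 * np.cos(2 * np.pi * t / 720))
        assert p.power_24h < 1e-6 and not p.rhythmic

    def test_white_noise_rarely_rhythmic(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p = fft_rhythm_power(rng.poisson(2, 5 * 1440))
            hits += p.rhythmic
        assert hits <= 1

    def test_all_zero_window(self):
        p = fft_rhythm_power(np.zeros(3 * 1440))
        assert p.power_24h == 0.0 and not p.rhythmic

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            fft_rhythm_power(np.ones(1440))


class TestCompareGroups:
    def test_two_control_rule_requires_both(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(0, 1, 40)
        # experimental differs from GAL4 only; UAS tracks experimental
        exp = rng.normal(3, 1, 40)
        uas = rng.normal(3, 1, 40)
        cmp_ = compare_groups({"exp": exp, "GAL4": ctrl, "UAS": uas},
                              design="multi_group", controls=("GAL4", "UAS"))
        assert cmp_.pairwise_p[("exp", "GAL4")] < 0.05
        assert not cmp_.both_controls_significant

    def test_normality_gate_selects_nonparametric(self):
        rng = np.random.default_rng(1)
        heavy = rng.lognormal(0, 2.5, 30)
        normal = rng.normal(5, 1, 30)
        cmp_ = compare_groups({"a": heavy, "b": normal}, design="two_group")
        assert cmp_.test_used == "mann_whitney"
        cmp2 = compare_groups({"a": rng.normal(0, 1, 30),
                               "b": rng.normal(0, 1, 30)}, design="two_group")
        assert cmp2.test_used == "t"

    def test_welch_option(self):
        rng = np.random.default_rng(2)
        cmp_ = compare_groups({"a": rng.normal(0, 1, 20),
                               "b": rng.normal(0, 5, 20)},
                              design="two_group", welch=True)
        assert cmp_.test_used == "welch_t"

    def test_timepoints_design_bonferroni(self):
        rng = np.random.default_rng(3)
        groups = {f"ZT{z}": rng.normal(z / 4, 1, 8) for z in (0, 8, 16)}
        cmp_ = compare_groups(groups, design="timepoints")
        assert cmp_.test_used.endswith("bonferroni")
        assert len(cmp_.pairwise_p) == 3
        assert all(0 <= p <= 1 for p in cmp_.pairwise_p.values())

    def test_zero_variance_group_falls_back(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning):
            cmp_ = compare_groups({"a": np.full(10, 2.0),
                                   "b": rng.normal(0, 1, 10)},
                                  design="two_group")
        assert cmp_.test_used == "mann_whitney"

    def test_kruskal_dunn_path(self):
        rng = np.random.default_rng(5)
        groups = {
            "a": rng.lognormal(0, 2.0, 25),
            "b": rng.lognormal(1.5, 2.0, 25),
            "c": rng.lognormal(0, 2.0, 25),
        }
        cmp_ = compare_groups(groups, design="multi_group")
        assert cmp_.test_used == "kruskal_dunn"
        assert set(cmp_.pairwise_p) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1, 2], "b": [1, 2, 3]})
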