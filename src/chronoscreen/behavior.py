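"""Drosophila activity-monitor ingestion, filtering, sleep scoring and stats.

Implements the behavioral analysis chain for Trikinetics DAM2 monitor data:
parse the 42-field tab-separated monitor files, replace spike artifacts
(values at least six standard deviations above the mean of pooled non-zero
per-minute counts) with the average of the adjacent minutes, score sleep by
the 5-minute inactivity definition, summarize sleep/activity per fly per
day, estimate rhythmicity from the 24-h bin of an FFT periodogram, and run
the group-comparison harness: a Shapiro-Wilk normality gate selecting
parametric (t-test / one-way ANOVA with Tukey) or nonparametric
(Mann-Whitney / Kruskal-Wallis with Dunn) tests, pairwise-Bonferroni
timepoint series, and the two-control rule under which a phenotype counts
only when the experimental genotype differs from both the GAL4 and UAS
controls.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "LightSchedule",
    "ActivityTable",
    "SleepRecord",
    "SleepSummary",
    "RhythmPower",
    "GroupComparison",
    "read_dam",
    "filter_artifacts",
    "score_sleep",
    "summarize_sleep",
    "exclude_dead",
    "fft_rhythm_power",
    "compare_groups",
]


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class LightSchedule:
    mode: str = "LD"       # "LD" or "DD" (DD keeps the prior entrainment phase)
    lights_on: int = 8     # clock hour of (subjective) lights-on

    def is_day(self, index: pd.DatetimeIndex) -> np.ndarray:
        minute_of_day = index.hour * 60 + index.minute
        rel = np.asarray((minute_of_day - self.lights_on * 60) % 1440)
        return rel < 720


@dataclass
class ActivityTable:
    """Minute-binned beam-crossing counts, minutes x flies."""

    counts: pd.DataFrame              # DatetimeIndex, one column per channel
    schedule: LightSchedule
    monitor_id: str = "M01"
    bad_rows: pd.DataFrame | None = None   # non-OK status rows (excluded)
    gaps: list[pd.Timestamp] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")


@dataclass
class SleepRecord:
    fly_id: str
    sleep: np.ndarray                 # bool, minute resolution
    bouts: list[tuple[int, int]]      # (start index, length >= 5)


@dataclass
class SleepSummary:
    fly_id: str
    per_day: pd.DataFrame             # one row per full day
    window_days: int

    @property
    def total_sleep(self) -> float:
        return float(self.per_day["total_sleep"].mean())

    @property
    def waking_activity(self) -> float:
        return float(self.per_day["waking_activity"].mean())


@dataclass
class RhythmPower:
    fly_id: str
    periods_h: np.ndarray
    power: np.ndarray                 # normalized periodogram over the band
    power_24h: float
    peak_period_h: float
    rhythmic: bool


@dataclass
class GroupComparison:
    design: str
    test_used: str
    normal: dict[str, bool]
    statistics: dict
    pairwise_p: dict[tuple[str, str], float]   # adjusted p-values
    both_controls_significant: bool | None = None


# --------------------------------------------------------------------------
# DAM2 ingestion
# --------------------------------------------------------------------------

_DAM2_FIELDS = 42
_STATUS_OK = 1


def read_dam(path, monitor_id: str | None = None,
             schedule: LightSchedule | None = None) -> ActivityTable:
    """Parse a DAM2 monitor text file.

    Each tab-separated line carries: record index, date, time, monitor
    status, six reserved metadata fields, then the 32 channel counts.
    Rows with a non-OK status are flagged and excluded; gaps in the minute
    sequence are reported on the returned table.
    """
    rows = []
    bad = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != _DAM2_FIELDS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_DAM2_FIELDS} fields, "
                    f"got {len(fields)}"
                )
            try:
                status = int(fields[3])
                counts = [int(v) for v in fields[10:42]]
            except ValueError as e:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from e
            ts = pd.to_datetime(fields[1] + " " + fields[2], format="%d %b %y %H:%M:%S")
            if status != _STATUS_OK:
                bad.append({"line": lineno, "timestamp": ts, "status": status})
                continue
            rows.append((ts, counts))

    if not rows:
        raise ValueError(f"{path}: no valid data rows")
    index = pd.DatetimeIndex([r[0] for r in rows])
    mid = monitor_id or "M01"
    cols = [f"{mid}_c{ch:02d}" for ch in range(1, 33)]
    df = pd.DataFrame([r[1] for r in rows], index=index, columns=cols)

    gaps = []
    deltas = index.to_series().diff().dropna()
    for ts, d in deltas.items():
        if d != pd.Timedelta(minutes=1):
            gaps.append(ts)
    return ActivityTable(
        counts=df,
        schedule=schedule or LightSchedule(),
        monitor_id=mid,
        bad_rows=pd.DataFrame(bad) if bad else None,
        gaps=gaps,
    )


# --------------------------------------------------------------------------
# Artifact filtering
# --------------------------------------------------------------------------

def filter_artifacts(table: ActivityTable):
    """Replace spike artifacts with the mean of the adjacent minutes.

    The outlier threshold is mean + 6*SD of the non-zero per-minute counts
    pooled across all flies of the experiment.  Edge outliers use the single
    existing neighbor; runs of consecutive outliers use the nearest
    non-outlier neighbor on each side.  Replacement values stay real-valued.
    Returns (filtered table, artifact log DataFrame).
    """
    arr = table.counts.to_numpy(float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 minutes of data")
    nz = arr[arr > 0]
    log_rows = []
    out = arr.copy()
    if nz.size:
        thr = nz.mean() + 6 * nz.std()
        for j, fly in enumerate(table.counts.columns):
            col = arr[:, j]
            mask = col >= thr
            if not mask.any():
                continue
            idx = np.flatnonzero(mask)
            # group consecutive outlier minutes
            for _, run in itertools.groupby(enumerate(idx), key=lambda t: t[1] - t[0]):
                run_idx = [m for _, m in run]
                lo, hi = run_idx[0] - 1, run_idx[-1] + 1
                neighbors = []
                if lo >= 0:
                    neighbors.append(col[lo])
                if hi < col.size:
                    neighbors.append(col[hi])
                repl = float(np.mean(neighbors))
                for m in run_idx:
                    out[m, j] = repl
                    log_rows.append({
                        "fly_id": fly,
                        "timestamp": table.counts.index[m],
                        "minute": int(m),
                        "original": float(col[m]),
                        "replacement": repl,
                    })
    if not log_rows:  # untouched data keeps its dtype
        out_df = table.counts.copy()
    else:
        out_df = pd.DataFrame(out, index=table.counts.index,
                              columns=table.counts.columns)
    filtered = ActivityTable(
        counts=out_df,
        schedule=table.schedule,
        monitor_id=table.monitor_id,
        bad_rows=table.bad_rows,
        gaps=list(table.gaps),
    )
    cols = ["fly_id", "timestamp", "minute", "original", "replacement"]
    return filtered, pd.DataFrame(log_rows, columns=cols)


# --------------------------------------------------------------------------
# Sleep scoring
# --------------------------------------------------------------------------

def score_sleep(counts, fly_id: str = "fly") -> SleepRecord:
    """Score sleep with the 5-minute definition: every maximal run of >= 5
    consecutive zero-count minutes is sleep in its entirety."""
    c = np.asarray(counts, float)
    zero = c == 0
    sleep = np.zeros(c.size, dtype=bool)
    bouts = []
    i = 0
    while i < c.size:
        if zero[i]:
            j = i
            while j < c.size and zero[j]:
                j += 1
            if j - i >= 5:
                sleep[i:j] = True
                bouts.append((i, j - i))
            i = j
        else:
            i += 1
    return SleepRecord(fly_id=fly_id, sleep=sleep, bouts=bouts)


def _full_day_slices(index: pd.DatetimeIndex, schedule: LightSchedule,
                     n_days: int | None):
    """Complete 1440-minute days aligned to the (subjective) lights-on hour,
    skipping any partial leading day."""
    minute_of_day = index.hour * 60 + index.minute
    rel = (minute_of_day - schedule.lights_on * 60) % 1440
    starts = np.flatnonzero(np.asarray(rel) == 0)
    slices = [(int(s), int(s) + 1440) for s in starts if s + 1440 <= index.size]
    if n_days is not None:
        slices = slices[:n_days]
    return slices


def summarize_sleep(record: SleepRecord, counts, schedule: LightSchedule,
                    index: pd.DatetimeIndex, window_days: int | None = None) -> SleepSummary:
    """Per-day sleep/activity summary over full days only.

    Day/night split by the light schedule (in DD, subjective day carried
    forward from the prior entrainment phase).  Waking activity is total
    counts per waking minute; a fully asleep day reports it as missing.
    Enforces the conservation invariant sleep + wake = 1440 min per day.
    """
    c = np.asarray(counts, float)
    slices = _full_day_slices(index, schedule, window_days)
    if not slices:
        raise ValueError("no full day inside the window")
    is_day = schedule.is_day(index)
    rows = []
    for d, (a, b) in enumerate(slices, start=1):
        sl = record.sleep[a:b]
        cc = c[a:b]
        day_mask = is_day[a:b]
        total_sleep = int(sl.sum())
        wake_min = 1440 - total_sleep
        assert total_sleep + wake_min == 1440
        day_bouts = [(s, L) for s, L in record.bouts if s < b and s + L > a]
        bout_lens = [min(s + L, b) - max(s, a) for s, L in day_bouts]
        total_counts = float(cc.sum())
        rows.append({
            "day": d,
            "total_sleep": total_sleep,
            "day_sleep": int(sl[day_mask].sum()),
            "night_sleep": int(sl[~day_mask].sum()),
            "bout_count": len(day_bouts),
            "mean_bout_length": float(np.mean(bout_lens)) if bout_lens else 0.0,
            "total_activity": total_counts,
            "waking_activity": total_counts / wake_min if wake_min else np.nan,
        })
    return SleepSummary(fly_id=record.fly_id, per_day=pd.DataFrame(rows),
                        window_days=len(slices))


def exclude_dead(table: ActivityTable):
    """Drop flies with zero counts over the final 24 h; returns
    (table without them, list of excluded fly ids)."""
    tail = table.counts.iloc[-1440:]
    dead = [c for c in table.counts.columns if tail[c].sum() == 0]
    kept = table.counts.drop(columns=dead)
    out = ActivityTable(counts=kept, schedule=table.schedule,
                        monitor_id=table.monitor_id, bad_rows=table.bad_rows,
                        gaps=list(table.gaps))
    return out, dead


# --------------------------------------------------------------------------
# FFT rhythmicity
# --------------------------------------------------------------------------

def fft_rhythm_power(counts, fly_id: str = "fly", band_h=(18.0, 30.0),
                     threshold: float = 0.01) -> RhythmPower:
    """Periodogram rhythmicity of a minute-binned activity trace.

    The mean-subtracted series is Fourier transformed; power is |F_k|^2
    normalized to the total power over all positive-frequency bins.  Reports
    the normalized power at the bin nearest 24 h and the peak period within
    the searched 18-30 h band; the trace is rhythmic iff the 24-h power
    reaches ``threshold``.
    """
    c = np.asarray(counts, float)
    n = c.size
    if n < 3 * 1440:
        raise ValueError("need at least 3 days of minute-binned data")
    x = c - c.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    spec[0] = 0.0
    total = spec.sum()
    if total == 0:
        return RhythmPower(fly_id, np.array([]), np.array([]), 0.0,
                           float("nan"), False)
    norm = spec / total
    k = np.arange(1, spec.size)
    periods = n / (60.0 * k)  # hours
    k24 = int(np.argmin(np.abs(periods - 24.0))) + 1
    in_band = (periods >= band_h[0]) & (periods <= band_h[1])
    band_k = k[in_band]
    if band_k.size:
        peak_k = int(band_k[np.argmax(norm[band_k])])
        peak_period = n / (60.0 * peak_k)
    else:
        peak_period = float("nan")
    p24 = float(norm[k24])
    return RhythmPower(
        fly_id=fly_id,
        periods_h=periods[in_band],
        power=norm[band_k] if band_k.size else np.array([]),
        power_24h=p24,
        peak_period_h=float(peak_period),
        rhythmic=p24 >= threshold,
    )


# --------------------------------------------------------------------------
# Group comparisons
# --------------------------------------------------------------------------

def _shapiro_ok(x: np.ndarray, alpha: float = 0.05) -> bool:
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        return False  # constant group: gate fails, nonparametric path
    return scipy.stats.shapiro(x).pvalue >= alpha


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's post-hoc z-tests on pooled ranks with tie correction,
    Bonferroni-adjusted across all pairs."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    N = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    mean_ranks = {}
    i = 0
    for g in labels:
        n = groups[g].size
        mean_ranks[g] = ranks[i:i + n].mean()
        i += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(labels, 2))
    out = {}
    for a, b in pairs:
        na, nb = groups[a].size, groups[b].size
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2 * scipy.stats.norm.sf(abs(z))
        out[(a, b)] = min(1.0, p * len(pairs))
    return out


def compare_groups(values: dict[str, "np.ndarray | list[float]"],
                   design: str = "two_group",
                   controls: tuple[str, str] | None = None,
                   experimental: str | None = None,
                   alpha: float = 0.05,
                   welch: bool = False) -> GroupComparison:
    """Normality-gated group comparison with the two-control rule.

    Shapiro-Wilk on each group at alpha = 0.05 picks the test family: all
    normal -> t-test (two-group; Welch optional) or one-way ANOVA with Tukey
    (multi-group); any non-normal (or zero-variance) group -> Mann-Whitney
    or Kruskal-Wallis with Dunn.  ``design="timepoints"`` runs all pairwise
    comparisons among the groups (ZT bins) with Bonferroni adjustment.
    When ``controls`` is given, ``both_controls_significant`` is true iff
    the experimental group differs from each control at adjusted p < 0.05.
    """
    groups = {g: np.asarray(v, float) for g, v in values.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
    if design not in ("two_group", "multi_group", "timepoints"):
        raise ValueError("unknown design")

    normal = {g: _shapiro_ok(v, alpha=0.05) for g, v in groups.items()}
    parametric = all(normal.values())
    if any(np.ptp(v) == 0 for v in groups.values()):
        warnings.warn("zero-variance group: falling back to nonparametric tests")
        parametric = False

    labels = list(groups)
    pairwise: dict[tuple[str, str], float] = {}
    stats: dict = {}

    if design == "two_group":
        if len(groups) != 2:
            raise ValueError("two_group design needs exactly 2 groups")
        a, b = labels
        if parametric:
            res = scipy.stats.ttest_ind(groups[a], groups[b], equal_var=not welch)
            test = "welch_t" if welch else "t"
        else:
            res = scipy.stats.mannwhitneyu(groups[a], groups[b],
                                           alternative="two-sided")
            test = "mann_whitney"
        stats = {"statistic": float(res.statistic), "p": float(res.pvalue)}
        pairwise[(a, b)] = float(res.pvalue)
    elif design == "multi_group":
        if parametric:
            f = scipy.stats.f_oneway(*groups.values())
            tk = scipy.stats.tukey_hsd(*groups.values())
            test = "anova_tukey"
            stats = {"F": float(f.statistic), "p": float(f.pvalue)}
            for i, j in itertools.combinations(range(len(labels)), 2):
                pairwise[(labels[i], labels[j])] = float(tk.pvalue[i, j])
        else:
            kw = scipy.stats.kruskal(*groups.values())
            test = "kruskal_dunn"
            stats = {"H": float(kw.statistic), "p": float(kw.pvalue)}
            pairwise = _dunn_pairwise(groups)
    else:  # timepoints: pairwise among ZT bins, Bonferroni-corrected
        pairs = list(itertools.combinations(labels, 2))
        raw = {}
        for a, b in pairs:
            if parametric:
                raw[(a, b)] = float(scipy.stats.ttest_ind(groups[a], groups[b]).pvalue)
            else:
                raw[(a, b)] = float(scipy.stats.mannwhitneyu(
                    groups[a], groups[b], alternative="two-sided").pvalue)
        test = ("pairwise_t_bonferroni" if parametric
                else "pairwise_mw_bonferroni")
        pairwise = {k: min(1.0, p * len(pairs)) for k, p in raw.items()}

    both = None
    if controls is not None:
        c1, c2 = controls
        exp = experimental
        if exp is None:
            rest = [g for g in labels if g not in controls]
            if len(rest) != 1:
                raise ValueError("cannot infer the experimental group")
            exp = rest[0]
        def _adj(a, b):
            if (a, b) in pairwise:
                return pairwise[(a, b)]
            if (b, a) in pairwise:
                return pairwise[(b, a)]
            raise KeyError((a, b))
        both = bool(_adj(exp, c1) < alpha and _adj(exp, c2) < alpha)

    return GroupComparison(
        design=design, test_used=test, normal=normal, statistics=stats,
        pairwise_p=pairwise, both_controls_significant=both,
    )
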