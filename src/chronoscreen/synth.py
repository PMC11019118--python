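"""Synthetic data generators with known ground truth.

Every downstream stage of the package (rhythm screening, OPLS modeling,
sleep/activity analysis, ratiometric imaging) is exercised on data produced
here, so each generator returns the ground truth alongside the data: the
omics generator records which features are rhythmic with which amplitude and
phase, the activity generator records the minutes where spike artifacts were
injected, and the imaging generators record the true per-brain ratios and
foreground masks.  File writers emit only the data portion, in the formats
the analysis modules read (TSV omics tables, DAM2 monitor text files,
2-channel TIFF stacks, ROI CSVs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "OmicsSimConfig",
    "ActivitySimConfig",
    "ImagingSimConfig",
    "TimeCourseMatrix",
    "OmicsGroundTruth",
    "ActivityGroundTruth",
    "ImageStack",
    "generate_omics",
    "generate_activity",
    "generate_roi_table",
    "generate_rogfp_stack",
    "young_like_config",
    "old_like_config",
    "write_omics_tsv",
    "read_omics_tsv",
    "write_dam_file",
    "write_roi_csv",
    "write_rogfp_tiff",
    "read_rogfp_tiff",
]


# --------------------------------------------------------------------------
# Shared containers
# --------------------------------------------------------------------------

@dataclass
class TimeCourseMatrix:
    """Feature-by-sample omics table with per-sample metadata.

    ``values`` is a features x samples DataFrame of nonnegative peak heights
    (mTIC-normalized semantics); ``sample_meta`` has one row per sample with
    columns ``sample_id``, ``group``, ``zt``, ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.sample_meta["sample_id"]):
            raise ValueError("sample_meta rows must match value columns in order")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        zts = self.sample_meta["zt"].to_numpy(float)
        if ((zts < 0) | (zts >= 24)).any():
            raise ValueError("ZT hours must lie in [0, 24)")
        for g, sub in self.sample_meta.groupby("group"):
            if sub["zt"].nunique() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 distinct ZTs")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["group"]))

    def group_samples(self, group: str) -> pd.DataFrame:
        """Metadata rows of one group, ordered by (zt, replicate)."""
        sub = self.sample_meta[self.sample_meta["group"] == group]
        if sub.empty:
            raise KeyError(f"group {group!r} not present")
        return sub.sort_values(["zt", "replicate"], kind="stable")


@dataclass
class OmicsGroundTruth:
    baselines: pd.Series               # per feature
    rhythmic_sets: dict[str, set[str]]  # group -> feature ids
    amplitude_rel: dict[str, float]     # group -> relative amplitude
    phase_hours: dict[str, float]       # feature -> peak hour


@dataclass
class ActivityGroundTruth:
    artifact_minutes: dict[str, list[int]]  # fly id -> injected minute indices
    sleep_state: pd.DataFrame               # minutes x flies, True = asleep


@dataclass
class ImageStack:
    """Two-channel (405 nm, 488 nm) 8-bit z-stack for redox imaging."""

    ch405: np.ndarray  # (z, y, x) uint8
    ch488: np.ndarray  # (z, y, x) uint8
    brain_id: str = "brain"
    run_id: str = "run1"
    genotype: str = "control"
    zt: float = 0.0

    def __post_init__(self) -> None:
        if self.ch405.shape != self.ch488.shape:
            raise ValueError("channel shapes differ")
        if self.ch405.dtype != np.uint8 or self.ch488.dtype != np.uint8:
            raise ValueError("stacks must be 8-bit")


# --------------------------------------------------------------------------
# Omics time-course generator
# --------------------------------------------------------------------------

@dataclass
class OmicsSimConfig:
    """Design of a simulated circadian omics time course.

    The default grid of six ZTs at 4-h spacing over one 24-h cycle matches
    the standard six-timepoint circadian collection design.  Peak heights are
    positive and right-skewed, so noise is multiplicative lognormal with the
    given coefficient of variation; ``sample_noise_cv`` adds a per-sample
    lognormal factor shared across all features of that sample, emulating
    pooled-collection variability (the mechanism behind a noisy group in
    which individual features still cycle but no sample-level time-of-day
    model can be built).
    """

    n_features: int = 159
    zt_hours: tuple[float, ...] = (0, 4, 8, 12, 16, 20)
    reps_per_group: dict[str, int] = field(default_factory=lambda: {"young": 5, "old": 4})
    rhythmic_sets: dict[str, set[str]] = field(default_factory=dict)
    amplitude_rel: dict[str, float] = field(default_factory=dict)
    phase_hours: dict[str, float] = field(default_factory=dict)
    baseline_scale: float = 1000.0
    noise_cv: dict[str, float] = field(default_factory=dict)
    sample_noise_cv: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def feature_ids(self) -> list[str]:
        return [f"met{i:03d}" for i in range(1, self.n_features + 1)]

    def validate(self) -> None:
        zts = list(self.zt_hours)
        if any(b <= a for a, b in zip(zts, zts[1:])):
            raise ValueError("zt_hours must be strictly increasing")
        if any(t < 0 or t >= 24 for t in zts):
            raise ValueError("zt_hours must lie in [0, 24)")
        if len(zts) < 2:
            raise ValueError("need at least 2 distinct ZTs")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if self.baseline_scale <= 0:
            raise ValueError("baseline_scale must be positive")
        ids = set(self.feature_ids())
        for g, n in self.reps_per_group.items():
            if n < 1:
                raise ValueError(f"reps_per_group[{g!r}] must be >= 1")
        for g, s in self.rhythmic_sets.items():
            if g not in self.reps_per_group:
                raise ValueError(f"rhythmic set for unknown group {g!r}")
            if not set(s) <= ids:
                raise ValueError(f"rhythmic_sets[{g!r}] contains unknown feature ids")
        for g, a in self.amplitude_rel.items():
            if not 0 <= a <= 1:
                raise ValueError("amplitude_rel must lie in [0, 1]")
        for g, cv in self.noise_cv.items():
            if cv < 0:
                raise ValueError("noise_cv must be >= 0")
        for g, cv in self.sample_noise_cv.items():
            if cv < 0:
                raise ValueError("sample_noise_cv must be >= 0")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate_omics(config: OmicsSimConfig) -> tuple[TimeCourseMatrix, OmicsGroundTruth]:
    """Simulate a feature x sample peak-height table with cosine rhythms.

    Each feature f in group g follows
    ``baseline_f * (1 + a_f * cos(2*pi*(t - phi_f)/24)) * eps`` with
    ``eps`` lognormal of unit mean and CV ``noise_cv[g]``; ``a_f`` is
    ``amplitude_rel[g]`` for features in the group's rhythmic set and 0
    otherwise.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = config.feature_ids()

    baselines = pd.Series(
        config.baseline_scale * _lognormal_unit_mean(rng, 0.5, len(ids)),
        index=ids,
        name="baseline",
    )
    # default phases: deterministic spread over the cycle
    phases = {f: config.phase_hours.get(f, (4.0 * i) % 24) for i, f in enumerate(ids)}

    cols: list[str] = []
    meta_rows: list[dict] = []
    data: list[np.ndarray] = []
    t_arr = np.array(config.zt_hours, float)
    for group, reps in config.reps_per_group.items():
        rset = config.rhythmic_sets.get(group, set())
        amp = config.amplitude_rel.get(group, 0.0)
        cv = config.noise_cv.get(group, 0.0)
        scv = config.sample_noise_cv.get(group, 0.0)
        a = np.array([amp if f in rset else 0.0 for f in ids])
        phi = np.array([phases[f] for f in ids])
        for zt in t_arr:
            mean_profile = baselines.to_numpy() * (
                1.0 + a * np.cos(2 * np.pi * (zt - phi) / 24.0)
            )
            for rep in range(1, reps + 1):
                eps = _lognormal_unit_mean(rng, cv, len(ids))
                sfac = float(_lognormal_unit_mean(rng, scv, 1)[0])
                data.append(mean_profile * eps * sfac)
                sid = f"{group}_ZT{int(zt):02d}_rep{rep}"
                cols.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "group": group, "zt": float(zt), "replicate": rep}
                )

    values = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    meta = pd.DataFrame(meta_rows)
    truth = OmicsGroundTruth(
        baselines=baselines,
        rhythmic_sets={g: set(s) for g, s in config.rhythmic_sets.items()},
        amplitude_rel=dict(config.amplitude_rel),
        phase_hours=phases,
    )
    return TimeCourseMatrix(values=values, sample_meta=meta), truth


def _spread_phases(ids: list[str], hours: tuple[float, ...]) -> dict[str, float]:
    return {f: hours[i % len(hours)] for i, f in enumerate(ids)}


def young_like_config(seed: int = 0, n_features: int = 159, n_rhythmic: int = 17,
                      reps: int = 5) -> OmicsSimConfig:
    """Strong, low-noise rhythms with coherent phases (young-head-like)."""
    cfg = OmicsSimConfig(n_features=n_features, seed=seed,
                         reps_per_group={"young": reps})
    ids = cfg.feature_ids()
    rhythmic = ids[:n_rhythmic]
    cfg.rhythmic_sets = {"young": set(rhythmic)}
    cfg.amplitude_rel = {"young": 0.5}
    cfg.noise_cv = {"young": 0.1}
    cfg.sample_noise_cv = {"young": 0.0}
    # phases clustered in the first half of the day: coherent time signal
    cfg.phase_hours = _spread_phases(rhythmic, (0.0, 2.0, 4.0, 6.0, 8.0))
    return cfg


def old_like_config(seed: int = 0, n_features: int = 159, n_rhythmic: int = 17,
                    reps: int = 4, n_shared: int = 4) -> OmicsSimConfig:
    """Weak discordant rhythms with inflated noise (old-head-like).

    A distinct rhythmic set overlapping the young-like set in ``n_shared``
    features, damped amplitude, higher per-value noise, and a per-sample
    variance component shared across features.
    """
    cfg = OmicsSimConfig(n_features=n_features, seed=seed,
                         reps_per_group={"old": reps})
    ids = cfg.feature_ids()
    rhythmic = ids[:n_shared] + ids[17:17 + (n_rhythmic - n_shared)]
    cfg.rhythmic_sets = {"old": set(rhythmic)}
    cfg.amplitude_rel = {"old": 0.2}
    cfg.noise_cv = {"old": 0.3}
    cfg.sample_noise_cv = {"old": 0.25}
    # discordant phases spread over the whole cycle
    cfg.phase_hours = _spread_phases(rhythmic, (0.0, 7.0, 14.0, 21.0, 3.0, 10.0, 17.0))
    return cfg


# --------------------------------------------------------------------------
# Activity (DAM) generator
# --------------------------------------------------------------------------

@dataclass
class ActivitySimConfig:
    """Minute-binned locomotor-activity simulation for one monitor.

    Per-minute wake/sleep follows a two-state Markov chain whose stationary
    wake probability equals ``mean_active_prob_day``/``night`` and whose
    sleep-episode mean length is ``sleep_bout_mean_min``; wake minutes carry
    Poisson(counts_rate) beam-crossing counts.  Rare spike artifacts (dead
    channels, vibration) are injected as isolated minutes with counts of
    ``artifact_magnitude * counts_rate``.
    """

    n_flies: int = 32
    days: int = 5
    schedule: str = "LD"           # "LD" or "DD"
    lights_on: int = 8             # clock hour of lights-on (or subjective, in DD)
    mean_active_prob_day: float = 0.6
    mean_active_prob_night: float = 0.15
    counts_rate: float = 2.0
    sleep_bout_mean_min: float = 25.0
    artifact_rate: float = 0.5     # expected spikes per fly-day
    artifact_magnitude: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_flies < 1 or self.days < 1:
            raise ValueError("n_flies and days must be >= 1")
        if self.schedule not in ("LD", "DD"):
            raise ValueError("schedule must be 'LD' or 'DD'")
        for p in (self.mean_active_prob_day, self.mean_active_prob_night):
            if not 0 <= p <= 1:
                raise ValueError("activity probabilities must lie in [0, 1]")
        if self.counts_rate < 0 or self.artifact_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.artifact_magnitude <= 1:
            raise ValueError("artifact_magnitude must exceed 1")
        if self.sleep_bout_mean_min < 1:
            raise ValueError("sleep_bout_mean_min must be >= 1 minute")


def generate_activity(config: ActivitySimConfig):
    """Simulate per-fly minute counts; returns (ActivityTable, ground truth).

    Imported lazily to avoid a circular dependency: the table type lives in
    :mod:`chronoscreen.behavior`.
    """
    from .behavior import ActivityTable, LightSchedule

    config.validate()
    rng = np.random.default_rng(config.seed)
    n_min = config.days * 1440
    # recording starts at lights-on, so minutes-since-start give phase directly
    is_day = (np.arange(n_min) % 1440) < 720

    p_wake = np.where(is_day, config.mean_active_prob_day, config.mean_active_prob_night)
    b = 1.0 / config.sleep_bout_mean_min  # P(sleep -> wake)

    counts = np.zeros((n_min, config.n_flies), dtype=float)
    asleep = np.zeros((n_min, config.n_flies), dtype=bool)
    artifact_minutes: dict[str, list[int]] = {}
    fly_ids = [f"M01_c{ch:02d}" for ch in range(1, config.n_flies + 1)]

    for j, fid in enumerate(fly_ids):
        awake = rng.random() < p_wake[0]
        u = rng.random(n_min)
        pois = rng.poisson(config.counts_rate, n_min)
        for i in range(n_min):
            pi = p_wake[i]
            if pi <= 0:
                awake = False
            elif pi >= 1:
                awake = True
            elif awake:
                # P(wake->sleep) chosen so stationary P(wake) = pi
                if u[i] < min(b * (1 - pi) / pi, 1.0):
                    awake = False
            else:
                if u[i] < b:
                    awake = True
            if awake:
                counts[i, j] = pois[i]
            else:
                asleep[i, j] = True

        n_art = rng.poisson(config.artifact_rate * config.days)
        placed: list[int] = []
        if n_art > 0:
            candidates = rng.permutation(n_min)
            for m in candidates:
                if len(placed) >= n_art:
                    break
                if any(abs(m - q) <= 1 for q in placed):
                    continue  # keep artifacts isolated
                counts[m, j] = np.ceil(config.artifact_magnitude * config.counts_rate)
                placed.append(int(m))
        artifact_minutes[fid] = sorted(placed)

    start = pd.Timestamp("2023-01-02") + pd.Timedelta(hours=config.lights_on)
    index = pd.date_range(start, periods=n_min, freq="min")
    table = ActivityTable(
        counts=pd.DataFrame(counts.astype(int), index=index, columns=fly_ids),
        schedule=LightSchedule(mode=config.schedule, lights_on=config.lights_on),
        monitor_id="M01",
    )
    truth = ActivityGroundTruth(
        artifact_minutes=artifact_minutes,
        sleep_state=pd.DataFrame(asleep, index=index, columns=fly_ids),
    )
    return table, truth


# --------------------------------------------------------------------------
# Imaging generators
# --------------------------------------------------------------------------

@dataclass
class ImagingSimConfig:
    """Design of simulated CaLexA ROI tables and roGFP stacks (8-bit)."""

    n_brains: int = 8
    cells_per_brain: dict[str, int] = field(
        default_factory=lambda: {"l-LNv": 4, "s-LNv": 4}
    )
    true_ratio: dict[tuple[str, float], float] = field(
        default_factory=lambda: {("control", 14.0): 1.0, ("G6PD-OE", 14.0): 1.5}
    )
    background_level: float = 30.0
    stack_shape: tuple[int, int, int] = (6, 64, 64)
    mito_fraction: float = 0.15
    noise_cv: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_brains < 1:
            raise ValueError("n_brains must be >= 1")
        if any(d <= 0 for d in self.stack_shape):
            raise ValueError("stack_shape dimensions must be positive")
        if not 0 < self.mito_fraction < 1:
            raise ValueError("mito_fraction must lie in (0, 1)")
        if not 0 <= self.background_level <= 255:
            raise ValueError("8-bit intensities must lie in [0, 255]")


def generate_roi_table(config: ImagingSimConfig):
    """Simulate per-cell GFP/RFP ROI records for the CaLexA quantification.

    Returns (records, truth) where records is a list of
    :class:`chronoscreen.imaging.ROIRecord` and truth maps
    (brain_id, cell class) -> configured true ratio.
    """
    from .imaging import ROIRecord

    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[ROIRecord] = []
    truth: dict[tuple[str, str], float] = {}
    conditions = list(config.true_ratio.items())
    for b in range(config.n_brains):
        (genotype, zt), ratio = conditions[b % len(conditions)]
        brain_id = f"brain{b + 1:02d}"
        for cls, n_cells in config.cells_per_brain.items():
            truth[(brain_id, cls)] = ratio
            for c in range(n_cells):
                sl = int(rng.integers(1, config.stack_shape[0] + 1))
                bg_g = config.background_level * float(
                    _lognormal_unit_mean(rng, config.noise_cv, 1)[0]
                )
                bg_r = config.background_level * float(
                    _lognormal_unit_mean(rng, config.noise_cv, 1)[0]
                )
                rfp_sig = 3.0 * float(_lognormal_unit_mean(rng, config.noise_cv, 1)[0])
                gfp_sig = ratio * rfp_sig * float(
                    _lognormal_unit_mean(rng, config.noise_cv, 1)[0]
                )
                records.append(
                    ROIRecord(
                        brain_id=brain_id,
                        cell_class=cls,
                        slice_index=sl,
                        gfp=bg_g * gfp_sig,
                        rfp=bg_r * rfp_sig,
                        bg_gfp=bg_g,
                        bg_rfp=bg_r,
                        genotype=genotype,
                        zt=float(zt),
                    )
                )
    return records, truth


def generate_rogfp_stack(config: ImagingSimConfig, brain_index: int = 0,
                         true_ratio: float | None = None):
    """Simulate a 2-channel roGFP z-stack.

    Foreground "mitochondria" pixels carry a 488 signal near 180 with the 405
    channel at ``true_ratio`` times the 488 value; background is dim in both
    channels; a small saturating blob emulates trachea autofluorescence (not
    part of the ground-truth mask).  Returns (ImageStack, truth mask).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + brain_index)
    z, ny, nx = config.stack_shape
    if true_ratio is None:
        true_ratio = next(iter(config.true_ratio.values()))
    if not 0 < true_ratio * 200 <= 255:
        raise ValueError("true_ratio too large for an 8-bit 405 channel")

    bg405 = rng.normal(config.background_level, 4.0, size=(z, ny, nx))
    bg488 = rng.normal(config.background_level, 4.0, size=(z, ny, nx))

    mask = np.zeros((z, ny, nx), dtype=bool)
    n_fg = int(config.mito_fraction * ny * nx)
    for k in range(z):
        # clustered foreground: a few blobs per slice
        n_blobs = max(1, n_fg // 40)
        placed = 0
        for _ in range(n_blobs * 4):
            if placed >= n_fg:
                break
            cy = int(rng.integers(6, ny - 6))
            cx = int(rng.integers(6, nx - 6))
            r = int(rng.integers(2, 5))
            yy, xx = np.ogrid[:ny, :nx]
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            mask[k] |= blob
            placed = int(mask[k].sum())

    sig488 = 180.0 * _lognormal_unit_mean(rng, config.noise_cv, mask.sum())
    ch488 = bg488.copy()
    ch488[mask] = sig488
    ch405 = bg405.copy()
    ch405[mask] = true_ratio * sig488

    # trachea-like saturating blob in a corner, bright in both channels
    ch405[:, :4, :4] = 255.0
    ch488[:, :4, :4] = 255.0

    stack = ImageStack(
        ch405=np.clip(ch405, 0, 255).astype(np.uint8),
        ch488=np.clip(ch488, 0, 255).astype(np.uint8),
        brain_id=f"brain{brain_index + 1:02d}",
    )
    return stack, mask


# --------------------------------------------------------------------------
# File writers / readers (data portion only)
# --------------------------------------------------------------------------

FLOAT_FMT = "%.9g"


def write_omics_tsv(matrix: TimeCourseMatrix, data_path, meta_path) -> None:
    """TSV with feature ids in the first column; companion metadata TSV."""
    matrix.values.to_csv(data_path, sep="\t", index_label="feature_id",
                         float_format=FLOAT_FMT)
    matrix.sample_meta.to_csv(meta_path, sep="\t", index=False,
                              float_format=FLOAT_FMT)


def read_omics_tsv(data_path, meta_path) -> TimeCourseMatrix:
    values = pd.read_csv(data_path, sep="\t", index_col="feature_id")
    meta = pd.read_csv(meta_path, sep="\t")
    return TimeCourseMatrix(values=values, sample_meta=meta)


def write_dam_file(table, path) -> None:
    """Write an ActivityTable as a DAM2 monitor text file (32 channels)."""
    counts = table.counts
    n_ch = counts.shape[1]
    if n_ch > 32:
        raise ValueError("a DAM2 monitor holds at most 32 channels")
    with open(path, "w") as fh:
        for i, (ts, row) in enumerate(counts.iterrows(), start=1):
            date = ts.strftime("%d %b %y")
            time = ts.strftime("%H:%M:%S")
            vals = list(row.astype(int)) + [0] * (32 - n_ch)
            fields = [str(i), date, time, "1"] + ["0"] * 6 + [str(v) for v in vals]
            fh.write("\t".join(fields) + "\n")


def write_roi_csv(records, path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows).rename(columns={
        "cell_class": "class", "slice_index": "slice",
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_rogfp_tiff(stack: ImageStack, path) -> None:
    """Multi-page TIFF, pages interleaved (405 then 488 per z-plane)."""
    z = stack.ch405.shape[0]
    pages = np.empty((2 * z,) + stack.ch405.shape[1:], dtype=np.uint8)
    pages[0::2] = stack.ch405
    pages[1::2] = stack.ch488
    tifffile.imwrite(path, pages, metadata={"channels": "405,488"})


def read_rogfp_tiff(path, **meta) -> ImageStack:
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] % 2:
        raise ValueError("expected an interleaved 2-channel multi-page TIFF")
    return ImageStack(ch405=pages[0::2], ch488=pages[1::2], **meta)
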