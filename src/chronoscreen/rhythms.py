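"""Nonparametric circadian rhythm detection (JTK) and FDR screening.

The JTK (Jonckheere-Terpstra-Kendall) statistic tests monotone agreement
between an omics time series and a cyclic cosine reference: Kendall's S is
the number of concordant minus discordant pairs between the observed values
and the reference cosine evaluated at each observation's ZT for a candidate
phase lag.  Replicates share their timepoint's reference value and therefore
form tied reference groups; the exact one-sided null distribution of S under
random permutation of (distinct) data values against such a tied reference
is the Jonckheere-Terpstra null, computed here by dynamic-programming
convolution of Gaussian-binomial coefficients.  A screen evaluates every lag
on the sampling grid at a fixed 24-h period, takes the minimum p across
lags, and applies a Bonferroni factor equal to the number of lags tested
(the correction over candidate reference waveforms that keeps the
per-feature p honest; the uncorrected minimum is kept on the result as
``p_min_lag``).  Features are then corrected across the screen with
Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .synth import TimeCourseMatrix

__all__ = [
    "JTKResult",
    "RhythmScreen",
    "OverlapSummary",
    "jtk_statistic",
    "jtk_exact_pvalue",
    "jtk_mc_pvalue",
    "jtk_screen",
    "benjamini_hochberg",
    "overlap_summary",
    "zscale_features",
]

_REF_DECIMALS = 9  # rounding used to identify ties in the float-valued reference


# --------------------------------------------------------------------------
# Kendall S against a cyclic reference
# --------------------------------------------------------------------------

def _reference(zts: np.ndarray, period: float, lag: float) -> np.ndarray:
    return np.cos(2 * np.pi * (np.asarray(zts, float) - lag) / period)


def _sign_matrix(x: np.ndarray) -> np.ndarray:
    return np.sign(x[:, None] - x[None, :])


def _tie_group_sizes(x: np.ndarray, decimals: int | None = None) -> list[int]:
    if decimals is not None:
        x = np.round(x, decimals)
    _, counts = np.unique(x, return_counts=True)
    return sorted(int(c) for c in counts)


def _n_tied_pairs(x: np.ndarray, decimals: int | None = None) -> int:
    return sum(c * (c - 1) // 2 for c in _tie_group_sizes(x, decimals))


@dataclass
class JTKStat:
    S: int
    tau: float
    constant: bool = False  # all data values identical -> tau undefined, set 0


def jtk_statistic(zts, values, period: float = 24.0, lag: float = 0.0) -> JTKStat:
    """Kendall S and tau-b between ``values`` and the lagged cosine reference.

    ``zts``/``values`` are parallel sequences including replicates (which
    receive tied reference values).  ``tau`` uses the average-rank tie
    correction on both vectors; an all-constant series returns tau = 0 with
    ``constant=True``.
    """
    zts = np.asarray(zts, float)
    values = np.asarray(values, float)
    if values.size < 3:
        raise ValueError("need at least 3 observations")
    if zts.shape != values.shape:
        raise ValueError("zts and values must have equal length")

    ref = np.round(_reference(zts, period, lag), _REF_DECIMALS)
    d = _sign_matrix(values)
    r = _sign_matrix(ref)
    S = int(round((d * r).sum() / 2))

    n = values.size
    n0 = n * (n - 1) // 2
    n1 = _n_tied_pairs(values)
    n2 = _n_tied_pairs(ref)
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        return JTKStat(S=S, tau=0.0, constant=n1 == n0)
    return JTKStat(S=S, tau=S / denom)


# --------------------------------------------------------------------------
# Exact null distribution (Jonckheere-Terpstra via Gaussian binomials)
# --------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _gaussian_binomial(n: int, k: int) -> tuple[int, ...]:
    """Coefficients of the q-binomial [n choose k]_q as exact integers.

    Coefficient u counts the interleavings of k items among n with u
    crossings; recurrence C(n,k)_q = C(n-1,k-1)_q + q^k C(n-1,k)_q.
    """
    if k < 0 or k > n:
        raise ValueError("require 0 <= k <= n")
    if k == 0 or k == n:
        return (1,)
    a = _gaussian_binomial(n - 1, k - 1)
    b = _gaussian_binomial(n - 1, k)
    deg = k * (n - k)
    out = [0] * (deg + 1)
    for i, c in enumerate(a):
        out[i] += c
    for i, c in enumerate(b):
        out[i + k] += c
    return tuple(out)


@lru_cache(maxsize=None)
def _jt_null(group_sizes: tuple[int, ...]) -> tuple[tuple[int, ...], int]:
    """Null counts of the Jonckheere-Terpstra statistic J for tied-reference
    groups of the given sizes; returns (counts over J = 0..M, total)."""
    dist = [1]
    m = 0
    for g in group_sizes:
        qb = _gaussian_binomial(m + g, g)
        new = [0] * (len(dist) + len(qb) - 1)
        for i, a in enumerate(dist):
            if a:
                for j, b in enumerate(qb):
                    if b:
                        new[i + j] += a * b
        dist = new
        m += g
    return tuple(dist), sum(dist)


def jtk_exact_pvalue(S: int, group_sizes) -> float:
    """Exact one-sided p = P(S* >= S) for distinct data values permuted
    uniformly against a reference with tied groups of ``group_sizes``.

    S relates to the Jonckheere-Terpstra count J of concordant cross-group
    pairs by S = 2J - M with M the number of cross-group pairs.
    """
    sizes = tuple(sorted(int(g) for g in group_sizes))
    n = sum(sizes)
    M = (n * n - sum(g * g for g in sizes)) // 2
    if abs(S) > M:
        raise ValueError("S out of range for this tie pattern")
    counts, total = _jt_null(sizes)
    j_min = math.ceil((S + M) / 2)
    tail = sum(counts[j_min:])
    return tail / total


def jtk_mc_pvalue(S: int, zts, values, period: float = 24.0, lag: float = 0.0,
                  n_perm: int = 100_000, seed: int = 0) -> float:
    """Seeded Monte-Carlo permutation p for data with tied values.

    Returns (1 + #{S* >= S}) / (n_perm + 1), the standard add-one estimator.
    """
    zts = np.asarray(zts, float)
    values = np.asarray(values, float)
    ref = np.round(_reference(zts, period, lag), _REF_DECIMALS)
    r = _sign_matrix(ref)
    d = _sign_matrix(values)
    rng = np.random.default_rng(seed)
    n = values.size
    hits = 0
    batch = 2000
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        dp = d[perms[:, :, None], perms[:, None, :]]
        s_star = np.einsum("bij,ij->b", dp, r) / 2
        hits += int((s_star >= S).sum())
        done += b
    return (1 + hits) / (n_perm + 1)


# --------------------------------------------------------------------------
# Screening
# --------------------------------------------------------------------------

@dataclass
class JTKResult:
    feature_id: str
    period_hours: float
    lag_hours: float
    kendall_S: int
    tau: float
    p_value: float
    q_value: float = float("nan")
    amplitude_est: float = float("nan")
    method: str = "exact"  # "exact" | "mc" | "constant"
    p_min_lag: float = float("nan")  # best-lag p before the lag-grid correction


@dataclass
class RhythmScreen:
    group: str
    results: list[JTKResult]
    q_threshold: float

    @property
    def significant_ids(self) -> set[str]:
        return {r.feature_id for r in self.results if r.q_value < self.q_threshold}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature_id": r.feature_id,
                "period": r.period_hours,
                "lag": r.lag_hours,
                "tau": r.tau,
                "S": r.kendall_S,
                "p": r.p_value,
                "BHQ": r.q_value,
                "amplitude": r.amplitude_est,
                "method": r.method,
                "significant": r.q_value < self.q_threshold,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


@dataclass
class OverlapSummary:
    only_a: set[str]
    shared: set[str]
    only_b: set[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.only_a), len(self.shared), len(self.only_b))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m*p_(j)/j,
    capped at 1 and mapped back to input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([])
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def jtk_screen(matrix: TimeCourseMatrix, group: str, q_threshold: float = 0.2,
               lags=None, period: float = 24.0, n_perm: int = 100_000,
               seed: int = 0) -> RhythmScreen:
    """Screen every feature of one group for 24-h rhythmicity.

    Per feature: Kendall S/tau against the cosine reference at every lag on
    the sampling grid, exact DP p-value per lag (Monte-Carlo fallback when
    the data values themselves are tied), minimum p across lags (best lag
    recorded, smallest lag on ties) multiplied by the number of lags tested
    (Bonferroni over the candidate waveforms, capped at 1).  BH q-values
    across all features of the group; the significant set uses a strict
    ``q < q_threshold``.
    """
    meta = matrix.group_samples(group)
    zts = meta["zt"].to_numpy(float)
    vals = matrix.values[meta["sample_id"]].to_numpy(float)
    n = zts.size
    if lags is None:
        lags = sorted(set(zts))
    lags = list(lags)

    ref_signs = []
    tie_patterns = []
    n2_list = []
    for lag in lags:
        ref = np.round(_reference(zts, period, lag), _REF_DECIMALS)
        ref_signs.append(_sign_matrix(ref))
        tie_patterns.append(tuple(sorted(_tie_group_sizes(ref))))
        n2_list.append(_n_tied_pairs(ref))
    R = np.stack(ref_signs)  # (L, n, n)

    # survival lookups per distinct tie pattern
    sf_cache: dict[tuple[int, ...], tuple[np.ndarray, int]] = {}
    for pat in set(tie_patterns):
        counts, total = _jt_null(pat)
        c = np.asarray([float(x) for x in counts])
        sf = np.cumsum(c[::-1])[::-1] / float(total)  # P(J >= j)
        sf_cache[pat] = (sf, (n * n - sum(g * g for g in pat)) // 2)

    n0 = n * (n - 1) // 2
    results: list[JTKResult] = []
    X = vals
    D = np.sign(X[:, :, None] - X[:, None, :])  # (F, n, n)
    S_all = np.einsum("fij,lij->fl", D, R) / 2  # (F, L)

    # group-mean profiles for the descriptive amplitude estimate
    zt_order = sorted(set(zts))
    prof = np.stack([X[:, zts == t].mean(axis=1) for t in zt_order], axis=1)
    amp = (prof.max(axis=1) - prof.min(axis=1)) / 2

    for fi, fid in enumerate(matrix.feature_ids):
        x = X[fi]
        n1 = _n_tied_pairs(x)
        if n1 == n0:  # all-constant feature
            results.append(JTKResult(fid, period, lags[0], 0, 0.0, 1.0,
                                     amplitude_est=float(amp[fi]),
                                     method="constant", p_min_lag=1.0))
            continue
        best_p, best_lag, best_S, best_tau = np.inf, lags[0], 0, 0.0
        tied = n1 > 0
        for li, lag in enumerate(lags):
            S = int(round(S_all[fi, li]))
            if tied:
                p = jtk_mc_pvalue(S, zts, x, period, lag, n_perm=n_perm,
                                  seed=seed + 7919 * fi + li)
            else:
                sf, M = sf_cache[tie_patterns[li]]
                j_min = math.ceil((S + M) / 2)
                p = float(sf[j_min]) if j_min < sf.size else 0.0
            if p < best_p:
                denom = math.sqrt((n0 - n1) * (n0 - n2_list[li]))
                best_p, best_lag, best_S = p, lag, S
                best_tau = S / denom if denom else 0.0
        results.append(JTKResult(fid, period, best_lag, best_S, best_tau,
                                 min(len(lags) * best_p, 1.0),
                                 amplitude_est=float(amp[fi]),
                                 method="mc" if tied else "exact",
                                 p_min_lag=min(best_p, 1.0)))

    q = benjamini_hochberg([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return RhythmScreen(group=group, results=results, q_threshold=q_threshold)


def overlap_summary(screen_a: RhythmScreen, screen_b: RhythmScreen) -> OverlapSummary:
    """Venn partition of the two screens' significant sets."""
    ua = {r.feature_id for r in screen_a.results}
    ub = {r.feature_id for r in screen_b.results}
    if ua != ub:
        raise ValueError("screens cover different feature universes")
    a, b = screen_a.significant_ids, screen_b.significant_ids
    return OverlapSummary(only_a=a - b, shared=a & b, only_b=b - a)


def zscale_features(matrix: TimeCourseMatrix):
    """Per-feature unit-variance scaling and mean centering (population SD).

    Zero-variance rows map to all-zeros; returns (scaled matrix, flags)
    where flags marks the zero-variance features.
    """
    v = matrix.values.to_numpy(float)
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)  # population convention
    flags = pd.Series(sd[:, 0] == 0, index=matrix.values.index, name="zero_variance")
    safe = np.where(sd == 0, 1.0, sd)
    scaled = (v - mu) / safe
    scaled[flags.to_numpy(), :] = 0.0
    out = TimeCourseMatrix(
        values=pd.DataFrame(scaled, index=matrix.values.index,
                            columns=matrix.values.columns),
        sample_meta=matrix.sample_meta.copy(),
    )
    return out, flags
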