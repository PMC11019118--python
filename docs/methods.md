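# Methods

This note records the models implemented in `chronoscreen`, the conventions
the implementation pins where the field's software disagrees, what the
synthetic-data generators do and do not emulate, and the package's known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## JTK rhythm detection (`rhythms`)

**Model.** A feature is rhythmic if its values agree monotonically with a
24-h cosine reference at some phase. For observations $(t_i, x_i)$ and
reference $r_i(\varphi) = \cos(2\pi(t_i-\varphi)/24)$, Kendall's
$S(\varphi)$ counts concordant minus discordant pairs; replicates at the
same ZT receive tied reference values and pairs tied in either vector
contribute zero. `tau` is Kendall's tau-b (average-rank tie correction on
both vectors).

**Exact null.** With distinct data values, permuting data against a
reference whose tie groups have sizes $g_1,\dots,g_k$ makes $S$ a linear
function of the Jonckheere–Terpstra count $J$ ($S = 2J - M$, $M$ the number
of cross-group pairs). The null distribution of $J$ is the coefficient
sequence of the Gaussian multinomial, computed exactly by convolving
q-binomial coefficients in integer arithmetic (`_jt_null`); p-values are
one-sided tails $P(S^* \ge S)$. On the package's default design (six ZTs,
five replicates, tie groups 5/10/10/5) this is exact and fast, and is
verified against full 720-permutation enumeration at n = 6.

**Ties in the data.** The DP null assumes distinct values. Tied data fall
back to a seeded Monte-Carlo permutation p (default 100,000 permutations,
add-one estimator); the method used is recorded per feature. Continuous
peak-height data essentially never tie, so the fallback exists for
degenerate inputs (an all-constant feature is reported with p = 1, tau = 0
and a flag).

**Lag multiplicity.** The screen evaluates every lag on the sampling grid
(six lags at 4-h steps by default) and takes the best lag. The minimum of
six one-sided exact p-values is strongly anti-conservative: measured on
pure-noise matrices, $P(p_{\min} < 0.05) \approx 0.18$. Left uncorrected
this does not just inflate the per-feature error — once a screen contains
genuine rhythms, the BH step-up threshold moves right and the inflated null
p-values cascade into the significant set (measured FDR near 0.7 at a
nominal 0.2). The screen therefore multiplies the best-lag p by the number
of lags tested (Bonferroni over the candidate waveforms, capped at 1),
which restores BH's validity; the uncorrected best-lag p is kept on each
result as `p_min_lag` for users who want the raw convention. The lag grid
equals the sampling grid because, at this resolution, ranks of any
symmetric unimodal reference coincide with the cosine's.

**Scope.** Period search is fixed at 24 h: with six points over one cycle,
shorter periods are unidentifiable (configurable for denser designs).
Asymmetric alternative waveforms are not implemented; the symmetric cosine
is the only reference family. The amplitude estimate is half the range of
the group-mean profile — descriptive only.

**BH.** `benjamini_hochberg` is the direct step-up construction
$q_{(i)} = \min_{j\ge i} m\,p_{(j)}/j$, capped at 1. It is compared against
an independent implementation (statsmodels) in the tests, never backed by
it. Correction is applied within one group and omic layer at a time;
thresholding is strict (`q < threshold`), with 0.2 the default for
metabolite-style layers and 0.05 for lipid-style layers.

## OPLS time-of-day modeling (`multivariate`)

**Preprocessing.** Per-group samples ordered by (ZT, replicate); features
unit-variance scaled and mean centered (sample SD, ddof = 1); zero-variance
features dropped with a warning; optional log1p transform (default off,
since which variables "need" transforming is data-dependent). The response
is the ZT hour as a single numeric y by default — mirroring the standard
chemometrics workflow — with a circular (sin, cos) encoding available
because ZT is periodic and a linear y cannot distinguish ZT 0 from ZT 24;
the verdict logic uses the numeric encoding.

**Model.** Single-response orthogonal projections: $w \propto X^\top y$
(invariant under the orthogonal deflations), each orthogonal component
$w_o \propto p - (w^\top p)w$ with $t_o = Xw_o$ and deflation
$X \leftarrow X - t_o p_o^\top$, then the predictive component on the
deflated X. With zero orthogonal components the predictions are exactly
one-component PLS1, an identity the tests assert at 1e-8. R²X partitions
into predictive + orthogonal + residual fractions summing to 1.

**Cross-validation.** Deterministic venetian blinds (sample i → fold
i mod 7) so reports are reproducible; scaling is re-estimated inside every
training fold (leakage is checked by the shuffled-y property: training R²Y
stays high while Q² collapses). For each component count a = 0..n_ortho,
$\mathrm{PRESS}_a = \sum_i (y_i - \hat y_{(-\mathrm{fold}(i))})^2$ and
$\mathrm{SS}_a = \sum_i (y_i - \bar y_{\mathrm{train}(-\mathrm{fold}(i))})^2$;
$Q^2_{\mathrm{cum}} = 1 - \prod_a \mathrm{PRESS}_a/\mathrm{SS}_a$.

**CV-ANOVA.** Conventions differ across software, so this one is pinned:
with N samples and $k = 1 + n_{\mathrm{ortho}}$ fitted components,
$F = ((\mathrm{SS}_y - \mathrm{PRESS})/k)\,/\,(\mathrm{PRESS}/(N-1-k))$ on
$(k,\,N-1-k)$ degrees of freedom, using the final model's PRESS;
PRESS ≥ SS_y reports F = 0, p = 1 (no model). The p-value is validated
against numerical quadrature of the F density.

**Model growth.** `model_significance` adds orthogonal components while
Q²(cum) improves by more than 0.01, capped at `max_ortho` (default 3), then
declares the model significant iff CV-ANOVA p < alpha (default 0.05). The
0.01 step is the smallest improvement worth a component at these sample
sizes; it is a package choice, configurable.

## Behavioral analysis (`behavior`)

**DAM2 parsing.** 42 tab-separated fields per line: record index, date,
time, monitor status, six reserved fields, 32 channel counts. Non-OK status
rows are flagged and excluded; minute gaps are reported. Multibeam data are
outside scope — counts are treated as single-beam equivalents.

**Artifact filter.** Pooled non-zero per-minute counts across all flies of
the experiment define the threshold mean + 6·SD; minutes at or above it are
replaced by the mean of the adjacent minutes' counts. Edge cases the rule
does not specify are pinned as: an outlier at the first/last minute takes
its single existing neighbor; runs of consecutive outliers take the nearest
non-outlier value on each side. Replacements stay real-valued (no
re-rounding) and are logged. Statistics are pooled per experiment, which is
also the natural unit for the global option.

**Sleep.** Any maximal run of ≥ 5 consecutive zero-count minutes is sleep
in its entirety (the standard 5-minute definition); sleep is a pure
function of the zero/non-zero pattern. Summaries use full days only,
aligned to lights-on, skipping a partial leading day; LD experiments
conventionally use the first four full days and DD circadian runs five.
Day/night in DD is subjective time carried forward from entrainment.
Waking activity is total counts per waking minute (undefined on an all-
sleep day, reported as missing); sleep + wake = 1440 min/day is asserted.
Flies with zero counts over the final 24 h are excluded as dead — standard
field practice.

**FFT.** The mean-subtracted minute series is Fourier transformed; power is
normalized to the total over positive-frequency bins (a pinned convention —
periodogram software differs). Reported: normalized power at the bin
nearest 24 h and the peak period in the 18–30 h band; rhythmic iff the
24-h power reaches 0.01 (configurable; at 5 days of white noise each bin
carries ~3e-4, so 0.01 is a comfortable margin).

**Statistics harness.** Shapiro–Wilk at alpha 0.05 per group gates the test
family: all normal → t-test (Welch optional) or one-way ANOVA with Tukey;
otherwise Mann–Whitney or Kruskal–Wallis with Dunn's rank-based post hoc
(implemented here with tie-corrected rank variances and Bonferroni
adjustment). Timepoint panels use all pairwise comparisons with Bonferroni.
A zero-variance group forces the nonparametric path with a warning. The
two-control rule reports a phenotype only when the experimental group
differs from both controls at adjusted p < 0.05.

## Imaging quantification (`imaging`)

CaLexA signal per cell is (GFP/background)/(RFP/background), both
backgrounds from the cell's slice; per-brain summaries average cells of one
class, and l-LNv/s-LNv are never pooled. Hand-drawn ROI segmentation is
human work and out of scope — the module starts at intensity tables.

roGFP masking uses per-slice Otsu thresholds on the 488 channel plus an
upper intensity cap (default 250 of 255) that excludes saturating
trachea-like structures; the macro this emulates is unpublished, so the
threshold rule is a declared default, switchable, with threshold provenance
returned. The brain ratio is mean(405)/mean(488) within the mask, and
per-run normalization divides by the mean raw ratio of that run's control
brains pooled across timepoints (runs never mix); normalized control means
are exactly 1 by construction.

## Synthetic data (`synth`)

**Omics.** value(f, sample at ZT t) = baseline_f · (1 + a_f·cos(2π(t −
φ_f)/24)) · ε with ε lognormal of unit mean and configured CV; baselines are
lognormal around a peak-height-like scale (default 1000). The default
design is six ZTs at 4-h spacing — the standard six-timepoint circadian
collection — with 5 (young-like) or 4 (old-like) replicates. The young-like
preset plants 17 rhythmic features of 159 at relative amplitude 0.5, noise
CV 0.1, phases coherently spread over the first third of the day. The
old-like preset plants a distinct 17-feature set sharing 4 features with
the young set, amplitude damped to 0.2, noise CV 0.3, discordant phases,
plus a per-sample lognormal factor (CV 0.25) shared across features — the
pooled-collection variability that leaves individual rhythms present but
destroys the sample-level time-of-day signal, so that an OPLS model can be
built for young-like but not old-like data. Under these old-like conditions
the JTK screen typically recovers few or none of the damped rhythms at
BHQ < 0.2; the asymmetry of model-buildability, not the old-group rhythm
count, is what these conditions are designed to probe.

**Activity.** Wake/sleep is a two-state Markov chain whose stationary wake
probability equals the configured day/night activity probability and whose
mean sleep-episode length is `sleep_bout_mean_min`; wake minutes carry
Poisson(counts_rate) counts. This is the minimal model that honors both the
activity-probability and bout-length parameters while producing realistic
zero-runs. Spike artifacts are injected as isolated minutes at
`artifact_magnitude × counts_rate` (default 50 × 2), far above the 6·SD
threshold of the pooled non-zero distribution; their positions are returned
as ground truth.

**Imaging.** ROI tables draw background and signal factors lognormally
around the configured true GFP/RFP ratio; roGFP stacks place clustered
foreground blobs (488 ≈ 180, 405 = ratio × 488) over dim noisy background,
plus a saturating corner blob emulating trachea, with the foreground mask
returned as ground truth. All stacks are 8-bit.

**What passing tests do not show.** The generators emulate the statistical
structure the analysis stages assume — they are not fly physiology. Real
peak-height data have correlated features, batch effects, and missingness;
real activity has bout-length heavy tails, arousal dynamics, and
entrainment transients; real stacks have depth-dependent attenuation and
segmentation ambiguity. Passing the simulation suite shows the algorithms
implement their contracts and recover known structure at realistic
noise — not that any biological conclusion transfers.

## Problem sizes and determinism

Simulation-based checks use 20 seeds per scenario at the full study scale
(159 features × 30 or 24 samples) for omics, 16 flies × 3–5 days for
activity, and 3 stacks of 6×64×64 voxels for imaging — sizes at which every
quantity in `scripts/acceptance.py` is stable to well within its margin
while the whole script runs in seconds. All randomness flows from explicit
seeds through `numpy.random.default_rng`; pipeline outputs format floats to
9 significant digits so SHA-256 manifests reproduce across platforms.

## Known limitations

- The exact null applies to tie-free data; heavily discretized data fall to
  Monte-Carlo p-values with resolution 1/(n_perm + 1).
- The lag-grid Bonferroni is conservative for correlated reference
  waveforms; power at small amplitudes is correspondingly reduced.
- CV-ANOVA degrees of freedom are one convention among several; absolute
  p-values from other software will differ slightly.
- The numeric-ZT response cannot represent the circular topology of time;
  the (sin, cos) encoding is provided but the significance logic currently
  uses the numeric path.
- FFT rhythmicity uses a fixed normalization and threshold rather than a
  significance test; it is a screening heuristic, not an inference.
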