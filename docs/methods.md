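# Methods

## The estimator

For a voltage series V(t) sampled at rate fs, time interval Δt (seconds)
and lag L = round(Δt · fs), the per-instant information-transfer constant
is

    κ(t; Δt) = ln |V(t + Δt) − V(t)| / ln Δt,

evaluated at every candidate instant t = 1 … n − L. Instants with
V(t + Δt) = V(t) are excluded and counted in `n_excluded`; recordings are
integer-quantized, so exact ties are genuine and no epsilon tolerance is
applied. The segment summary `kappa_avg` is the arithmetic mean over the
*retained* values: dividing by the candidate count instead would treat
every excluded instant as an implicit κ = 0 and drag the mean toward
zero, so the exclusion count is reported separately rather than folded
into the denominator.

Two conventions matter and are fixed as follows:

- **Δt is in seconds** in the logarithm's argument; the lag is in
  samples. This makes κ_avg flip sign at Δt > 1 s for sub-unit voltage
  amplitudes (ln Δt > 0, ln |ΔV| < 0), a regime the default 4 s scale
  deliberately exercises. Δt = 1 s is rejected outright (ln Δt = 0).
- **Units are preserved, never rescaled.** κ is the log of a dimensional
  quantity, so rescaling voltages by a shifts every κ by ln a / ln Δt
  (an exact identity, tested as such). All outputs carry the unit label;
  cross-dataset comparisons require matched units.

Non-integer fs·Δt is rejected beyond a 10⁻⁶ relative rounding error
unless lag rounding is explicitly allowed, so a reported Δt always means
what it says.

Closed-form anchors used throughout testing: for Gaussian increments
ΔV ~ N(0, s²), E[κ] = (ln s + E ln|Z|)/ln Δt with
E ln|Z| = −(γ + ln 2)/2 ≈ −0.635181; for fBm with
Var[ΔV] = σ²Δt^{2H} this becomes E[κ] = H + (ln σ + E ln|Z|)/ln Δt, and
regressing κ_avg·ln Δt on ln Δt across scales recovers H in the slope
(`hurst_regression`).

## Density and periodicity of the κ sample

The κ values of a segment are summarized by a Gaussian-kernel density on
512 evenly spaced points spanning the data ± 3 bandwidths, with the
rule-of-thumb bandwidth 0.9·min(SD, IQR/1.34)·n^{−1/5} (SD fallback when
the IQR is zero). These defaults reproduce R's `density()` with
`bw="nrd0"`, n = 512, cut = 3, and the test suite cross-checks the full
curve against Rscript when R is available (agreement to ~10⁻³; R
evaluates by binned FFT convolution). Fewer than 10 finite values or
zero spread is a degenerate-data error, not a NaN.

Periodicity of the density is quantified by the classical
variance-normalized Lomb–Scargle periodogram with the κ grid as abscissa
and the mean-subtracted density as signal: frequencies from
1/(span·oversample) to hifac·n_grid/(2·span) in steps of
1/(span·oversample) (oversample 4, hifac 1), power divided by the sample
variance (ddof = 1) of the centered density so that Gaussian white noise
gives asymptotically Exp(1) powers (verified by simulation). The
false-alarm threshold at significance p solves p = 1 − (1 − e^{−z})^M
with M = 2·n_grid independent frequencies — a deliberately generous
count — and `significant_power` is the sum of power at or above z
(boundary inclusive). For n_grid = 512 and p = 0.01, z ≈ 11.5316.

**Interpretation caveat.** The statistic measures *structured shape*,
not only comb periodicity: any peaked density — including the smooth
bump of a unimodal κ sample — concentrates variance-normalized power of
order 10²–10³ at low frequencies, far above z. Significant power is
therefore essentially always positive, and the scientifically meaningful
quantity is its *magnitude contrast* between states (comb structure adds
power near 1/spacing on top of the envelope's contribution), not the
exceedance event itself. The comb-detection guarantee tested is
correspondingly local: a significant peak within one frequency step of
the reciprocal comb spacing. A threshold-crossing indicator should not
be read as a calibrated 1% test on these densities; KDE smoothing also
correlates neighboring grid points, further inflating low-frequency
power.

Sum versus area: the significant "power" is the plain sum of normalized
power over significant frequencies; integrating over frequency instead
would only rescale it by the constant grid step and change no contrast.

## Group comparisons

Per-segment metrics (κ_avg, low-IT fraction, significant power) are
stacked into a long table keyed by (subject, state, segment, Δt,
metric). A pair of states is compared by a two-way fixed-effects
decomposition on segment-level values — y ~ state + subject with
sequential Type-I sums of squares, state entered first — giving
F = MS_state/MS_error on (1, N − 1 − 1 − (n_subjects − 1)) degrees of
freedom. The fit itself is delegated to statsmodels (`ols` +
`anova_lm(typ=1)`); an independently hand-coded projection oracle in the
test suite reproduces F and p to 10⁻¹⁰ relative on random tables.
Subjects present in only one state are retained (the sequential SS is
well defined on the observed cells) and logged prominently. Degenerate
tables (a missing state, fewer than two shared subjects, zero residual
df) raise errors rather than returning NaN; an exactly null contrast is
reported as F = 0, p = 1.

The Bonferroni family defaults to the four time scales of one
(state pair, metric) cell, m = 4, overridable. Mixed models with
unstructured covariance are intentionally out of scope: the cohort TSV
is a clean long-format export for external statistics environments.

## Synthetic data

The generators emulate the target recording conditions — 250 Hz
single-channel segments of one minute, grouped by subject and state —
not EEG physiology. Signal families and their roles:

- `ramp`, `alternating`, `powerlaw_increment`: machine-precision oracles
  (κ ≡ 1; κ ≡ ln a/ln Δt; κ ≡ κ₀ + ln c/ln Δt at the declared lag, the
  last built as a square wave of period twice the lag so the increment
  magnitude is exactly c·Δt^{κ₀} at every instant).
- `white_noise`, `fbm`: stochastic surrogates with closed-form E[κ]. fBm
  uses exact circulant embedding (Davies–Harte) of the fractional
  Gaussian noise covariance, so increment variances are exact at every
  lag and the Hurst-recovery tests are sharp. Amplitudes default to
  mV-like σ = 0.1 so the 4 s scale drives κ negative.
- `sinusoid_mix`: deterministic narrowband content with seeded phases.

Cohorts perturb one template parameter per subject (H for fbm, σ
otherwise) with a N(0, sd) offset shared across that subject's states —
a repeated-measures structure with an analytically known effect size —
clipped to H ∈ (0.05, 0.95) with a warning if clipping touches more than
10% of subject/state cells. The truth table records every realized
parameter, so expected κ_avg is recomputable per segment. All
randomness flows from `numpy.random.SeedSequence` spawning; identical
specs are bit-identical.

What the synthetic conditions do **not** model: movement and muscle
artifacts, apnea-disordered epochs, electrode/reference heterogeneity,
nonstationarity within a segment, and the comb fine structure of real κ
densities. Passing tests demonstrate estimator and pipeline correctness
under known ground truth, not clinical discriminative performance.

## File handling

EDF/EDF+ reading and minimal fixture writing are implemented directly
(ASCII header, int16 records, linear physical scaling) so channel unit
labels survive round trips verbatim; the reader is cross-checked against
mne's EDF reader in the tests. The CSV dialect (`time_s,voltage`)
requires a uniform time base to 1 part in 10⁴ and infers fs from the
median step. Stage annotations are half-open, non-overlapping
`[start, end)` intervals; epochs tile each interval from its start and
partial epochs are dropped. CLI outputs print floats at 6 significant
digits with fixed row order, and each output carries a provenance JSON
sidecar (config echo, version, seed), so identical configs give
byte-identical files.

## Problem sizes in the verification scripts

Simulation-based checks use: 10 one-minute fBm segments for Hurst
recovery; 50–60 comb samples (5 teeth × 400 draws) and 200 white-noise
samples (n = 2000) for periodogram calibration; 100 random small tables
plus 500 within-subject permutations for the ANOVA oracle; and cohorts
of 10 subjects × 8 segments × 2 states × 60 s for end-to-end
discrimination (100 runs each for contrast and null in the test suite,
30 each in `scripts/acceptance.py`). These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances.

## Known limitations

- κ's unit dependence means absolute κ_avg values are comparable only
  within one unit convention; contrasts between states are the robust
  quantity.
- The ANOVA treats segments as independent replicates within
  subject/state; temporally adjacent clinical epochs violate this, so
  printed p-values on real data are anti-conservative to an unknown
  degree.
- The significance-thresholded periodogram power is a shape statistic,
  not a calibrated periodicity test (see the caveat above).
- WFDB-native input and automated artifact rejection are not
  implemented; convert to EDF/CSV and pre-select epochs upstream.
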