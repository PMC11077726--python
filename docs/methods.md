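# Methods

This note documents the models, conventions and numerical choices behind
`gapassr`: what the synthetic cohorts emulate, how each analysis stage is
defined, and where the design was genuinely open.

## Stimulus model

A gap-ASSR session alternates 250 ms segments of noise and
gap-interrupted noise. Gaps recur at 25 ms spacing (40 Hz); each gapped
segment carries one parametric pair, gap width ∈ {2,4,6,8,10,12} ms ×
modulation depth ∈ {75,100} %, drawn uniformly at random per segment from a
seeded generator. The session is extended until every pair has at least the
requested trial count (default 101, so every pair exceeds 100 trials).

Conventions where the protocol under-specifies the waveform:

* **Gap placement.** The first gap onset sits 25 ms after segment start and
  onsets repeat every 25 ms. Nine gaps fit strictly inside a 250 ms segment
  under this rule (onsets 25…225 ms); a tenth onset would coincide with the
  segment boundary and contain no in-segment samples, so nine are used.
  The 40 Hz rate and 25 ms spacing are preserved exactly.
* **Gap edges** are rectangular; the modulation depth acts as a pure
  amplitude scale (100 % → bit-exact zeros, 75 % → in-gap samples × 0.25).
  "Gap width" counts the full reduced-amplitude interval.
* **Noise tokens** are independent draws per segment (whether noise-only
  segments share a token with the adjacent gapped segment is unspecified;
  independent was chosen).
* **Level.** Waveforms are peak-normalized and unitless; the nominal
  75 dB SPL is metadata only — no acoustic calibration is in scope.
* **Audio synthesis rate** defaults to 48 kHz (the 6–12 kHz band fits);
  event schedules are independent of the audio rate.

The ERP protocol is fixed by its published constants: 120 repetitions of a
6–12 kHz narrowband noise burst, 100 ms long with 5 ms cosine-squared
ramps, at 0.25 Hz.

## Synthetic EEG generator

Each channel (AC, FC) of a simulated recording is the sum of

1. **1/f^α background noise** (spectral shaping of white Gaussian noise,
   α = 1.0 default, RMS 15 µV default — typical of awake rodent epidural
   EEG at these bandwidths);
2. **ERP components**: polarity-signed Gaussian-windowed deflections
   (P1 +, ~25 ms, σ 8 ms; N1 −, ~64 ms, σ 14 ms; P2 +, ~150 ms, σ 30 ms),
   added at every burst onset with multiplicative log-normal per-trial
   amplitude jitter (sd of log = 0.2 default; latency jitter off by
   default). Components are truncated at ±4 widths and quantized to the
   sample grid;
3. **40 Hz ASSR bursts**: one cosine burst per gapped segment spanning the
   segment, amplitude 8 µV default, with a common per-segment phase offset
   drawn von Mises(0, κ(pair)). Jitter therefore operates at the segment
   (= trial) level, matching the ITPC trial definition.

The von Mises concentration κ is the generator's single knob for temporal
reliability: the population mean resultant length of the burst phases is
R(κ) = I₁(κ)/I₀(κ) (`kappa_to_expected_itpc`), which the analysis chain
must recover. R(0)=0, R is strictly increasing, R→1 as κ→∞.

**Cohort presets** (`cohort_presets`) are a *qualitative emulation*: they
encode only the direction of the group effects under study, not measured
values. κ(pair) = κ_top · (gap/12)^0.7 · depth-factor · age-factor, with
AC κ identical across genotype and sex, FC κ reduced ×0.3 in knock-out
females at p21 and in knock-out males at p21 (×0.3) and p30 (×0.5)
(slower male maturation), and WT sexes identical. ERP amplitudes grow
faster with age in knock-outs, with the largest KO−WT gap at p60 and a
1.25× N1/P2 boost in adult KO females relative to KO males. Per-trial
response variability in real data is unreported; the jitter default is a
convention.

Default cell sizes follow the recorded female cohorts — WT (11, 9, 8) and
KO (8, 9, 8) at p21/p30/p60; the male companion cohorts' ns are not
restated in this protocol, so (10, 9, 8) per genotype is used as a
configurable convention. Sub-seeds are spawned per subject from the master
seed (`numpy.random.SeedSequence`), so cohorts are reproducible and
subjects independent.

The native simulation rate defaults to 4096 Hz rather than the acquisition
hardware's 24.414 kHz: every analyzed band lies far below either Nyquist
rate, and 4096 Hz still exercises the down-sampling path to 1024 Hz.

**What the generator does not emulate:** volume conduction and shared
noise between channels, non-stationary arousal states, movement artifacts,
line noise, electrode drift, evoked *power* changes (only phase is
modeled for the ASSR), and any biophysics of the underlying circuits.
Passing tests therefore demonstrate correctness of the analysis chain and
recoverability of effects of the modeled kind — not robustness to every
artifact structure of real recordings (artifact screening is exercised
with injected spikes/flatlines instead).

## Preprocessing

* **Down-sampling** to 1024 Hz uses a zero-phase (forward–backward)
  8th-order Butterworth low-pass at 0.4 × target rate before decimation,
  so 40 Hz phase estimates cannot be biased by filter delay. TTL times are
  kept in seconds and re-quantized to the output grid at epoching.
* **Epoching** cuts one row per TTL event fully inside the recording;
  out-of-bounds events are dropped and counted. ERP window: −250…+750 ms
  (the post-stimulus extent is a convention — it covers P2 at all ages —
  and is recorded in output metadata). ASSR window: −100…+350 ms around
  gapped-segment onset, i.e. the 250 ms segment plus 100 ms context per
  side for wavelet edge handling.
* **Baseline correction** subtracts the per-trial mean of the 250 ms
  pre-onset window; **detrending** then removes the per-trial least-squares
  line over the full epoch (order matches the stated procedure). Both are
  idempotent/linear and tested as such.
* **Artifact screening** flags (never deletes) trials exceeding an
  amplitude bound (default 2000 µV) or containing flatline runs (default
  300 ms); defaults are permissive so clean synthetic data yields zero
  flags, mirroring a protocol in which no data were rejected. Flagged
  trials are excluded from averages only in strict mode.

## Time–frequency analysis and ITPC

Complex Morlet wavelets are unit-energy, truncated at ±3 temporal sigmas.
The "dynamic" cycle rule grows linearly from 3 cycles at 10 Hz to 8 cycles
at 100 Hz (config-exposed; the exact published rule is not stated). The
frequency grid is 31 log-spaced points over 10–100 Hz with the nearest
point snapped to exactly 40 Hz. Convolution is FFT-based per frequency;
samples within max(wavelet half-support, 100 ms edge pad) of either epoch
edge are flagged invalid and excluded from summaries. An epoch shorter
than the longest wavelet support is an error.

ITPC is the modulus of the mean unit phase vector across trials, computed
from phase angles or complex coefficients (amplitude is discarded first,
so ITPC is amplitude-invariant by construction). The per-pair summary
averages the 40 Hz row over 50–250 ms after segment onset — excluding the
onset transient and wavelet edges; whether the original analysis averaged
a window or the whole segment is unstated, and the window is recorded in
outputs. Under uniform phases the sample ITPC is biased upward,
E[ITPC] ≈ √π/(2√N); the bias level is reported alongside N but not
subtracted (an optional Rayleigh-based correction,
√(max(NR²−1,0)/(N−1)), is available and off by default). Noise-only
segments are generated but unused by default.

## Statistics

All sums of squares are Type III, computed by general-linear-hypothesis
tests under sum-to-zero coding on the full factorial design — appropriate
for the unbalanced cell sizes (8–11). Degenerate inputs follow documented
sentinels: zero residual variance yields F = ∞, p = 0 (or F = 0, p = 1
when the effect SS is also zero).

The repeated-measures ANOVA is the classical split-plot decomposition:
between-subject effects are tested on subject means against the
subjects-within-cells stratum; the within factor (gap duration) and its
interactions are tested on orthonormal (Helmert) contrast scores against
the within-subject residual. Mauchly's W and the Greenhouse–Geisser ε̂ are
computed from the pooled within-cell covariance of the within-level
responses (the SPSS/split-plot convention; pingouin's mixed-design variant
uses the grand covariance, which is why the suite cross-checks W exactly
only in the no-between case). ε̂ is clipped to its theoretical range
[1/(k−1), 1]. By default the GG correction multiplies the within dfs only
when Mauchly rejects at 0.05 ("correct if necessary"); an always/never
policy is config-exposed. One ε̂ implementation serves both the two- and
three-factor variants — the source material's distinction between the two
correction descriptions is not operationally defined, and the ε̂ formula
is common to both.

Post hocs: Bonferroni min(1, m·p); Sidak 1−(1−p)^m; Tukey HSD via the
studentized range with the Tukey–Kramer standard error (pairwise
harmonic-mean cell size), appropriate for unbalanced cells. The analysis
grid applies Tukey/Bonferroni to ERP measures and Sidak to gap-ASSR
contrasts (overridable). Genotype-at-age and sex-at-age contrasts are
computed on gap-collapsed subject means with the error variance pooled
within cells, adjusted across the three ages of a family. Residual
diagnostics report Shapiro–Wilk, bias-corrected sample skewness and excess
kurtosis (the ±2 screening rule applies to excess kurtosis), and QQ
points.

Type-I calibration of both ANOVA variants is verified by simulation (2000
null replicates each, acceptance band 4–6 % at α = 0.05).

## Pipeline

`run_all` executes simulate → preprocess → erp → itpc → stats → figures.
Each stage writes its outputs plus a marker containing the configuration
hash; re-running skips clean stages, and outputs are pure functions of
(config, seed) — tables are byte-identical across re-runs in fresh
directories. The run manifest lists every output with a sha256 hash.
Figures reproduce the panel layouts of the study's result graphics
(ITPC heat maps, ITPC-vs-gap curves by age and depth, gap-collapsed bars,
grand-average ERPs) without claiming numeric equivalence. Recordings and
epochs are stored in a documented HDF5 layout; schedules export to JSON,
tab-separated event tables and WAV.

## Problem sizes used in verification

Monte Carlo checks run at reduced but statistically adequate scale, chosen
so the whole suite runs on a laptop-class single core: von Mises recovery
at N = 200 trials with 3·SE bands from 200-replicate Monte Carlo; null
calibrations at 2000 replicates; and the cohort-level directional checks
at 25 trials per parametric pair (vs >100 in a full session), protocol
cell sizes, 1024 Hz native simulation, a 40 Hz-only wavelet grid, and 20
cohort seeds. The encoded FC deficit is large enough that detection power
is essentially 1 at this scale, while null contrasts (AC genotype, WT sex)
stay at their familywise error level.

## Known limitations

* One within-subject factor per repeated-measures model (gap duration);
  modulation depth and region are analyzed separately, as in the source
  analysis grid, not as additional within factors.
* ITPC is the only phase metric; no evoked/total power, cross-frequency
  coupling or connectivity measures.
* The generator's κ → ITPC mapping ignores background-noise attenuation:
  with noise on, measured ITPC is biased toward the small-sample floor, so
  recovery tests against I₁(κ)/I₀(κ) use noise-free traces, and cohort
  tests assert directions, not absolute levels.
* EDF export is not provided; recordings use an HDF5 layout (and WAV for
  stimuli) instead.
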