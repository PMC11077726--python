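# gapassr

Analysis pipeline for auditory temporal processing and cortical
hypersensitivity in mouse EEG: the **40 Hz gap-in-noise auditory
steady-state response (gap-ASSR)** quantified by **inter-trial phase
clustering (ITPC)**, and **auditory event-related potentials (ERPs)** with
P1/N1/P2 peak extraction — plus the repeated-measures statistical battery
used to compare genotype (wild-type vs *Fmr1* knock-out, a Fragile X
Syndrome model) × sex × age cohorts.

Because no public recordings exist for this paradigm, the package ships a
first-class synthetic-EEG generator that emulates two-channel epidural
recordings from auditory cortex (AC) and frontal cortex (FC), with
configurable cohort presets. The generator doubles as the ground truth for
verifying every stage of the analysis.

## The measurements

**Gap-ASSR.** The stimulus alternates 250 ms segments of noise and
gap-interrupted noise; gaps recur every 25 ms (40 Hz). Each gapped segment
carries one *parametric pair* — gap width ∈ {2, 4, 6, 8, 10, 12} ms ×
modulation depth ∈ {75, 100} % — and sessions continue until every pair has
>100 trials. Phase locking to the 40 Hz gap train is summarized by ITPC at
each time–frequency point of a dynamic complex Morlet wavelet transform:

    ITPC(t, f) = | (1/N) Σₖ exp(i φₖ(t, f)) |,  k = 1..N trials

which is 0 for uniformly random phases and 1 when every trial has the same
phase. The per-condition summary is the 40 Hz ITPC averaged over the
50–250 ms response window.

**ERP.** Narrowband noise bursts (6–12 kHz, 100 ms, 5 ms ramps, 0.25 Hz,
120 repetitions) are epoched on TTL pulses, baseline-corrected against the
250 ms pre-stimulus window, detrended and averaged; P1/N1/P2 amplitudes
(baseline-to-peak, µV) and latencies (ms) are read from configurable search
windows.

**Statistics.** Type III factorial ANOVA (genotype × age, sex × age) for
ERP measures with Tukey/Bonferroni post hocs; split-plot repeated-measures
ANOVA (between factors × gap duration within) for ITPC with Mauchly's
sphericity test, Greenhouse–Geisser correction and Sidak-adjusted
contrasts; Shapiro–Wilk and skewness/kurtosis (±2 rule) residual
diagnostics. The machinery is implemented in plain linear algebra and
cross-checked against statsmodels and pingouin in the test suite.

**Generator.** Each channel is 1/f background noise plus Gaussian-windowed
ERP components and one 40 Hz burst per gapped segment whose phase is drawn
von Mises(0, κ). κ is set per parametric pair, so the expected ITPC has the
closed form I₁(κ)/I₀(κ) — the oracle used throughout the tests.

## Worked example

```python
import numpy as np
from gapassr import synth, preprocess, itpc

from gapassr.stimulus import ParametricPair, make_gap_assr_session

# one wild-type adult, a short gap-ASSR session, noise-free for clarity
pair = ParametricPair(12.0, 100.0)
model = synth.ChannelModel(assr_kappa={pair: 2.0}, noise_rms_uv=0.0)
params = synth.NeuralModelParams({"AC": model, "FC": model})
sched = make_gap_assr_session(200, 1024.0, seed=5, pairs=(pair,))
rec = synth.simulate_recording(
    synth.SubjectSpec("demo", "WT", "F", "p60"), sched, params,
    seed=6, sample_rate_hz=1024.0)

ep = preprocess.extract_epochs(rec, window_ms=(-100, 350)).select(pair.label)
summary, _ = itpc.itpc_by_pair(
    ep, "FC", itpc.MorletParams(freqs_hz=np.array([40.0])), min_trials_warn=0)
print(f"measured ITPC {summary[pair]:.3f}  "
      f"expected I1(2)/I0(2) = {synth.kappa_to_expected_itpc(2.0):.3f}")
```

prints

```
measured ITPC 0.688  expected I1(2)/I0(2) = 0.698
```

i.e. the analysis chain recovers the generator's phase-clustering level
(κ = 2 → mean resultant length 0.698) from 200 simulated trials to within
sampling error.

The full pipeline — cohort simulation, preprocessing, ERP and ITPC tables,
the statistics report and the figure set — runs from the CLI:

```bash
gapassr run-all --seed 7 --out runs/demo
```

and writes `erp_table.csv`, `itpc_table.csv`, `stats_report.json`, figures
and a hashed `run_manifest.json` under `runs/demo/`.

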