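"""Synthetic two-channel (AC, FC) mouse EEG with controllable phase locking.

The generator is a *qualitative emulation* of awake epidural recordings from
auditory cortex (AC) and frontal cortex (FC): 1/f background noise, plus

* stimulus-locked ERP components — polarity-signed Gaussian-windowed
  deflections (P1, N1, P2) added at every ERP-burst onset, with
  multiplicative log-normal per-trial amplitude jitter, and
* one 40 Hz oscillatory burst per gapped segment, whose per-segment phase
  offset is drawn von Mises(mu=0, kappa).  kappa is set per parametric pair,
  so the expected inter-trial phase clustering of a condition is the von
  Mises mean resultant length R(kappa) = I1(kappa)/I0(kappa).

Cohort presets encode only the *direction* of the group effects under
study (FC phase-locking deficit in young knock-outs, age-growing ERP
hypersensitivity); they are conventions, not measured values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import special

from .stimulus import (
    ASSR_RATE_HZ,
    SEGMENT_MS,
    ErpProtocol,
    InvalidParameterError,
    ParametricPair,
    StimulusSchedule,
    default_pairs,
    make_erp_session,
    make_gap_assr_session,
)

__all__ = [
    "GENOTYPES",
    "SEXES",
    "AGE_GROUPS",
    "SubjectSpec",
    "ErpComponent",
    "ChannelModel",
    "NeuralModelParams",
    "Recording",
    "SubjectData",
    "ConfigurationError",
    "simulate_recording",
    "kappa_to_expected_itpc",
    "cohort_presets",
    "default_female_design",
    "default_male_design",
    "simulate_cohort",
    "write_cohort_manifest",
]

GENOTYPES = ("WT", "KO")
SEXES = ("M", "F")
AGE_GROUPS = ("p21", "p30", "p60")
CHANNELS = ("AC", "FC")

DEFAULT_SIM_RATE_HZ = 4096.0


class ConfigurationError(ValueError):
    """Generator parameters do not cover the requested schedule."""


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    genotype: str
    sex: str
    age_group: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise InvalidParameterError(f"genotype must be one of {GENOTYPES}")
        if self.sex not in SEXES:
            raise InvalidParameterError(f"sex must be one of {SEXES}")
        if self.age_group not in AGE_GROUPS:
            raise InvalidParameterError(f"age_group must be one of {AGE_GROUPS}")

    @property
    def cell(self) -> tuple[str, str, str]:
        return (self.genotype, self.sex, self.age_group)


@dataclass(frozen=True)
class ErpComponent:
    """One Gaussian-windowed monophasic deflection of the evoked response."""

    name: str  # P1 | N1 | P2
    polarity: int  # +1 | -1
    latency_ms: float
    amplitude_uv: float
    width_ms: float
    trial_jitter_sd: float = 0.2  # sd of log amplitude, multiplicative

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise InvalidParameterError("polarity must be +1 or -1")
        if self.name in ("P1", "P2") and self.polarity != 1:
            raise InvalidParameterError(f"{self.name} must have positive polarity")
        if self.name == "N1" and self.polarity != -1:
            raise InvalidParameterError("N1 must have negative polarity")
        if self.width_ms <= 0 or self.amplitude_uv < 0:
            raise InvalidParameterError("width must be > 0 and amplitude >= 0")


@dataclass
class ChannelModel:
    erp_components: list[ErpComponent] = field(default_factory=list)
    assr_kappa: dict[ParametricPair, float] = field(default_factory=dict)
    assr_amplitude_uv: float = 8.0
    noise_exponent: float = 1.0  # 1/f^alpha spectral slope
    noise_rms_uv: float = 15.0

    def __post_init__(self) -> None:
        for kappa in self.assr_kappa.values():
            if not kappa >= 0:
                raise InvalidParameterError("kappa must be >= 0")


@dataclass
class NeuralModelParams:
    channels: dict[str, ChannelModel]


@dataclass
class Recording:
    """Two-channel EEG trace with TTL event annotations (times in seconds)."""

    sample_rate_hz: float
    channels: dict[str, np.ndarray]
    ttl_events: list[tuple[float, str]]
    subject: SubjectSpec | None = None

    def __post_init__(self) -> None:
        lengths = {v.size for v in self.channels.values()}
        if len(lengths) > 1:
            raise InvalidParameterError("all channels must have equal length")
        dur = self.duration_s
        for t, _ in self.ttl_events:
            if not 0 <= t <= dur:
                raise InvalidParameterError("TTL event outside recording span")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def events(self, prefix: str | None = None) -> list[tuple[float, str]]:
        if prefix is None:
            return list(self.ttl_events)
        return [(t, c) for t, c in self.ttl_events if c.startswith(prefix)]

    # -------------------------------------------------------------- HDF5 I/O
    def to_hdf5(self, path_or_group) -> None:
        own = isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__")
        h = h5py.File(path_or_group, "w") if own else path_or_group
        try:
            h.attrs["sample_rate_hz"] = self.sample_rate_hz
            if self.subject is not None:
                for k in ("subject_id", "genotype", "sex", "age_group"):
                    h.attrs[k] = getattr(self.subject, k)
            for name, data in self.channels.items():
                h.create_dataset(f"channels/{name}", data=data)
            times = np.array([t for t, _ in self.ttl_events])
            codes = np.array([c for _, c in self.ttl_events], dtype="S32")
            h.create_dataset("ttl/times_s", data=times)
            h.create_dataset("ttl/codes", data=codes)
        finally:
            if own:
                h.close()

    @classmethod
    def from_hdf5(cls, path_or_group) -> "Recording":
        own = isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__")
        h = h5py.File(path_or_group, "r") if own else path_or_group
        try:
            channels = {name: h[f"channels/{name}"][...] for name in h["channels"]}
            times = h["ttl/times_s"][...]
            codes = [c.decode() for c in h["ttl/codes"][...]]
            subject = None
            if "subject_id" in h.attrs:
                subject = SubjectSpec(
                    h.attrs["subject_id"],
                    h.attrs["genotype"],
                    h.attrs["sex"],
                    h.attrs["age_group"],
                )
            return cls(
                sample_rate_hz=float(h.attrs["sample_rate_hz"]),
                channels=channels,
                ttl_events=list(zip(times.tolist(), codes)),
                subject=subject,
            )
        finally:
            if own:
                h.close()


@dataclass
class SubjectData:
    subject: SubjectSpec
    erp: Recording | None = None
    assr: Recording | None = None


# --------------------------------------------------------------------------
# primitives


def kappa_to_expected_itpc(kappa):
    """Population mean resultant length R(kappa) = I1(kappa)/I0(kappa).

    This is the expected ITPC of trials whose phases are von Mises with
    concentration kappa: R(0) = 0 (uniform phases), R -> 1 as kappa -> inf.
    Uses exponentially-scaled Bessel functions for numerical stability.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise InvalidParameterError("kappa must be >= 0")
    out = special.i1e(kappa) / special.i0e(kappa)
    return float(out) if out.ndim == 0 else out


def one_over_f_noise(n_samples: int, sample_rate_hz: float, exponent: float,
                     rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, scaled to target RMS."""
    if rms == 0 or n_samples == 0:
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate_hz)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # zero-mean
    x = np.fft.irfft(spec * shape, n_samples)
    return x * (rms / np.sqrt(np.mean(x**2)))


def _component_waveform(comp: ErpComponent, fs: float) -> tuple[np.ndarray, int]:
    """Gaussian bump sampled over +-4 widths; returns (waveform, offset_samples)."""
    half = int(round(4 * comp.width_ms / 1000.0 * fs))
    t = (np.arange(-half, half + 1)) / fs * 1000.0  # ms relative to peak
    bump = comp.polarity * comp.amplitude_uv * np.exp(-(t**2) / (2 * comp.width_ms**2))
    offset = int(round(comp.latency_ms / 1000.0 * fs)) - half
    return bump, offset


def simulate_recording(
    subject: SubjectSpec,
    schedule: StimulusSchedule,
    params: NeuralModelParams,
    seed=None,
    sample_rate_hz: float = DEFAULT_SIM_RATE_HZ,
    pad_s: float = 1.0,
) -> Recording:
    """Simulate one session: 1/f noise + ERP components + 40 Hz ASSR bursts.

    Each gapped segment contributes one 40 Hz cosine burst spanning the
    segment with a common phase offset drawn von Mises(0, kappa(pair)):
    phase jitter operates at the segment (= trial) level, matching the ITPC
    trial definition.
    """
    rng = np.random.default_rng(seed)
    fs = sample_rate_hz
    n = int(np.ceil((schedule.duration_s + pad_s) * fs))
    seg_n = int(round(SEGMENT_MS / 1000.0 * fs))

    gapped = schedule.gapped_segments()
    for seg in gapped:
        for ch in CHANNELS:
            if seg.pair not in params.channels[ch].assr_kappa:
                raise ConfigurationError(
                    f"no kappa configured for pair {seg.pair.label} on {ch}"
                )

    channels: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        model = params.channels[ch]
        x = one_over_f_noise(n, fs, model.noise_exponent, model.noise_rms_uv, rng)

        for t0 in schedule.erp_onsets_s:
            i_on = int(round(t0 * fs))
            for comp in model.erp_components:
                bump, off = _component_waveform(comp, fs)
                jitter = (
                    rng.lognormal(0.0, comp.trial_jitter_sd)
                    if comp.trial_jitter_sd > 0
                    else 1.0
                )
                i0 = i_on + off
                j0, j1 = max(i0, 0), min(i0 + bump.size, n)
                if j1 > j0:
                    x[j0:j1] += jitter * bump[j0 - i0 : j1 - i0]

        if gapped and model.assr_amplitude_uv > 0:
            t_seg = np.arange(seg_n) / fs
            for seg in gapped:
                kappa = model.assr_kappa[seg.pair]
                phi = rng.vonmises(0.0, kappa) if np.isfinite(kappa) else 0.0
                i0 = int(round(seg.start_s * fs))
                burst = model.assr_amplitude_uv * np.cos(
                    2 * np.pi * ASSR_RATE_HZ * t_seg + phi
                )
                j1 = min(i0 + seg_n, n)
                x[i0:j1] += burst[: j1 - i0]
        channels[ch] = x

    ttl = [(float(t), "erp") for t in schedule.erp_onsets_s]
    ttl += [(seg.start_s, seg.pair.label) for seg in gapped]
    ttl.sort(key=lambda e: e[0])
    return Recording(fs, channels, ttl, subject)


# --------------------------------------------------------------------------
# cohort presets (qualitative emulation — directions only, not measured values)

_AGE_KAPPA_FACTOR = {"p21": 0.45, "p30": 0.75, "p60": 1.0}
_KAPPA_TOP = {"AC": 3.0, "FC": 2.5}
# FC phase-locking multipliers: young KO females are impaired at p21 only;
# KO males remain impaired through p30 (slower maturation).  AC is spared in
# every group, and WT sexes are identical.
_FC_GENO_FACTOR = {
    ("KO", "F"): {"p21": 0.3, "p30": 1.0, "p60": 1.0},
    ("KO", "M"): {"p21": 0.3, "p30": 0.5, "p60": 1.0},
}

# ERP peak amplitudes (uV) by wave, genotype and age; KO growth with age is
# steeper, largest KO-WT gap at p60.  Latencies/widths are shared.
_ERP_AMP = {
    ("WT", "P1"): {"p21": 8.0, "p30": 8.5, "p60": 9.0},
    ("WT", "N1"): {"p21": 10.0, "p30": 11.0, "p60": 12.0},
    ("WT", "P2"): {"p21": 6.0, "p30": 6.5, "p60": 7.0},
    ("KO", "P1"): {"p21": 9.0, "p30": 12.0, "p60": 15.0},
    ("KO", "N1"): {"p21": 11.0, "p30": 14.5, "p60": 19.0},
    ("KO", "P2"): {"p21": 7.0, "p30": 9.0, "p60": 12.0},
}
# Adult KO females are more hypersensitive than adult KO males (N1/P2).
_KO_P60_FEMALE_BOOST = {"N1": 1.25, "P2": 1.25}

_WAVE_SHAPE = {  # (polarity, latency_ms, width_ms)
    "P1": (1, 25.0, 8.0),
    "N1": (-1, 64.0, 14.0),
    "P2": (1, 150.0, 30.0),
}


def _preset_kappa(channel: str, genotype: str, sex: str, age: str) -> dict:
    table = {}
    for pair in default_pairs():
        base = (pair.gap_width_ms / 12.0) ** 0.7
        depth = 1.0 if pair.mod_depth_pct == 100.0 else 0.8
        kappa = _KAPPA_TOP[channel] * base * depth * _AGE_KAPPA_FACTOR[age]
        if channel == "FC":
            kappa *= _FC_GENO_FACTOR.get((genotype, sex), {}).get(age, 1.0)
        table[pair] = kappa
    return table


def _preset_components(genotype: str, sex: str, age: str, jitter_sd: float) -> list:
    comps = []
    for wave, (pol, lat, width) in _WAVE_SHAPE.items():
        amp = _ERP_AMP[(genotype, wave)][age]
        if genotype == "KO" and sex == "F" and age == "p60":
            amp *= _KO_P60_FEMALE_BOOST.get(wave, 1.0)
        comps.append(ErpComponent(wave, pol, lat, amp, width, jitter_sd))
    return comps


def cohort_presets(
    noise_rms_uv: float = 15.0,
    assr_amplitude_uv: float = 8.0,
    trial_jitter_sd: float = 0.2,
) -> dict[tuple[str, str, str], NeuralModelParams]:
    """Generator parameters per (genotype, sex, age) cell.

    Qualitative emulation only.  Encoded directions: reduced FC kappa in
    KO females at p21 and in KO males at p21/p30; AC kappa identical across
    genotypes and sexes; ERP amplitudes growing faster with age in KO, with
    the largest KO-WT gap at p60 and KO-female > KO-male N1/P2 at p60.
    """
    presets = {}
    for genotype in GENOTYPES:
        for sex in SEXES:
            for age in AGE_GROUPS:
                channels = {
                    ch: ChannelModel(
                        erp_components=_preset_components(genotype, sex, age, trial_jitter_sd),
                        assr_kappa=_preset_kappa(ch, genotype, sex, age),
                        assr_amplitude_uv=assr_amplitude_uv,
                        noise_rms_uv=noise_rms_uv,
                    )
                    for ch in CHANNELS
                }
                presets[(genotype, sex, age)] = NeuralModelParams(channels)
    return presets


def default_female_design() -> dict[tuple[str, str, str], int]:
    """Female cohort cell sizes: WT (11, 9, 8) and KO (8, 9, 8) at p21/p30/p60."""
    return {
        ("WT", "F", "p21"): 11, ("WT", "F", "p30"): 9, ("WT", "F", "p60"): 8,
        ("KO", "F", "p21"): 8, ("KO", "F", "p30"): 9, ("KO", "F", "p60"): 8,
    }


def default_male_design() -> dict[tuple[str, str, str], int]:
    """Male cohort cell sizes (convention; the male ns come from a companion study)."""
    return {
        ("WT", "M", "p21"): 10, ("WT", "M", "p30"): 9, ("WT", "M", "p60"): 8,
        ("KO", "M", "p21"): 10, ("KO", "M", "p30"): 9, ("KO", "M", "p60"): 8,
    }


def simulate_cohort(
    design: dict[tuple[str, str, str], int],
    seed=None,
    presets: dict | None = None,
    sessions: str = "both",  # "both" | "erp" | "assr"
    n_trials_per_pair: int = 101,
    erp_protocol: ErpProtocol | None = None,
    sample_rate_hz: float = DEFAULT_SIM_RATE_HZ,
    pairs: tuple[ParametricPair, ...] | None = None,
) -> list[SubjectData]:
    """Simulate one ERP and/or one gap-ASSR session per synthetic subject.

    Sub-seeds are spawned deterministically from the master seed, one per
    subject, so cohorts are reproducible and subjects independent.
    """
    if any(n < 1 for n in design.values()):
        raise InvalidParameterError("every design cell needs n >= 1")
    presets = presets if presets is not None else cohort_presets()
    ss = np.random.SeedSequence(seed)
    subjects: list[SubjectData] = []
    cells = sorted(design)
    child_seeds = ss.spawn(sum(design[c] for c in cells))
    i = 0
    for cell in cells:
        genotype, sex, age = cell
        params = presets[cell]
        for k in range(design[cell]):
            sub_ss = child_seeds[i]
            i += 1
            spec = SubjectSpec(f"{genotype}-{sex}-{age}-{k:02d}", genotype, sex, age)
            rng = np.random.default_rng(sub_ss)
            data = SubjectData(spec)
            if sessions in ("both", "erp"):
                sched = make_erp_session(erp_protocol, sample_rate_hz, rng)
                data.erp = simulate_recording(
                    spec, sched, params, rng, sample_rate_hz
                )
            if sessions in ("both", "assr"):
                sched = make_gap_assr_session(
                    n_trials_per_pair, sample_rate_hz, rng, pairs=pairs
                )
                data.assr = simulate_recording(
                    spec, sched, params, rng, sample_rate_hz
                )
            subjects.append(data)
    return subjects


def write_cohort_manifest(subjects: list[SubjectData], files: dict[str, str], path) -> None:
    """CSV manifest: subject_id, genotype, sex, age_group, file."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "genotype", "sex", "age_group", "file"])
        for s in subjects:
            writer.writerow(
                [s.subject.subject_id, s.subject.genotype, s.subject.sex,
                 s.subject.age_group, files.get(s.subject.subject_id, "")]
            )
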