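"""Auditory stimulus construction: ERP noise bursts and the 40 Hz gap-in-noise ASSR.

The gap-ASSR session alternates 250 ms segments of plain noise and
gap-interrupted noise.  Within a gapped segment, brief silent (or
partially attenuated) gaps repeat every 25 ms, i.e. at a 40 Hz rate, so a
phase-locked cortical response shows up as 40 Hz activity.  Each gapped
segment carries one *parametric pair*: a gap width in {2,4,6,8,10,12} ms and
a modulation depth in {75, 100} %.  The ERP session presents narrowband
noise bursts (6-12 kHz, 100 ms, 5 ms ramps) at a slow 0.25 Hz rate.

Waveforms are peak-normalized and unitless; the nominal sound level (75 dB
SPL) is carried as metadata only — no acoustic calibration is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile

__all__ = [
    "InvalidParameterError",
    "ParametricPair",
    "ErpProtocol",
    "Segment",
    "StimulusSchedule",
    "default_pairs",
    "make_narrowband_noise",
    "make_gap_segment",
    "make_gap_assr_session",
    "make_erp_session",
    "GAP_WIDTHS_MS",
    "MOD_DEPTHS_PCT",
    "SEGMENT_MS",
    "GAP_SPACING_MS",
    "GAPS_PER_SEGMENT",
    "ASSR_RATE_HZ",
]

GAP_WIDTHS_MS = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
MOD_DEPTHS_PCT = (75.0, 100.0)
SEGMENT_MS = 250.0
GAP_SPACING_MS = 25.0  # 40 Hz presentation rate
GAPS_PER_SEGMENT = 9  # onsets at 25, 50, ..., 225 ms within the segment
ASSR_RATE_HZ = 40.0
DEFAULT_AUDIO_RATE_HZ = 48_000.0
DEFAULT_LEVEL_DB = 75.0


class InvalidParameterError(ValueError):
    """A stimulus parameter violates its physical or protocol constraints."""


@dataclass(frozen=True, order=True)
class ParametricPair:
    """One gap-ASSR condition: (gap width in ms, modulation depth in %)."""

    gap_width_ms: float
    mod_depth_pct: float

    def __post_init__(self) -> None:
        if not 0 < self.gap_width_ms < GAP_SPACING_MS:
            raise InvalidParameterError(
                f"gap width must lie in (0, {GAP_SPACING_MS}) ms, "
                f"got {self.gap_width_ms}"
            )
        if not 0 < self.mod_depth_pct <= 100:
            raise InvalidParameterError(
                f"modulation depth must lie in (0, 100] %, got {self.mod_depth_pct}"
            )

    @property
    def label(self) -> str:
        return f"gap{self.gap_width_ms:g}_depth{self.mod_depth_pct:g}"

    @classmethod
    def from_label(cls, label: str) -> "ParametricPair":
        gap, depth = label.removeprefix("gap").split("_depth")
        return cls(float(gap), float(depth))


def default_pairs() -> tuple[ParametricPair, ...]:
    """The 12 conditions of the protocol: 6 gap widths x 2 depths."""
    return tuple(
        ParametricPair(g, d) for d in MOD_DEPTHS_PCT for g in GAP_WIDTHS_MS
    )


@dataclass(frozen=True)
class ErpProtocol:
    """ERP session parameters.

    Defaults follow the protocol: 120 narrowband noise bursts (6-12 kHz),
    100 ms long with 5 ms cosine-squared ramps, presented at 0.25 Hz and a
    nominal 75 dB SPL.
    """

    n_repetitions: int = 120
    stim_duration_ms: float = 100.0
    ramp_ms: float = 5.0
    repetition_rate_hz: float = 0.25
    band_low_hz: float = 6000.0
    band_high_hz: float = 12000.0
    level_db: float = DEFAULT_LEVEL_DB

    def __post_init__(self) -> None:
        if self.n_repetitions <= 0:
            raise InvalidParameterError("n_repetitions must be positive")
        if self.stim_duration_ms <= 2 * self.ramp_ms:
            raise InvalidParameterError(
                "stimulus must be longer than the two ramps combined"
            )
        if not self.band_low_hz < self.band_high_hz:
            raise InvalidParameterError("band_low_hz must be below band_high_hz")
        if self.repetition_rate_hz <= 0:
            raise InvalidParameterError("repetition rate must be positive")


@dataclass(frozen=True)
class Segment:
    kind: str  # "noise" | "gapped"
    start_s: float
    pair: ParametricPair | None = None


@dataclass
class StimulusSchedule:
    """Event-level description of one session.

    ``gap_onsets_s``/``gap_onset_pairs`` list every individual gap;
    ``segments`` lists the alternating 250 ms segments for gap-ASSR sessions
    (empty for ERP sessions); ``erp_onsets_s`` lists noise-burst onsets.
    The audio ``waveform`` is optional — analysis only needs the events.
    """

    sample_rate_hz: float
    segments: list[Segment] = field(default_factory=list)
    gap_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    gap_onset_pairs: list[ParametricPair] = field(default_factory=list)
    erp_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    waveform: np.ndarray | None = None
    level_db: float = DEFAULT_LEVEL_DB
    kind: str = "gap_assr"  # "gap_assr" | "erp"

    @property
    def duration_s(self) -> float:
        ends = [0.0]
        if self.segments:
            ends.append(self.segments[-1].start_s + SEGMENT_MS / 1000.0)
        if self.erp_onsets_s.size:
            ends.append(float(self.erp_onsets_s[-1]) + 1.0)
        if self.waveform is not None:
            ends.append(self.waveform.size / self.sample_rate_hz)
        return max(ends)

    def gapped_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "gapped"]

    def pair_counts(self) -> dict[ParametricPair, int]:
        counts: dict[ParametricPair, int] = {}
        for seg in self.gapped_segments():
            counts[seg.pair] = counts.get(seg.pair, 0) + 1
        return counts

    # ------------------------------------------------------------------ I/O
    def to_json(self, path) -> None:
        payload = {
            "kind": self.kind,
            "sample_rate_hz": self.sample_rate_hz,
            "level_db": self.level_db,
            "segments": [
                {
                    "kind": s.kind,
                    "start_s": s.start_s,
                    "pair": s.pair.label if s.pair else None,
                }
                for s in self.segments
            ],
            "gap_onsets_s": self.gap_onsets_s.tolist(),
            "gap_onset_pairs": [p.label for p in self.gap_onset_pairs],
            "erp_onsets_s": self.erp_onsets_s.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StimulusSchedule":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            sample_rate_hz=payload["sample_rate_hz"],
            segments=[
                Segment(
                    s["kind"],
                    s["start_s"],
                    ParametricPair.from_label(s["pair"]) if s["pair"] else None,
                )
                for s in payload["segments"]
            ],
            gap_onsets_s=np.asarray(payload["gap_onsets_s"]),
            gap_onset_pairs=[
                ParametricPair.from_label(p) for p in payload["gap_onset_pairs"]
            ],
            erp_onsets_s=np.asarray(payload["erp_onsets_s"]),
            level_db=payload["level_db"],
            kind=payload["kind"],
        )

    def to_events_tsv(self, path) -> None:
        """BED-like tab-separated event table: onset_s, duration_ms, label."""
        rows = []
        for s in self.segments:
            label = s.kind if s.pair is None else s.pair.label
            rows.append((s.start_s, SEGMENT_MS, f"segment:{label}"))
        for t, p in zip(self.gap_onsets_s, self.gap_onset_pairs):
            rows.append((float(t), p.gap_width_ms, f"gap:{p.label}"))
        for t in self.erp_onsets_s:
            rows.append((float(t), 0.0, "erp_onset"))
        rows.sort(key=lambda r: r[0])
        with open(path, "w") as fh:
            fh.write("onset_s\tduration_ms\tlabel\n")
            for onset, dur, label in rows:
                fh.write(f"{onset:.6f}\t{dur:g}\t{label}\n")

    def to_wav(self, path) -> None:
        if self.waveform is None:
            raise ValueError("schedule was built without a waveform")
        wavfile.write(path, int(self.sample_rate_hz), self.waveform.astype(np.float32))


# --------------------------------------------------------------------------
# waveform primitives


def _cosine_squared_ramps(n_samples: int, ramp_ms: float, fs: float) -> np.ndarray:
    env = np.ones(n_samples)
    n_ramp = int(round(ramp_ms / 1000.0 * fs))
    if n_ramp > 0:
        ramp = np.sin(np.linspace(0.0, np.pi / 2, n_ramp)) ** 2
        env[:n_ramp] *= ramp
        env[-n_ramp:] *= ramp[::-1]
    return env


def make_narrowband_noise(
    duration_ms: float,
    band_low_hz: float,
    band_high_hz: float,
    ramp_ms: float,
    sample_rate_hz: float,
    seed=None,
) -> np.ndarray:
    """Band-limited Gaussian noise, cosine-squared ramped, peak-normalized.

    Band limiting is done by zeroing out-of-band rFFT bins of a white draw,
    so >=90 % of spectral power sits inside [band_low_hz, band_high_hz]
    (the ramps leak a little power out of band).
    """
    if duration_ms <= 2 * ramp_ms:
        raise InvalidParameterError("duration must exceed twice the ramp time")
    if band_high_hz >= sample_rate_hz / 2:
        raise InvalidParameterError("band extends above Nyquist")
    if not 0 < band_low_hz < band_high_hz:
        raise InvalidParameterError("need 0 < band_low_hz < band_high_hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms / 1000.0 * sample_rate_hz))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    spec[(freqs < band_low_hz) | (freqs > band_high_hz)] = 0.0
    x = np.fft.irfft(spec, n)
    x *= _cosine_squared_ramps(n, ramp_ms, sample_rate_hz)
    peak = np.abs(x).max()
    if peak > 0:
        x /= peak
    return x


def _gap_onset_samples(fs: float) -> np.ndarray:
    """Sample-quantized gap onsets within one 250 ms segment (25..225 ms)."""
    k = np.arange(1, GAPS_PER_SEGMENT + 1)
    return np.round(k * GAP_SPACING_MS / 1000.0 * fs).astype(int)


def make_gap_segment(
    pair: ParametricPair,
    sample_rate_hz: float = DEFAULT_AUDIO_RATE_HZ,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """One 250 ms gap-interrupted noise segment.

    Returns ``(waveform, gap_onsets_ms)``.  Amplitude inside each gap is
    scaled by ``1 - mod_depth_pct/100`` (100 % depth -> exact silence); gap
    edges are rectangular.  Consecutive onsets are 25 ms apart.
    """
    if not isinstance(pair, ParametricPair):
        pair = ParametricPair(*pair)
    rng = np.random.default_rng(seed)
    fs = sample_rate_hz
    n = int(round(SEGMENT_MS / 1000.0 * fs))
    x = rng.standard_normal(n)
    x /= np.abs(x).max()
    scale = 1.0 - pair.mod_depth_pct / 100.0
    onsets = _gap_onset_samples(fs)
    width = int(round(pair.gap_width_ms / 1000.0 * fs))
    for i0 in onsets:
        x[i0 : i0 + width] *= scale
    return x, onsets / fs * 1000.0


def make_gap_assr_session(
    n_trials_per_pair: int = 101,
    sample_rate_hz: float = DEFAULT_AUDIO_RATE_HZ,
    seed=None,
    pairs: tuple[ParametricPair, ...] | None = None,
    build_waveform: bool = False,
) -> StimulusSchedule:
    """Alternating noise / gap-interrupted-noise session.

    Each gapped segment's parametric pair is drawn uniformly at random; the
    session is extended until every pair has accumulated at least
    ``n_trials_per_pair`` gapped segments (default 101, i.e. >100 trials
    per pair).  Noise tokens are independent draws per segment.
    """
    if n_trials_per_pair < 1:
        raise InvalidParameterError("n_trials_per_pair must be >= 1")
    pairs = tuple(pairs) if pairs is not None else default_pairs()
    rng = np.random.default_rng(seed)
    seg_s = SEGMENT_MS / 1000.0

    counts = {p: 0 for p in pairs}
    segments: list[Segment] = []
    gap_onsets: list[float] = []
    gap_pairs: list[ParametricPair] = []
    chunks: list[np.ndarray] = []
    rel_onsets = _gap_onset_samples(sample_rate_hz) / sample_rate_hz

    t = 0.0
    while min(counts.values()) < n_trials_per_pair:
        segments.append(Segment("noise", t))
        if build_waveform:
            noise = rng.standard_normal(int(round(seg_s * sample_rate_hz)))
            chunks.append(noise / np.abs(noise).max())
        t += seg_s

        pair = pairs[rng.integers(len(pairs))]
        counts[pair] += 1
        segments.append(Segment("gapped", t, pair))
        if build_waveform:
            wav, _ = make_gap_segment(pair, sample_rate_hz, rng)
            chunks.append(wav)
        gap_onsets.extend(t + rel_onsets)
        gap_pairs.extend([pair] * len(rel_onsets))
        t += seg_s

    return StimulusSchedule(
        sample_rate_hz=sample_rate_hz,
        segments=segments,
        gap_onsets_s=np.asarray(gap_onsets),
        gap_onset_pairs=gap_pairs,
        waveform=np.concatenate(chunks) if build_waveform else None,
        kind="gap_assr",
    )


def make_erp_session(
    protocol: ErpProtocol | None = None,
    sample_rate_hz: float = DEFAULT_AUDIO_RATE_HZ,
    seed=None,
    lead_in_s: float = 1.0,
    build_waveform: bool = False,
) -> StimulusSchedule:
    """ERP session: ``n_repetitions`` noise-burst onsets at the repetition rate."""
    protocol = protocol or ErpProtocol()
    onsets = lead_in_s + np.arange(protocol.n_repetitions) / protocol.repetition_rate_hz
    waveform = None
    if build_waveform:
        n_total = int(
            round(
                (onsets[-1] + protocol.stim_duration_ms / 1000.0 + lead_in_s)
                * sample_rate_hz
            )
        )
        waveform = np.zeros(n_total)
        rng = np.random.default_rng(seed)
        for t0 in onsets:
            burst = make_narrowband_noise(
                protocol.stim_duration_ms,
                protocol.band_low_hz,
                protocol.band_high_hz,
                protocol.ramp_ms,
                sample_rate_hz,
                rng,
            )
            i0 = int(round(t0 * sample_rate_hz))
            waveform[i0 : i0 + burst.size] = burst
    return StimulusSchedule(
        sample_rate_hz=sample_rate_hz,
        erp_onsets_s=onsets,
        waveform=waveform,
        level_db=protocol.level_db,
        kind="erp",
    )
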