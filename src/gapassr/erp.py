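"""Grand-average event-related potentials and P1/N1/P2 peak extraction.

The auditory ERP is a P1-N1-P2 complex: an early positive wave (~25 ms in
mouse cortex), a negativity (~60 ms) and a late positivity (~150 ms).
Amplitudes are read baseline-to-peak (signed, from the baseline-corrected
average), latencies as the argmax/argmin time within configurable search
windows; ties break toward the earlier latency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EmptyEpochsError, EpochSet
from .stimulus import InvalidParameterError

__all__ = [
    "DEFAULT_PEAK_WINDOWS_MS",
    "ErpWaveform",
    "ErpPeaks",
    "average_erp",
    "detect_peaks",
    "erp_group_table",
]

logger = logging.getLogger(__name__)

#: default search windows (ms after sound onset); config-exposed
DEFAULT_PEAK_WINDOWS_MS = {
    "P1": (10.0, 50.0),
    "N1": (30.0, 100.0),
    "P2": (80.0, 250.0),
}
_WAVE_SIGN = {"P1": 1, "N1": -1, "P2": 1}


@dataclass
class ErpWaveform:
    channel: str
    times_ms: np.ndarray
    mean_uv: np.ndarray
    n_trials: int
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise EmptyEpochsError("ERP average needs at least one trial")
        if not (self.times_ms[0] <= 0.0 <= self.times_ms[-1]):
            raise InvalidParameterError("ERP time axis must include sound onset (0 ms)")


@dataclass
class ErpPeaks:
    """Signed baseline-referenced amplitudes (uV) and latencies (ms) per wave."""

    waves: dict[str, tuple[float, float]]  # wave -> (amplitude_uv, latency_ms)
    windows_ms: dict[str, tuple[float, float]] = field(default_factory=dict)

    def amplitude(self, wave: str) -> float:
        return self.waves[wave][0]

    def latency(self, wave: str) -> float:
        return self.waves[wave][1]


def average_erp(epochs: EpochSet, channel: str, strict: bool = False,
                subject_id: str | None = None) -> ErpWaveform:
    """Point-wise mean over (unflagged, in strict mode) trials of one channel."""
    if not (epochs.baselined and epochs.detrended):
        logger.warning("averaging epochs that are not baseline-corrected+detrended")
    use = epochs.usable_mask(strict)
    if not use.any():
        raise EmptyEpochsError("no usable trials to average")
    data = epochs.channels[channel][use]
    return ErpWaveform(
        channel=channel,
        times_ms=epochs.times_ms,
        mean_uv=data.mean(axis=0),
        n_trials=int(use.sum()),
        subject_id=subject_id,
    )


def detect_peaks(
    waveform: ErpWaveform,
    windows_ms: dict[str, tuple[float, float]] | None = None,
) -> ErpPeaks:
    """Sequential P1 -> N1 -> P2 extraction.

    P1 is the maximum in its window, N1 the minimum, P2 the maximum.  To
    preserve the ordering P1 < N1 < P2 when windows overlap, each search
    starts no earlier than one sample past the previous peak.
    """
    windows = dict(windows_ms or DEFAULT_PEAK_WINDOWS_MS)
    order = ["P1", "N1", "P2"]
    starts = [windows[w][0] for w in order]
    if starts != sorted(starts):
        raise InvalidParameterError("peak windows must be ordered P1, N1, P2")
    t = waveform.times_ms
    dt = t[1] - t[0]
    peaks: dict[str, tuple[float, float]] = {}
    prev_latency = -np.inf
    for wave in order:
        lo, hi = windows[wave]
        if lo < t[0] or hi > t[-1]:
            raise InvalidParameterError(f"{wave} window outside the epoch span")
        lo = max(lo, prev_latency + dt)
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            raise InvalidParameterError(f"{wave} window collapsed to zero samples")
        seg = waveform.mean_uv[mask]
        # argmax/argmin return the first occurrence -> earlier-latency tie rule
        i = int(np.argmax(seg)) if _WAVE_SIGN[wave] > 0 else int(np.argmin(seg))
        t_seg = t[mask]
        peaks[wave] = (float(seg[i]), float(t_seg[i]))
        prev_latency = t_seg[i]
    return ErpPeaks(waves=peaks, windows_ms=windows)


def erp_group_table(
    results: list[tuple[object, dict[str, ErpPeaks]]]
) -> pd.DataFrame:
    """Long-format cohort table: one row per subject x channel x wave.

    ``results`` pairs each SubjectSpec with a {channel: ErpPeaks} mapping.
    Subjects with missing channels are logged and excluded.
    """
    rows = []
    for subject, by_channel in results:
        if not by_channel:
            logger.warning("subject %s has no peaks; excluded", subject.subject_id)
            continue
        for channel, peaks in by_channel.items():
            for wave, (amp, lat) in peaks.waves.items():
                rows.append(
                    dict(
                        subject=subject.subject_id,
                        genotype=subject.genotype,
                        sex=subject.sex,
                        age=subject.age_group,
                        channel=channel,
                        wave=wave,
                        amplitude_uv=amp,
                        latency_ms=lat,
                    )
                )
    return pd.DataFrame(rows)
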