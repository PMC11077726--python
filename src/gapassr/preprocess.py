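"""Raw-recording conditioning: down-sampling, epoching, baseline, detrend, QC.

The analysis chain mirrors standard evoked-potential practice: recordings
are decimated to the 1024 Hz analysis rate behind a zero-phase anti-alias
filter, split into trials on the TTL pulses, baseline-corrected against the
250 ms pre-stimulus window, linearly detrended, and screened for amplitude
or flatline artifacts.  Screening only *flags* trials (rejected_mask);
nothing is deleted, and flagged trials are excluded from averages only in
strict mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import signal

from .stimulus import InvalidParameterError
from .synth import Recording

__all__ = [
    "EmptyEpochsError",
    "EpochSet",
    "downsample",
    "extract_epochs",
    "baseline_correct",
    "detrend_epochs",
    "screen_artifacts",
]

logger = logging.getLogger(__name__)

ANALYSIS_RATE_HZ = 1024.0


class EmptyEpochsError(ValueError):
    """No usable events/trials remain."""


@dataclass
class EpochSet:
    """Trials x samples per channel, with the epoch time axis in ms.

    ``event_labels[i]`` is the stimulus label of trial i ("erp" or a
    parametric-pair label); ``rejected_mask[i]`` marks trials flagged by
    artifact screening (flag-don't-drop policy).
    """

    channels: dict[str, np.ndarray]  # each (n_trials, n_samples), uV
    times_ms: np.ndarray
    sample_rate_hz: float
    event_labels: np.ndarray  # (n_trials,) str
    baselined: bool = False
    detrended: bool = False
    rejected_mask: np.ndarray | None = None
    n_dropped_events: int = 0

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise InvalidParameterError("channel epoch arrays must share a shape")
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.n_trials, dtype=bool)

    @property
    def n_trials(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    def _time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        return (self.times_ms >= lo) & (self.times_ms <= hi)

    def select(self, labels) -> "EpochSet":
        """Sub-set trials by event label(s)."""
        labels = {labels} if isinstance(labels, str) else set(labels)
        keep = np.isin(self.event_labels, list(labels))
        if not keep.any():
            raise EmptyEpochsError(f"no trials with labels {sorted(labels)}")
        return replace(
            self,
            channels={k: v[keep] for k, v in self.channels.items()},
            event_labels=self.event_labels[keep],
            rejected_mask=self.rejected_mask[keep],
        )

    def usable_mask(self, strict: bool = False) -> np.ndarray:
        return ~self.rejected_mask if strict else np.ones(self.n_trials, bool)

    # -------------------------------------------------------------- HDF5 I/O
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as h:
            h.attrs.update(
                sample_rate_hz=self.sample_rate_hz,
                baselined=self.baselined,
                detrended=self.detrended,
                n_dropped_events=self.n_dropped_events,
            )
            h.create_dataset("times_ms", data=self.times_ms)
            h.create_dataset("event_labels", data=self.event_labels.astype("S32"))
            h.create_dataset("rejected_mask", data=self.rejected_mask)
            for name, data in self.channels.items():
                h.create_dataset(f"channels/{name}", data=data)

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as h:
            return cls(
                channels={k: h[f"channels/{k}"][...] for k in h["channels"]},
                times_ms=h["times_ms"][...],
                sample_rate_hz=float(h.attrs["sample_rate_hz"]),
                event_labels=np.array([s.decode() for s in h["event_labels"][...]]),
                baselined=bool(h.attrs["baselined"]),
                detrended=bool(h.attrs["detrended"]),
                rejected_mask=h["rejected_mask"][...],
                n_dropped_events=int(h.attrs["n_dropped_events"]),
            )


def downsample(recording: Recording, target_rate_hz: float = ANALYSIS_RATE_HZ) -> Recording:
    """Decimate to the analysis rate behind a zero-phase anti-alias filter.

    The low-pass corner sits at 0.4 x target rate so that the 40 Hz band is
    deep inside the passband and, being zero-phase (forward-backward), the
    filter cannot bias phase estimates.  TTL event times are kept in
    seconds and therefore survive unchanged.
    """
    native = recording.sample_rate_hz
    if target_rate_hz > native:
        raise InvalidParameterError("target rate exceeds native rate")
    if target_rate_hz == native:
        return recording
    factor = native / target_rate_hz
    if abs(factor - round(factor)) > 1e-9:
        raise InvalidParameterError("target rate must divide the native rate")
    factor = int(round(factor))
    sos = signal.butter(8, 0.4 * target_rate_hz, btype="low", fs=native, output="sos")
    channels = {
        name: signal.sosfiltfilt(sos, data)[::factor]
        for name, data in recording.channels.items()
    }
    return Recording(target_rate_hz, channels, list(recording.ttl_events),
                     recording.subject)


def extract_epochs(
    recording: Recording,
    events: list[tuple[float, str]] | None = None,
    window_ms: tuple[float, float] = (-250.0, 750.0),
) -> EpochSet:
    """Split the trace into trials around event times.

    Events whose window falls partly outside the recording are dropped and
    counted (``n_dropped_events``, also logged).
    """
    if window_ms[0] >= window_ms[1]:
        raise InvalidParameterError("epoch window must be increasing")
    events = recording.ttl_events if events is None else events
    fs = recording.sample_rate_hz
    i_lo = int(round(window_ms[0] / 1000.0 * fs))
    i_hi = int(round(window_ms[1] / 1000.0 * fs))
    n_samp = i_hi - i_lo + 1
    n_total = recording.n_samples

    rows, labels, dropped = [], [], 0
    for t, code in events:
        i_on = int(round(t * fs))
        if i_on + i_lo < 0 or i_on + i_hi >= n_total:
            dropped += 1
            continue
        rows.append(i_on + i_lo)
        labels.append(code)
    if dropped:
        logger.info("extract_epochs: dropped %d out-of-bounds events", dropped)
    if not rows:
        raise EmptyEpochsError("no events fall fully inside the recording")

    idx = np.asarray(rows)[:, None] + np.arange(n_samp)[None, :]
    channels = {name: data[idx] for name, data in recording.channels.items()}
    times_ms = (np.arange(n_samp) + i_lo) / fs * 1000.0
    return EpochSet(
        channels=channels,
        times_ms=times_ms,
        sample_rate_hz=fs,
        event_labels=np.asarray(labels, dtype=object).astype(str),
        n_dropped_events=dropped,
    )


def baseline_correct(
    epochs: EpochSet, baseline_ms: tuple[float, float] = (-250.0, 0.0)
) -> EpochSet:
    """Subtract each trial's mean over the baseline window from the whole trial."""
    mask = epochs._time_mask(baseline_ms)
    if not mask.any() or baseline_ms[0] < epochs.times_ms[0] - 1e-9 \
            or baseline_ms[1] > epochs.times_ms[-1] + 1e-9:
        raise InvalidParameterError("baseline window must lie inside the epoch")
    channels = {
        name: data - data[:, mask].mean(axis=1, keepdims=True)
        for name, data in epochs.channels.items()
    }
    return replace(epochs, channels=channels, baselined=True)


def detrend_epochs(epochs: EpochSet) -> EpochSet:
    """Remove the least-squares straight line from each trial (full epoch)."""
    channels = {
        name: signal.detrend(data, axis=1, type="linear")
        for name, data in epochs.channels.items()
    }
    return replace(epochs, channels=channels, detrended=True)


def screen_artifacts(
    epochs: EpochSet,
    max_abs_uv: float = 2000.0,
    flatline_ms: float = 300.0,
    flat_tol_uv: float = 1e-9,
) -> EpochSet:
    """Flag trials with amplitude excursions or flatline runs.

    Defaults are permissive (clean synthetic data yields zero flags).
    Nothing is deleted: flags land in ``rejected_mask`` and only strict-mode
    consumers exclude flagged trials.
    """
    if max_abs_uv <= 0 or flatline_ms <= 0:
        raise InvalidParameterError("thresholds must be positive")
    n_flat = max(int(round(flatline_ms / 1000.0 * epochs.sample_rate_hz)), 2)
    mask = np.zeros(epochs.n_trials, dtype=bool)
    for data in epochs.channels.values():
        mask |= np.abs(data).max(axis=1) > max_abs_uv
        flat = np.abs(np.diff(data, axis=1)) <= flat_tol_uv
        # longest run of consecutive flat first-differences, per trial:
        # run length at j = j - (last non-flat index at or before j)
        m = flat.shape[1]
        idx = np.arange(m)[None, :]
        last_not_flat = np.maximum.accumulate(np.where(~flat, idx, -1), axis=1)
        longest = (idx - last_not_flat).max(axis=1)
        mask |= longest + 1 >= n_flat
    return replace(epochs, rejected_mask=mask)
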