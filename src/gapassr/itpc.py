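"""Complex Morlet time-frequency decomposition and inter-trial phase clustering.

ITPC at a time-frequency point is the length of the mean of the unit phase
vectors across trials:

    ITPC(t, f) = | (1/N) * sum_k exp(i * phi_k(t, f)) |

so it ranges from 0 (uniform phases) to 1 (identical phase on every trial)
and is independent of per-trial amplitude.  Phases come from convolution
with unit-energy complex Morlet wavelets whose cycle count grows linearly
with frequency (the "dynamic" rule): 3 cycles at 10 Hz to 8 cycles at
100 Hz.  The session summary is the 40 Hz ITPC averaged over a response
window, grouped by parametric pair.

Under uniform phases the sample ITPC is positively biased,
E[ITPC] ~= sqrt(pi)/(2*sqrt(N)); the bias is reported alongside N but not
corrected by default (an optional Rayleigh-based correction is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EpochSet
from .stimulus import ASSR_RATE_HZ, InvalidParameterError, ParametricPair

__all__ = [
    "InsufficientTrialsError",
    "MissingPairError",
    "MorletParams",
    "ItpcSurface",
    "default_freq_grid",
    "dynamic_cycles",
    "morlet_wavelet",
    "morlet_transform",
    "compute_itpc",
    "uniform_phase_itpc_bias",
    "itpc_by_pair",
    "itpc_group_table",
    "collapse_gap_widths",
]

logger = logging.getLogger(__name__)

DEFAULT_SUMMARY_WINDOW_MS = (50.0, 250.0)


class InsufficientTrialsError(ValueError):
    """ITPC needs at least two trials."""


class MissingPairError(KeyError):
    """A requested parametric pair has no trials in the epochs."""


def default_freq_grid(n: int = 31, lo: float = 10.0, hi: float = 100.0) -> np.ndarray:
    """Log-spaced grid with the point nearest 40 Hz snapped to exactly 40 Hz."""
    freqs = np.geomspace(lo, hi, n)
    freqs[np.argmin(np.abs(freqs - ASSR_RATE_HZ))] = ASSR_RATE_HZ
    return freqs


def dynamic_cycles(freqs_hz: np.ndarray) -> np.ndarray:
    """Linear cycle rule: 3 cycles at 10 Hz rising to 8 cycles at 100 Hz."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    return np.clip(3.0 + 5.0 * (freqs_hz - 10.0) / 90.0, 1.0, None)


@dataclass
class MorletParams:
    freqs_hz: np.ndarray = field(default_factory=default_freq_grid)
    cycles: np.ndarray | None = None  # default: dynamic_cycles(freqs_hz)
    edge_pad_ms: float = 100.0

    def __post_init__(self) -> None:
        self.freqs_hz = np.atleast_1d(np.asarray(self.freqs_hz, dtype=float))
        if np.any(self.freqs_hz <= 0):
            raise InvalidParameterError("frequencies must be positive")
        if self.cycles is None:
            self.cycles = dynamic_cycles(self.freqs_hz)
        else:
            self.cycles = np.broadcast_to(
                np.asarray(self.cycles, dtype=float), self.freqs_hz.shape
            ).copy()
        if np.any(self.cycles < 1):
            raise InvalidParameterError("cycle counts must be >= 1")

    def freq_index(self, f_hz: float = ASSR_RATE_HZ) -> int:
        i = int(np.argmin(np.abs(self.freqs_hz - f_hz)))
        if abs(self.freqs_hz[i] - f_hz) > 1e-6:
            logger.warning("grid has no exact %g Hz point; using %g Hz",
                           f_hz, self.freqs_hz[i])
        return i


@dataclass
class ItpcSurface:
    """freqs x times ITPC values for one condition and channel."""

    values: np.ndarray  # (n_freqs, n_times), in [0, 1]
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    n_trials: int
    valid: np.ndarray  # (n_freqs, n_times) bool, False near epoch edges
    pair: ParametricPair | None = None
    channel: str | None = None
    uniform_bias: float = 0.0  # expected ITPC of N uniform phases

    def at_frequency(self, f_hz: float = ASSR_RATE_HZ) -> np.ndarray:
        return self.values[int(np.argmin(np.abs(self.freqs_hz - f_hz)))]

    def mean_in_window(self, f_hz: float, window_ms: tuple[float, float]) -> float:
        i = int(np.argmin(np.abs(self.freqs_hz - f_hz)))
        mask = (self.times_ms >= window_ms[0]) & (self.times_ms <= window_ms[1])
        mask &= self.valid[i]
        if not mask.any():
            raise InvalidParameterError("summary window has no valid samples")
        return float(self.values[i, mask].mean())


def morlet_wavelet(freq_hz: float, n_cycles: float, sample_rate_hz: float) -> np.ndarray:
    """Unit-energy complex Morlet wavelet truncated at +-3 temporal sigmas."""
    sigma_t = n_cycles / (2 * np.pi * freq_hz)
    half = int(np.ceil(3 * sigma_t * sample_rate_hz))
    t = np.arange(-half, half + 1) / sample_rate_hz
    w = np.exp(2j * np.pi * freq_hz * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return w / np.linalg.norm(w)


def morlet_transform(
    data: np.ndarray,
    sample_rate_hz: float,
    params: MorletParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve trials with complex Morlet wavelets.

    Parameters
    ----------
    data : (n_trials, n_samples) real array.

    Returns
    -------
    coeffs : complex (n_trials, n_freqs, n_samples)
    valid : bool (n_freqs, n_samples); False inside the edge region, which
        spans the larger of the wavelet half-support and ``edge_pad_ms``.
    """
    params = params or MorletParams()
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_trials, n_samp = data.shape
    fs = sample_rate_hz

    wavelets = [
        morlet_wavelet(f, c, fs) for f, c in zip(params.freqs_hz, params.cycles)
    ]
    longest = max(w.size for w in wavelets)
    if longest > n_samp:
        raise InvalidParameterError(
            f"epoch ({n_samp} samples) shorter than the longest wavelet support "
            f"({longest} samples at {params.freqs_hz[np.argmin(params.freqs_hz)]:g} Hz)"
        )

    # single FFT of the data, one spectrum product per frequency
    nfft = int(2 ** np.ceil(np.log2(n_samp + longest - 1)))
    spec = np.fft.fft(data, nfft, axis=1)
    coeffs = np.empty((n_trials, len(wavelets), n_samp), dtype=complex)
    pad = int(round(params.edge_pad_ms / 1000.0 * fs))
    valid = np.ones((len(wavelets), n_samp), dtype=bool)
    for j, w in enumerate(wavelets):
        wf = np.fft.fft(w, nfft)
        full = np.fft.ifft(spec * wf[None, :], axis=1)
        half = (w.size - 1) // 2
        coeffs[:, j, :] = full[:, half : half + n_samp]  # 'same' alignment
        n_edge = max(half, pad)
        valid[j, :n_edge] = False
        if n_edge > 0:
            valid[j, -n_edge:] = False
    return coeffs, valid


def uniform_phase_itpc_bias(n_trials: int) -> float:
    """Expected sample ITPC of N uniformly random phases, ~= sqrt(pi)/(2*sqrt(N))."""
    return float(np.sqrt(np.pi) / (2.0 * np.sqrt(n_trials)))


def compute_itpc(
    phases_or_coeffs: np.ndarray,
    freqs_hz: np.ndarray | None = None,
    times_ms: np.ndarray | None = None,
    valid: np.ndarray | None = None,
    pair: ParametricPair | None = None,
    channel: str | None = None,
    bias_corrected: bool = False,
) -> ItpcSurface:
    """ITPC over the trial axis (axis 0) of a trials x freqs x times array.

    Accepts either phase angles (radians, real) or complex wavelet
    coefficients; coefficients are reduced to unit phase vectors first, so
    the result is independent of per-trial amplitude.  With
    ``bias_corrected=True`` the Rayleigh-based unbiased variant
    sqrt(max(N*R^2 - 1, 0)/(N - 1)) is returned instead of plain R.
    """
    x = np.asarray(phases_or_coeffs)
    if x.shape[0] < 2:
        raise InsufficientTrialsError("ITPC requires at least 2 trials")
    if np.iscomplexobj(x):
        mag = np.abs(x)
        unit = np.where(mag > 0, x / np.where(mag > 0, mag, 1.0), 0.0)
    else:
        unit = np.exp(1j * x)
    n = x.shape[0]
    r = np.abs(unit.mean(axis=0))
    r = np.clip(r, 0.0, 1.0)
    if bias_corrected:
        r = np.sqrt(np.maximum(n * r**2 - 1.0, 0.0) / (n - 1.0))
    if x.ndim == 2:  # trials x times at a single frequency
        r = r[None, :]
    freqs_hz = np.atleast_1d(freqs_hz) if freqs_hz is not None else np.full(r.shape[0], np.nan)
    times_ms = times_ms if times_ms is not None else np.arange(r.shape[-1], dtype=float)
    valid = valid if valid is not None else np.ones(r.shape, dtype=bool)
    return ItpcSurface(
        values=r,
        freqs_hz=freqs_hz,
        times_ms=times_ms,
        n_trials=n,
        valid=np.broadcast_to(valid, r.shape),
        pair=pair,
        channel=channel,
        uniform_bias=uniform_phase_itpc_bias(n),
    )


def itpc_by_pair(
    epochs: EpochSet,
    channel: str,
    params: MorletParams | None = None,
    window_ms: tuple[float, float] = DEFAULT_SUMMARY_WINDOW_MS,
    pairs: list[ParametricPair] | None = None,
    strict: bool = False,
    keep_surfaces: bool = True,
    min_trials_warn: int = 100,
) -> tuple[dict[ParametricPair, float], dict[ParametricPair, ItpcSurface]]:
    """Per-pair mean 40 Hz ITPC over the response window.

    Trials of each parametric pair are grouped, Morlet-transformed and
    reduced to the mean 40 Hz ITPC inside ``window_ms``.  Returns
    ``(summaries, surfaces)``; surfaces are full freq x time ITPC maps
    (empty dict when ``keep_surfaces`` is False).
    """
    params = params or MorletParams()
    present = set(epochs.event_labels)
    if pairs is None:
        wanted = sorted(
            ParametricPair.from_label(lbl) for lbl in present if lbl.startswith("gap")
        )
    else:
        wanted = list(pairs)
    if not wanted:
        raise MissingPairError("epochs contain no parametric-pair trials")

    summaries: dict[ParametricPair, float] = {}
    surfaces: dict[ParametricPair, ItpcSurface] = {}
    f_idx = params.freq_index(ASSR_RATE_HZ)
    for pair in wanted:
        if pair.label not in present:
            raise MissingPairError(f"pair {pair.label} absent from epochs")
        sub = epochs.select(pair.label)
        use = sub.usable_mask(strict)
        data = sub.channels[channel][use]
        if data.shape[0] < min_trials_warn:
            logger.warning(
                "pair %s has %d trials (<%d)", pair.label, data.shape[0], min_trials_warn
            )
        coeffs, valid = morlet_transform(data, epochs.sample_rate_hz, params)
        surface = compute_itpc(
            coeffs, params.freqs_hz, epochs.times_ms, valid, pair, channel
        )
        summaries[pair] = surface.mean_in_window(ASSR_RATE_HZ, window_ms)
        if keep_surfaces:
            surfaces[pair] = surface
    return summaries, surfaces


def itpc_group_table(
    results: list[tuple[object, dict[str, dict[ParametricPair, float]]]]
) -> pd.DataFrame:
    """Long-format cohort table: subject x channel x gap width x depth -> ITPC."""
    rows = []
    for subject, by_channel in results:
        for channel, summaries in by_channel.items():
            for pair, value in summaries.items():
                rows.append(
                    dict(
                        subject=subject.subject_id,
                        genotype=subject.genotype,
                        sex=subject.sex,
                        age=subject.age_group,
                        channel=channel,
                        gap_width_ms=pair.gap_width_ms,
                        mod_depth_pct=pair.mod_depth_pct,
                        itpc=value,
                    )
                )
    return pd.DataFrame(rows)


def collapse_gap_widths(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean ITPC across gap widths at fixed modulation depth."""
    keys = ["subject", "genotype", "sex", "age", "channel", "mod_depth_pct"]
    return (
        table.groupby(keys, as_index=False)["itpc"]
        .mean()
        .rename(columns={"itpc": "itpc_collapsed"})
    )
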