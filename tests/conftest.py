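import numpy as np
import pytest

from gapassr import stimulus as st
from gapassr import synth
from gapassr.preprocess import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_pair():
    return st.ParametricPair(12.0, 100.0)


def make_epochs(data_by_channel, sample_rate_hz=1024.0, t0_ms=-250.0,
                labels=None, baselined=False, detrended=False):
    """Build an EpochSet directly from arrays (helper for unit tests)."""
    first = next(iter(data_by_channel.values()))
    n_trials, n_samp = first.shape
    times = t0_ms + np.arange(n_samp) / sample_rate_hz * 1000.0
    if labels is None:
        labels = np.array(["erp"] * n_trials)
    return EpochSet(
        channels={k: np.asarray(v, dtype=float) for k, v in data_by_channel.items()},
        times_ms=times,
        sample_rate_hz=sample_rate_hz,
        event_labels=np.asarray(labels),
        baselined=baselined,
        detrended=detrended,
    )


@pytest.fixture
def epochs_factory():
    return make_epochs


def noise_free_params(kappa_map, assr_amplitude_uv=8.0, components=()):
    """NeuralModelParams with zero background noise on both channels."""
    model = synth.ChannelModel(
        erp_components=list(components),
        assr_kappa=dict(kappa_map),
        assr_amplitude_uv=assr_amplitude_uv,
        noise_rms_uv=0.0,
    )
    import copy
    return synth.NeuralModelParams({"AC": copy.deepcopy(model), "FC": model})


@pytest.fixture
def noise_free_params_factory():
    return noise_free_params
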