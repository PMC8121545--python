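import numpy as np
import pytest

from monitorlearn.erp_features import EpochArray


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def waveform_epochs(waveforms, channel_names, srate=500.0, t0=-200.0):
    """Stack per-channel waveform callables into a one-epoch EpochArray.

    ``waveforms`` maps channel name -> callable of the time axis (ms);
    channels without an entry are zero.
    """
    n_samples = 500
    times = t0 + (1000.0 / srate) * np.arange(n_samples)
    data = np.zeros((1, len(channel_names), n_samples))
    for j, ch in enumerate(channel_names):
        if ch in waveforms:
            data[0, j, :] = waveforms[ch](times)
    return EpochArray(data, tuple(channel_names), srate, t0)


@pytest.fixture
def make_epochs():
    return waveform_epochs
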