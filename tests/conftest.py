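import warnings

import numpy as np
import pytest

from cryptofrog import acoustics, synth


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    """Mixed-model boundary fits warn; keep test output readable."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*[Cc]onverge.*")
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def rate() -> float:
    return 44100.0


@pytest.fixture(scope="session")
def short_call_pair(rate):
    """Two synthesized short calls at known onsets, 1 s apart, with noise."""
    p1 = synth.CallSynthParams(call_class="short", carrier_freq=3200.0,
                               dt_target=0.10, rt_target=0.02, ft_target=0.08,
                               noise_snr_db=np.inf, seed=1)
    p2 = synth.CallSynthParams(call_class="short", carrier_freq=3200.0,
                               dt_target=0.12, rt_target=0.03, ft_target=0.09,
                               noise_snr_db=np.inf, seed=2)
    w1, w2 = synth.synth_call(p1, rate), synth.synth_call(p2, rate)
    sil = np.zeros(int(1.0 * rate))
    samples = np.concatenate([sil, w1, sil, w2, sil])
    rng = np.random.default_rng(3)
    sig_rms = np.sqrt(np.mean(np.concatenate([w1, w2]) ** 2))
    samples = samples + rng.normal(0, sig_rms / 10 ** (30 / 20), samples.size)
    onsets = (1.0, 1.0 + w1.size / rate + 1.0)
    return acoustics.CallRecording(samples, rate, individual_id="fx"), onsets
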