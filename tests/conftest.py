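import numpy as np
import pytest

from facehrv.pulse import NNISeries
from facehrv.synthetic import generate_rr_series


@pytest.fixture(scope="session")
def modulated_truth():
    """2-min RR ground truth with LF+HF modulation and mild jitter."""
    return generate_rr_series(
        120.0, mean_hr_bpm=70.0, lf_amp=0.03, lf_freq_hz=0.1,
        hf_amp=0.025, hf_freq_hz=0.25, jitter_sd_ms=3.0, seed=11,
    )


@pytest.fixture(scope="session")
def long_nni():
    """10-min jittered NN series, long enough for every feature family."""
    truth = generate_rr_series(
        600.0, mean_hr_bpm=70.0, lf_amp=0.03, lf_freq_hz=0.1,
        hf_amp=0.025, hf_freq_hz=0.25, jitter_sd_ms=5.0, seed=29,
    )
    return NNISeries(nni=truth.nni, nni_times=truth.beat_times[1:],
                     beat_times=truth.beat_times)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
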