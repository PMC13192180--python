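import numpy as np
import pytest

from neuroslice import classify, spectral
from neuroslice.synth import LfpGenSpec, generate_lfp


@pytest.fixture(scope="session")
def bursts_fixture():
    """Standard 300-s bursting trace (0.55 Hz rate, 100 Hz intra-burst)."""
    spec = LfpGenSpec(state_kind="bursts", burst_rate=0.55, intra_burst_freq=100.0, seed=11)
    trace, truth = generate_lfp(spec)
    filtered = spectral.lowpass_butterworth(trace)
    events = classify.detect_bursts(filtered)
    return spec, trace, truth, filtered, events


@pytest.fixture(scope="session")
def gamma_fixture():
    """60-s carbachol-style gamma trace at 35 Hz."""
    spec = LfpGenSpec(state_kind="gamma", gamma_freq=35.0, duration_s=60.0, seed=7)
    trace, truth = generate_lfp(spec)
    filtered = spectral.lowpass_butterworth(trace)
    psd = spectral.welch_psd(filtered)
    peak = spectral.find_spectral_peak(psd)
    return spec, trace, filtered, psd, peak


@pytest.fixture(scope="session")
def short_freq_grid():
    """Coarse wavelet grid for fast unit tests."""
    return np.logspace(np.log10(0.3), np.log10(150.0), 40)
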