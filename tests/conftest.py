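import numpy as np
import pytest

import nlpvox as nv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def material():
    return nv.make_material(7)


@pytest.fixture(scope="session")
def exp1_manifest():
    return nv.build_exp1_manifest(11)


@pytest.fixture(scope="session")
def exp2_manifest():
    return nv.build_exp2_manifest(11)


@pytest.fixture(scope="session")
def exp3_manifest(material):
    return nv.build_exp3_manifest(11, material)


def spectrum_db(wave, pad=1):
    """Windowed FFT magnitude in dB and its frequency axis."""
    x = wave.samples * np.hanning(wave.samples.size)
    n = wave.samples.size * pad
    mag = np.abs(np.fft.rfft(x, n))
    freqs = np.fft.rfftfreq(n, 1.0 / wave.sample_rate)
    return 20 * np.log10(np.maximum(mag, 1e-12)), freqs


def peak_level_db(wave, freq, half_width=8.0):
    """Peak FFT level (dB) within +-half_width Hz of a target frequency."""
    db, freqs = spectrum_db(wave)
    sel = (freqs >= freq - half_width) & (freqs <= freq + half_width)
    return float(db[sel].max())
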