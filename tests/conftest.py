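import numpy as np
import pytest

from woodsans import InstrumentConfig


@pytest.fixture
def short_config():
    """1.7 m configuration covering the diffraction-peak region."""
    return InstrumentConfig(wavelength_A=6.0, wavelength_spread=0.13,
                            sdd_m=1.7, beam_center_px=(64.0, 64.0),
                            pixel_pitch_mm=8.0, detector_shape=(128, 128),
                            q_range=(0.02, 0.27))


@pytest.fixture
def long_config():
    """14.5 m configuration covering the lowest q values."""
    return InstrumentConfig(wavelength_A=6.0, wavelength_spread=0.13,
                            sdd_m=14.5, beam_center_px=(64.0, 64.0),
                            pixel_pitch_mm=8.0, detector_shape=(128, 128),
                            q_range=(0.003, 0.035))


@pytest.fixture
def tiny_config():
    """Small 64x64 detector for brute-force oracle comparisons."""
    return InstrumentConfig(wavelength_A=6.0, wavelength_spread=0.13,
                            sdd_m=1.7, beam_center_px=(32.0, 32.0),
                            pixel_pitch_mm=8.0, detector_shape=(64, 64),
                            q_range=(0.02, 0.15))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
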