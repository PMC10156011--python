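import numpy as np
import pytest
from hypothesis import settings

from emovox import pitch_tools as pt
from emovox import voicegen as vg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def vowel_200():
    """Flat 200 Hz synthetic vowel, 1.5 s at 22050 Hz."""
    return vg.flat_vowel(200.0, seed=0)


@pytest.fixture(scope="session")
def vowel_220():
    return vg.flat_vowel(220.0, seed=0)


@pytest.fixture(scope="session")
def contour_200(vowel_200):
    return pt.estimate_f0(vowel_200)


@pytest.fixture(scope="session")
def fast_contour_200(vowel_200):
    """Short-window, fine-hop track for measuring fast modulations."""
    return pt.estimate_f0(vowel_200, fmin=150, fmax=300, frame_step_s=0.005)


@pytest.fixture(scope="session")
def white_noise_44k():
    rng = np.random.default_rng(0)
    from emovox.waveform import Waveform

    return Waveform(rng.standard_normal(44100), 44100)
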