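import numpy as np
import pytest

from adhf_voice import VoiceSpec, synth_voice
from adhf_voice.signal_io import Sensor, Waveform


@pytest.fixture(scope="session")
def modal_vowel():
    """Noiseless 100 Hz sustained vowel with exact truth."""
    return synth_voice(VoiceSpec(f0_contour=100.0, duration=3.0, seed=1))


@pytest.fixture(scope="session")
def creaky_clip():
    """Fully creaky (irregular low-F0 pulses) one-second clip."""
    return synth_voice(
        VoiceSpec(f0_contour=120.0, creak_segments=((0.0, 1.0),), duration=1.0, seed=4)
    )


@pytest.fixture(scope="session")
def white_noise():
    rng = np.random.default_rng(0)
    return Waveform(rng.standard_normal(75_000), 25_000, Sensor.MIC)


def mic_tone(freq: float, duration: float = 3.0, rate: int = 44_100) -> Waveform:
    t = np.arange(int(duration * rate)) / rate
    return Waveform(np.sin(2 * np.pi * freq * t), rate, Sensor.MIC)
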