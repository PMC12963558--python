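import numpy as np
import pytest

import neuroload as nl
from neuroload.pipeline import compute_neurometrics


#: scaled-down study dimensions used throughout the suite; rejection-rate
#: and direction statistics do not depend on recording length, so short
#: recordings keep the suite fast without changing what is being tested
SMALL_STUDY_KW = dict(fs=128.0, task_duration=16.0, rest_duration=30.0)


@pytest.fixture(scope="session")
def default_config():
    return nl.config_from_dict({}, seed=7)


@pytest.fixture(scope="session")
def small_study():
    """One scaled synthetic study with the default programmed effects."""
    cfg = nl.StudyConfig(seed=7, **SMALL_STUDY_KW)
    return nl.generate_study(cfg)


@pytest.fixture(scope="session")
def small_study_neurometrics(small_study, default_config):
    return compute_neurometrics(small_study.recordings,
                                small_study.rest_segments, default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_tone_recording(freqs_by_channel: dict, fs: float = 128.0,
                        duration: float = 8.0, montage=None,
                        amplitude: float = 1.0) -> nl.Recording:
    """A recording whose listed channels carry pure sinusoids (everything
    else zero); handy for band-power and filter contracts."""
    montage = montage or nl.default_montage()
    n = int(duration * fs)
    t = np.arange(n) / fs
    samples = np.zeros((montage.n_channels, n))
    for ch, freq in freqs_by_channel.items():
        samples[montage.index(ch)] = amplitude * np.sin(2 * np.pi * freq * t)
    return nl.Recording(samples, fs, montage)
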