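import numpy as np
import pytest

from preictal.ingest import RawRecording, SeizureAnnotation
from preictal.pipeline import build_segments, config_for_synth
from preictal.synthio import SynthSpec, generate_subject


@pytest.fixture(scope="session")
def small_spec():
    """A desk-scale dual-signal subject: 4 seizures, 2-min pre-ictal blocks."""
    return SynthSpec(n_channels=8, fs=64, n_seizures=4,
                     interictal_minutes_per_block=5, preictal_minutes=2,
                     effect_size=1.0, seed=11)


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return generate_subject(small_spec)


@pytest.fixture(scope="session")
def small_segments(small_spec, small_subject):
    return build_segments(small_subject,
                          config_for_synth(small_spec, balance_seed=1))


@pytest.fixture
def toy_recording():
    """A deterministic 2-channel recording with one seizure annotation."""
    rng = np.random.default_rng(5)
    fs = 32
    data = rng.standard_normal((2, fs * 120)) * 20
    return RawRecording(data=data, fs=fs, channel_names=["CH01", "CH02"],
                        annotations=[SeizureAnnotation(80.0, 90.0)],
                        subject_id="toy")
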