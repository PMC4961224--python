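import numpy as np
import pytest

from contextgain.drc import DRCParams, Spectrogram, generate_drc
from contextgain.models import CGFField, CGFModel, PRFField
from contextgain.synth import make_ground_truth, simulate_trials


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec(rng):
    """Dense-ish random spectrogram on a 9-channel grid (2-32 kHz, 2/oct)."""
    levels = rng.random((60, 9)) * (rng.random((60, 9)) < 0.4)
    return Spectrogram(levels, bin_duration=20.0, channels_per_octave=2)


@pytest.fixture
def small_model(rng):
    prf = rng.standard_normal((3, 9))
    cgf = 0.2 * rng.standard_normal((4, 5))
    cgf[0, 2] = 0.0
    return CGFModel(0.5, PRFField(prf), CGFField(cgf))


@pytest.fixture
def small_recording():
    """Short synthetic recording with a contextual ground-truth neuron."""
    neuron = make_ground_truth(seed=7)
    spec = generate_drc(
        DRCParams(
            n_time_bins=2500,
            presence_prob=0.25,
            level_set=(0.4, 0.6, 0.8, 1.0),
            channels_per_octave=3,
            seed=8,
        )
    )
    trials = simulate_trials(neuron, spec, 10, seed=9)
    return neuron, spec, trials
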