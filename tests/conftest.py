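import numpy as np
import pytest

from eegworkload import synth, tasks


@pytest.fixture
def compact_params():
    """Noise-free, artifact-free generator settings on the small montage."""
    return synth.EEGGenParams(
        channel_labels=tuple(synth.compact_montage()),
        noise_amplitude=0.0,
        artifact_prob=0.0,
    )


@pytest.fixture
def stroop_trials():
    """One simulated error-free Stroop session (288 trials)."""
    design = tasks.build_stroop_design(11, "congruent")
    model = synth.BehaviorModel(
        {
            k: synth.RTParams(v.mean, v.sd, error_prob=0.0, omission_prob=0.0)
            for k, v in synth.BehaviorModel().cells.items()
        }
    )
    return synth.simulate_behavior(design, model, 12)


@pytest.fixture
def short_trials(stroop_trials):
    """First 40 trials of the Stroop session, for cheap EEG synthesis."""
    return stroop_trials[:40]


@pytest.fixture
def short_recording(short_trials, compact_params):
    return synth.simulate_eeg(short_trials, compact_params, 13)


def perfect_behavior_model():
    base = synth.BehaviorModel()
    return synth.BehaviorModel(
        {
            k: synth.RTParams(v.mean, v.sd, error_prob=0.0, omission_prob=0.0)
            for k, v in base.cells.items()
        }
    )
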