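"""Shared fixtures: small synthetic recordings reused across test modules."""

import numpy as np
import pytest

import vigikit as vk


@pytest.fixture(scope="session")
def noise_free_params():
    return vk.EEGSynthesisParams(background_rms=0.0, line_noise_amp=0.0,
                                 seed=5)


@pytest.fixture(scope="session")
def all_a1_recording(noise_free_params):
    """60 s of pure occipital alpha (stage A1), no noise."""
    seq = vk.StageSequence(labels=np.array(["A1"] * 60))
    return vk.synthesize_eeg(seq, noise_free_params)


@pytest.fixture(scope="session")
def mixed_truth():
    """A 480-s trajectory visiting every stage, plus its default-SNR EEG."""
    params = vk.TrajectoryParams(
        n_segments=480, start_stage_probs={"0": 0.1, "A1": 0.9},
        decline_rate=1.2, recovery_rate=0.5, dwell_min=5, seed=7)
    seq = vk.simulate_trajectory(params)
    rec = vk.synthesize_eeg(seq, vk.EEGSynthesisParams(seed=7))
    return seq, rec


@pytest.fixture(scope="session")
def mixed_analysis(mixed_truth):
    _, rec = mixed_truth
    return vk.analyze_recording(rec)
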