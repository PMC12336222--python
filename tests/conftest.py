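import numpy as np
import pytest

from bcgsleep import synthetic as syn


@pytest.fixture(scope="session")
def metronome_recording():
    """Noise-free recording with exactly periodic 1.0-s beats."""
    profiles = {s: syn.StageProfile(s, 1.0, 0.0, 0.25) for s in syn.STAGES}
    return syn.generate_recording(
        profiles, ["N2"] * 4, seed=1, noise_sigma=0.0
    )


@pytest.fixture(scope="session")
def noisy_recording():
    """Realistic 2-min recording with default profiles and mild noise."""
    hyp = syn.generate_hypnogram(4, seed=5)
    return syn.generate_recording(None, hyp, seed=5, noise_sigma=0.05)


@pytest.fixture(scope="session")
def planted_table():
    """Small planted feature table for selection/classifier tests."""
    spec = syn.PlantedFeatureSpec(
        n_samples=600, n_informative=10, n_redundant=5, n_noise=30,
        effect_size=2.0, seed=11,
    )
    return syn.generate_feature_table(spec)


@pytest.fixture(scope="session")
def small_feature_table(noisy_recording):
    from bcgsleep import features, signals

    jj, bb = signals.process_recording(noisy_recording)
    table, mask = features.assemble(jj, bb, stages=noisy_recording.stages)
    return table, mask
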