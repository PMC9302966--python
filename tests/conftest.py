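import numpy as np
import pytest

from f1adapt import SimConfig, generate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """4 participants x 60 trials with the default effect sizes."""
    cfg = SimConfig(n_participants=4, n_trials=60, seed=42)
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def noise_free_cfg():
    """Deterministic generator config: no noise, fixed gains and shift."""
    return SimConfig(
        n_participants=3,
        n_trials=60,
        comp_gain_mean=0.05,
        comp_gain_sd=0.0,
        adapt_gain_mean=0.02,
        adapt_gain_sd=0.0,
        shift_mean_mels=125.0,
        shift_sd_mels=0.0,
        noise_trial_sd_mels=0.0,
        noise_sample_sd_mels=0.0,
        short_vowel_fraction=0.0,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
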