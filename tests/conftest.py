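import pytest

from pavcond import synth


@pytest.fixture(scope="session")
def trials_200():
    return synth.generate_trials(200, rng_seed=1)


@pytest.fixture(scope="session")
def small_session():
    """120-trial session with 2 DA-like and 1 SNr-like unit."""
    cfg = synth.SessionConfig(n_trials=120, n_da=2, n_snr=1)
    session, truth = synth.generate_session(cfg, rng_seed=42)
    return session, truth


@pytest.fixture(scope="session")
def fast_trial_config():
    return synth.TrialConfig(
        inter_trial_interval=0.3, post_reward_pause=0.5, invalid_trial_prob=0.0
    )
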