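import numpy as np
import pytest

import headcode as hc


@pytest.fixture(scope="session")
def sp_noiseless_session():
    """Noiseless single-peaked population on a realistic trajectory.

    Ground-truth kappa spread and no AHV modulation: used for parameter
    recovery (preferred direction, kappa via MVL, FWHM).
    """
    spec = hc.SyntheticPopSpec(
        n_sp=12,
        n_mp=0,
        sp_concentration_range=(1.0, 8.0),
        ahv_gain_class="none",
        noise_model="none",
        seed=11,
    )
    return hc.make_session(spec, n_steps=40_000)


@pytest.fixture(scope="session")
def mixed_session():
    """Poisson SP/MP population with AHV gain on the MP class."""
    spec = hc.SyntheticPopSpec(
        n_sp=20,
        n_mp=8,
        sp_concentration_range=(2.0, 8.0),
        mp_peak_width=0.5,
        ahv_gain_class="mp",
        ahv_gain_range=(0.2, 0.4),
        base_rate=20.0,
        noise_model="poisson",
        seed=7,
    )
    return hc.make_session(spec, n_steps=48_000)


@pytest.fixture(scope="session")
def tiny_rnn():
    """A briefly trained integrator network for dynamics-level tests."""
    cfg = hc.RNNConfig(
        n_units=32,
        trial_len=120,
        n_trials=60,
        epochs=100,
        batch_size=30,
        seed=3,
    )
    return hc.train(cfg)


@pytest.fixture(scope="session")
def study_rnn():
    """Study-condition integrator network shared by the slower checks.

    100 units, 500-step trials, 500 epochs of minibatch Adam with the
    standard velocity process: the configuration at which the emergent
    single-peaked/multipeaked structure is analyzed.
    """
    cfg = hc.RNNConfig(
        n_units=100,
        trial_len=500,
        n_trials=250,
        epochs=500,
        batch_size=50,
        learning_rate=2e-3,
        rate_l2=1e-2,
        seed=0,
    )
    return hc.train(cfg)


@pytest.fixture(scope="session")
def study_session(study_rnn):
    return hc.generate_session(study_rnn, n_steps=60_000, seed=1).exclude_silent()
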