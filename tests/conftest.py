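import numpy as np
import pytest

from navclust import simulate as sim


@pytest.fixture
def quiet_ephys_cfg():
    """Noise-free generator config with the default gating parameters."""
    return sim.EphysSimConfig(noise_sd=0.0)


@pytest.fixture
def const_tau_cfg():
    """Noise-free config with voltage-independent time constants.

    With constant tau_m/tau_h the peak-transient shape factor is common to
    all sweeps, so the normalized peak-conductance curve equals the
    steady-state activation Boltzmann.
    """
    return sim.EphysSimConfig(noise_sd=0.0,
                              tau_m_of_v=lambda v: 0.3,
                              tau_h_of_v=lambda v: 2.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
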