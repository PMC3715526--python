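import numpy as np
import pytest

from gainnet import defaults
from gainnet.meanfield import GainParams, MeanFieldParams


@pytest.fixture(scope="session")
def gain():
    return GainParams(**defaults.GAIN)


@pytest.fixture(scope="session")
def mf_params(gain):
    """Default mean-field operating parameters (on the f=0.5 gain-control boundary)."""
    return MeanFieldParams(defaults.POPS, defaults.CONN, gain)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)


def random_admissible_params(rng, g_EE_max=0.0):
    """Random parameter draw in the stable, inhibition-dominated regime.

    Lateral excitation is bounded by ``g_EE_max`` (0 disables it); strengths
    are kept in the range where the default population sizes put couplings
    at order unity.
    """
    conn = defaults.CONN.replace(
        p_EE=float(rng.uniform(0, 0.05)) if g_EE_max > 0 else 0.0,
        p_EI=float(rng.uniform(0.2, 1.0)),
        p_IE=float(rng.uniform(0.2, 1.0)),
        p_II=float(rng.uniform(0.05, 0.6)),
        g_EE=float(rng.uniform(0, g_EE_max)) if g_EE_max > 0 else 0.0,
        g_EI=float(rng.uniform(0.004, 0.02)),
        g_IE=float(rng.uniform(0.002, 0.01)),
        g_II=float(rng.uniform(0.004, 0.02)),
    )
    gain = GainParams(
        beta_E=float(rng.uniform(0.5, 2.0)),
        beta_I=float(rng.uniform(0.5, 2.0)),
        theta_E=1.0,
        theta_I=2.0,
        tau_E=float(rng.uniform(5, 20)),
        tau_I=float(rng.uniform(5, 20)),
    )
    return MeanFieldParams(defaults.POPS, conn, gain)
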