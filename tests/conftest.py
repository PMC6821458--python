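import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pac_sim():
    """One seeded 20 s trace with strong phase-amplitude coupling."""
    from glmcfc.simulate import simulate_pac

    return simulate_pac(i_pac=1.0, duration=20.0, fs=1000.0, seed=7)


@pytest.fixture(scope="session")
def pac_decomposition(pac_sim):
    """Trimmed band decomposition of the shared PAC trace."""
    from glmcfc.decompose import decompose

    return decompose(pac_sim.v, pac_sim.fs).trimmed(1.0)


@pytest.fixture(scope="session")
def pac_results(pac_sim):
    """Fitted coupling models for the shared PAC trace."""
    from glmcfc import CFCModel

    return CFCModel(pac_sim.v, pac_sim.fs).fit()
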