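import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from idrctd import ChainSpec, generate_chain_ensemble, packaged_region


@pytest.fixture(scope="session")
def ctd2a():
    return packaged_region("CTD2A")


@pytest.fixture(scope="session")
def ctd2b():
    return packaged_region("CTD2B")


@pytest.fixture(scope="session")
def helix_traj():
    """Ideal alpha-helix backbone fixture (15 residues, 1 frame)."""
    return generate_chain_ensemble(ChainSpec(n_residues=15, model="ideal-helix"))


@pytest.fixture(scope="session")
def strands_traj():
    """Two antiparallel strands at H-bond register (10 residues each)."""
    return generate_chain_ensemble(ChainSpec(n_residues=10, model="paired-strands"))


@pytest.fixture(scope="session")
def extended_traj():
    """Single fully extended chain: no intra-chain H-bond partners."""
    from idrctd.synthetic import _extended_trajectory

    return _extended_trajectory(ChainSpec(n_residues=12, model="ideal-helix"))
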