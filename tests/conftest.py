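import pytest

from seedvar.simulate import SimulationConfig, simulate_world


@pytest.fixture(scope="session")
def world():
    """A deterministic synthetic world shared across tests."""
    return simulate_world(SimulationConfig(rng_seed=11))


@pytest.fixture(scope="session")
def mirs_by_name(world):
    return {m.name: m for m in world.mirs}


@pytest.fixture(scope="session")
def utrs_by_name(world):
    return {u.name: u for u in world.utrs}


@pytest.fixture(scope="session")
def snps_by_rsid(world):
    return {s.rsid: s for s in world.snps}
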