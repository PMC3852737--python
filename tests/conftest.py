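import pytest

from phenonet import (
    GeneratorConfig,
    Phenophase,
    build_network,
    generate_community,
    generate_observations,
)


@pytest.fixture
def staggered_phenophases():
    """Five species with staggered phenophases over a 165-234 season."""
    phens = {
        "P1": Phenophase("P1", 165, 200),
        "P2": Phenophase("P2", 205, 220),
        "A1": Phenophase("A1", 180, 220),
        "A2": Phenophase("A2", 165, 175),
        "A3": Phenophase("A3", 210, 230),
    }
    pairs = frozenset({("P1", "A1"), ("P1", "A2"), ("P2", "A1"), ("P2", "A3")})
    return phens, pairs


@pytest.fixture(scope="session")
def default_community():
    """One default-config synthetic community (seed 0) and its observations."""
    cfg = GeneratorConfig(seed=0)
    species, phen, pairs = generate_community(cfg)
    records = generate_observations(phen, pairs, cfg)
    return cfg, species, phen, pairs, records


@pytest.fixture(scope="session")
def default_static(default_community):
    _, _, phen, pairs, _ = default_community
    return build_network(phen, pairs)
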