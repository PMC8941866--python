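import pytest

import trophnet as tn
from trophnet.synthetic import FRACTIONS, TREATMENTS

#: 3 strains per treatment x fraction cell: 27 strains, 3 x C(9,2) = 108 pairs.
SMALL_CELL_COUNTS = {(t, f): 3 for t in TREATMENTS for f in FRACTIONS}


@pytest.fixture(scope="session")
def small_config():
    return tn.GeneratorConfig(cell_counts=SMALL_CELL_COUNTS)


@pytest.fixture(scope="session")
def small_run(small_config):
    """A small seeded community with its biofilm assays (shared, read-only)."""
    community = tn.generate_community(small_config, 7)
    assays = tn.generate_biofilm_assays(community, small_config, 7)
    return small_config, community, assays


@pytest.fixture(scope="session")
def default_run():
    """The full default community (122 strains, 2450 pairs), seeded."""
    config = tn.GeneratorConfig()
    community = tn.generate_community(config, 7)
    assays = tn.generate_biofilm_assays(community, config, 7)
    return config, community, assays


@pytest.fixture(scope="session")
def small_interactions(small_run):
    _, community, assays = small_run
    return tn.classify_all(assays.biofilm, community.metadata)
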