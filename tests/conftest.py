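"""Shared fixtures: simulated individuals and their mapped clone matrices."""

import pytest
from hypothesis import settings

from minihet.align import map_clones
from minihet.simulate import G_AUREI, T_MINOR, generate_bundle, generate_species_pair

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gaurei_bundle():
    return generate_bundle(G_AUREI, label="gaurei_sim")


@pytest.fixture(scope="session")
def gaurei_matrix(gaurei_bundle):
    return map_clones(gaurei_bundle.circle, gaurei_bundle.clones)


@pytest.fixture(scope="session")
def tminor_bundle():
    return generate_bundle(T_MINOR, label="tminor_sim")


@pytest.fixture(scope="session")
def tminor_matrix(tminor_bundle):
    return map_clones(tminor_bundle.circle, tminor_bundle.clones)


@pytest.fixture(scope="session")
def species_pair():
    return generate_species_pair(1)
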