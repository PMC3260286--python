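import numpy as np
import pytest

import barcodebench as bb


@pytest.fixture(scope="session")
def small_replicate():
    """A small but non-trivial simulated dataset shared across tests.

    10 species, 8 individuals each (6 reference + 2 query), 300 bp,
    moderate Ne — small enough to be fast, structured enough to exercise
    every matcher.
    """
    st = bb.simulate_yule_tree(10, 1e6, seed=11)
    cp = bb.CoalescentParams(ne=10000, samples_per_species=8)
    model = bb.SubstitutionModel(length=300)
    sim = bb.simulate_replicate(
        st, cp, bb.NoiseParams(0.7), model, n_ref=6, n_query=2, seed=12
    )
    return sim


@pytest.fixture(scope="session")
def fig1():
    return bb.fig1_fixture()
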