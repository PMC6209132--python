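import numpy as np
import pytest

import mitocmp as m


@pytest.fixture(scope="session")
def palmi():
    """The published 39-feature T. palmi gene table (no sequence)."""
    return m.thrips_palmi_table()


@pytest.fixture(scope="session")
def palmi_ledger(palmi):
    return m.ign_ledger(palmi)


@pytest.fixture(scope="session")
def ancestor():
    return m.ancestral_insect_order()


@pytest.fixture(scope="session")
def synthetic_genome():
    """A full-size synthetic genome on the published template, seed 1."""
    spec = m.SyntheticSpec(seed=1, origin_offset=175)
    return m.generate_genome(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
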