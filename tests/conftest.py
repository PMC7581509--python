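import numpy as np
import pytest

from fhtwohit import simulate as sim
from fhtwohit.datasets import fh_ul_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    """The bundled 13-sample FH-deficient UL cohort (printed values)."""
    return fh_ul_cohort()


@pytest.fixture(scope="session")
def toy():
    """Toy transcript + helix structure + domain map (seeded)."""
    return sim.make_toy_fixtures(seed=1)


@pytest.fixture(scope="session")
def helix20():
    """20-residue ideal helix used for exhaustive clustering oracles."""
    return sim.make_helix_structure(20)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
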