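import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from docknet.synthetic_data import assemble_complex, gen_toy_structures


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def half_sphere_pair():
    """Complementary cup/ball fixture at the planted pose."""
    return gen_toy_structures("half_sphere_pair", 30, seed=11)


@pytest.fixture(scope="session")
def half_sphere_complex(half_sphere_pair):
    receptor, ligand = half_sphere_pair
    return assemble_complex(receptor, ligand)
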