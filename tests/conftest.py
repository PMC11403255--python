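import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracles imports

from spinescreen.morphometry import NeuronRecord, SpineGeometry
from spinescreen.synthetic import b6_profile, btbr_profile

# Canonical in-class example geometries (length, head, neck) for each class.
MUSHROOM_GEOM = SpineGeometry(1.0, 0.50, 0.30)
THIN_GEOM = SpineGeometry(2.0, 0.25, 0.25)
STUBBY_GEOM = SpineGeometry(0.8, 0.30, 0.30)
FILOPODIUM_GEOM = SpineGeometry(4.0, 0.20, 0.10)


def make_neuron(
    n_mushroom=0, n_thin=0, n_stubby=0, n_filopodium=0,
    dendrite_length=20.0, damaged=False, neuron_id="n0",
) -> NeuronRecord:
    spines = (
        [MUSHROOM_GEOM] * n_mushroom
        + [THIN_GEOM] * n_thin
        + [STUBBY_GEOM] * n_stubby
        + [FILOPODIUM_GEOM] * n_filopodium
    )
    return NeuronRecord(neuron_id, spines, dendrite_length, damaged)


@pytest.fixture
def rng():
    return np.random.default_rng(20240829)


@pytest.fixture(scope="session")
def b6():
    return b6_profile()


@pytest.fixture(scope="session")
def btbr():
    return btbr_profile()
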