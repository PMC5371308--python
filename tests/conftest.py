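import numpy as np
import pytest

from marcpfs.envmap import MapConfig, generate_field
from marcpfs.params import Params


@pytest.fixture(scope="session")
def params():
    return Params()


@pytest.fixture(scope="session")
def reference_map():
    """One landscape at the reference condition (aggreg 3, 180 g/h, 150 km)."""
    return generate_field(MapConfig(aggreg=3, abund=180, dist=150, seed=42))


@pytest.fixture(scope="session")
def rich_uniform_map(reference_map):
    """Synthetic landscape with uniform rich cells everywhere food is allowed;
    removes search stochasticity for energetics-focused runs."""
    import copy

    m = copy.deepcopy(reference_map)
    vals = np.where(m.values > 0, 400.0, 0.0)
    m.values = vals
    return m
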