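import numpy as np
import pytest

from alfrange import GridSpec, gen_landscape


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def grid100():
    """100x100 cells of 30 m: a 3-km square landscape."""
    return GridSpec(0.0, 0.0, 30.0, 100, 100)


@pytest.fixture(scope="session")
def tile10km():
    """A 10-km tile: the availability domain exactly spans it."""
    return GridSpec(0.0, 0.0, 30.0, 334, 334)


@pytest.fixture(scope="session")
def winter_bundle(grid100):
    return gen_landscape(grid100, seed=42, season_month=2)
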