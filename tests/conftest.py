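import numpy as np
import pytest

from zeromark import BasisSpec, ChebyshevKey, PhantomSpec, SelectionKey, make_phantom


@pytest.fixture(scope="session")
def small_spec() -> BasisSpec:
    """Cheap basis for unit tests: 16x16 grid, degrees up to 6."""
    return BasisSpec(grid_n=16, nmax=6)


@pytest.fixture(scope="session")
def mid_spec() -> BasisSpec:
    """Basis sized for a 16x16 payload on a 64x64 carrier (pool 324 >= 256)."""
    return BasisSpec(grid_n=64, nmax=11)


@pytest.fixture(scope="session")
def keys() -> tuple[SelectionKey, ChebyshevKey]:
    return SelectionKey(42), ChebyshevKey(r=4.0, x0=0.631)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom64() -> np.ndarray:
    return make_phantom(PhantomSpec(side=64, seed=7))


@pytest.fixture(scope="session")
def phantom256() -> np.ndarray:
    return make_phantom(PhantomSpec(side=256, seed=7))
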