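import numpy as np
import pytest

from camonorm.illuminants import d65
from camonorm.spectra import Spectrum, StandardGrid
from camonorm.synthetic import ViewerFixtureSpec, make_sensitivity_set


@pytest.fixture(scope="session")
def grid() -> StandardGrid:
    return StandardGrid()


@pytest.fixture(scope="session")
def receptors(grid):
    return make_sensitivity_set(ViewerFixtureSpec(), grid)


@pytest.fixture(scope="session")
def illuminant(grid):
    return d65(grid)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def flat_spectrum(grid):
    def make(level: float, name: str = "flat") -> Spectrum:
        return Spectrum(grid.wavelengths,
                        np.full(len(grid), float(level)), name=name)
    return make
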