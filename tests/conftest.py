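import numpy as np
import pytest

from lottor.experiments import improvement_suite
from lottor.io_maps import DensityMap
from lottor.phantom import PhantomSpec, make_synthetic_phantom


@pytest.fixture(scope="session")
def phantom64():
    """Standard 64³ desk phantom, seed 1."""
    return make_synthetic_phantom(PhantomSpec(box=64, seed=1))


@pytest.fixture(scope="session")
def smooth_phantom48():
    """A small, smooth (band-limited) test object for interpolation-heavy ops."""
    n = 48
    c = n // 2
    x, y, z = np.meshgrid(*(np.arange(n, dtype=float) - c,) * 3, indexing="ij")
    values = (np.exp(-(x**2 + y**2 + z**2) / (2 * 5.0**2))
              + 0.6 * np.exp(-((x - 6) ** 2 + y**2 + (z + 3) ** 2) / (2 * 3.0**2)))
    return DensityMap(values, 1.0, label="smooth test object")


@pytest.fixture(scope="session")
def improvement_studies():
    """The standard 3-seed restoration experiment (shared: it is expensive)."""
    return improvement_suite(seeds=(1, 2, 3))
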