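import numpy as np
import pytest

from organseg.core import ImageGrid, default_registry
from organseg.phantom import (
    generate_phantom,
    make_organ_phantom_spec,
    make_spine_phantom_spec,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def organ_truth():
    """Three-organ phantom (lung / liver / hip bone) with 20 HU noise."""
    return generate_phantom(make_organ_phantom_spec(seed=7))


@pytest.fixture(scope="session")
def spine_truth():
    """Five-vertebra spine phantom with rib tubes."""
    return generate_phantom(make_spine_phantom_spec(seed=7, n_vertebrae=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_grid():
    return ImageGrid((8, 8, 8), (1.0, 1.0, 1.0))
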