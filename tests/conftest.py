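import numpy as np
import pytest

from condensax.geometry import MODEL_GEOMETRIES, Spherocylinder
from condensax.synthetic import default_link_populations, generate_xl_tables


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def model1_rod():
    return Spherocylinder(np.zeros(3), np.array([0.0, 0.0, 1.0]), 300.0, 12.0)


@pytest.fixture
def model1():
    return MODEL_GEOMETRIES["model1"]


@pytest.fixture(scope="session")
def xl_tables():
    """Synthetic identification + transition tables with known ground truth."""
    return generate_xl_tables(default_link_populations(), seed=123)
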