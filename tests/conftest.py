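import numpy as np
import pytest

from ihccal.colorimetry import XYZColor, cie_1931_cmf, d65_illuminant, srgb_matrix
from ihccal.synthetic import make_experiment, reference_chart_colors


@pytest.fixture(scope="session")
def C():
    return srgb_matrix()


@pytest.fixture(scope="session")
def white(C):
    return XYZColor(*(C.C @ np.ones(3)))


@pytest.fixture(scope="session")
def cmf():
    return cie_1931_cmf()


@pytest.fixture(scope="session")
def d65():
    return d65_illuminant()


@pytest.fixture(scope="session")
def chart_reference():
    return reference_chart_colors()


@pytest.fixture(scope="session")
def bundle():
    """The full 10-target synthetic experiment, rendered once per session."""
    return make_experiment(seed=7)
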