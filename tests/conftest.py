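import numpy as np
import pytest

from walkmet import Cohort
from walkmet.models import WOMEN_PIECEWISE, PolynomialMetModel


@pytest.fixture
def collinear_cohort():
    """Points exactly on M = 1 + 0.5 v: every unity-intercept line fit is exact."""
    v = np.array([1.0, 2.0, 3.0])
    return Cohort(v, 1.0 + 0.5 * v, "collinear")


@pytest.fixture
def noiseless_piecewise_cohort():
    """Dense noiseless sample from the women's reference piecewise model."""
    v = np.linspace(0.5, 8.0, 500)
    return Cohort(v, WOMEN_PIECEWISE.predict(v), "noiseless-pl")


@pytest.fixture
def noiseless_polynomial_cohort():
    """Noiseless sample from a cubic unity-intercept MET curve."""
    model = PolynomialMetModel((0.5, -0.03, 0.027))
    v = np.linspace(0.5, 8.0, 200)
    return Cohort(v, model.predict(v), "noiseless-pe"), model
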