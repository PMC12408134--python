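import numpy as np
import pytest

from redquant import BindingModel, REDGeometry, ResponseModel, StudyDesign


@pytest.fixture
def geometry() -> REDGeometry:
    return REDGeometry()


@pytest.fixture
def binding() -> BindingModel:
    return BindingModel(fu=0.05)


@pytest.fixture
def response() -> ResponseModel:
    return ResponseModel()


@pytest.fixture
def quiet_response() -> ResponseModel:
    """Noiseless, carry-over-free instrument response."""
    return ResponseModel(sigma_prop=0.0, sigma_add=0.0, carryover_frac=0.0)


@pytest.fixture
def design() -> StudyDesign:
    return StudyDesign()


def wls_normal_equations(x, y, w):
    """Independent brute-force weighted least-squares oracle.

    Solves the 2x2 weighted normal equations
        [S   Sx ] [a]   [Sy ]
        [Sx  Sxx] [b] = [Sxy]
    by elimination about the weighted means (algebraically identical,
    numerically stable):
        b = sum w (x - xw)(y - yw) / sum w (x - xw)^2,  a = yw - b xw
    """
    x, y, w = (np.asarray(v, dtype=float) for v in (x, y, w))
    xw = (w * x).sum() / w.sum()
    yw = (w * y).sum() / w.sum()
    slope = (w * (x - xw) * (y - yw)).sum() / (w * (x - xw) ** 2).sum()
    return slope, yw - slope * xw
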