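import numpy as np
import pytest

from seqeffort.growth_models import eval_weibull2, eval_weibull4
from seqeffort.rarefaction import curve_from_vector


@pytest.fixture
def weibull2_curve():
    """Noiseless 100-knot curve generated from W(x) = 1000 (1 - e^{-5e-6 x})."""
    x = np.round(np.linspace(1, 1_000_000, 100)).astype(int)
    return curve_from_vector(x, eval_weibull2(x, 1000.0, 5e-6)), {"a": 1000.0, "c": 5e-6}


@pytest.fixture
def weibull4_curve():
    """Noiseless 100-knot curve from a four-parameter Weibull sigmoid."""
    params = {"a": 2000.0, "b": 1800.0, "c": 1e-3, "m": 0.8}
    x = np.round(np.linspace(1, 30_000, 100)).astype(int)
    return curve_from_vector(x, eval_weibull4(x, **params)), params
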