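import numpy as np
import pytest

from hemocorr.correction import HemolysisIncrementModel
from hemocorr.simulate import NoiseModel, simulate_spiking_experiment


@pytest.fixture(scope="session")
def spiking_cohort():
    """Default seeded spiking experiment (253 aliquots)."""
    return simulate_spiking_experiment(noise=NoiseModel(seed=0))


@pytest.fixture(scope="session")
def fitted_model(spiking_cohort):
    """Increment line fitted from the default spiking run."""
    return HemolysisIncrementModel.from_cohort(spiking_cohort.frame).fit()


@pytest.fixture(scope="session")
def personalized(fitted_model):
    """Fitted line normalized by the spiking donor's NSE/HI ratio."""
    return fitted_model.personalize(0.31)


def ols_oracle(x, y):
    """Closed-form normal-equations least squares (independent of scipy)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept
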