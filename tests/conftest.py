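import numpy as np
import pytest

from phenolkin import (
    GompertzParams,
    HaldaneParams,
    LogisticParams,
    TimeSeries,
    default_truth,
)


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture
def logistic_200():
    return LogisticParams(X0=0.05, mu_m=0.300, X_m=0.293)


@pytest.fixture
def haldane_ref():
    return HaldaneParams(mu_max=2.28, K_s=4.3, K_i=291.0)


@pytest.fixture
def gompertz_700():
    return GompertzParams(S0=700.0, R_m=9.0, lam=10.2)


def make_series(times, values, kind="biomass", label="test", conc=None):
    return TimeSeries(times=np.asarray(times, dtype=float),
                      values=np.asarray(values, dtype=float),
                      kind=kind, condition_label=label, concentration=conc)


@pytest.fixture
def series_factory():
    return make_series
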