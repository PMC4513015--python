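import numpy as np
import pandas as pd
import pytest

from smcfcs.data_model import (
    CovariateModelSpec,
    SubstantiveModelSpec,
    linear,
    power,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def quadratic_spec():
    return SubstantiveModelSpec(
        family="normal", outcome="y", terms=(linear("x"), power("x", 2))
    )


@pytest.fixture
def quadratic_cov_specs():
    return [CovariateModelSpec("x", "normal")]


def make_missing_frame(n=20, seed=0, frac=0.3):
    """Small (y, x, z) frame with some x entries missing."""
    r = np.random.default_rng(seed)
    x = r.normal(2, 1, n)
    z = r.normal(0, 1, n)
    y = 4 - 4 * x + x**2 + r.normal(0, 1, n)
    xm = x.copy()
    xm[r.random(n) < frac] = np.nan
    if np.isnan(xm).all():
        xm[0] = x[0]
    return pd.DataFrame({"y": y, "x": xm, "z": z})
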