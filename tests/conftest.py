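import numpy as np
import pandas as pd
import pytest

from mixbalance import MixtureSample, simulation as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def e1y1_sample(rng):
    """One small replicate of the linear exposure / linear outcome design."""
    return sim.make_dataset("E1", "Y1", 300, 0.2, rng)


@pytest.fixture
def confounder_sample(e1y1_sample):
    """Same replicate with the weight models' confounder-only covariate view."""
    s = e1y1_sample
    return MixtureSample(s.exposures, s.covariates[["X1", "X2", "X3"]], s.outcome)


@pytest.fixture
def small_sample(rng):
    """Tiny generic sample (2 exposures, 2 covariates) with a known outcome."""
    n = 80
    X = rng.normal(size=(n, 2))
    T = X @ np.array([[0.8, 0.1], [0.2, 0.7]]) + rng.normal(size=(n, 2))
    y = T @ np.array([1.0, -0.5]) + X @ np.array([0.5, 0.5]) + rng.normal(size=n)
    return MixtureSample(
        exposures=pd.DataFrame(T, columns=["a", "b"]),
        covariates=pd.DataFrame(X, columns=["u", "v"]),
        outcome=pd.Series(y, name="y"),
    )
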