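import numpy as np
import pandas as pd
import pytest

from wlpred.rf import CVConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_cv():
    """Lightweight CV spec for tests where the fixed hyperparameters are
    not themselves under test (scaled down for runtime)."""
    return CVConfig(n_shuffles=3, n_folds=3, n_trees=15, seed=7)


def make_xy(n=120, n_noise=5, effect=0.0, seed=0, n_planted=1):
    """Balanced binary problem: `n_planted` features shifted by `effect` SDs
    in class 1, plus pure-noise features."""
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    rng.shuffle(y)
    cols = {}
    for j in range(n_planted):
        cols[f"planted_{j}"] = rng.normal(0, 1, n) + effect * y
    for j in range(n_noise):
        cols[f"noise_{j}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols, index=[f"S{i:04d}" for i in range(n)]), pd.Series(y)


@pytest.fixture
def xy_separable():
    X, y = make_xy(n=60, n_noise=2, effect=8.0, seed=1)
    return X, y


@pytest.fixture
def xy_null():
    X, y = make_xy(n=120, n_noise=4, effect=0.0, seed=2)
    return X, y
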