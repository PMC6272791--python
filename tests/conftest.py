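import numpy as np
import pandas as pd
import pytest

from plsvip import generate_synthetic_qsar, pretreat_pipeline, train_test_arrays


@pytest.fixture(scope="session")
def table3():
    """Observed/calculated CI arrays of the packaged placental dataset."""
    return train_test_arrays()


@pytest.fixture(scope="session")
def synth_default():
    """Default synthetic dataset with ground truth (seed 11)."""
    return generate_synthetic_qsar(seed=11)


@pytest.fixture(scope="session")
def synth_pretreated(synth_default):
    X, y, truth = synth_default
    Xp, log = pretreat_pipeline(X)
    return Xp, y, truth, log


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_strong_problem(n=40, m_noise=5, seed=0):
    """Small problem where y is an exact linear function of the first column."""
    r = np.random.default_rng(seed)
    x1 = r.standard_normal(n)
    X = np.column_stack([x1] + [r.standard_normal(n) for _ in range(m_noise)])
    y = 2.0 * x1
    cols = [f"x{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=cols), y
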