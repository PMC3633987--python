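import numpy as np
import pandas as pd
import pytest

import betaboost as bb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear_fixture():
    """Small variable-dispersion dataset with two active mean effects and
    one active precision effect among linear predictors."""
    rng = np.random.default_rng(42)
    n = 400
    X = rng.normal(0, 1, (n, 5))
    eta_mu = 0.3 + 0.8 * X[:, 0] - 0.8 * X[:, 1]
    eta_phi = 1.2 + 0.5 * X[:, 2]
    state = bb.make_state(eta_mu, eta_phi)
    sample = bb.sample_beta(state, seed=43)
    df = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(5)])
    return sample, df, X


def make_linear_learners(X, df_target=1.0):
    n = X.shape[0]
    learners = [bb.build_intercept(n)]
    for j in range(X.shape[1]):
        learners.append(bb.build_linear(X[:, j], f"x{j + 1}", df_target=df_target))
    return learners
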