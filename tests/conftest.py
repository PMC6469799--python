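import numpy as np
import pytest

from rgwas.mfmr import CovariateSet, FitOptions, TraitMatrix
from rgwas.simulate import make_scenario

FAST_FIT = dict(n_restarts=2, max_iter=150, rel_tol=1e-6)


def fast_opts(K=2, seed=0, **kw):
    merged = {**FAST_FIT, **kw}
    return FitOptions(K=K, seed=seed, **merged)


def onehot(labels, k=None):
    labels = np.asarray(labels, dtype=int)
    k = k or labels.max()
    return np.eye(k)[labels - 1].astype(float)


def small_regression_data(seed=0, n=250, q=2):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, q))
    y = x @ rng.standard_normal(q) + 1.5 + rng.standard_normal(n)
    traits = TraitMatrix(quant=y[:, None], binary=np.zeros((n, 0)))
    cov = CovariateSet(homogeneous=x, heterogeneous=np.ones((n, 1)))
    return traits, cov, x, y


@pytest.fixture(scope="session")
def baseline_k2():
    """One moderately sized two-subtype draw shared across tests."""
    return make_scenario("baseline_k2", {"n_samples": 2000}, seed=42)


@pytest.fixture(scope="session")
def baseline_k1():
    return make_scenario("baseline_k1", {"n_samples": 2000}, seed=43)
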