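import numpy as np
import pytest

from mvhmm.data import FourWayData
from mvhmm.inference import HMMParams
from mvhmm.parsimony import CovDecomposition, decompose


def random_spd(rng, q, jitter=0.5):
    """A well-conditioned random symmetric positive definite matrix."""
    a = rng.standard_normal((q, q))
    return a @ a.T + (jitter + q) * np.eye(q)


def random_unit_det_spd(rng, q):
    """Random SPD matrix scaled to unit determinant."""
    m = random_spd(rng, q)
    sign, logdet = np.linalg.slogdet(m)
    return m / np.exp(logdet / q)


def decomp_from_matrices(mats):
    """CovDecomposition from a stack of SPD matrices."""
    mats = np.asarray(mats, dtype=float)
    K, Q = mats.shape[0], mats.shape[1]
    lam = np.empty(K)
    Gam = np.empty((K, Q, Q))
    Del = np.empty((K, Q))
    for k in range(K):
        lam[k], Gam[k], Del[k] = decompose(mats[k])
    return CovDecomposition(lam, Gam, Del)


def random_hmm_params(rng, K=2, P=2, R=2, mean_scale=2.0):
    """A valid random HMM parameter set with unit-determinant Psi_k."""
    pi = rng.dirichlet(np.ones(K))
    Pi = rng.dirichlet(np.ones(K), size=K)
    means = rng.standard_normal((K, P, R)) * mean_scale
    sigma = decomp_from_matrices([random_spd(rng, P) for _ in range(K)])
    psi = decomp_from_matrices([random_unit_det_spd(rng, R) for _ in range(K)])
    return HMMParams(pi, Pi, means, sigma, psi)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_data(rng):
    """A tiny balanced four-way dataset (pure noise)."""
    return FourWayData(rng.standard_normal((6, 4, 2, 2)))
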