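"""Hidden-chain inference: scaled forward-backward, smoothed posteriors,
sequence log-likelihood and local decoding.

Units are independent given the parameters, so all recursions run
vectorized across the I units.  Scaling follows the classical normalized
forward-variable scheme: at each occasion the forward vector is divided by
its sum, the log scale factors accumulate into the log-likelihood, and the
backward recursion reuses the same constants.  State-dependent log-densities
are additionally max-shifted per (unit, occasion) before exponentiation so
that sequences whose densities span hundreds of log-units neither overflow
nor underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FourWayData
from .errors import DimensionError, UnderflowError
from .parsimony import COL_CODES, ROW_CODES, CovDecomposition

__all__ = ["HMMParams", "ForwardBackward", "Posteriors", "forward_backward",
           "posteriors", "decode_local"]

_SIMPLEX_TOL = 1e-8


def _check_simplex(vec: np.ndarray, what: str) -> None:
    if vec.min(initial=0.0) < -1e-12 or np.abs(
        vec.sum(axis=-1) - 1.0
    ).max() > _SIMPLEX_TOL:
        raise DimensionError(f"{what} is not a probability vector: {vec}")


@dataclass
class HMMParams:
    """Parameters of one matrix-variate HMM.

    pi is the K-vector of initial state probabilities, Pi the K x K
    transition matrix (row j holds the law of the next state given current
    state j), means the (K, P, R) stack of state mean matrices, and
    sigma / psi the eigen decompositions of the row and (unit-determinant)
    column covariances.
    """

    pi: np.ndarray
    Pi: np.ndarray
    means: np.ndarray
    sigma: CovDecomposition
    psi: CovDecomposition
    row_code: str = "VVV"
    col_code: str = "VV"

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.Pi = np.asarray(self.Pi, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if self.means.ndim != 3:
            raise DimensionError("means must have shape (K, P, R)")
        K = self.means.shape[0]
        if self.pi.shape != (K,) or self.Pi.shape != (K, K):
            raise DimensionError("pi/Pi shapes do not match the number of states")
        _check_simplex(self.pi, "pi")
        _check_simplex(self.Pi, "a row of Pi")
        if self.row_code not in ROW_CODES:
            raise ValueError(f"unknown row structure {self.row_code!r}")
        if self.col_code not in COL_CODES:
            raise ValueError(f"unknown column structure {self.col_code!r}")

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def P(self) -> int:
        return self.means.shape[1]

    @property
    def R(self) -> int:
        return self.means.shape[2]

    def state_log_densities(self, values: np.ndarray) -> np.ndarray:
        """Log matrix-normal densities, shape (I, T, K).

        Inverses and log-determinants come analytically from the eigen
        components (Sigma^-1 = Gamma diag(1/(lam Delta)) Gamma',
        log|Sigma| = P log lam), so the whole K-state evaluation is a single
        batched contraction.
        """
        P, R = self.P, self.R
        D = values[None] - self.means[:, None, None]  # (K, I, T, P, R)
        quad = np.einsum(
            "kpq,kitqr,krs,kitps->kit",
            self.sigma.inverses(), D, self.psi.inverses(), D,
            optimize=True,
        )
        logdet = (
            R * self.sigma.log_dets() + P * self.psi.log_dets()
        )  # per state
        const = -0.5 * P * R * np.log(2.0 * np.pi)
        out = const - 0.5 * logdet[:, None, None] - 0.5 * quad
        return out.transpose(1, 2, 0)


@dataclass
class ForwardBackward:
    """Scaled forward/backward variables and per-(i, t) scaling constants.

    ``gamma`` holds the normalized forward variables (each (i, t) slice sums
    to one), ``beta`` the correspondingly scaled backward variables, and
    ``log_scale`` the per-occasion log normalizers, whose row sums are the
    per-unit log-likelihoods.
    """

    gamma: np.ndarray
    beta: np.ndarray
    log_scale: np.ndarray

    @property
    def per_unit_loglik(self) -> np.ndarray:
        return self.log_scale.sum(axis=1)

    @property
    def loglik(self) -> float:
        return float(self.log_scale.sum())


@dataclass
class Posteriors:
    """Smoothed memberships z (I, T, K), transition posteriors zz
    (I, T-1, K, K) indexed (from-state j, to-state k), and log-likelihoods."""

    z: np.ndarray
    zz: np.ndarray
    loglik: float
    per_unit_loglik: np.ndarray


def _forward_backward_arrays(
    logB: np.ndarray, pi: np.ndarray, Pi: np.ndarray
) -> tuple[ForwardBackward, np.ndarray]:
    I, T, K = logB.shape
    shift = logB.max(axis=2)
    b = np.exp(logB - shift[:, :, None])  # (I, T, K), max entry 1 per (i, t)

    gamma = np.empty((I, T, K))
    c = np.empty((I, T))
    a = pi[None, :] * b[:, 0]
    s = a.sum(axis=1)
    if np.any(s <= 0):
        i = int(np.argmax(s <= 0))
        raise UnderflowError(i, 0)
    gamma[:, 0] = a / s[:, None]
    c[:, 0] = s
    for t in range(1, T):
        a = (gamma[:, t - 1] @ Pi) * b[:, t]
        s = a.sum(axis=1)
        if np.any(s <= 0):
            i = int(np.argmax(s <= 0))
            raise UnderflowError(i, t)
        gamma[:, t] = a / s[:, None]
        c[:, t] = s

    beta = np.empty((I, T, K))
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = (b[:, t + 1] * beta[:, t + 1]) @ Pi.T / c[:, t + 1, None]

    return ForwardBackward(gamma=gamma, beta=beta, log_scale=np.log(c) + shift), b


def forward_backward(data: FourWayData, params: HMMParams) -> ForwardBackward:
    """Scaled forward-backward recursions for every unit.

    The per-unit log-likelihood equals the log of the matrix product
    pi' diag(phi(X_i1)) Pi diag(phi(X_i2)) ... Pi diag(phi(X_iT)) 1.
    """
    if data.values.shape[2:] != (params.P, params.R):
        raise DimensionError(
            f"data matrices are {data.values.shape[2:]}, parameters expect "
            f"{(params.P, params.R)}"
        )
    logB = params.state_log_densities(data.values)
    fb, _ = _forward_backward_arrays(logB, params.pi, params.Pi)
    return fb


def _posteriors_arrays(
    fb: ForwardBackward, b: np.ndarray, Pi: np.ndarray, c: np.ndarray
) -> Posteriors:
    z = fb.gamma * fb.beta
    z /= z.sum(axis=2, keepdims=True)
    # zz[i, t-1, j, k] = gamma[i, t-1, j] Pi[j, k] b[i, t, k] beta[i, t, k] / c[i, t]
    zz = (
        fb.gamma[:, :-1, :, None]
        * Pi[None, None, :, :]
        * (b[:, 1:, None, :] * fb.beta[:, 1:, None, :])
        / c[:, 1:, None, None]
    )
    return Posteriors(
        z=z, zz=zz, loglik=fb.loglik, per_unit_loglik=fb.per_unit_loglik
    )


def posteriors(fb: ForwardBackward, data: FourWayData, params: HMMParams) -> Posteriors:
    """Smoothed state memberships and transition posteriors from the
    forward/backward variables."""
    logB = params.state_log_densities(data.values)
    if logB.shape != fb.gamma.shape:
        raise DimensionError("forward-backward variables do not match the data")
    shift = logB.max(axis=2)
    b = np.exp(logB - shift[:, :, None])
    c = np.exp(fb.log_scale - shift)
    return _posteriors_arrays(fb, b, params.Pi, c)


def loglik_only(data_values: np.ndarray, params: HMMParams) -> float:
    """Total log-likelihood via the forward recursion alone (no backward
    pass, no posteriors); used to score short-EM candidates cheaply."""
    logB = params.state_log_densities(data_values)
    shift = logB.max(axis=2)
    b = np.exp(logB - shift[:, :, None])
    T = logB.shape[1]
    a = params.pi[None, :] * b[:, 0]
    s = a.sum(axis=1)
    if np.any(s <= 0):
        raise UnderflowError(int(np.argmax(s <= 0)), 0)
    total = np.log(s)
    g = a / s[:, None]
    for t in range(1, T):
        a = (g @ params.Pi) * b[:, t]
        s = a.sum(axis=1)
        if np.any(s <= 0):
            raise UnderflowError(int(np.argmax(s <= 0)), t)
        total += np.log(s)
        g = a / s[:, None]
    return float(total.sum() + shift.sum())


def estep(data_values: np.ndarray, params: HMMParams) -> Posteriors:
    """One-shot E-step: densities, recursions and posteriors together."""
    logB = params.state_log_densities(data_values)
    fb, b = _forward_backward_arrays(logB, params.pi, params.Pi)
    c = np.exp(fb.log_scale - logB.max(axis=2))
    return _posteriors_arrays(fb, b, params.Pi, c)


def decode_local(post: Posteriors) -> np.ndarray:
    """Local (posterior-mode) decoding: argmax_k z[i, t, k].

    Ties break toward the smallest state index.  Returns integer labels of
    shape (I, T), states numbered from 0.
    """
    return np.argmax(post.z, axis=2)
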