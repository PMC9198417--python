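"""Matrix-normal distribution: density evaluation and sampling.

A random P x R matrix X follows a matrix-normal law MN(M, Sigma, Psi) when
vec(X) is multivariate normal with mean vec(M) and covariance Psi ⊗ Sigma
(column-stacking convention).  Sigma (P x P) carries the covariances between
the rows of X, Psi (R x R) those between the columns.  The pair
(Sigma, Psi) is identified only up to a reciprocal scalar: (a Sigma,
a^-1 Psi) gives the same law, which is why hidden-state column covariances
are constrained to unit determinant elsewhere in this package.

All determinants and quadratic forms are computed through Cholesky factors;
no covariance is ever inverted explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .errors import DimensionError, NotPositiveDefiniteError

__all__ = ["MatrixNormalParams", "log_density", "log_density_stack", "sample"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _chol_lower(mat: np.ndarray, name: str) -> np.ndarray:
    """Lower Cholesky factor of a symmetric PD matrix, or a named error."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise DimensionError(f"{name} must be square, got shape {mat.shape}")
    if np.abs(mat - mat.T).max(initial=0.0) > 1e-10:
        raise NotPositiveDefiniteError(f"{name} is not symmetric")
    try:
        return cholesky(mat, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise NotPositiveDefiniteError(f"{name} is not positive definite") from exc
    except Exception as exc:
        raise NotPositiveDefiniteError(f"{name} is not positive definite") from exc


@dataclass
class MatrixNormalParams:
    """Parameters (M, Sigma, Psi) of one matrix-normal law.

    M is the P x R mean matrix, Sigma the P x P row covariance, Psi the
    R x R column covariance.  Cholesky factors are cached on construction.
    """

    M: np.ndarray
    Sigma: np.ndarray
    Psi: np.ndarray
    _chol_sigma: np.ndarray = field(init=False, repr=False)
    _chol_psi: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2:
            raise DimensionError(f"M must be a matrix, got ndim={self.M.ndim}")
        self._chol_sigma = _chol_lower(self.Sigma, "Sigma")
        self._chol_psi = _chol_lower(self.Psi, "Psi")
        P, R = self.M.shape
        if self._chol_sigma.shape[0] != P:
            raise DimensionError(
                f"Sigma is {self._chol_sigma.shape[0]}x{self._chol_sigma.shape[0]} "
                f"but M has {P} rows"
            )
        if self._chol_psi.shape[0] != R:
            raise DimensionError(
                f"Psi is {self._chol_psi.shape[0]}x{self._chol_psi.shape[0]} "
                f"but M has {R} columns"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape

    @property
    def log_det_sigma(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self._chol_sigma))))

    @property
    def log_det_psi(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self._chol_psi))))


def log_density_stack(
    X: np.ndarray, M: np.ndarray, Sigma: np.ndarray, Psi: np.ndarray
) -> np.ndarray:
    """Matrix-normal log-density for a stack of observations.

    Parameters
    ----------
    X : array of shape (..., P, R)
    M, Sigma, Psi : mean and covariances of one matrix-normal law.

    Returns
    -------
    array of shape (...,) of log-density values.
    """
    params = (
        MatrixNormalParams(M, Sigma, Psi)
        if not isinstance(M, MatrixNormalParams)
        else M
    )
    return _log_density_impl(np.asarray(X, dtype=float), params)


def _log_density_impl(X: np.ndarray, params: MatrixNormalParams) -> np.ndarray:
    P, R = params.shape
    if X.shape[-2:] != (P, R):
        raise DimensionError(
            f"observation shape {X.shape[-2:]} does not match mean shape {(P, R)}"
        )
    lead = X.shape[:-2]
    D = (X - params.M).reshape(-1, P, R)
    n = D.shape[0]
    # tr[Sigma^-1 D Psi^-1 D'] = || L_S^-1 D L_P^-T ||_F^2
    U = solve_triangular(
        params._chol_sigma,
        D.transpose(1, 0, 2).reshape(P, n * R),
        lower=True,
        check_finite=False,
    ).reshape(P, n, R)
    V = solve_triangular(
        params._chol_psi,
        U.transpose(2, 1, 0).reshape(R, n * P),
        lower=True,
        check_finite=False,
    ).reshape(R, n, P)
    quad = np.einsum("rnp,rnp->n", V, V)
    out = (
        -0.5 * P * R * _LOG_2PI
        - 0.5 * R * params.log_det_sigma
        - 0.5 * P * params.log_det_psi
        - 0.5 * quad
    )
    return out.reshape(lead)


def log_density(X: np.ndarray, params: MatrixNormalParams) -> float:
    """Log-density of a single P x R observation under ``params``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimensionError(f"X must be a matrix, got ndim={X.ndim}")
    return float(_log_density_impl(X, params))


def sample(
    params: MatrixNormalParams,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` matrices X = M + A Z B' with A A' = Sigma, B B' = Psi.

    A and B are the lower-triangular Cholesky factors, so draws are
    reproducible across platforms for a fixed seed.  Returns an array of
    shape (n, P, R).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    P, R = params.shape
    Z = rng.standard_normal((n, P, R))
    A = params._chol_sigma
    B = params._chol_psi
    return params.M + np.einsum("pq,nqr,sr->nps", A, Z, B)
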