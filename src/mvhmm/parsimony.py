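"""Parsimonious covariance structures via the eigen (volume/shape/orientation)
decomposition.

Any Q x Q covariance can be written Phi_k = lam_k * Gamma_k Delta_k Gamma_k',
with lam_k = |Phi_k|^(1/Q) the volume, Gamma_k an orthogonal orientation
matrix and Delta_k a unit-determinant diagonal shape matrix.  Constraining
each component to be equal (E) or variable (V) across hidden states, or
fixing it to the identity (I, spherical/axis-aligned cases), yields 14
structures for the row covariance Sigma_k.  The column covariance Psi_k is
restricted to unit determinant (see :mod:`mvhmm.matrix_normal` on the
Kronecker identifiability degeneracy), which removes its volume parameter
and leaves 7 structures; the family therefore has 14 x 7 = 98 members.

This module provides parameter counting, the conditional M-step estimators
for every structure (built from responsibility-weighted scatter matrices),
the minorization-maximization (MM) update for a shared orientation with
state-specific shapes, and the eigen update for state-specific orientations
with a shared shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateStateError, NotPositiveDefiniteError

__all__ = [
    "ROW_CODES",
    "COL_CODES",
    "family",
    "count_row_params",
    "count_col_params",
    "CovDecomposition",
    "ScatterSet",
    "assemble",
    "decompose",
    "mm_rotation",
    "update_sigma",
    "update_psi",
]

#: Admissible row-covariance structure codes (volume, shape, orientation).
ROW_CODES: tuple[str, ...] = (
    "EII", "VII", "EEI", "VEI", "EVI", "VVI", "EEE",
    "VEE", "EVE", "VVE", "EEV", "VEV", "EVV", "VVV",
)

#: Admissible column-covariance codes (shape, orientation; volume fixed by
#: the unit-determinant restriction).
COL_CODES: tuple[str, ...] = ("II", "EI", "VI", "EE", "VE", "EV", "VV")

_WEIGHT_TOL = 1e-8


def family() -> list[str]:
    """All 98 admissible "ROW-COL" structure pairs."""
    return [f"{r}-{c}" for r in ROW_CODES for c in COL_CODES]


def count_row_params(code: str, K: int, Q: int) -> int:
    """Number of free covariance parameters of a row structure.

    ``K`` is the number of hidden states and ``Q`` the matrix side length.
    """
    if K < 1 or Q < 1:
        raise ValueError("K and Q must be >= 1")
    counts = {
        "EII": 1,
        "VII": K,
        "EEI": Q,
        "VEI": K + Q - 1,
        "EVI": K * (Q - 1) + 1,
        "VVI": K * Q,
        "EEE": Q * (Q + 1) // 2,
        "VEE": Q * (Q + 1) // 2 + K - 1,
        "EVE": Q * (Q - 1) // 2 + K * (Q - 1) + 1,
        "VVE": Q * (Q - 1) // 2 + K * Q,
        "EEV": K * Q * (Q - 1) // 2 + Q,
        "VEV": K * Q * (Q - 1) // 2 + K + Q - 1,
        "EVV": K * Q * (Q + 1) // 2 - K + 1,
        "VVV": K * Q * (Q + 1) // 2,
    }
    try:
        return counts[code]
    except KeyError:
        raise ValueError(
            f"unknown row structure {code!r}; admissible: {', '.join(ROW_CODES)}"
        ) from None


def count_col_params(code: str, K: int, Q: int) -> int:
    """Number of free parameters of a (unit-determinant) column structure.

    Each count is the corresponding row-structure count minus its volume
    parameter(s).
    """
    if K < 1 or Q < 1:
        raise ValueError("K and Q must be >= 1")
    counts = {
        "II": 0,
        "EI": Q - 1,
        "VI": K * (Q - 1),
        "EE": Q * (Q + 1) // 2 - 1,
        "VE": Q * (Q - 1) // 2 + K * (Q - 1),
        "EV": K * Q * (Q - 1) // 2 + Q - 1,
        "VV": K * Q * (Q + 1) // 2 - K,
    }
    try:
        return counts[code]
    except KeyError:
        raise ValueError(
            f"unknown column structure {code!r}; admissible: {', '.join(COL_CODES)}"
        ) from None


@dataclass
class CovDecomposition:
    """Per-state eigen components (lam, Gamma, Delta) of K covariances.

    lam has shape (K,), Gamma (K, Q, Q) with orthogonal slices, Delta (K, Q)
    holding the unit-determinant diagonal shapes.  Components constrained to
    be equal across states are stored as identical rows/slices.
    """

    lam: np.ndarray
    Gamma: np.ndarray
    Delta: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.Delta = np.asarray(self.Delta, dtype=float)
        # fail fast on collapsed states instead of propagating NaN/inf
        if not np.all(np.isfinite(self.lam)) or self.lam.min(initial=1.0) <= 0:
            raise NotPositiveDefiniteError("non-positive covariance volume")
        if not np.all(np.isfinite(self.Delta)) or self.Delta.min(initial=1.0) <= 0:
            raise NotPositiveDefiniteError("non-positive covariance shape entry")

    @property
    def K(self) -> int:
        return self.lam.shape[0]

    @property
    def Q(self) -> int:
        return self.Gamma.shape[-1]

    @classmethod
    def identity(cls, K: int, Q: int) -> "CovDecomposition":
        """K copies of the identity covariance."""
        return cls(
            lam=np.ones(K),
            Gamma=np.broadcast_to(np.eye(Q), (K, Q, Q)).copy(),
            Delta=np.ones((K, Q)),
        )

    def matrices(self) -> np.ndarray:
        """Assembled covariances, shape (K, Q, Q)."""
        scaled = self.Gamma * self.Delta[:, None, :]  # Gamma @ diag(Delta)
        out = scaled @ self.Gamma.transpose(0, 2, 1)
        out *= self.lam[:, None, None]
        return 0.5 * (out + out.transpose(0, 2, 1))

    def inverses(self) -> np.ndarray:
        """Inverse covariances, shape (K, Q, Q), from the eigen components."""
        scaled = self.Gamma / self.Delta[:, None, :]
        out = scaled @ self.Gamma.transpose(0, 2, 1)
        out /= self.lam[:, None, None]
        return 0.5 * (out + out.transpose(0, 2, 1))

    def log_dets(self) -> np.ndarray:
        """log |Phi_k| = Q log lam_k (Delta has unit determinant)."""
        return self.Q * np.log(self.lam)


@dataclass
class ScatterSet:
    """Responsibility-weighted scatter matrices for the K states.

    ``S`` holds the per-state Q x Q scatters (row side: the within-state row
    scatter built with the current column-covariance inverse; column side:
    vice versa) and ``n`` the per-state total responsibilities.
    """

    S: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.n = np.atleast_1d(np.asarray(self.n, dtype=float))
        # symmetrize to control floating-point drift from the accumulation
        self.S = 0.5 * (self.S + self.S.transpose(0, 2, 1))

    @property
    def total(self) -> np.ndarray:
        return self.S.sum(axis=0)

    def check_weights(self) -> None:
        bad = np.flatnonzero(self.n < _WEIGHT_TOL)
        if bad.size:
            raise DegenerateStateError(int(bad[0]), float(self.n[bad[0]]))


def assemble(lam: float, Gamma: np.ndarray, Delta: np.ndarray) -> np.ndarray:
    """Assemble lam * Gamma diag(Delta) Gamma' for a single state."""
    Gamma = np.asarray(Gamma, dtype=float)
    d = np.asarray(Delta, dtype=float)
    if d.ndim == 2:
        d = np.diag(d)
    out = float(lam) * (Gamma * d) @ Gamma.T
    return 0.5 * (out + out.T)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each eigenvector column positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def _eig_desc(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvectors (sign-fixed) and eigenvalues of a symmetric matrix,
    eigenvalues in descending order."""
    w, v = np.linalg.eigh(0.5 * (mat + mat.T))
    order = np.argsort(w, kind="stable")[::-1]
    return _fix_signs(v[:, order]), w[order]


def decompose(Phi: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Split a symmetric PD matrix into (volume, orientation, shape).

    Returns (lam, Gamma, Delta) with lam = |Phi|^(1/Q), Gamma orthogonal
    (descending eigenvalue order, sign-fixed columns) and Delta the
    unit-determinant vector of scaled eigenvalues.
    """
    Phi = np.asarray(Phi, dtype=float)
    Q = Phi.shape[0]
    Gamma, w = _eig_desc(Phi)
    if np.any(w <= 0):
        raise NotPositiveDefiniteError("matrix passed to decompose is not PD")
    lam = float(np.exp(np.mean(np.log(w))))
    return lam, Gamma, w / lam


def _norm_diag(d: np.ndarray, Q: int) -> tuple[np.ndarray, float]:
    """Scale a positive vector to unit geometric mean; return (shape, scale).

    ``scale`` is |diag(d)|^(1/Q), so d = scale * shape with |shape| = 1.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise NotPositiveDefiniteError("scatter has a non-positive diagonal element")
    scale = float(np.exp(np.mean(np.log(d))))
    return d / scale, scale


def _det_root(mat: np.ndarray, Q: int) -> float:
    """|mat|^(1/Q) via slogdet, requiring a positive determinant."""
    sign, logdet = np.linalg.slogdet(mat)
    if sign <= 0:
        raise NotPositiveDefiniteError("scatter matrix is singular or indefinite")
    return float(np.exp(logdet / Q))


def _mm_criterion(scatters: np.ndarray, inv_shapes: np.ndarray, G: np.ndarray) -> float:
    # sum_k tr(Y_k G Delta_k^-1 G') = sum_k sum_q inv_shape_kq * (G' Y_k G)_qq
    rotated = np.einsum("pq,kpr,rs->kqs", G, scatters, G)
    return float(np.einsum("kqq,kq->", rotated, inv_shapes))


def mm_rotation(
    scatters: np.ndarray,
    shapes: np.ndarray,
    init: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Shared orthogonal orientation by minorization-maximization.

    Minimizes g(Gamma) = sum_k tr(Y_k Gamma Delta_k^-1 Gamma') over the
    orthogonal group, Y_k the per-state scatters and Delta_k fixed diagonal
    shapes.  Each sweep majorizes g by the tangent plane of its concave part
    (using e_k, the largest eigenvalue of Y_k) and minimizes the resulting
    linear function tr(F Gamma) through the singular value decomposition of
    F = sum_k Delta_k^-1 Gamma' (Y_k - e_k I); the criterion is
    non-increasing across sweeps.  Stops when the criterion improves by less
    than ``tol`` or after ``max_iter`` sweeps.
    """
    scatters = np.asarray(scatters, dtype=float)
    shapes = np.atleast_2d(np.asarray(shapes, dtype=float))
    G = np.asarray(init, dtype=float)
    Q = G.shape[0]
    eye = np.eye(Q)
    if np.abs(G @ G.T - eye).max() > 1e-8:
        raise ValueError("mm_rotation init must be orthogonal")
    inv_shapes = 1.0 / shapes
    e = np.linalg.eigvalsh(scatters)[:, -1]  # largest eigenvalue per state
    shifted = scatters - e[:, None, None] * eye
    crit = _mm_criterion(scatters, inv_shapes, G)
    for _ in range(max_iter):
        F = np.einsum("kq,pq,kpr->qr", inv_shapes, G, shifted)
        U, _, Vt = np.linalg.svd(F)
        G_new = -(Vt.T @ U.T)
        crit_new = _mm_criterion(scatters, inv_shapes, G_new)
        if crit_new > crit + 1e-12:  # safeguard; MM guarantees descent
            break
        improved = crit - crit_new
        G, crit = G_new, crit_new
        if improved < tol:
            break
    return G


def update_sigma(
    code: str,
    scatters: ScatterSet,
    prev: CovDecomposition,
    dims: tuple[int, int, int, int],
    mm_max_iter: int = 1000,
    mm_tol: float = 1e-10,
) -> CovDecomposition:
    """Conditional M-step update of the row covariances Sigma_1..Sigma_K.

    ``scatters`` holds the within-state row scatters Y_k (built with the
    current responsibilities and the previous column-covariance inverses)
    and the state weights n_k.  ``prev`` supplies previous-iteration volumes
    and orientation where the conditional update needs them (VEI, VEE, VEV,
    EVE, VVE).  ``dims`` is (P, R, T, I).
    """
    P, R, T, I = dims
    scatters.check_weights()
    Yk, n = scatters.S, scatters.n
    K = Yk.shape[0]
    Y = scatters.total
    eye = np.broadcast_to(np.eye(P), (K, P, P)).copy()
    ones = np.ones((K, P))

    if code == "EII":
        lam = np.trace(Y) / (P * R * T * I)
        return CovDecomposition(np.full(K, lam), eye, ones)
    if code == "VII":
        lam = np.einsum("kpp->k", Yk) / (P * R * n)
        return CovDecomposition(lam, eye, ones)
    if code == "EEI":
        delta, scale = _norm_diag(np.diagonal(Y), P)
        lam = scale / (R * T * I)
        return CovDecomposition(np.full(K, lam), eye, np.tile(delta, (K, 1)))
    if code == "VEI":
        pooled = np.einsum("k,kpq->pq", 1.0 / prev.lam, Yk)
        delta, _ = _norm_diag(np.diagonal(pooled), P)
        lam = np.einsum("kp,p->k", np.diagonal(Yk, axis1=1, axis2=2), 1.0 / delta) / (
            P * R * n
        )
        return CovDecomposition(lam, eye, np.tile(delta, (K, 1)))
    if code == "EVI":
        diags = np.diagonal(Yk, axis1=1, axis2=2)
        if np.any(diags <= 0):
            raise NotPositiveDefiniteError("state scatter has non-positive diagonal")
        scales = np.exp(np.mean(np.log(diags), axis=1))
        deltas = diags / scales[:, None]
        lam = scales.sum() / (R * T * I)
        return CovDecomposition(np.full(K, lam), eye, deltas)
    if code == "VVI":
        diags = np.diagonal(Yk, axis1=1, axis2=2)
        if np.any(diags <= 0):
            raise NotPositiveDefiniteError("state scatter has non-positive diagonal")
        scales = np.exp(np.mean(np.log(diags), axis=1))
        deltas = diags / scales[:, None]
        lam = scales / (R * n)
        return CovDecomposition(lam, eye, deltas)
    if code == "EEE":
        lam, G, d = decompose(Y / (R * T * I))
        return CovDecomposition(
            np.full(K, lam), np.tile(G, (K, 1, 1)), np.tile(d, (K, 1))
        )
    if code == "VEE":
        pooled = np.einsum("k,kpq->pq", 1.0 / prev.lam, Yk)
        C = pooled / _det_root(pooled, P)
        _, G, d = decompose(C)
        Cinv = (G / d[None, :]) @ G.T
        lam = np.einsum("pq,kqp->k", Cinv, Yk) / (P * R * n)
        return CovDecomposition(lam, np.tile(G, (K, 1, 1)), np.tile(d, (K, 1)))
    if code in ("EVE", "VVE"):
        # rotation criterion weights each scatter by the previous inverse
        # volume; for a shared volume (EVE) this leaves the minimizer
        # unchanged, for VVE it is what keeps the conditional update an
        # ascent step
        G = mm_rotation(
            Yk / prev.lam[:, None, None], prev.Delta, prev.Gamma[0],
            max_iter=mm_max_iter, tol=mm_tol,
        )
        rotated = np.einsum("pq,kpr,rs->kqs", G, Yk, G)
        diags = np.diagonal(rotated, axis1=1, axis2=2)
        if np.any(diags <= 0):
            raise NotPositiveDefiniteError("rotated scatter has non-positive diagonal")
        scales = np.exp(np.mean(np.log(diags), axis=1))
        deltas = diags / scales[:, None]
        if code == "EVE":
            lam_val = float(np.sum(diags / deltas)) / (P * R * T * I)
            lam = np.full(K, lam_val)
        else:
            lam = scales / (R * n)
        return CovDecomposition(lam, np.tile(G, (K, 1, 1)), deltas)
    if code in ("EEV", "VEV"):
        Gk = np.empty((K, P, P))
        Om = np.empty((K, P))
        for k in range(K):
            Gk[k], Om[k] = _eig_desc(Yk[k])
        if code == "EEV":
            s = Om.sum(axis=0)
        else:
            s = np.einsum("k,kp->p", 1.0 / prev.lam, Om)
        delta, scale = _norm_diag(s, P)
        if code == "EEV":
            lam = np.full(K, scale / (R * T * I))
        else:
            lam = np.einsum("kp,p->k", Om, 1.0 / delta) / (P * R * n)
        return CovDecomposition(lam, Gk, np.tile(delta, (K, 1)))
    if code == "EVV":
        roots = np.array([_det_root(Yk[k], P) for k in range(K)])
        lam = np.full(K, roots.sum() / (R * T * I))
        Gk = np.empty((K, P, P))
        Dk = np.empty((K, P))
        for k in range(K):
            _, Gk[k], Dk[k] = decompose(Yk[k] / roots[k])
        return CovDecomposition(lam, Gk, Dk)
    if code == "VVV":
        lam = np.empty(K)
        Gk = np.empty((K, P, P))
        Dk = np.empty((K, P))
        for k in range(K):
            lam[k], Gk[k], Dk[k] = decompose(Yk[k] / (R * n[k]))
        return CovDecomposition(lam, Gk, Dk)
    raise ValueError(
        f"unknown row structure {code!r}; admissible: {', '.join(ROW_CODES)}"
    )


def update_psi(
    code: str,
    scatters: ScatterSet,
    prev: CovDecomposition,
    mm_max_iter: int = 1000,
    mm_tol: float = 1e-10,
) -> CovDecomposition:
    """Conditional M-step update of the unit-determinant column covariances.

    ``scatters`` holds the within-state column scatters W_k (built with the
    current responsibilities, means and row-covariance inverses).  Every
    returned state covariance has determinant one.
    """
    scatters.check_weights()
    Wk = scatters.S
    K, R = Wk.shape[0], Wk.shape[1]
    W = scatters.total
    eye = np.broadcast_to(np.eye(R), (K, R, R)).copy()
    ones_lam = np.ones(K)

    if code == "II":
        return CovDecomposition(ones_lam, eye, np.ones((K, R)))
    if code == "EI":
        delta, _ = _norm_diag(np.diagonal(W), R)
        return CovDecomposition(ones_lam, eye, np.tile(delta, (K, 1)))
    if code == "VI":
        diags = np.diagonal(Wk, axis1=1, axis2=2)
        if np.any(diags <= 0):
            raise NotPositiveDefiniteError("state scatter has non-positive diagonal")
        deltas = diags / np.exp(np.mean(np.log(diags), axis=1))[:, None]
        return CovDecomposition(ones_lam, eye, deltas)
    if code == "EE":
        Psi = W / _det_root(W, R)
        _, G, d = decompose(Psi)
        return CovDecomposition(ones_lam, np.tile(G, (K, 1, 1)), np.tile(d, (K, 1)))
    if code == "VE":
        G = mm_rotation(
            Wk, prev.Delta, prev.Gamma[0], max_iter=mm_max_iter, tol=mm_tol
        )
        rotated = np.einsum("pq,kpr,rs->kqs", G, Wk, G)
        diags = np.diagonal(rotated, axis1=1, axis2=2)
        if np.any(diags <= 0):
            raise NotPositiveDefiniteError("rotated scatter has non-positive diagonal")
        deltas = diags / np.exp(np.mean(np.log(diags), axis=1))[:, None]
        return CovDecomposition(ones_lam, np.tile(G, (K, 1, 1)), deltas)
    if code == "EV":
        Gk = np.empty((K, R, R))
        Om = np.empty((K, R))
        for k in range(K):
            Gk[k], Om[k] = _eig_desc(Wk[k])
        delta, _ = _norm_diag(Om.sum(axis=0), R)
        return CovDecomposition(ones_lam, Gk, np.tile(delta, (K, 1)))
    if code == "VV":
        Gk = np.empty((K, R, R))
        Dk = np.empty((K, R))
        for k in range(K):
            _, Gk[k], Dk[k] = decompose(Wk[k] / _det_root(Wk[k], R))
        return CovDecomposition(ones_lam, Gk, Dk)
    raise ValueError(
        f"unknown column structure {code!r}; admissible: {', '.join(COL_CODES)}"
    )
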