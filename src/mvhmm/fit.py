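"""ECM estimation of parsimonious matrix-variate HMMs.

One ECM iteration is an E-step (scaled forward-backward posteriors) followed
by two conditional maximizations: CM-step 1 updates the chain parameters
(pi, Pi), the state means and the row covariances Sigma_k (the row scatters
are built with the *previous* column covariances), CM-step 2 updates the
unit-determinant column covariances Psi_k with the freshly updated means and
row covariances.  The observed-data log-likelihood is non-decreasing across
iterations.

Starting values come from a short-EM strategy: H random hard assignments of
the (unit, occasion) pairs to states, each advanced for s ECM iterations,
with the best-log-likelihood candidate seeding the full run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .data import FourWayData
from .errors import (
    DegenerateStateError,
    FitFailedError,
    InitializationError,
    NotPositiveDefiniteError,
    UnderflowError,
)
from .inference import HMMParams, Posteriors, decode_local, estep, loglik_only
from .parsimony import (
    COL_CODES,
    ROW_CODES,
    CovDecomposition,
    ScatterSet,
    update_psi,
    update_sigma,
)

__all__ = ["InitConfig", "FitResult", "update_chain_and_means", "short_em_init",
           "ecm_fit", "align_labels"]

_log = logging.getLogger(__name__)

_RECOVERABLE = (DegenerateStateError, NotPositiveDefiniteError, UnderflowError)


@dataclass
class InitConfig:
    """Short-EM initialization settings: H random starts, s iterations each."""

    H: int = 100
    s: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.H < 1 or self.s < 1:
            raise ValueError("H and s must be >= 1")


@dataclass
class FitResult:
    """A converged (or iteration-capped) ECM fit."""

    params: HMMParams
    loglik_trace: np.ndarray
    posteriors: Posteriors
    labels: np.ndarray
    n_params: int
    bic: float
    converged: bool
    n_iter: int
    n_restarts: int = 0

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def update_chain_and_means(
    post: Posteriors, data: FourWayData
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form CM-step 1 updates of (pi, Pi, M_1..M_K).

    pi_k averages the first-occasion memberships, each row of Pi normalizes
    the summed transition posteriors, and M_k is the responsibility-weighted
    mean matrix.  A state with zero total responsibility raises
    :class:`DegenerateStateError`.
    """
    z, zz = post.z, post.zz
    nk = z.sum(axis=(0, 1))
    bad = np.flatnonzero(nk < 1e-8)
    if bad.size:
        raise DegenerateStateError(int(bad[0]), float(nk[bad[0]]))
    pi = z[:, 0, :].sum(axis=0)
    pi = pi / pi.sum()
    trans = zz.sum(axis=(0, 1))  # (K, K), from-state j by to-state k
    rows = trans.sum(axis=1)
    badrow = np.flatnonzero(rows < 1e-12)
    if badrow.size:
        raise DegenerateStateError(int(badrow[0]), float(rows[badrow[0]]))
    Pi = trans / rows[:, None]
    means = np.einsum("itk,itpr->kpr", z, data.values) / nk[:, None, None]
    return pi, Pi, means


def _row_scatters(
    values: np.ndarray, z: np.ndarray, means: np.ndarray, psi: CovDecomposition
) -> ScatterSet:
    """Within-state row scatters Y_k = sum_it z_itk D Psi_k^-1 D',
    D = X_it - M_k."""
    D = values[None] - means[:, None, None]  # (K, I, T, P, R)
    Yk = np.einsum(
        "itk,kitpr,krs,kitqs->kpq", z, D, psi.inverses(), D, optimize=True
    )
    return ScatterSet(Yk, z.sum(axis=(0, 1)))


def _col_scatters(
    values: np.ndarray, z: np.ndarray, means: np.ndarray, sigma: CovDecomposition
) -> ScatterSet:
    """Within-state column scatters W_k = sum_it z_itk D' Sigma_k^-1 D."""
    D = values[None] - means[:, None, None]  # (K, I, T, P, R)
    Wk = np.einsum(
        "itk,kitpr,kpq,kitqs->krs", z, D, sigma.inverses(), D, optimize=True
    )
    return ScatterSet(Wk, z.sum(axis=(0, 1)))


def _cm_steps(
    data: FourWayData,
    post: Posteriors,
    params: HMMParams,
    mm_max_iter: int = 50,
) -> HMMParams:
    """One full CM sweep: (pi, Pi, M) -> Sigma (old Psi) -> Psi (new Sigma).

    ``mm_max_iter`` caps the inner MM rotation sweeps; the rotation is
    warm-started from the previous iterate, so a capped inner loop keeps
    the ECM ascent property while the orientation converges jointly with
    the outer iterations.
    """
    I, T, P, R = data.shape
    pi, Pi, means = update_chain_and_means(post, data)
    row = _row_scatters(data.values, post.z, means, params.psi)
    sigma = update_sigma(
        params.row_code, row, params.sigma, (P, R, T, I),
        mm_max_iter=mm_max_iter, mm_tol=1e-8,
    )
    col = _col_scatters(data.values, post.z, means, sigma)
    psi = update_psi(
        params.col_code, col, params.psi, mm_max_iter=mm_max_iter, mm_tol=1e-8
    )
    return HMMParams(pi, Pi, means, sigma, psi, params.row_code, params.col_code)


def _hard_posteriors(labels: np.ndarray, K: int) -> Posteriors:
    """One-hot memberships and transition indicators from hard labels."""
    I, T = labels.shape
    z = np.zeros((I, T, K))
    z[np.arange(I)[:, None], np.arange(T)[None, :], labels] = 1.0
    zz = np.zeros((I, max(T - 1, 0), K, K))
    if T > 1:
        ii = np.repeat(np.arange(I), T - 1)
        tt = np.tile(np.arange(T - 1), I)
        zz[ii, tt, labels[:, :-1].ravel(), labels[:, 1:].ravel()] = 1.0
    return Posteriors(z=z, zz=zz, loglik=np.nan, per_unit_loglik=np.full(I, np.nan))


def _params_from_hard(
    data: FourWayData, labels: np.ndarray, K: int, row_code: str, col_code: str
) -> HMMParams:
    """First CM sweep from a hard random assignment (identity covariances as
    the previous iterate)."""
    P, R = data.P, data.R
    base = HMMParams(
        pi=np.full(K, 1.0 / K),
        Pi=np.full((K, K), 1.0 / K),
        means=np.zeros((K, P, R)),
        sigma=CovDecomposition.identity(K, P),
        psi=CovDecomposition.identity(K, R),
        row_code=row_code,
        col_code=col_code,
    )
    post = _hard_posteriors(labels, K)
    return _cm_steps(data, post, base, mm_max_iter=10)


def short_em_init(
    data: FourWayData,
    row_code: str,
    col_code: str,
    K: int,
    cfg: InitConfig | None = None,
) -> HMMParams:
    """Best-of-H short-EM starting point.

    Each start assigns every (unit, occasion) a uniform random state, takes
    one CM sweep from the hard assignment, then runs ``s`` full ECM
    iterations; the candidate with the highest observed-data log-likelihood
    wins.  Degenerate starts (an empty state, a singular scatter) are
    skipped; if all H starts fail an :class:`InitializationError` is raised.
    """
    cfg = cfg or InitConfig()
    rng = np.random.default_rng(cfg.seed)
    I, T = data.I, data.T
    best_params, best_ll = None, -np.inf
    for _ in range(cfg.H):
        labels = rng.integers(0, K, size=(I, T))
        try:
            params = _params_from_hard(data, labels, K, row_code, col_code)
            for _ in range(cfg.s):
                post = estep(data.values, params)
                params = _cm_steps(data, post, params, mm_max_iter=10)
            ll = loglik_only(data.values, params)
        except _RECOVERABLE:
            continue
        if ll > best_ll:
            best_params, best_ll = params, ll
    if best_params is None:
        raise InitializationError(
            f"all {cfg.H} short-EM starts were degenerate for "
            f"{row_code}-{col_code}, K={K}"
        )
    return best_params


def ecm_fit(
    data: FourWayData,
    row_code: str,
    col_code: str,
    K: int,
    init: InitConfig | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    max_restarts: int = 5,
    start: HMMParams | None = None,
) -> FitResult:
    """Fit one parsimonious matrix-variate HMM by ECM.

    Stops when the relative log-likelihood improvement drops below ``tol``
    or after ``max_iter`` iterations.  A degeneracy during the main loop
    triggers re-initialization (fresh short-EM seed), up to ``max_restarts``
    times.  The returned states are relabeled by ascending grand mean (see
    :func:`align_labels`).  ``start`` bypasses the short-EM search with an
    explicit starting parameter set (its structure codes are overridden by
    ``row_code``/``col_code``).
    """
    from .selection import bic as _bic, n_params as _n_params  # local: avoid cycle

    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if row_code not in ROW_CODES:
        raise ValueError(f"unknown row structure {row_code!r}")
    if col_code not in COL_CODES:
        raise ValueError(f"unknown column structure {col_code!r}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    init = init or InitConfig()
    seed_seq = np.random.SeedSequence(init.seed)
    last_exc: Exception | None = None
    for attempt in range(max_restarts + 1):
        attempt_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
        cfg = replace(init, seed=attempt_seed)
        try:
            if start is not None and attempt == 0:
                params = HMMParams(
                    start.pi, start.Pi, start.means, start.sigma, start.psi,
                    row_code, col_code,
                )
            else:
                params = short_em_init(data, row_code, col_code, K, cfg)
            trace: list[float] = []
            converged = False
            post = estep(data.values, params)
            for _ in range(max_iter):
                trace.append(post.loglik)
                _log.debug(
                    "%s-%s K=%d iter %d loglik %.6f",
                    row_code, col_code, K, len(trace), post.loglik,
                )
                if len(trace) > 1 and (
                    trace[-1] - trace[-2] < tol * abs(trace[-2])
                ):
                    converged = True
                    break
                params = _cm_steps(data, post, params)
                post = estep(data.values, params)
            else:
                trace.append(post.loglik)
        except (InitializationError, *_RECOVERABLE) as exc:
            last_exc = exc
            continue
        m = _n_params(row_code, col_code, K, data.P, data.R)
        _log.info(
            "fit %s-%s K=%d: loglik %.4f in %d iterations (converged=%s)",
            row_code, col_code, K, trace[-1], len(trace), converged,
        )
        result = FitResult(
            params=params,
            loglik_trace=np.asarray(trace),
            posteriors=post,
            labels=decode_local(post),
            n_params=m,
            bic=_bic(trace[-1], m, data.I, data.T),
            converged=converged,
            n_iter=len(trace),
            n_restarts=attempt,
        )
        return align_labels(result)
    raise FitFailedError(
        f"ECM failed for {row_code}-{col_code}, K={K} after "
        f"{max_restarts + 1} attempts: {last_exc}"
    )


def align_labels(result: FitResult) -> FitResult:
    """Relabel states by ascending grand mean of the estimated mean matrices.

    The likelihood is invariant under relabeling, so pi, Pi, the state
    parameters, the posteriors and the decoded labels are permuted
    consistently; exact ties keep the original order.
    """
    p = result.params
    key = p.means.mean(axis=(1, 2))
    order = np.argsort(key, kind="stable")
    if np.array_equal(order, np.arange(p.K)):
        return result
    inv = np.argsort(order)
    new_params = HMMParams(
        pi=p.pi[order],
        Pi=p.Pi[np.ix_(order, order)],
        means=p.means[order],
        sigma=CovDecomposition(
            p.sigma.lam[order], p.sigma.Gamma[order], p.sigma.Delta[order]
        ),
        psi=CovDecomposition(
            p.psi.lam[order], p.psi.Gamma[order], p.psi.Delta[order]
        ),
        row_code=p.row_code,
        col_code=p.col_code,
    )
    post = result.posteriors
    new_post = Posteriors(
        z=post.z[..., order],
        zz=post.zz[:, :, order][:, :, :, order],
        loglik=post.loglik,
        per_unit_loglik=post.per_unit_loglik,
    )
    return FitResult(
        params=new_params,
        loglik_trace=result.loglik_trace,
        posteriors=new_post,
        labels=inv[result.labels],
        n_params=result.n_params,
        bic=result.bic,
        converged=result.converged,
        n_iter=result.n_iter,
        n_restarts=result.n_restarts,
    )
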