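"""Simulation of four-way data from any model in the family, scenario
presets, and the parameter-recovery (MSE) experiment driver.

Scenario presets mirror a two-factor longitudinal design: matrices of
dimension D1 = 2 x 2 or D2 = 4 x 8, T1 = 5 or T2 = 10 occasions, K = 2 or 4
hidden states, I = 100 units, and two separation levels for the state
means — O1 places adjacent state means 2 average within-state standard
deviations apart, O2 places them 4 apart.  Generators are provided for the
two showcased structures EII-II (spherical row covariance, identity column
covariance) and VVE-EV (variable volume/shape, shared orientation rows;
shared shape, variable orientation columns).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np

from .data import FourWayData
from .errors import FitFailedError
from .fit import InitConfig, ecm_fit
from .inference import HMMParams
from .matrix_normal import MatrixNormalParams, sample
from .parsimony import CovDecomposition

__all__ = ["Scenario", "MSEReport", "simulate_chain", "simulate_data",
           "scenario_params", "preset", "run_scenario"]

#: Mean separation of adjacent states, in average within-state SD units.
OVERLAP_SEPARATION = {"O1": 2.0, "O2": 4.0}

DIMENSIONS = {"D1": (2, 2), "D2": (4, 8)}
TIMES = {"T1": 5, "T2": 10}


@dataclass
class Scenario:
    """One cell of the simulation design."""

    dims: tuple[int, int] = (2, 2)
    T: int = 5
    K: int = 2
    overlap: str = "O1"
    I: int = 100
    replicates: int = 50
    seed: int = 0
    model: str = "EII-II"

    def __post_init__(self) -> None:
        if self.overlap not in OVERLAP_SEPARATION:
            raise ValueError(f"overlap must be one of {list(OVERLAP_SEPARATION)}")
        if min(self.dims) < 1 or self.T < 1 or self.K < 1 or self.I < 1:
            raise ValueError("all scenario sizes must be positive")


@dataclass
class MSEReport:
    """Entrywise mean squared errors averaged over states and replicates."""

    mse: dict[str, float]
    n_completed: int
    n_replicates: int
    scenario: Scenario | None = None


def simulate_chain(
    pi: np.ndarray,
    Pi: np.ndarray,
    I: int,
    T: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate I independent first-order Markov chains of length T.

    Returns integer states (0-based) of shape (I, T); S_1 ~ pi and
    S_t | S_{t-1} = j follows row j of Pi.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = np.asarray(pi, dtype=float)
    Pi = np.asarray(Pi, dtype=float)
    K = pi.shape[0]
    states = np.empty((I, T), dtype=np.int64)
    cum_pi = np.cumsum(pi)
    cum_Pi = np.cumsum(Pi, axis=1)
    u = rng.random((I, T))
    states[:, 0] = np.searchsorted(cum_pi, u[:, 0], side="right").clip(0, K - 1)
    for t in range(1, T):
        rows = cum_Pi[states[:, t - 1]]
        states[:, t] = (u[:, t, None] > rows[:, :-1]).sum(axis=1)
    return states


def simulate_data(
    params: HMMParams,
    I: int,
    T: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[FourWayData, np.ndarray]:
    """Simulate a balanced four-way data set and its true state paths."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = simulate_chain(params.pi, params.Pi, I, T, rng)
    sigmas = params.sigma.matrices()
    psis = params.psi.matrices()
    values = np.empty((I, T, params.P, params.R))
    flat_states = states.ravel()
    flat_values = values.reshape(-1, params.P, params.R)
    for k in range(params.K):
        mask = flat_states == k
        if mask.any():
            mn = MatrixNormalParams(params.means[k], sigmas[k], psis[k])
            flat_values[mask] = sample(mn, int(mask.sum()), rng)
    return FourWayData(values), states


def _fixed_orthogonal(Q: int, seed: int) -> np.ndarray:
    """A deterministic orthogonal matrix with sign-fixed columns."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((Q, Q)))
    idx = np.argmax(np.abs(q), axis=0)
    signs = np.sign(q[idx, np.arange(Q)])
    signs[signs == 0] = 1.0
    return q * signs


def _unit_det_diag(base: np.ndarray) -> np.ndarray:
    base = np.asarray(base, dtype=float)
    return base / np.exp(np.mean(np.log(base)))


def scenario_params(
    model: str = "EII-II",
    dims: tuple[int, int] = (2, 2),
    K: int = 2,
    overlap: str = "O1",
) -> HMMParams:
    """Generating parameters for one scenario cell.

    States are ordered by ascending mean level.  The chain is persistent
    (self-transition 0.85, the remainder split evenly) with a uniform
    initial law.
    """
    P, R = dims
    sep_units = OVERLAP_SEPARATION[overlap]
    if model == "EII-II":
        sigma = CovDecomposition.identity(K, P)
        psi = CovDecomposition.identity(K, R)
    elif model == "VVE-EV":
        lam = np.array([0.8, 1.2, 1.0, 1.4, 0.9, 1.1])[:K]
        Gamma_row = _fixed_orthogonal(P, seed=7)
        Delta_row = np.stack(
            [
                _unit_det_diag(np.linspace(1.0, 1.0 + 0.6 * (k + 1), P))
                for k in range(K)
            ]
        )
        sigma = CovDecomposition(
            lam, np.tile(Gamma_row, (K, 1, 1)), Delta_row
        )
        Gamma_col = np.stack([_fixed_orthogonal(R, seed=11 + k) for k in range(K)])
        Delta_col = np.tile(
            _unit_det_diag(np.linspace(1.6, 0.8, R)), (K, 1)
        )
        psi = CovDecomposition(np.ones(K), Gamma_col, Delta_col)
    else:
        raise ValueError(f"no scenario preset for generator {model!r}")

    # average within-state SD of an entry: Var(X_pr) = Sigma_pp * Psi_rr
    sig_diag = np.diagonal(sigma.matrices(), axis1=1, axis2=2)
    psi_diag = np.diagonal(psi.matrices(), axis1=1, axis2=2)
    avg_sd = float(np.sqrt(sig_diag.mean() * psi_diag.mean()))
    step = sep_units * avg_sd
    means = np.stack([np.full((P, R), k * step) for k in range(K)])

    pi = np.full(K, 1.0 / K)
    if K == 1:
        Pi = np.ones((1, 1))
    else:
        Pi = np.full((K, K), 0.15 / (K - 1))
        np.fill_diagonal(Pi, 0.85)
    row_code, col_code = model.split("-")
    return HMMParams(pi, Pi, means, sigma, psi, row_code, col_code)


_PRESET_RE = re.compile(
    r"^(?:(?P<model>[A-Z]{3}-[A-Z]{2})-)?"
    r"(?P<D>D[12])-(?P<T>T[12])-K(?P<K>\d+)-(?P<O>O[12])$"
)


def preset(name: str) -> tuple[Scenario, HMMParams]:
    """Scenario and generating parameters for a named preset.

    Names look like "D1-T1-K2-O1" (EII-II generator by default) or
    "VVE-EV-D2-T2-K4-O2".
    """
    m = _PRESET_RE.match(name)
    if not m:
        raise ValueError(
            f"unrecognized preset {name!r}; expected e.g. 'D1-T1-K2-O1' or "
            f"'VVE-EV-D1-T1-K2-O1'"
        )
    model = m.group("model") or "EII-II"
    dims = DIMENSIONS[m.group("D")]
    T = TIMES[m.group("T")]
    K = int(m.group("K"))
    scn = Scenario(dims=dims, T=T, K=K, overlap=m.group("O"), model=model)
    return scn, scenario_params(model, dims, K, m.group("O"))


def _best_permutation(est_means: np.ndarray, true_means: np.ndarray) -> tuple[int, ...]:
    """Permutation of estimated states minimizing total squared mean error."""
    K = est_means.shape[0]
    if K > 6:
        raise ValueError("brute-force alignment supported for K <= 6")
    return min(
        itertools.permutations(range(K)),
        key=lambda p: float(((est_means[list(p)] - true_means) ** 2).sum()),
    )


def run_scenario(
    scn: Scenario,
    generator_params: HMMParams | None = None,
    fit_spec=None,
    tol: float = 1e-8,
    max_iter: int = 500,
    init: InitConfig | None = None,
) -> MSEReport:
    """Replicated simulate -> fit -> align -> accumulate-MSE experiment.

    By default the fitted structure and K are those of the generator (the
    parameter-recovery protocol).  Estimated states are matched to the truth
    by the mean-sort rule, refined by the brute-force permutation that
    minimizes the total squared error of the mean matrices when sorting
    alone is ambiguous.  Column-covariance MSE is omitted for generators
    with identity column structure (nothing is estimated there).
    """
    params = generator_params or scenario_params(
        scn.model, scn.dims, scn.K, scn.overlap
    )
    if fit_spec is None:
        row_code, col_code, K = params.row_code, params.col_code, scn.K
    else:
        row_code, col_code, K = fit_spec.row_code, fit_spec.col_code, fit_spec.K
    if K != params.K:
        raise ValueError("recovery protocol requires fitting the true K")

    true_sig = params.sigma.matrices()
    true_psi = params.psi.matrices()
    keys = ["M", "Sigma", "pi", "Pi"]
    report_psi = col_code != "II"
    if report_psi:
        keys.insert(2, "Psi")
    sums = {key: 0.0 for key in keys}
    completed = 0
    for rep in range(scn.replicates):
        data_ss, fit_ss = np.random.SeedSequence((scn.seed, rep)).spawn(2)
        data, _ = simulate_data(
            params, scn.I, scn.T, np.random.default_rng(data_ss)
        )
        cfg = init or InitConfig()
        cfg = InitConfig(
            H=cfg.H, s=cfg.s, seed=int(fit_ss.generate_state(1)[0] % (2**31))
        )
        try:
            res = ecm_fit(
                data, row_code, col_code, K, init=cfg, tol=tol, max_iter=max_iter
            )
        except FitFailedError:
            continue
        est = res.params
        perm = list(_best_permutation(est.means, params.means))
        est_sig = est.sigma.matrices()[perm]
        sums["M"] += float(((est.means[perm] - params.means) ** 2).mean())
        sums["Sigma"] += float(((est_sig - true_sig) ** 2).mean())
        if report_psi:
            est_psi = est.psi.matrices()[perm]
            sums["Psi"] += float(((est_psi - true_psi) ** 2).mean())
        sums["pi"] += float(((est.pi[perm] - params.pi) ** 2).mean())
        sums["Pi"] += float(
            ((est.Pi[np.ix_(perm, perm)] - params.Pi) ** 2).mean()
        )
        completed += 1
    if completed == 0:
        raise FitFailedError("every replicate of the scenario failed to fit")
    return MSEReport(
        mse={key: val / completed for key, val in sums.items()},
        n_completed=completed,
        n_replicates=scn.replicates,
        scenario=scn,
    )
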