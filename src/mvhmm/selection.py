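"""Model selection across the 98-member family and the sojourn-time test.

BIC here is on the "smaller is better" scale, -2 loglik + m log N, with N
the number of matrix observations I*T by default (a units-only convention
N = I is available as a switch).  The sojourn test checks the geometric
run-length implication of a homogeneous hidden Markov chain: for each state
the observed lengths of maximal decoded segments are compared with the
geometric law of parameter pi_{k|k} by a chi-square goodness-of-fit test,
and the K per-state p-values are combined by Holm's step-down adjustment
(union-intersection: reject the global null iff the smallest adjusted
p-value is below alpha).
"""

from __future__ import annotations

import itertools
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import FourWayData
from .fit import FitResult, InitConfig, ecm_fit
from .parsimony import COL_CODES, ROW_CODES, count_col_params, count_row_params, family

__all__ = ["ModelSpec", "SelectionResult", "SojournTestResult", "n_params", "bic",
           "select", "sojourn_geometric_test"]


@dataclass(frozen=True)
class ModelSpec:
    """One member of the family: row structure, column structure, K states."""

    row_code: str
    col_code: str
    K: int

    def __post_init__(self) -> None:
        if self.row_code not in ROW_CODES:
            raise ValueError(f"unknown row structure {self.row_code!r}")
        if self.col_code not in COL_CODES:
            raise ValueError(f"unknown column structure {self.col_code!r}")
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def name(self) -> str:
        return f"{self.row_code}-{self.col_code}"


def n_params(
    row_code: str, col_code: str, K: int, P: int, R: int
) -> int:
    """Total free parameters of one model.

    (K-1) initial probabilities + K(K-1) transition probabilities + K*P*R
    mean entries + the two structured covariance counts.
    """
    return (
        (K - 1)
        + K * (K - 1)
        + K * P * R
        + count_row_params(row_code, K, P)
        + count_col_params(col_code, K, R)
    )


def bic(
    loglik: float,
    m: int,
    n_units: int,
    n_times: int,
    sample_size: str = "occasions",
) -> float:
    """Bayesian information criterion, smaller is better.

    ``sample_size="occasions"`` uses N = I*T matrix observations;
    ``"units"`` uses N = I.
    """
    if m < 0:
        raise ValueError("n_params must be >= 0")
    if sample_size == "occasions":
        N = n_units * n_times
    elif sample_size == "units":
        N = n_units
    else:
        raise ValueError("sample_size must be 'occasions' or 'units'")
    return -2.0 * loglik + m * np.log(N)


@dataclass
class SelectionResult:
    """Grid-search outcome: one table row per (structure, K) fit."""

    table: pd.DataFrame
    best: ModelSpec
    fits: dict = field(default_factory=dict, repr=False)

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.best]


def _fit_one(data, spec: ModelSpec, seed: int, tol, max_iter, H, s):
    start = time.perf_counter()
    try:
        res = ecm_fit(
            data, spec.row_code, spec.col_code, spec.K,
            init=InitConfig(H=H, s=s, seed=seed), tol=tol, max_iter=max_iter,
        )
        row = dict(
            row_code=spec.row_code, col_code=spec.col_code, K=spec.K,
            loglik=res.loglik, n_params=res.n_params, bic=res.bic,
            converged=res.converged, n_iter=res.n_iter,
            seconds=time.perf_counter() - start, error="",
        )
        return spec, res, row
    except Exception as exc:  # record, do not abort the grid
        row = dict(
            row_code=spec.row_code, col_code=spec.col_code, K=spec.K,
            loglik=np.nan, n_params=n_params(spec.row_code, spec.col_code,
                                             spec.K, data.P, data.R),
            bic=np.nan, converged=False, n_iter=0,
            seconds=time.perf_counter() - start, error=str(exc),
        )
        return spec, None, row


def select(
    data: FourWayData,
    structures: list[str] | None = None,
    K_range=(1, 2, 3),
    jobs: int = 1,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    init_runs: int = 100,
    init_iters: int = 1,
    keep_fits: bool = False,
) -> SelectionResult:
    """Fit every (structure, K) pair on the grid and pick the BIC-best model.

    ``structures`` is a list of "ROW-COL" codes (default: all 98).  Each fit
    gets a seed derived from ``seed`` and its grid position, so results are
    identical whatever ``jobs`` is.  Failed fits are recorded with a blank
    BIC and do not abort the grid.  Ties on BIC break toward fewer
    parameters, then fewer states.
    """
    from joblib import Parallel, delayed

    structures = structures or family()
    specs = []
    for name in structures:
        row_code, col_code = name.split("-")
        for K in K_range:
            specs.append(ModelSpec(row_code, col_code, K))
    if not specs:
        raise ValueError("empty model grid")
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(len(specs))
    ]
    tasks = (
        delayed(_fit_one)(data, spec, sd, tol, max_iter, init_runs, init_iters)
        for spec, sd in zip(specs, seeds)
    )
    results = Parallel(n_jobs=jobs)(tasks)
    rows = [row for _, _, row in results]
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["bic"])
    if ok.empty:
        raise RuntimeError(
            "every fit on the grid failed; first diagnostic: "
            + str(table["error"].iloc[0])
        )
    ranked = ok.sort_values(["bic", "n_params", "K"], kind="stable")
    top = ranked.iloc[0]
    best = ModelSpec(top["row_code"], top["col_code"], int(top["K"]))
    fits = (
        {spec: res for spec, res, _ in results if res is not None}
        if keep_fits
        else {}
    )
    return SelectionResult(table=table, best=best, fits=fits)


@dataclass
class SojournTestResult:
    """Per-state chi-square sojourn tests with Holm adjustment."""

    states: np.ndarray
    statistic: np.ndarray
    df: np.ndarray
    p_value: np.ndarray
    p_adjusted: np.ndarray
    min_adjusted_p: float
    alpha: float
    reject: bool


def _label_rows(labels) -> list[np.ndarray]:
    if isinstance(labels, np.ndarray):
        return list(np.atleast_2d(labels))
    return [np.asarray(row) for row in labels]


def run_lengths(labels) -> dict[int, np.ndarray]:
    """Maximal run lengths of each state across the rows of ``labels``.

    ``labels`` is an (I, T) integer array or any iterable of 1-D label
    sequences (rows may differ in length).
    """
    out: dict[int, list[int]] = {}
    for row in _label_rows(labels):
        for state, grp in itertools.groupby(row):
            out.setdefault(int(state), []).append(sum(1 for _ in grp))
    return {k: np.asarray(v) for k, v in out.items()}


def _chi2_geometric(runs: np.ndarray, p_stay: float) -> tuple[float, int] | None:
    """Chi-square statistic and df against Geometric(1 - p_stay) run lengths.

    P(L = l) = p_stay^(l-1) (1 - p_stay).  The upper tail is binned so that
    every expected count is >= 5; returns None when fewer than two bins are
    available (test not feasible).
    """
    n = runs.size
    if n == 0 or not (0.0 < p_stay < 1.0):
        return None
    # largest m with all unit bins 1..m and the tail > m having expectation >= 5
    pmf1 = 1.0 - p_stay
    m = 0
    while True:
        nxt = m + 1
        exp_bin = n * pmf1 * p_stay ** (nxt - 1)
        exp_tail = n * p_stay**nxt
        if exp_bin >= 5.0 and exp_tail >= 5.0:
            m = nxt
        else:
            break
    if m < 1:
        return None
    lengths = np.arange(1, m + 1)
    expected = np.append(n * pmf1 * p_stay ** (lengths - 1), n * p_stay**m)
    observed = np.append(
        [(runs == l).sum() for l in lengths], (runs > m).sum()
    ).astype(float)
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    return statistic, m  # df = (#bins - 1) = m


def sojourn_geometric_test(
    labels, Pi: np.ndarray, alpha: float = 0.05
) -> SojournTestResult:
    """Test geometric sojourn times state by state, Holm-combined.

    For each decoded state k the maximal segment lengths across units are
    compared with the geometric law of continuation probability Pi[k, k].
    States never visited (or with too few runs to form two bins) are
    excluded with a warning, and the Holm adjustment runs over the remaining
    states only.  The global null (all states geometric) is rejected iff the
    smallest adjusted p-value is below ``alpha``.
    """
    Pi = np.asarray(Pi, dtype=float)
    K = Pi.shape[0]
    runs = run_lengths(labels)
    states, stat_list, df_list, p_list = [], [], [], []
    for k in range(K):
        if k not in runs:
            warnings.warn(f"state {k} never visited; excluded from the sojourn test")
            continue
        res = _chi2_geometric(runs[k], float(Pi[k, k]))
        if res is None:
            warnings.warn(
                f"state {k}: too few runs or degenerate persistence; excluded"
            )
            continue
        statistic, df = res
        states.append(k)
        stat_list.append(statistic)
        df_list.append(df)
        p_list.append(float(stats.chi2.sf(statistic, df)))
    if not states:
        raise ValueError("no state admits a sojourn test")
    _, p_adj, _, _ = multipletests(p_list, alpha=alpha, method="holm")
    min_adj = float(np.min(p_adj))
    return SojournTestResult(
        states=np.asarray(states),
        statistic=np.asarray(stat_list),
        df=np.asarray(df_list),
        p_value=np.asarray(p_list),
        p_adjusted=np.asarray(p_adj),
        min_adjusted_p=min_adj,
        alpha=alpha,
        reject=min_adj < alpha,
    )
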