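"""Structure counts, eigen decomposition, MM rotation and the 21
constrained covariance estimators."""

import numpy as np
import pytest
from scipy.linalg import expm

from mvhmm.errors import DegenerateStateError
from mvhmm.parsimony import (
    COL_CODES,
    ROW_CODES,
    CovDecomposition,
    ScatterSet,
    assemble,
    count_col_params,
    count_row_params,
    decompose,
    family,
    mm_rotation,
    update_psi,
    update_sigma,
    _mm_criterion,
)

from conftest import random_spd


# ---------------------------------------------------------------------------
# an independent chart of each structure: free coordinates -> covariance stack
# ---------------------------------------------------------------------------

def structure_chart(code, K, Q):
    """A smooth parameterization of one structure built from first
    principles (log-volumes, zero-sum log-shapes, matrix-exponential
    orientations).  Returns (n_free, build, segments)."""
    if len(code) == 3:
        vol, shape, orient = code
    else:
        vol, (shape, orient) = None, code
    nskew = Q * (Q - 1) // 2
    segments = []
    if vol == "E":
        segments.append(("vol", 1))
    elif vol == "V":
        segments.append(("vol", K))
    if shape == "E":
        segments.append(("shape", Q - 1))
    elif shape == "V":
        segments.append(("shape", K * (Q - 1)))
    if orient == "E":
        segments.append(("orient", nskew))
    elif orient == "V":
        segments.append(("orient", K * nskew))
    n_free = sum(n for _, n in segments)

    def mk_delta(x):
        return np.exp(np.append(x, -x.sum()))

    def mk_gamma(x):
        S = np.zeros((Q, Q))
        S[np.triu_indices(Q, 1)] = x
        return expm(S - S.T)

    def build(theta):
        theta = np.asarray(theta, dtype=float)
        parts, pos = {}, 0
        for name, n in segments:
            parts[name] = theta[pos:pos + n]
            pos += n
        if vol == "E":
            lam = np.full(K, np.exp(parts["vol"][0]))
        elif vol == "V":
            lam = np.exp(parts["vol"])
        else:
            lam = np.ones(K)
        if shape == "E":
            Delta = np.tile(mk_delta(parts["shape"]), (K, 1))
        elif shape == "V":
            Delta = np.stack(
                [mk_delta(parts["shape"][k * (Q - 1):(k + 1) * (Q - 1)])
                 for k in range(K)]
            )
        else:
            Delta = np.ones((K, Q))
        if orient == "E":
            Gamma = np.tile(mk_gamma(parts["orient"]), (K, 1, 1))
        elif orient == "V":
            Gamma = np.stack(
                [mk_gamma(parts["orient"][k * nskew:(k + 1) * nskew])
                 for k in range(K)]
            )
        else:
            Gamma = np.tile(np.eye(Q), (K, 1, 1))
        return CovDecomposition(lam, Gamma, Delta)

    return n_free, build, segments


def chart_jacobian_rank(code, K, Q, rng, h=1e-6):
    """Numerical rank of the chart's Jacobian at a generic point."""
    n_free, build, _ = structure_chart(code, K, Q)
    if n_free == 0:
        return 0
    theta0 = rng.standard_normal(n_free) * 0.4
    cols = []
    for i in range(n_free):
        e = np.zeros(n_free)
        e[i] = h
        hi = build(theta0 + e).matrices().ravel()
        lo = build(theta0 - e).matrices().ravel()
        cols.append((hi - lo) / (2 * h))
    J = np.column_stack(cols)
    s = np.linalg.svd(J, compute_uv=False)
    return int(np.sum(s > s[0] * 1e-8))


# ---------------------------------------------------------------------------
# conditional objectives of the two CM steps
# ---------------------------------------------------------------------------

def row_objective(decomp, Yk, n, R):
    """Expected complete-data log-likelihood terms depending on Sigma:
    sum_k [ -(R n_k / 2) log|Sigma_k| - tr(Sigma_k^-1 Y_k)/2 ]."""
    mats = decomp.matrices()
    val = 0.0
    for k in range(len(n)):
        sign, logdet = np.linalg.slogdet(mats[k])
        val += -0.5 * R * n[k] * logdet - 0.5 * np.trace(
            np.linalg.solve(mats[k], Yk[k])
        )
    return val


def col_objective(decomp, Wk):
    """Psi-dependent terms; the log-determinant vanishes (|Psi_k| = 1)."""
    mats = decomp.matrices()
    return -0.5 * sum(
        np.trace(np.linalg.solve(mats[k], Wk[k])) for k in range(Wk.shape[0])
    )


def random_scatters(rng, K, Q, total=24.0):
    n = rng.dirichlet(np.ones(K)) * total
    S = np.stack([random_spd(rng, Q, jitter=0.2) * n[k] for k in range(K)])
    return ScatterSet(S, n)


# ---------------------------------------------------------------------------
# cardinality and counting
# ---------------------------------------------------------------------------

class TestCounts:
    def test_family_cardinality(self):
        assert len(family()) == 98
        assert len(ROW_CODES) * len(ROW_CODES) == 196  # before |Psi| = 1
        assert len(COL_CODES) == 7

    @pytest.mark.parametrize(
        "code,K,Q,expected",
        [
            ("EII", 4, 2, 1),
            ("VVV", 4, 3, 24),
            ("VEE", 8, 2, 10),
            ("EEE", 1, 2, 3),
            ("EEE", 1, 4, 10),
        ],
    )
    def test_row_count_examples(self, code, K, Q, expected):
        assert count_row_params(code, K, Q) == expected

    @pytest.mark.parametrize(
        "code,K,Q,expected",
        [("II", 5, 4, 0), ("EE", 8, 3, 5), ("VV", 2, 2, 4), ("EE", 1, 3, 5)],
    )
    def test_col_count_examples(self, code, K, Q, expected):
        assert count_col_params(code, K, Q) == expected

    @pytest.mark.parametrize("code", ROW_CODES)
    def test_row_counts_equal_chart_rank(self, code, rng):
        for K, Q in ((2, 3), (3, 2)):
            assert chart_jacobian_rank(code, K, Q, rng) == count_row_params(
                code, K, Q
            )

    @pytest.mark.parametrize("code", COL_CODES)
    def test_col_counts_equal_chart_rank(self, code, rng):
        for K, Q in ((2, 3), (3, 2)):
            assert chart_jacobian_rank(code, K, Q, rng) == count_col_params(
                code, K, Q
            )

    def test_unknown_codes_rejected(self):
        with pytest.raises(ValueError, match="EII"):
            count_row_params("XXX", 2, 2)
        with pytest.raises(ValueError, match="II"):
            count_col_params("XX", 2, 2)

    def test_ordering_extremes(self):
        """Spherical-equal is minimal, fully variable maximal, at fixed K, Q."""
        K, Q = 3, 4
        rows = [count_row_params(c, K, Q) for c in ROW_CODES]
        assert min(rows) == count_row_params("EII", K, Q)
        assert max(rows) == count_row_params("VVV", K, Q)
        cols = [count_col_params(c, K, Q) for c in COL_CODES]
        assert min(cols) == count_col_params("II", K, Q)
        assert max(cols) == count_col_params("VV", K, Q)


# ---------------------------------------------------------------------------
# assemble / decompose
# ---------------------------------------------------------------------------

class TestAssemble:
    def test_identity(self):
        np.testing.assert_allclose(assemble(1.0, np.eye(2), np.ones(2)), np.eye(2))

    def test_determinant_is_volume_power(self, rng):
        Q = 3
        _, G, d = decompose(random_spd(rng, Q))
        mat = assemble(2.0, G, d)
        assert np.linalg.det(mat) == pytest.approx(8.0, rel=1e-8)
        np.testing.assert_allclose(mat, mat.T, atol=1e-10)

    def test_round_trip(self, rng):
        for _ in range(10):
            Phi = random_spd(rng, 4)
            lam, G, d = decompose(Phi)
            np.testing.assert_allclose(assemble(lam, G, d), Phi, atol=1e-8)
            np.testing.assert_allclose(G @ G.T, np.eye(4), atol=1e-10)
            assert np.prod(d) == pytest.approx(1.0, abs=1e-10)
            assert np.all(np.diff(d) <= 1e-12)  # descending scaled eigenvalues


# ---------------------------------------------------------------------------
# MM rotation
# ---------------------------------------------------------------------------

class TestMMRotation:
    def test_spherical_shape_is_rotation_invariant(self, rng):
        Y = random_spd(rng, 3)[None]
        G = mm_rotation(Y, np.ones((1, 3)), np.eye(3))
        np.testing.assert_allclose(G @ G.T, np.eye(3), atol=1e-8)
        assert _mm_criterion(Y, np.ones((1, 3)), G) == pytest.approx(
            np.trace(Y[0]), rel=1e-12
        )

    def test_identical_scatters_align_with_eigenvectors(self, rng):
        """With one shared scatter the minimizer pairs descending eigenvalues
        with descending shape entries (rearrangement inequality)."""
        Q, K = 3, 2
        Y1 = random_spd(rng, Q)
        Y = np.stack([Y1] * K)
        d = np.array([2.0, 1.0, 0.5])
        d = d / np.prod(d) ** (1 / Q)
        D = np.tile(d, (K, 1))
        G = mm_rotation(Y, D, np.eye(Q), max_iter=5000)
        omega = np.sort(np.linalg.eigvalsh(Y1))[::-1]
        closed_form = K * np.sum(omega / d)
        assert _mm_criterion(Y, 1.0 / D, G) == pytest.approx(
            closed_form, abs=1e-6 * closed_form
        )

    def test_matches_angle_grid(self, rng):
        """Q = 2: MM criterion within 1e-4 of a 10^4-point rotation grid."""
        for _ in range(5):
            K = 3
            Y = np.stack([random_spd(rng, 2, jitter=0.2) for _ in range(K)])
            D = rng.uniform(0.5, 2.0, (K, 2))
            D /= np.exp(np.mean(np.log(D), axis=1))[:, None]
            G = mm_rotation(Y, D, np.eye(2))
            crit = _mm_criterion(Y, 1.0 / D, G)
            thetas = np.linspace(0.0, np.pi, 10000, endpoint=False)
            rots = np.stack(
                [np.cos(thetas), -np.sin(thetas), np.sin(thetas), np.cos(thetas)],
                axis=-1,
            ).reshape(-1, 2, 2)
            vals = np.einsum("gpq,kpr,grq,kq->g", rots, Y, rots, 1.0 / D)
            assert crit <= vals.min() + 1e-4

    def test_criterion_never_increases_across_restarts(self, rng):
        Y = np.stack([random_spd(rng, 2) for _ in range(2)])
        D = np.tile([2.0, 0.5], (2, 1))
        G0 = np.eye(2)
        c0 = _mm_criterion(Y, 1.0 / D, G0)
        G = mm_rotation(Y, D, G0, max_iter=1)
        assert _mm_criterion(Y, 1.0 / D, G) <= c0 + 1e-12

    def test_rejects_non_orthogonal_init(self, rng):
        Y = random_spd(rng, 2)[None]
        with pytest.raises(ValueError, match="orthogonal"):
            mm_rotation(Y, np.ones((1, 2)), np.array([[1.0, 1.0], [0.0, 1.0]]))


# ---------------------------------------------------------------------------
# printed closed forms (direct evaluation)
# ---------------------------------------------------------------------------

class TestPrintedFormulas:
    def test_eii_scalar_update(self):
        scat = ScatterSet(np.diag([2.0, 2.0])[None], np.array([1.0]))
        dec = update_sigma("EII", scat, CovDecomposition.identity(1, 2), (2, 1, 1, 1))
        np.testing.assert_allclose(dec.matrices()[0], 2.0 * np.eye(2), atol=1e-12)

    def test_vvv_single_state(self, rng):
        Y = random_spd(rng, 3)
        scat = ScatterSet(Y[None], np.array([10.0]))
        dec = update_sigma("VVV", scat, CovDecomposition.identity(1, 3), (3, 1, 5, 2))
        np.testing.assert_allclose(dec.matrices()[0], Y / 10.0, atol=1e-8)

    def test_psi_ii_is_identity(self, rng):
        scat = ScatterSet(np.stack([random_spd(rng, 2)] * 2), np.array([3.0, 4.0]))
        dec = update_psi("II", scat, CovDecomposition.identity(2, 2))
        np.testing.assert_allclose(dec.matrices(), np.stack([np.eye(2)] * 2))

    def test_psi_ee_unit_determinant_scaling(self):
        scat = ScatterSet(np.diag([4.0, 1.0])[None], np.array([6.0]))
        dec = update_psi("EE", scat, CovDecomposition.identity(1, 2))
        np.testing.assert_allclose(dec.matrices()[0], np.diag([2.0, 0.5]), atol=1e-10)

    def test_degenerate_weight_raises(self, rng):
        scat = ScatterSet(np.stack([random_spd(rng, 2), np.zeros((2, 2))]),
                          np.array([5.0, 0.0]))
        with pytest.raises(DegenerateStateError, match="state 1"):
            update_sigma("VVV", scat, CovDecomposition.identity(2, 2), (2, 2, 3, 1))


# ---------------------------------------------------------------------------
# estimator near-optimality for all 21 structures
# ---------------------------------------------------------------------------

def _random_admissible(code, K, Q, rng, lam_center=0.0, scale=0.7):
    n_free, build, segments = structure_chart(code, K, Q)
    theta = rng.standard_normal(n_free) * scale
    pos = 0
    for name, n in segments:
        if name == "vol":
            theta[pos:pos + n] += lam_center
        pos += n
    return build(theta)


@pytest.mark.parametrize("code", ROW_CODES)
def test_sigma_update_beats_random_draws(code, rng):
    """The printed estimator's conditional objective dominates 200 random
    admissible parameter draws."""
    K, Q, R = 3, 3, 2
    scat = random_scatters(rng, K, Q)
    prev = _random_admissible(code, K, Q, rng)
    dims = (Q, R, 4, 2)  # T * I = 8 is irrelevant to the comparison scale
    n = scat.n
    est = update_sigma(code, scat, prev, (Q, R, 4, int(round(n.sum() / 4))))
    # recompute with consistent T*I: use the actual total weight
    total = n.sum()
    est = update_sigma(code, scat, prev, (Q, R, 1, int(round(total))))
    obj_est = row_objective(est, scat.S, n, R)
    lam_center = float(np.mean(np.log(est.lam)))
    for _ in range(200):
        cand = _random_admissible(code, K, Q, rng, lam_center)
        assert row_objective(cand, scat.S, n, R) <= obj_est + 1e-9 * abs(obj_est)


@pytest.mark.parametrize("code", COL_CODES)
def test_psi_update_beats_random_draws(code, rng):
    K, Q = 3, 3
    scat = random_scatters(rng, K, Q)
    prev = _random_admissible(code, K, Q, rng)
    est = update_psi(code, scat, prev)
    obj_est = col_objective(est, scat.S)
    for _ in range(200):
        cand = _random_admissible(code, K, Q, rng)
        assert col_objective(cand, scat.S) <= obj_est + 1e-9 * abs(obj_est)


_EXACT_ROW = ["EII", "VII", "EEI", "EVI", "VVI", "EEE", "EEV", "EVV", "VVV"]
_EXACT_COL = ["EI", "VI", "EE", "EV", "VV"]


@pytest.mark.parametrize("code", _EXACT_ROW)
def test_exact_sigma_updates_are_local_maxima(code, rng):
    """Closed-form updates cannot be improved by small admissible
    perturbations of their components."""
    K, Q, R = 2, 3, 2
    scat = random_scatters(rng, K, Q)
    prev = _random_admissible(code, K, Q, rng)
    total = scat.n.sum()
    est = update_sigma(code, scat, prev, (Q, R, 1, int(round(total))))
    obj_est = row_objective(est, scat.S, scat.n, R)
    for _ in range(100):
        pert = _perturb(est, code, rng, eps=1e-2)
        assert row_objective(pert, scat.S, scat.n, R) <= obj_est + 1e-8 * abs(obj_est)


@pytest.mark.parametrize("code", _EXACT_COL)
def test_exact_psi_updates_are_local_maxima(code, rng):
    K, Q = 2, 3
    scat = random_scatters(rng, K, Q)
    est = update_psi(code, scat, _random_admissible(code, K, Q, rng))
    obj_est = col_objective(est, scat.S)
    for _ in range(100):
        pert = _perturb(est, code, rng, eps=1e-2, with_volume=False)
        assert col_objective(pert, scat.S) <= obj_est + 1e-8 * abs(obj_est)


def _perturb(decomp, code, rng, eps, with_volume=True):
    """A small structure-respecting perturbation of a decomposition."""
    if len(code) == 3:
        vol, shape, orient = code
    else:
        vol, (shape, orient) = None, code
    K, Q = decomp.K, decomp.Q
    lam = decomp.lam.copy()
    Delta = decomp.Delta.copy()
    Gamma = decomp.Gamma.copy()
    if with_volume and vol is not None:
        dv = rng.standard_normal(1 if vol == "E" else K) * eps
        lam = lam * np.exp(dv if vol == "V" else np.full(K, dv[0]))
    if shape != "I":
        ds = rng.standard_normal((1 if shape == "E" else K, Q)) * eps
        new = Delta * np.exp(np.broadcast_to(ds, (K, Q)) if shape == "V"
                             else np.tile(ds[0], (K, 1)))
        Delta = new / np.exp(np.mean(np.log(new), axis=1))[:, None]
    if orient != "I":
        def rot(x):
            S = np.zeros((Q, Q))
            S[np.triu_indices(Q, 1)] = x
            return expm(S - S.T)
        if orient == "E":
            Rm = rot(rng.standard_normal(Q * (Q - 1) // 2) * eps)
            Gamma = Gamma @ Rm
        else:
            for k in range(K):
                Gamma[k] = Gamma[k] @ rot(
                    rng.standard_normal(Q * (Q - 1) // 2) * eps
                )
    return CovDecomposition(lam, Gamma, Delta)


# ---------------------------------------------------------------------------
# structural conformance of returned estimators
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("code", ROW_CODES)
def test_sigma_constraint_conformance(code, rng):
    K, Q = 3, 3
    scat = random_scatters(rng, K, Q)
    est = update_sigma(code, scat, _random_admissible(code, K, Q, rng),
                       (Q, 2, 1, int(round(scat.n.sum()))))
    vol, shape, orient = code
    for k in range(K):
        np.testing.assert_allclose(
            est.Gamma[k] @ est.Gamma[k].T, np.eye(Q), atol=1e-8
        )
        assert np.prod(est.Delta[k]) == pytest.approx(1.0, abs=1e-8)
    if vol == "E":
        assert np.ptp(est.lam) == 0.0
    if shape == "E":
        assert np.ptp(est.Delta, axis=0).max() == 0.0
    if shape == "I":
        np.testing.assert_array_equal(est.Delta, np.ones((K, Q)))
    if orient == "E":
        assert np.ptp(est.Gamma, axis=0).max() == 0.0
    if orient == "I":
        np.testing.assert_array_equal(est.Gamma, np.tile(np.eye(Q), (K, 1, 1)))
    mats = est.matrices()
    assert np.all(np.linalg.eigvalsh(mats) > 0)


@pytest.mark.parametrize("code", COL_CODES)
def test_psi_unit_determinant(code, rng):
    K, Q = 3, 3
    scat = random_scatters(rng, K, Q)
    est = update_psi(code, scat, _random_admissible(code, K, Q, rng))
    dets = np.linalg.det(est.matrices())
    np.testing.assert_allclose(dets, 1.0, atol=1e-8)
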