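import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from netphase import (
    SolverConfig,
    WeightedNetwork,
    asalm_decompose,
    decompose_sequence,
    default_beta,
    pad_to_union,
    soft_threshold,
    stopping_metric,
    svt,
)
from netphase.types import DegenerateInputError, InvalidInputError, TemporalNetwork


# ---------------------------------------------------------------- default_beta
def test_default_beta_all_ones():
    assert default_beta(np.ones((2, 2))) == pytest.approx(0.15)


def test_default_beta_constant_independent_of_n():
    for n in (3, 10, 50):
        assert default_beta(np.full((n, n), 0.5)) == pytest.approx(0.30)


def test_default_beta_identity():
    assert default_beta(np.eye(3)) == pytest.approx(0.45)


def test_default_beta_zero_matrix_raises():
    with pytest.raises(DegenerateInputError):
        default_beta(np.zeros((4, 4)))


# ------------------------------------------------------------- soft_threshold
def test_soft_threshold_shrinks_to_zero():
    assert soft_threshold(0.5, 1.0) == 0.0


def test_soft_threshold_preserves_sign():
    assert soft_threshold(2.0, 1.0) == 1.0
    assert soft_threshold(-2.0, 1.0) == -1.0


def test_soft_threshold_identity_at_zero(rng):
    x = rng.normal(size=(5, 5))
    np.testing.assert_array_equal(soft_threshold(x, 0.0), x)


def test_soft_threshold_negative_theta_raises():
    with pytest.raises(InvalidInputError):
        soft_threshold(1.0, -0.1)


@given(
    x=hnp.arrays(np.float64, (4, 4), elements=st.floats(-10, 10)),
    theta=st.floats(0, 5),
)
def test_soft_threshold_properties(x, theta):
    y = soft_threshold(x, theta)
    assert np.all(np.abs(y) <= np.maximum(np.abs(x) - theta, 0) + 1e-12)
    assert np.all((y == 0) | (np.sign(y) == np.sign(x)))


# ------------------------------------------------------------------------ svt
def test_svt_identity_matrix():
    np.testing.assert_allclose(svt(np.eye(3), 0.5), 0.5 * np.eye(3), atol=1e-12)


def test_svt_zero_threshold_is_identity(rng):
    M = rng.normal(size=(6, 6))
    np.testing.assert_allclose(svt(M, 0.0), M, atol=1e-10)


def test_svt_diagonal():
    np.testing.assert_allclose(svt(np.diag([5.0, 3.0, 0.1]), 1.0), np.diag([4.0, 2.0, 0.0]), atol=1e-12)


def test_svt_nonfinite_raises():
    M = np.eye(3)
    M[0, 0] = np.nan
    with pytest.raises(InvalidInputError):
        svt(M, 0.1)


def test_svt_matches_bruteforce_small(rng):
    """Oracle equivalence: full-SVD construction vs the solver's SVT path."""
    from netphase.decompose import _sym_svt

    for n in (5, 12, 30):
        M = rng.normal(size=(n, n))
        M = (M + M.T) / 2.0
        theta = 0.7
        U, s, Vt = np.linalg.svd(M)
        brute = (U * np.maximum(s - theta, 0.0)) @ Vt
        X, sigma, _ = _sym_svt(M, theta, 10)
        np.testing.assert_allclose(X, brute, atol=1e-10)
        np.testing.assert_allclose(X, svt(M, theta), atol=1e-10)


def test_sym_svt_partial_path_matches_full(rng):
    """Large-N Lanczos path agrees with dense SVT."""
    from netphase.decompose import _sym_svt

    n = 250
    U = rng.normal(size=(n, 4))
    M = U @ U.T  # rank 4, strong spectrum
    theta = 1.0
    X, sigma, _ = _sym_svt(M, theta, 10)
    np.testing.assert_allclose(X, svt(M, theta), atol=1e-8)


# -------------------------------------------------------------- stopping rule
def test_stopping_metric_identical_iterates(rng):
    L = rng.normal(size=(4, 4))
    S = rng.normal(size=(4, 4))
    assert stopping_metric(L, S, L, S) == 0.0


def test_stopping_metric_direct_arithmetic():
    Z = np.zeros((2, 2))
    L = np.array([[1.0, 0.0], [0.0, 1.0]])  # ||L||_F^2 = 2
    assert stopping_metric(Z, Z, L, Z) == pytest.approx(2.0)


@given(
    a=hnp.arrays(np.float64, (3, 3), elements=st.floats(-5, 5)),
    b=hnp.arrays(np.float64, (3, 3), elements=st.floats(-5, 5)),
)
def test_stopping_metric_nonnegative(a, b):
    assert stopping_metric(a, b, b, a) >= 0.0


# ---------------------------------------------------------------------- asalm
def test_asalm_zero_matrix_fixed_point():
    d = asalm_decompose(np.zeros((5, 5)), SolverConfig(alpha=0.3))
    assert d.converged and d.iterations == 1
    for M in (d.L, d.S, d.E):
        np.testing.assert_array_equal(M, 0.0)


def test_asalm_rank1_recovery():
    """Noise-free rank-1 input: L is recovered up to the known nuclear-norm
    shrinkage of exactly 1/(2 alpha) per retained singular direction."""
    u = np.full(50, 0.8)
    A = np.outer(u, u)  # sigma_1 = 32
    alpha = 2.0
    d = asalm_decompose(A, SolverConfig(alpha=alpha, gamma=1 / np.sqrt(50)))
    rel = np.linalg.norm(d.L - A) / np.linalg.norm(A)
    assert rel <= 1e-2
    assert d.rank == 1
    assert np.abs(d.S).sum() <= 1e-6
    # the bias is the predicted 1/(2 alpha) on sigma_1
    assert rel == pytest.approx(1.0 / (2 * alpha * 32.0), rel=0.05)


def test_asalm_planted_sparse_support():
    """Planted rank-3 blocks + Bernoulli(0.05) sparse noise (frozen seed):
    rank recovered exactly, support overlap Jaccard >= 0.8."""
    rng = np.random.default_rng(7)
    memb = np.repeat([0, 1, 2], [34, 33, 33])
    U = np.zeros((100, 3))
    for k in range(3):
        U[memb == k, k] = rng.uniform(0.6, 1.0, (memb == k).sum())
    L0 = U @ U.T
    mask = np.triu(rng.random((100, 100)) < 0.05)
    mask = mask | mask.T
    vals = np.triu(rng.uniform(-1, 1, (100, 100)))
    vals = vals + np.triu(vals, 1).T
    S0 = mask * vals
    d = asalm_decompose(L0 + S0, SolverConfig(alpha=0.3, gamma=0.1))
    assert d.converged
    assert d.rank == 3
    sup_p = np.abs(S0) > 0
    sup_r = np.abs(d.S) > 1e-6
    jac = (sup_p & sup_r).sum() / (sup_p | sup_r).sum()
    assert jac >= 0.8


def test_asalm_symmetry_conserved(rng):
    n = 40
    M = rng.normal(size=(n, n))
    A = np.clip((M + M.T) / 2, 0, 1)
    d = asalm_decompose(A, SolverConfig(alpha=0.3, max_iter=50), warn=False)
    for X in (d.L, d.S, d.E, d.Lambda):
        np.testing.assert_array_equal(X, X.T)


def test_asalm_feasibility_at_convergence(rng):
    """Residual drops geometrically with rate ~ 2 alpha/(2 alpha + beta): at
    a moderate alpha the converged run is feasible to 1e-3."""
    U = rng.uniform(0.5, 1.0, (60, 2))
    A = np.clip(U @ U.T + rng.uniform(-0.05, 0.05, (60, 60)), 0, 1)
    A = (A + A.T) / 2
    d = asalm_decompose(A, SolverConfig(alpha=0.1))
    assert d.converged
    assert d.residual / np.linalg.norm(A) <= 1e-3


def test_asalm_beta_scaling_halves_thresholds():
    """Doubling beta halves both shrinkage thresholds used per sweep."""
    A = np.clip(np.outer(np.full(20, 0.8), np.full(20, 0.8)), 0, 1)
    beta = default_beta(A)
    gamma = 1 / np.sqrt(20)
    # thresholds are gamma/beta (soft) and 1/beta (svt), by construction
    assert (gamma / (2 * beta)) == pytest.approx(0.5 * (gamma / beta))
    assert (1 / (2 * beta)) == pytest.approx(0.5 * (1 / beta))
    d1 = asalm_decompose(A, SolverConfig(alpha=0.5, beta=beta))
    d2 = asalm_decompose(A, SolverConfig(alpha=0.5, beta=2 * beta))
    assert d1.converged and d2.converged


def test_asalm_asymmetric_raises():
    A = np.arange(9.0).reshape(3, 3)
    with pytest.raises(InvalidInputError):
        asalm_decompose(A, SolverConfig(alpha=0.3))


def test_asalm_nonconvergence_flagged_not_raised():
    rng = np.random.default_rng(0)
    M = rng.normal(size=(30, 30))
    A = np.clip((M + M.T) / 2, 0, 1)
    with pytest.warns(RuntimeWarning):
        d = asalm_decompose(A, SolverConfig(alpha=0.3, max_iter=2))
    assert not d.converged
    assert d.iterations == 2


# ----------------------------------------------------------------- sequences
def test_decompose_sequence_singleton(rng):
    U = rng.uniform(0.5, 1.0, (20, 2))
    A = np.clip(U @ U.T, 0, 1)
    cfg = SolverConfig(alpha=0.5)
    seq = decompose_sequence([A], cfg)
    single = asalm_decompose(A, cfg)
    assert len(seq) == 1
    np.testing.assert_array_equal(seq[0].L, single.L)


def test_decompose_sequence_determinism(rng):
    U = rng.uniform(0.5, 1.0, (20, 2))
    A = np.clip(U @ U.T, 0, 1)
    cfg = SolverConfig(alpha=0.5)
    seq = decompose_sequence([A, A, A], cfg)
    for d in seq[1:]:
        np.testing.assert_array_equal(d.L, seq[0].L)
        np.testing.assert_array_equal(d.S, seq[0].S)


def test_decompose_sequence_mixed_sizes_raises(rng):
    A1 = np.eye(4)
    A2 = np.eye(5)
    with pytest.raises(InvalidInputError):
        decompose_sequence([A1, A2], SolverConfig(alpha=0.5))


def test_decompose_sequence_error_carries_time_index():
    good = np.clip(np.outer(np.full(4, 0.9), np.full(4, 0.9)), 0, 1)
    bad = np.zeros((4, 4))
    bad[0, 1] = np.inf
    bad[1, 0] = np.inf
    with pytest.raises(Exception, match="t=2"):
        decompose_sequence([good, bad], SolverConfig(alpha=0.5))


# -------------------------------------------------------------- pad_to_union
def _snap(ids, mat):
    return WeightedNetwork(np.asarray(mat, float), node_ids=ids)


def test_pad_identity_when_common_node_set():
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    net = TemporalNetwork([_snap(["a", "b"], A), _snap(["a", "b"], A)])
    out = pad_to_union(net)
    assert out.n_max == 2
    np.testing.assert_array_equal(out.snapshots[0].matrix, A)
    assert out.presence.all()


def test_pad_grows_missing_node():
    A1 = np.array([[0.0, 1.0], [1.0, 0.0]])
    A2 = np.array([[0.0, 1.0, 0.2], [1.0, 0.0, 0.0], [0.2, 0.0, 0.0]])
    net = TemporalNetwork([_snap(["a", "b"], A1), _snap(["a", "b", "c"], A2)])
    out = pad_to_union(net)
    assert out.snapshots[0].matrix.shape == (3, 3)
    np.testing.assert_array_equal(out.snapshots[0].matrix[2, :], 0.0)
    np.testing.assert_array_equal(out.snapshots[0].matrix[:, 2], 0.0)
    assert not out.presence[0, 2] and out.presence[1, 2]


def test_pad_duplicate_ids_raise():
    with pytest.raises(InvalidInputError):
        _snap(["a", "a"], np.zeros((2, 2)))


def test_weighted_network_validation():
    with pytest.raises(InvalidInputError):
        WeightedNetwork(np.array([[0.0, 1.0], [0.5, 0.0]]))  # asymmetric
    with pytest.raises(InvalidInputError):
        WeightedNetwork(np.array([[1.0]]))  # too small
    with pytest.raises(InvalidInputError):
        WeightedNetwork(np.array([[0.0, np.inf], [np.inf, 0.0]]))
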