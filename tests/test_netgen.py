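import numpy as np
import pytest

from netphase.netgen import (
    FactorSpec,
    SBMSpec,
    WSBMSpec,
    build_scenario,
    gen_dense_noise,
    gen_factor_L,
    gen_sbm_L,
    gen_sbm_noise,
    gen_sparse_noise,
    gen_wsbm_L,
    project_omega,
)
from netphase.types import InvalidInputError


# -------------------------------------------------------------- factor model
def test_factor_single_community_rank1():
    memb = np.zeros(20, int)
    L = gen_factor_L(memb, FactorSpec(r_out=0.0), np.random.default_rng(0))
    assert np.linalg.matrix_rank(L) == 1
    assert np.all(L >= 0.6**2 - 1e-12)


def test_factor_block_diagonal_when_rout_zero():
    memb = np.repeat([0, 1, 2], 10)
    L = gen_factor_L(memb, FactorSpec(r_out=0.0), np.random.default_rng(0))
    assert np.linalg.matrix_rank(L) == 3
    assert np.all(L[:10, 10:] == 0.0)


def test_factor_default_spec_k11_thresholded_rank():
    """Singular spectrum of the generated matrix has exactly 11 dominant
    values at moderate threshold."""
    sizes = [30] * 11
    memb = np.repeat(np.arange(11), 30)
    memb = np.concatenate([memb, np.full(20, -1)])  # outliers
    L = gen_factor_L(memb, FactorSpec(), np.random.default_rng(5))
    s = np.linalg.svd(L, compute_uv=False)
    assert int(np.sum(s > 3.0)) == 11


def test_factor_invalid_spec():
    with pytest.raises(InvalidInputError):
        FactorSpec(r_in=0.3, r_out=0.4)


def test_factor_no_community_raises():
    with pytest.raises(InvalidInputError):
        gen_factor_L(np.full(5, -1), FactorSpec(), np.random.default_rng(0))


# -------------------------------------------------------------------- noises
def test_sparse_noise_zero_density():
    S = gen_sparse_noise(10, 0.0, np.random.default_rng(0))
    np.testing.assert_array_equal(S, 0.0)


def test_dense_noise_zero_amplitude():
    E = gen_dense_noise(10, 0.0, np.random.default_rng(0))
    np.testing.assert_array_equal(E, 0.0)


def test_sparse_noise_full_density():
    rng = np.random.default_rng(1)
    S = gen_sparse_noise(30, 1.0, rng, np.random.default_rng(2))
    assert np.all(S != 0.0) or np.isclose((S != 0).mean(), 1.0, atol=0.01)


def test_sparse_noise_binomial_density():
    """Upper-triangle support fraction within 3 binomial SDs of p_s."""
    n, p = 300, 0.1
    S = gen_sparse_noise(n, p, np.random.default_rng(3), np.random.default_rng(4))
    iu = np.triu_indices(n)
    frac = np.mean(S[iu] != 0.0)
    m = len(iu[0])
    sd = np.sqrt(p * (1 - p) / m)
    assert abs(frac - p) <= 3 * sd + 1e-6  # values ~ Unif(-1,1) never exactly 0


def test_noise_symmetry():
    S = gen_sparse_noise(20, 0.3, np.random.default_rng(0), np.random.default_rng(1))
    E = gen_dense_noise(20, 0.2, np.random.default_rng(2))
    np.testing.assert_array_equal(S, S.T)
    np.testing.assert_array_equal(E, E.T)
    assert np.all(np.abs(E) < 0.2)


# ---------------------------------------------------------------- projection
def test_project_omega_fixed_point():
    X = np.clip(np.random.default_rng(0).random((5, 5)), 0, 1)
    X = (X + X.T) / 2
    np.testing.assert_array_equal(project_omega(X), X)


def test_project_omega_clips():
    X = np.array([[1.3, -0.2], [-0.2, 0.5]])
    P = project_omega(X)
    assert P[0, 0] == 1.0 and P[0, 1] == 0.0


def test_project_omega_symmetrizes():
    X = np.array([[0.0, 0.2], [0.6, 0.0]])
    P = project_omega(X)
    assert P[0, 1] == P[1, 0] == pytest.approx(0.4)


# ------------------------------------------------------------------ SBM/WSBM
def test_sbm_full_density_no_noise():
    memb = np.repeat([0, 1], 10)
    L = gen_sbm_L(memb, 1.0, np.random.default_rng(0))
    assert np.all(L[:10, :10] == 1.0)
    assert np.all(L[:10, 10:] == 0.0)


def test_sbm_within_density_simulation():
    memb = np.repeat([0], 200)
    rng = np.random.default_rng(7)
    L = gen_sbm_L(memb, 0.3, rng)
    A = project_omega(L + gen_sbm_noise(200, 0.05, rng))
    assert set(np.unique(A)) <= {0.0, 1.0}
    iu = np.triu_indices(200, 1)
    # P(edge) = 0.3 + 0.7*0.05 (zero flipped up); down-flips clip back to 0... up
    expected = 0.3 * 0.95 + 0.3 * 0.05 + 0.7 * 0.05  # kept + (1 clipped to 1) + raised
    assert np.mean(A[iu]) == pytest.approx(expected, abs=0.03)


def test_sbm_negative_flip_clipped():
    memb = np.repeat([0, 1], 5)
    A = project_omega(gen_sbm_L(memb, 1.0, np.random.default_rng(0)) - np.ones((10, 10)))
    assert np.all(A >= 0.0)


def test_wsbm_degenerate_ub_zero():
    memb = np.repeat([0, 1], 8)
    spec = WSBMSpec.from_ub(0.0)
    L = gen_wsbm_L(memb, spec, np.random.default_rng(0))
    assert np.all(L[:8, :8] == 1.0)
    assert np.all(L[:8, 8:] == 0.0)


def test_wsbm_segment_average_means():
    """Averaged within-community weight -> 0.7, between -> 0.3 for the
    (0.4,1)/(0,0.6) ranges."""
    memb = np.repeat([0, 1], 40)
    spec = WSBMSpec()
    rng = np.random.default_rng(9)
    Ls = [gen_wsbm_L(memb, spec, rng) for _ in range(40)]
    L_bar = np.mean(Ls, axis=0)
    within = L_bar[:40, :40][np.triu_indices(40, 1)].mean()
    between = L_bar[:40, 40:].mean()
    assert within == pytest.approx(0.7, abs=0.02)
    assert between == pytest.approx(0.3, abs=0.02)


def test_wsbm_invalid_ranges():
    with pytest.raises(InvalidInputError):
        WSBMSpec(in_low=0.0, in_high=0.4, out_low=0.3, out_high=0.6)


# ------------------------------------------------------------------ scenarios
def test_scenario_unknown_preset():
    with pytest.raises(InvalidInputError, match="available"):
        build_scenario("nope")


def test_three_model_shapes_and_truth():
    net, tl, info = build_scenario("three-model-factor", seed=0, n_scale=0.1)
    assert net.T == 30
    assert tl.epochs == [(9, 10), (19, 20)]
    m1 = tl.membership_at(5)
    m2 = tl.membership_at(15)
    m3 = tl.membership_at(25)
    assert len({c for c in np.unique(m1) if c >= 0}) == 11
    assert len({c for c in np.unique(m2) if c >= 0}) == 9
    assert len({c for c in np.unique(m3) if c >= 0}) == 7


def test_illustrative_presence_pattern():
    net, tl, info = build_scenario("illustrative", seed=0, n_scale=0.05, t_scale=0.2)
    # joiners absent in segment 1, present in segment 2
    from netphase.types import pad_to_union

    padded = pad_to_union(net)
    T = net.T
    seg1_t = tl.segments[0][1]
    seg2_t = tl.segments[1][0]
    assert padded.presence[seg1_t - 1].sum() < padded.presence[seg2_t - 1].sum()
    # segment 4 has 12 communities; segment 3 has 7
    m3 = tl.segments[2][2]
    m4 = tl.segments[3][2]
    assert len({c for c in np.unique(m3) if c >= 0}) == 7
    assert len({c for c in np.unique(m4) if c >= 0}) == 12


def test_wsbm_split_sizes():
    net, tl, info = build_scenario("wsbm-split", seed=0, n_scale=0.2)
    assert net.T == 40
    assert tl.epochs == [(20, 21)]
    m1, m2 = tl.segments[0][2], tl.segments[1][2]
    assert len(np.unique(m1)) == 4
    assert len(np.unique(m2)) == 5
    # split halves partition the original community
    assert set(np.flatnonzero(m2 == 0)) | set(np.flatnonzero(m2 == 4)) == set(
        np.flatnonzero(m1 == 0)
    )


def test_scenario_determinism():
    a = build_scenario("three-model-wsbm", seed=4, n_scale=0.08)
    b = build_scenario("three-model-wsbm", seed=4, n_scale=0.08)
    for sa, sb in zip(a[0].snapshots, b[0].snapshots):
        np.testing.assert_array_equal(sa.matrix, sb.matrix)
    c = build_scenario("three-model-wsbm", seed=5, n_scale=0.08)
    assert any(
        not np.array_equal(sa.matrix, sc.matrix)
        for sa, sc in zip(a[0].snapshots, c[0].snapshots)
    )


def test_scenario_outputs_in_omega():
    for preset in ("three-model-factor", "three-model-sbm", "three-model-wsbm"):
        net, _, _ = build_scenario(preset, seed=1, n_scale=0.06)
        for snap in net.snapshots[:5]:
            A = snap.matrix
            assert np.all((A >= 0) & (A <= 1))
            np.testing.assert_array_equal(A, A.T)
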