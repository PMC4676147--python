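"""Unit tests of the WPLA solver blocks and the bi-convex alternation."""

import numpy as np
import pytest

from wpla.solver import (
    Hyperparams,
    NumericError,
    adapt_rho,
    adaptive_beta_matrix,
    build_svt_target,
    effective_rank,
    objective,
    rho_beta,
    solve_adaptive_wpla,
    solve_wpla,
    solve_x_given_w,
    svt,
    update_dual,
    update_weights,
    update_Z,
)

HP = Hyperparams(alpha1=1.0, alpha2=1.0, beta=1.0, rho0=1.0)


# ---------------------------------------------------------------- objective

def test_objective_vanishes_at_perfect_zero_fit():
    D = np.zeros((3, 4))
    assert objective(D, D, np.ones_like(D), HP) == 0.0


def test_objective_reduces_to_half_frobenius(rng):
    D = rng.normal(size=(5, 7))
    got = objective(D, np.zeros_like(D), np.ones_like(D), HP)
    assert got == pytest.approx(0.5 * np.sum(D**2))


def test_objective_identity_hand_value():
    # fidelity 1/2*||I||^2 = 1, nuclear 2, TV per row 1+1 = 2 -> total 5
    D = np.zeros((2, 2))
    X = np.eye(2)
    assert objective(D, X, np.ones_like(D), HP) == pytest.approx(5.0)


def test_objective_rejects_out_of_range_weights(rng):
    D = rng.normal(size=(3, 3))
    W = np.ones_like(D)
    W[0, 0] = 1.5
    with pytest.raises(ValueError):
        objective(D, D, W, HP)
    W[0, 0] = 0.0
    with pytest.raises(ValueError):
        objective(D, D, W, HP)


# ------------------------------------------------------------------ weights

@pytest.mark.parametrize(
    "beta,resid,expected",
    [
        (1.0, 2.0, 0.5),  # sqrt(beta)/|r|
        (1.0, 0.0, 1.0),  # small residual keeps full weight
        (0.04, 0.2, 1.0),  # boundary |r| = sqrt(beta) belongs to the 1-branch
    ],
)
def test_update_weights_formula(beta, resid, expected):
    W = update_weights(np.array([[resid]]), np.array([[0.0]]), beta)
    assert W[0, 0] == pytest.approx(expected)


def test_update_weights_always_in_unit_interval(rng):
    D = 0.5 * rng.standard_t(1, size=(20, 30))  # includes huge residuals
    W = update_weights(D, np.zeros_like(D), 0.25)
    assert np.all(W > 0) and np.all(W <= 1)


# ----------------------------------------------------------------- rho_beta

def test_rho_beta_values():
    assert rho_beta(0.0, 1.0) == 0.0
    assert rho_beta(1.0, 1.0) == pytest.approx(1.0)  # continuity at |t| = sqrt(beta)
    assert rho_beta(np.e, 1.0) == pytest.approx(3.0)  # log branch: log(e^2) + 1


def test_weight_profile_equals_redescending_loss():
    """min_w w^2 t^2 + 2 beta |log w| = rho_beta(t), attained at Eq-8 weights."""
    from scipy.optimize import minimize_scalar

    for t in (0.0, 0.05, 0.3, 1.0, 2.5, 10.0, -4.0):
        for beta in (0.04, 0.25, 1.0, 4.0):
            w_star = update_weights(np.array([[t]]), np.array([[0.0]]), beta)[0, 0]
            val_at_star = w_star**2 * t**2 + 2 * beta * abs(np.log(w_star))
            assert val_at_star == pytest.approx(rho_beta(t, beta), abs=1e-10)
            res = minimize_scalar(
                lambda w: w**2 * t**2 + 2 * beta * abs(np.log(w)),
                bounds=(1e-9, 1.0),
                method="bounded",
                options={"xatol": 1e-12},
            )
            assert rho_beta(t, beta) <= res.fun + 1e-8


# ------------------------------------------------------------- ADMM pieces

def test_build_svt_target_fixed_point():
    D = np.arange(6, dtype=float).reshape(2, 3)
    C = build_svt_target(D, np.ones_like(D), D, np.zeros_like(D), rho=2.0)
    np.testing.assert_allclose(C, D)


def test_build_svt_target_hand_value():
    C = build_svt_target(
        np.array([[2.0]]), np.array([[0.5]]), np.array([[1.0]]), np.array([[0.5]]), rho=1.0
    )
    assert C[0, 0] == pytest.approx(0.5)  # (0.25*2 + 1 - 0.5) / 2


def test_build_svt_target_weightless_limit(rng):
    D = rng.normal(size=(3, 4))
    Z = rng.normal(size=(3, 4))
    W = np.full_like(D, 1e-9)
    C = build_svt_target(D, W, Z, np.zeros_like(D), rho=3.0)
    np.testing.assert_allclose(C, 3.0 * Z / 4.0, atol=1e-9)


def test_build_svt_target_requires_positive_rho(rng):
    D = rng.normal(size=(2, 2))
    with pytest.raises(ValueError):
        build_svt_target(D, np.ones_like(D), D, np.zeros_like(D), rho=0.0)


def test_svt_zero_threshold_is_identity(rng):
    C = rng.normal(size=(4, 6))
    np.testing.assert_allclose(svt(C, 0.0), C)


def test_svt_diagonal_case():
    C = np.diag([3.0, 1.0, 0.5])
    X = svt(C, 1.0)
    s = np.linalg.svd(X, compute_uv=False)
    np.testing.assert_allclose(s, [2.0, 0.0, 0.0], atol=1e-12)
    assert effective_rank(X) == 1


def test_svt_matches_eigendecomposition_oracle(rng):
    """Independent route: soft-threshold the eigenvalues of the symmetric
    dilation [[0, C], [C^T, 0]], whose positive spectrum is the singular
    spectrum of C."""
    C = rng.normal(size=(6, 8))
    tau = float(np.median(np.linalg.svd(C, compute_uv=False)))
    n, p = C.shape
    M = np.zeros((n + p, n + p))
    M[:n, n:] = C
    M[n:, :n] = C.T
    vals, vecs = np.linalg.eigh(M)
    shrunk = np.sign(vals) * np.maximum(np.abs(vals) - tau, 0.0)
    X_oracle = (vecs * shrunk) @ vecs.T
    np.testing.assert_allclose(svt(C, tau), X_oracle[:n, n:], atol=1e-8)


def test_svt_minimizes_nuclear_objective(rng):
    C = rng.normal(size=(5, 5))
    tau = 0.8
    X = svt(C, tau)

    def f(M):
        return np.sum((C - M) ** 2) + 2 * tau * np.sum(np.linalg.svd(M, compute_uv=False))

    base = f(X)
    for _ in range(50):
        assert base <= f(X + rng.normal(0, 0.05, X.shape)) + 1e-10


def test_svt_rejects_non_finite():
    C = np.ones((2, 2))
    C[0, 0] = np.nan
    with pytest.raises(ValueError):
        svt(C, 0.5)


def test_update_Z_zero_penalty(rng):
    X, Y = rng.normal(size=(3, 5)), rng.normal(size=(3, 5))
    np.testing.assert_allclose(update_Z(X, Y, rho=2.0, alpha2=0.0), X + Y / 2.0)


def test_update_Z_constant_rows_fixed():
    X = np.full((2, 6), 1.3)
    Z = update_Z(X, np.zeros_like(X), rho=1.0, alpha2=5.0)
    np.testing.assert_allclose(Z, X, atol=1e-12)


def test_update_Z_single_row_example():
    X = np.array([[0.0, 0.0, 1.0, 1.0]])
    Z = update_Z(X, np.zeros_like(X), rho=1.0, alpha2=0.25)
    np.testing.assert_allclose(Z, [[0.125, 0.125, 0.875, 0.875]], atol=1e-12)


def test_update_dual():
    Y = np.array([[1.0]])
    assert update_dual(Y, np.array([[0.5]]), np.array([[1.0]]), rho=2.0)[0, 0] == 0.0
    X, Z = np.array([[2.0]]), np.array([[0.5]])
    assert update_dual(np.zeros((1, 1)), X, Z, rho=1.0)[0, 0] == 1.5
    np.testing.assert_array_equal(update_dual(Y, X, X, rho=3.0), Y)


def test_adapt_rho_residual_balancing():
    assert adapt_rho(1.0, 11.0, 1.0) == 2.0
    assert adapt_rho(1.0, 1.0, 1.0) == 1.0
    assert adapt_rho(1.0, 1.0, 11.0) == 0.5


# ------------------------------------------------------- inner ADMM / outer

def test_inner_admm_zero_matrix_fixed_point():
    D = np.zeros((4, 6))
    X, Z, Y, rho, trace = solve_x_given_w(D, np.ones_like(D), 0.5, 0.1, 1.0, max_iter=5)
    assert np.all(X == 0)


def test_inner_admm_huge_nuclear_penalty_kills_everything(rng):
    D = rng.normal(size=(6, 10))
    smax = np.linalg.norm(D, 2)
    rho = 0.5
    X, *_ = solve_x_given_w(D, np.ones_like(D), alpha1=smax * (1 + rho) * 2, alpha2=1e-8,
                            rho0=rho, max_iter=200)
    assert np.linalg.norm(X) < 1e-8 * smax


def test_inner_admm_recovers_noiseless_low_rank_piecewise(rng):
    u = rng.uniform(0.5, 1.5, size=10)
    v = np.zeros(20)
    v[5:12] = 1.0
    D = np.outer(u, v)
    X, *_ = solve_x_given_w(D, np.ones_like(D), alpha1=0.1, alpha2=0.01, rho0=1.0,
                            max_iter=500, tol=1e-6)
    assert np.linalg.norm(X - D) / np.linalg.norm(D) < 0.1


def test_solve_wpla_zero_data():
    D = np.zeros((3, 5))
    fit = solve_wpla(D, HP)
    assert np.all(fit.X_hat == 0)
    assert np.all(fit.W_hat == 1.0)


def test_solve_wpla_rejects_non_finite():
    D = np.zeros((3, 5))
    D[1, 2] = np.inf
    with pytest.raises(ValueError):
        solve_wpla(D, HP)


def test_single_outlier_is_downweighted_not_fitted(rng):
    D = rng.normal(0, 0.1, (10, 20))
    D[3, 7] += 8.0
    hp = Hyperparams(alpha1=1.0, alpha2=0.1, beta=0.25, rho0=0.5)
    fit = solve_wpla(D, hp)
    assert fit.W_hat[3, 7] < 0.1
    others = np.delete(fit.W_hat.ravel(), 3 * 20 + 7)
    assert np.all(others == 1.0)
    assert np.linalg.norm(fit.X_hat) < 0.5


def test_objective_trace_non_increasing(case1_fit):
    tr = case1_fit.objective_trace
    assert len(tr) >= 1 and np.all(np.isfinite(tr))
    assert np.all(np.diff(tr) <= 1e-8 * (1.0 + np.abs(tr[:-1])))


def test_fitted_weights_in_unit_interval(case1_fit):
    W = case1_fit.W_hat
    assert np.all(W > 0) and np.all(W <= 1)


def test_effective_rank_non_increasing_in_alpha1(rng):
    u = np.ones(15)
    v = np.zeros(40)
    v[10:20] = 1.0
    D = np.outer(u, v) + rng.normal(0, 0.3, (15, 40))
    ranks = []
    for a1 in (0.5, 2.0, 5.0, 12.0):
        hp = Hyperparams(alpha1=a1, alpha2=0.1 * a1, beta=0.2, rho0=1.0)
        ranks.append(solve_wpla(D, hp).effective_rank)
    assert all(a >= b for a, b in zip(ranks, ranks[1:]))


def test_downweighting_limits_contamination_damage(case1_sim, case1_fit):
    """Corrupting 5% of cells at +/-10 moves the robust fit far less than a
    weights-fixed-at-1 fit."""
    D = case1_sim.D.values
    rng = np.random.default_rng(5)
    Dc = D.copy()
    idx = rng.choice(D.size, size=int(0.05 * D.size), replace=False)
    Dc.ravel()[idx] = rng.choice([-10.0, 10.0], size=idx.size)

    hp = Hyperparams.from_data(D)
    fit_c = solve_wpla(Dc, hp)
    delta_robust = np.linalg.norm(fit_c.X_hat - case1_fit.X_hat)

    ones = np.ones_like(D)
    Xa, *_ = solve_x_given_w(D, ones, hp.alpha1, hp.alpha2, hp.rho0, max_iter=hp.max_inner, tol=hp.tol)
    Xac, *_ = solve_x_given_w(Dc, ones, hp.alpha1, hp.alpha2, hp.rho0, max_iter=hp.max_inner, tol=hp.tol)
    delta_plain = np.linalg.norm(Xac - Xa)

    assert delta_robust < 0.25 * delta_plain


# ----------------------------------------------------------------- adaptive

def test_adaptive_beta_matrix_values():
    W0 = np.array([[1.0, np.exp(-1.0), np.exp(-4.0)]])
    B = adaptive_beta_matrix(W0, beta=0.5, denom_floor=0.001)
    np.testing.assert_allclose(B, [[500.0, 0.5, 0.25]])


def test_adaptive_with_unit_start_pins_all_weights(rng):
    D = rng.normal(0, 0.2, (8, 15))
    D[2, 3] += 6.0
    hp = Hyperparams(alpha1=1.0, alpha2=0.1, beta=0.2, rho0=0.5, adaptive=True)
    fit = solve_adaptive_wpla(D, hp, W0=np.ones_like(D))
    assert np.all(fit.W_hat == 1.0)


def test_adaptive_two_stage_keeps_outlier_downweighted(rng):
    D = rng.normal(0, 0.1, (10, 20))
    D[4, 11] += 8.0
    hp = Hyperparams(alpha1=1.0, alpha2=0.1, beta=0.25, rho0=0.5)
    first = solve_wpla(D, hp)
    second = solve_adaptive_wpla(D, hp, W0=first.W_hat)
    assert second.W_hat[4, 11] < 0.2
    clean = np.delete(second.W_hat.ravel(), 4 * 20 + 11)
    assert np.all(clean == 1.0)


def test_adaptive_rejects_bad_w0(rng):
    D = rng.normal(size=(4, 6))
    with pytest.raises(ValueError):
        solve_adaptive_wpla(D, HP, W0=np.full_like(D, 1.2))
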