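import numpy as np
import pytest
from scipy.optimize import nnls as activeset_nnls

from spotdeconv import (
    SolverConfig,
    cross_validate_lambda,
    nnls_estimate,
    nnls_objective,
    ols_estimate,
)


def _fast_cfg(**kw):
    kw.setdefault("learning_rate", 0.01)
    kw.setdefault("num_epochs", 10_000)
    kw.setdefault("ridge_lambda", 0.0)
    return SolverConfig(**kw)


class TestOLS:
    def test_identity_design_returns_y(self):
        X = np.eye(2)
        M = ols_estimate(np.array([[3.0, 5.0]]), X)
        np.testing.assert_allclose(M.weights, [[3.0, 5.0]])
        assert M.estimator == "OLS"
        assert not M.pinv_fallback

    def test_single_prototype_projection(self):
        # regress (2,4) on (1,2): (2*1 + 4*2) / (1 + 4) = 2
        M = ols_estimate(np.array([[2.0, 4.0]]), np.array([[1.0, 2.0]]))
        np.testing.assert_allclose(M.weights, [[2.0]])

    def test_negative_weights_possible(self):
        # normal equations of X=[[1,0],[1,1]], Y=[[0,1]] solve to (-1, 1)
        M = ols_estimate(np.array([[0.0, 1.0]]), np.array([[1.0, 0.0], [1.0, 1.0]]))
        np.testing.assert_allclose(M.weights, [[-1.0, 1.0]], atol=1e-12)

    def test_matches_generic_lstsq_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(4, 8))
        Y = rng.uniform(size=(3, 8))
        M = ols_estimate(Y, X).weights
        oracle = np.linalg.lstsq(X.T, Y.T, rcond=None)[0].T
        np.testing.assert_allclose(M, oracle, atol=1e-10)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(4, 9))
        Y = rng.uniform(size=(5, 9))
        M = ols_estimate(Y, X).weights
        np.testing.assert_allclose((M @ X - Y) @ X.T, 0.0, atol=1e-10)

    def test_rank_deficient_uses_pinv_and_flags(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 1.0]])  # duplicate prototypes
        Y = np.array([[2.0, 5.0]])
        M = ols_estimate(Y, X)
        assert M.pinv_fallback
        # still a least-squares solution: residual orthogonal to row space
        np.testing.assert_allclose((M.weights @ X - Y) @ X.T, 0.0, atol=1e-10)
        # minimum-norm solution spreads weight equally over duplicates
        np.testing.assert_allclose(M.weights[0, 0], M.weights[0, 1], atol=1e-10)

    def test_gene_dimension_mismatch(self):
        with pytest.raises(ValueError, match="gene dimensions"):
            ols_estimate(np.ones((1, 3)), np.ones((2, 4)))


class TestObjective:
    def test_perfect_fit_zero(self):
        X = np.array([[1.0, 2.0], [0.0, 1.0]])
        M = np.array([[2.0, 1.0]])
        assert nnls_objective(M, M @ X, X, 0.0) == 0.0

    def test_zero_weights_half_frobenius(self):
        Y = np.array([[3.0, 4.0]])
        assert nnls_objective(np.zeros((1, 2)), Y, np.eye(2), 0.0) == pytest.approx(12.5)

    def test_matches_termwise_summation_oracle(self):
        rng = np.random.default_rng(3)
        M, X, Y, lam = rng.normal(size=(3, 4)), rng.normal(size=(4, 5)), rng.normal(size=(3, 5)), 0.7
        expected = 0.0
        R = Y - M @ X
        for i in range(3):
            for j in range(5):
                expected += 0.5 * R[i, j] ** 2
        for i in range(3):
            for j in range(4):
                expected += 0.5 * lam * M[i, j] ** 2
        assert nnls_objective(M, Y, X, lam) == pytest.approx(expected)


class TestNNLS:
    def test_identity_design_feasible_optimum(self):
        Y = np.array([[1.0, 2.0], [0.5, 0.0]])
        M = nnls_estimate(Y, np.eye(2), _fast_cfg())
        np.testing.assert_allclose(M.weights, Y, atol=1e-6)
        assert M.estimator == "NNLS"
        assert M.lambda_used == 0.0

    def test_active_constraint_solution(self):
        # min (m1+m2)^2 + (m2-1)^2 over m >= 0 has optimum (0, 0.5)
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        Y = np.array([[0.0, 1.0]])
        M = nnls_estimate(Y, X, _fast_cfg())
        np.testing.assert_allclose(M.weights, [[0.0, 0.5]], atol=1e-4)

    def test_huge_ridge_shrinks_to_zero(self):
        rng = np.random.default_rng(4)
        Y, X = rng.uniform(size=(2, 5)), rng.uniform(size=(3, 5))
        M = nnls_estimate(Y, X, _fast_cfg(num_epochs=1000, learning_rate=1e-9), lam=1e8)
        assert np.linalg.norm(M.weights) < 1e-3

    def test_divergence_raises_with_advice(self):
        # mixed-sign design makes the overshooting fixed-step iteration blow up
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 4))
        Y = rng.normal(size=(2, 4)) ** 2
        with pytest.raises(FloatingPointError, match="learning_rate"):
            nnls_estimate(
                Y, X,
                SolverConfig(learning_rate=10.0, num_epochs=500, ridge_lambda=0.0, warm_start=False),
            )

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(6)
        Y, X = rng.uniform(size=(4, 6)), rng.uniform(size=(3, 6))
        M = nnls_estimate(Y, X, _fast_cfg(num_epochs=2000), record_objective=True)
        trace = M.objective_trace
        assert trace is not None and len(trace) > 1
        assert np.all(np.diff(trace) <= 1e-12)

    def test_warm_start_equals_clamped_ols_at_zero_epochs_limit(self):
        # one epoch from the warm start stays close to the clamped OLS point
        rng = np.random.default_rng(7)
        Y, X = rng.uniform(size=(2, 6)), rng.uniform(size=(2, 6))
        warm = np.maximum(ols_estimate(Y, X).weights, 0.0)
        M = nnls_estimate(Y, X, SolverConfig(learning_rate=1e-12, num_epochs=1, ridge_lambda=0.0))
        np.testing.assert_allclose(M.weights, warm, atol=1e-9)

    @pytest.mark.parametrize("warm", [True, False])
    def test_matches_activeset_oracle(self, warm):
        """Projected gradient at lambda=0 agrees with scipy's active-set NNLS."""
        for seed in range(203, 209):
            r = np.random.default_rng(seed)
            nc = int(r.integers(1, 5))
            ng = int(r.integers(nc, 7))
            ns = int(r.integers(1, 6))
            X, Y = r.uniform(size=(nc, ng)), r.uniform(size=(ns, ng))
            M = nnls_estimate(Y, X, _fast_cfg(warm_start=warm)).weights
            oracle = np.vstack([activeset_nnls(X.T, Y[i])[0] for i in range(ns)])
            assert nnls_objective(M, Y, X, 0.0) == pytest.approx(
                nnls_objective(oracle, Y, X, 0.0), abs=1e-4
            )

    def test_exact_recovery_full_rank(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(size=(3, 10))
        M_true = rng.uniform(size=(4, 3))
        M = nnls_estimate(M_true @ X, X, _fast_cfg()).weights
        np.testing.assert_allclose(M, M_true, atol=1e-5)

    def test_kkt_conditions_at_solution(self):
        rng = np.random.default_rng(9)
        X, Y = rng.uniform(size=(3, 6)), rng.uniform(size=(4, 6))
        M = nnls_estimate(Y, X, _fast_cfg()).weights
        grad = (M @ X - Y) @ X.T
        active = M > 1e-10
        if active.any():
            assert np.max(np.abs(grad[active])) < 1e-4
        if (~active).any():
            assert grad[~active].min() > -1e-4

    def test_interior_solution_matches_ridge_closed_form(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0.5, 1.5, size=(3, 8))
        M_true = rng.uniform(1.0, 2.0, size=(2, 3))
        Y = M_true @ X
        for lam in (0.01, 0.1, 0.5):
            M = nnls_estimate(Y, X, _fast_cfg(num_epochs=50_000), lam=lam).weights
            ridge = Y @ X.T @ np.linalg.inv(X @ X.T + lam * np.eye(3))
            assert np.all(M > 0), "test premise: solution must be interior"
            np.testing.assert_allclose(M, ridge, atol=1e-4)

    def test_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(11)
        X, Y = rng.uniform(size=(3, 8)), rng.uniform(size=(4, 8))
        norms = [
            np.linalg.norm(nnls_estimate(Y, X, _fast_cfg(num_epochs=20_000), lam=lam).weights)
            for lam in np.arange(0.0, 0.21, 0.02)
        ]
        assert np.all(np.diff(norms) <= 1e-8)


class TestCrossValidation:
    def test_single_grid_value_selected(self):
        rng = np.random.default_rng(12)
        Y, X = rng.uniform(size=(3, 10)), rng.uniform(size=(2, 10))
        rep = cross_validate_lambda(Y, X, _fast_cfg(ridge_lambda=[0.3], n_fold=2, num_epochs=500))
        assert rep.selected_lambda == 0.3
        assert rep.fold_mse.shape == (1, 2)

    def test_noiseless_selects_zero(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(0.5, 1.5, size=(3, 30))
        M_true = rng.uniform(size=(5, 3))
        Y = M_true @ X
        cfg = _fast_cfg(ridge_lambda=(0.0, 0.1, 1.0), n_fold=3, num_epochs=2000, seed=13)
        rep = cross_validate_lambda(Y, X, cfg)
        assert rep.selected_lambda == 0.0
        assert rep.mean_mse[0] < rep.mean_mse[1:].min()

    def test_fold_assignment_reproducible(self):
        rng = np.random.default_rng(14)
        Y, X = rng.uniform(size=(3, 12)), rng.uniform(size=(2, 12))
        cfg = _fast_cfg(ridge_lambda=(0.0, 0.5), n_fold=3, num_epochs=200, seed=99)
        a = cross_validate_lambda(Y, X, cfg)
        b = cross_validate_lambda(Y, X, cfg)
        np.testing.assert_array_equal(a.fold_mse, b.fold_mse)
        assert a.selected_lambda == b.selected_lambda

    def test_more_folds_than_genes_errors(self):
        with pytest.raises(ValueError, match="folds"):
            cross_validate_lambda(
                np.ones((2, 3)), np.ones((1, 3)), _fast_cfg(ridge_lambda=[0.0], n_fold=5)
            )

    def test_mmse_matches_printed_formula(self):
        """Fold scores must equal 1/(2 n_test) * ||Y_test - M X_test||_F^2."""
        rng = np.random.default_rng(15)
        Y, X = rng.uniform(size=(2, 9)), rng.uniform(size=(2, 9))
        cfg = _fast_cfg(ridge_lambda=[0.05], n_fold=3, num_epochs=3000, seed=4)
        rep = cross_validate_lambda(Y, X, cfg)
        # recompute fold 0 by hand with the same seeded permutation
        perm = np.random.default_rng(cfg.seed).permutation(9)
        folds = np.array_split(perm, 3)
        test_idx = folds[0]
        train_idx = np.setdiff1d(perm, test_idx)
        M = nnls_estimate(Y[:, train_idx], X[:, train_idx], cfg, lam=0.05).weights
        expected = 0.5 / test_idx.size * np.sum((Y[:, test_idx] - M @ X[:, test_idx]) ** 2)
        assert rep.fold_mse[0, 0] == pytest.approx(expected, rel=1e-12)


def test_solver_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        SolverConfig(num_epochs=0)
    with pytest.raises(ValueError):
        SolverConfig(ridge_lambda=-0.1)
    with pytest.raises(ValueError):
        nnls_estimate(np.ones((1, 2)), np.ones((1, 2)), SolverConfig(ridge_lambda=(0.0, 0.1)))
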