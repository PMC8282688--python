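import numpy as np
import pytest

from tracreg.solver import (TracProblem, kkt_certificate, lambda_max,
                            solve_path)

from .conftest import random_problem
from .oracles import lambda_max_grid, slsqp_solve, two_column_path


class TestLambdaMax:
    def test_symmetric_two_columns(self, rng):
        # c = (c, -c) with unit weights: optimal mu is 0, lambda_max = |c|
        n = 40
        z = rng.normal(size=n)
        Z = np.column_stack([z, -z])
        y = rng.normal(size=n)
        prob = TracProblem(y=y, Z=Z, w=np.ones(2), fit_intercept=False)
        c = Z.T @ y / n
        assert lambda_max(prob) == pytest.approx(abs(c[0]), rel=1e-12)

    def test_single_column_is_zero(self, rng):
        prob = TracProblem(y=rng.normal(size=10),
                           Z=rng.normal(size=(10, 1)), w=np.ones(1))
        assert lambda_max(prob) == 0.0

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_dense_grid_search(self, trial):
        # weights >= 1 keep the grid oracle's own resolution below 1e-6
        rng = np.random.default_rng(100 + trial)
        Z = rng.normal(size=(25, 5))
        y = 0.5 * rng.normal(size=25)
        w = rng.uniform(1.0, 2.0, size=5)
        prob = TracProblem(y=y, Z=Z, w=w)
        exact = lambda_max(prob)
        grid = lambda_max_grid(Z, y, w, n_points=1_000_000)
        assert exact == pytest.approx(grid, abs=1e-6)

    def test_zero_is_optimal_at_lambda_max(self, rng):
        prob = random_problem(rng, n=30, m=6)
        lam = lambda_max(prob)
        assert kkt_certificate(prob, np.zeros(6), lam) <= 1e-10
        path = solve_path(prob, n_lambda=5)
        assert np.allclose(path.alpha[:, 0], 0.0, atol=1e-10)

    def test_nonpositive_weight_rejected(self, rng):
        with pytest.raises(ValueError, match="> 0"):
            TracProblem(y=rng.normal(size=5), Z=rng.normal(size=(5, 2)),
                        w=np.array([1.0, 0.0]))


class TestSolvePath:
    def test_alpha_zero_and_intercept_is_mean_at_lambda_max(self, rng):
        prob = random_problem(rng, n=20, m=4)
        path = solve_path(prob, n_lambda=8)
        assert np.allclose(path.alpha[:, 0], 0.0, atol=1e-12)
        assert path.intercept[0] == pytest.approx(prob.y.mean(), abs=1e-12)

    def test_two_column_soft_threshold_closed_form(self, rng):
        n = 35
        Z = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        prob = TracProblem(y=y, Z=Z, w=np.ones(2))
        path = solve_path(prob, n_lambda=20)
        expected = two_column_path(Z, y, path.lambdas)
        assert np.allclose(path.alpha, expected, atol=1e-8)

    @pytest.mark.parametrize("a", [1.0, 0.5, -2.0])
    def test_objective_matches_convex_oracle(self, a):
        rng = np.random.default_rng(hash(a) % 2**31)
        prob = random_problem(rng, n=30, m=8, a=a)
        path = solve_path(prob, n_lambda=8)
        for k in [0, 3, 7]:
            lam = path.lambdas[k]
            mine = prob.objective(path.alpha[:, k], lam)
            _, oracle = slsqp_solve(prob.Z, prob.y, prob.w, lam)
            assert mine <= oracle + 1e-6
            assert abs(mine - oracle) <= 1e-6

    def test_feasibility_along_path(self, rng):
        prob = random_problem(rng, n=40, m=10)
        path = solve_path(prob, n_lambda=30)
        assert np.all(np.abs(path.alpha.sum(axis=0)) <= 1e-8)

    def test_certified_to_tolerance(self, rng):
        prob = random_problem(rng, n=40, m=10)
        path = solve_path(prob, n_lambda=30)
        c0 = prob.Z_centered.T @ prob.y_centered / len(prob.y)
        tol = 1e-7 * max(1.0, np.abs(c0).max())
        assert np.all(path.kkt_residual <= tol)

    def test_objective_nonincreasing_down_the_path(self, rng):
        prob = random_problem(rng, n=40, m=9)
        path = solve_path(prob, n_lambda=25)
        objs = [prob.objective(path.alpha[:, k], path.lambdas[k])
                for k in range(len(path.lambdas))]
        assert np.all(np.diff(objs) <= 1e-10)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            TracProblem(y=np.array([1.0, np.nan, 0.0]),
                        Z=np.ones((3, 2)), w=np.ones(2))

    def test_duplicate_columns_collapse_to_min_weight(self, rng):
        """Identical columns: the coefficient lands on the member with the
        smallest weight and the collapsed problem gives the same sum."""
        n = 30
        z = rng.normal(size=(n, 3))
        Z = np.column_stack([z[:, 0], z[:, 0], z[:, 1], z[:, 2]])
        y = z[:, 0] * 2.0 - z[:, 1] + rng.normal(size=n) * 0.1
        w = np.array([0.5, 0.25, 1.0, 1.0])
        prob = TracProblem(y=y, Z=Z, w=w)
        path = solve_path(prob, n_lambda=10)
        # all weight on the cheaper duplicate (index 1)
        assert np.allclose(path.alpha[0], 0.0, atol=1e-12)
        collapsed = TracProblem(y=y, Z=Z[:, 1:], w=w[1:])
        cpath = solve_path(collapsed, lambdas=path.lambdas)
        assert np.allclose(path.alpha[1], cpath.alpha[0], atol=1e-8)
        assert np.allclose(path.alpha[2:], cpath.alpha[1:], atol=1e-8)


class TestKKTCertificate:
    def test_zero_residual_for_zero_solution_above_lambda_max(self, rng):
        prob = random_problem(rng, n=20, m=5)
        lam = lambda_max(prob) * 1.5
        assert kkt_certificate(prob, np.zeros(5), lam) == pytest.approx(0, abs=1e-12)

    def test_oracle_solution_certifies(self, rng):
        prob = random_problem(rng, n=30, m=6)
        lam = 0.3 * lambda_max(prob)
        path = solve_path(prob, lambdas=np.array([lam]))
        assert kkt_certificate(prob, path.alpha[:, 0], lam) <= 1e-7

    def test_perturbed_solution_fails(self, rng):
        prob = random_problem(rng, n=30, m=6)
        lam = 0.3 * lambda_max(prob)
        path = solve_path(prob, lambdas=np.array([lam]))
        bad = path.alpha[:, 0].copy()
        bad[0] += 0.05
        bad[1] -= 0.05  # keep feasible
        assert kkt_certificate(prob, bad, lam) > 1e-4

    def test_infeasible_alpha_rejected(self, rng):
        prob = random_problem(rng, n=20, m=4)
        with pytest.raises(ValueError, match="zero-sum"):
            kkt_certificate(prob, np.array([1.0, 0, 0, 0]), 0.1)


class TestLambdaMaxProperty:
    """Property check of the closed-form threshold against direct scalar
    minimization of max_u |c_u - mu| / w_u."""

    from hypothesis import given, settings, strategies as st

    @given(
        c=st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=6),
        w=st.lists(st.floats(0.2, 4.0, allow_nan=False), min_size=6,
                   max_size=6),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_pairwise_formula_equals_scalar_minimization(self, c, w):
        from scipy.optimize import minimize_scalar

        c = np.asarray(c)
        w = np.asarray(w[: len(c)])
        closed = max(float(np.max((c[:, None] - c[None, :]) /
                                  (w[:, None] + w[None, :]))), 0.0)

        def f(mu):
            return float(np.max(np.abs(c - mu) / w))

        res = minimize_scalar(f, bounds=(c.min() - 1, c.max() + 1),
                              method="bounded", options={"xatol": 1e-12})
        numeric = min(float(res.fun), f(float(res.x)))
        # the closed form is the exact minimum; the scalar search can only
        # land slightly above it
        assert -1e-12 <= numeric - closed <= 1e-7
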