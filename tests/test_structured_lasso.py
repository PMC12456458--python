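import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import Lasso

from clusso.structured_lasso import (
    BoundInputs,
    cv_lambda,
    normalize_threshold,
    predict,
    solve_multi_init,
    solve_single,
    random_init,
    theoretical_bound,
)


def _instance(seed, n=30, G=2, q=3, sparse=False, noise=0.3):
    """Random standardized-scale problem with a planted bilinear signal."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, G, q))
    alpha = rng.standard_normal(G)
    alpha /= np.abs(alpha).sum()
    beta = rng.standard_normal(q) * 2
    if sparse:
        beta[q // 2 :] = 0.0
    y = np.einsum("igq,g,q->i", X, alpha, beta) + noise * rng.standard_normal(n)
    return X, y, alpha, beta


def _alpha_grid_oracle(X, y, lam, step=1e-3):
    """Independent global check: grid alpha = (t, +/-(1-|t|)) over t in [-1, 1]
    and solve the convex lasso in beta at each alpha with sklearn."""
    n = X.shape[0]
    best = np.inf
    model = Lasso(alpha=lam / 2.0, fit_intercept=False, max_iter=10_000, tol=1e-10,
                  warm_start=True)
    for t in np.arange(-1.0, 1.0 + step / 2, step):
        for s in (1.0, -1.0):
            a = np.array([t, s * (1.0 - abs(t))])
            if np.abs(a).sum() == 0:
                continue
            Z = np.einsum("igq,g->iq", X, a)
            model.fit(Z, y)
            b = model.coef_
            obj = np.mean((y - Z @ b) ** 2) + lam * np.abs(b).sum()
            best = min(best, obj)
    return best


class TestSolveSingle:
    def test_identifiable_scalar_case(self):
        """G=q=1, lambda=0, noiseless y=2x: the sign constraint picks
        (alpha, beta) = (1, 2) over (-1, -2)."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        X = x.reshape(-1, 1, 1)
        y = 2.0 * x
        sol = solve_single(X, y, lam=0.0, init=(np.array([-1.0]), np.array([-5.0])))
        assert sol.alpha[0] == pytest.approx(1.0)
        assert sol.beta[0] == pytest.approx(2.0, abs=1e-6)

    def test_full_shrinkage_at_huge_lambda(self):
        X, y, *_ = _instance(1)
        lam_dead = 10.0 * np.max(np.abs(y)) * np.max(np.abs(X))
        sol = solve_single(X, y, lam_dead, init=random_init(np.random.default_rng(1), 2, 3))
        np.testing.assert_array_equal(sol.beta, 0.0)
        assert sol.objective == pytest.approx(np.mean(y**2))

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_monotone_and_alpha_normalized(self, seed):
        X, y, *_ = _instance(seed, n=40, G=2, q=5)
        sol = solve_single(
            X, y, lam=0.5, init=random_init(np.random.default_rng(seed + 100), 2, 5)
        )
        diffs = np.diff(sol.trace)
        assert np.all(diffs <= 1e-9 * np.maximum(1.0, np.abs(sol.trace[:-1])))
        assert np.abs(sol.alpha).sum() == pytest.approx(1.0, abs=1e-10)

    def test_sign_canonicalization(self):
        X, y, *_ = _instance(3)
        sol = solve_single(X, y, 0.1, init=random_init(np.random.default_rng(5), 2, 3))
        if np.any(sol.beta != 0):
            assert sol.beta[np.argmax(np.abs(sol.beta))] > 0

    def test_objective_consistent_with_stored_solution(self):
        X, y, *_ = _instance(4)
        sol = solve_single(X, y, 0.5, init=random_init(np.random.default_rng(6), 2, 3))
        recomputed = np.mean(
            (y - np.einsum("igq,g,q->i", X, sol.alpha, sol.beta)) ** 2
        ) + 0.5 * np.abs(sol.beta).sum()
        assert sol.objective == pytest.approx(recomputed, abs=1e-8)


@pytest.mark.parametrize("seed", range(20))
def test_multi_init_matches_alpha_grid_oracle(seed):
    """The alternating solver with restarts reaches the global optimum found
    by brute-force search over the alpha constraint set (G=2, q=3, n=30)."""
    X, y, *_ = _instance(seed, n=30, G=2, q=3, sparse=True)
    sol = solve_multi_init(X, y, lam=0.5, n_inits=5, seed=seed)
    oracle = _alpha_grid_oracle(X, y, lam=0.5)
    assert sol.objective <= oracle * (1 + 1e-4) + 1e-12
    assert abs(sol.objective - oracle) <= 1e-4 * max(1.0, oracle)


class TestMultiInit:
    def test_single_init_equals_solve_single(self):
        X, y, *_ = _instance(7)
        seed = 42
        a0, b0 = random_init(np.random.default_rng(seed), 2, 3)
        direct = solve_single(X, y, 0.5, (a0, b0))
        multi = solve_multi_init(X, y, 0.5, n_inits=1, seed=seed)
        assert multi.objective == pytest.approx(direct.objective)
        np.testing.assert_allclose(multi.beta, direct.beta)

    def test_more_inits_never_worse(self):
        X, y, *_ = _instance(8)
        one = solve_multi_init(X, y, 0.5, n_inits=1, seed=9)
        five = solve_multi_init(X, y, 0.5, n_inits=5, seed=9)
        assert five.objective <= one.objective + 1e-12


class TestCvLambda:
    def test_single_value_grid_returned(self):
        X, y, *_ = _instance(10, n=25)
        lam, table = cv_lambda(X, y, [0.7], n_folds=5, seed=0, n_inits=2)
        assert lam == 0.7
        assert len(table) == 1

    def test_noiseless_sparse_curve_shape(self):
        X, y, *_ = _instance(11, n=60, q=5, sparse=True, noise=0.0)
        grid = np.arange(0.5, 5.01, 0.5)
        lam, table = cv_lambda(X, y, grid, n_folds=5, seed=1, n_inits=3)
        mse = table["fold_mse_mean"].to_numpy()
        assert lam <= grid[1]  # minimized at small lambda on noiseless data
        assert mse[-1] > mse.min()

    def test_empty_grid_rejected(self):
        X, y, *_ = _instance(12)
        with pytest.raises(ValueError, match="empty"):
            cv_lambda(X, y, [], n_folds=2)


class TestNormalizeThreshold:
    def test_hand_computed_example(self):
        out = normalize_threshold(np.array([3.0, -1.0, 0.002]), 0.001)
        np.testing.assert_allclose(
            out, [3 / 4.002, -1 / 4.002, 0.0], atol=1e-12
        )

    def test_zero_vector_passes_through(self):
        np.testing.assert_array_equal(
            normalize_threshold(np.zeros(3), 0.001), np.zeros(3)
        )

    def test_not_renormalized_after_zeroing(self):
        out = normalize_threshold(np.array([1.0, 1e-6]), 0.001)
        assert np.abs(out).sum() < 1.0

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_surviving_components_at_least_threshold(self, vals):
        out = normalize_threshold(np.asarray(vals), 0.001)
        nz = out[out != 0]
        assert np.all(np.abs(nz) >= 0.001)
        assert np.abs(out).sum() <= 1.0 + 1e-12


class TestPredict:
    def test_in_sample_mse_matches_objective_identity(self):
        X, y, *_ = _instance(13)
        sol = solve_multi_init(X, y, 0.5, n_inits=3, seed=2)
        pred = predict(sol, X)
        mse = np.mean((y - pred) ** 2)
        assert mse == pytest.approx(sol.objective - 0.5 * np.abs(sol.beta).sum(), abs=1e-8)

    def test_invariant_to_joint_row_permutation(self):
        X, y, *_ = _instance(14, G=3)
        sol = solve_multi_init(X, y, 0.3, n_inits=3, seed=3)
        perm = [2, 0, 1]
        p1 = predict(sol, X)
        p2 = predict((sol.alpha[perm], sol.beta), X[:, perm, :])
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_invariant_to_joint_sign_flip(self):
        X, y, *_ = _instance(15)
        sol = solve_multi_init(X, y, 0.3, n_inits=3, seed=4)
        np.testing.assert_allclose(
            predict(sol, X), predict((-sol.alpha, -sol.beta), X), atol=1e-12
        )


class TestTheoreticalBound:
    def test_lambda_n_formula(self):
        inputs = BoundInputs(
            delta0=1.0, a=1.0, sigma=1.0, G=2, q=10, n=300,
            kappa2=1.0, s0=4, beta_star=np.array([2.0, 1.0, 0.0]),
        )
        lam_n, _ = theoretical_bound(inputs)
        assert lam_n == pytest.approx(2.0 * np.sqrt(4.0 * np.log(20.0) / 300.0))
        assert lam_n == pytest.approx(0.3997, abs=5e-4)

    def test_empty_support_gives_zero_bound(self):
        inputs = BoundInputs(
            delta0=1.0, a=1.0, sigma=1.0, G=2, q=10, n=300,
            kappa2=1.0, s0=0, beta_star=np.array([1.0]),
        )
        assert theoretical_bound(inputs)[1] == 0.0

    def test_bound_decreasing_in_n(self):
        bounds = [
            theoretical_bound(
                BoundInputs(
                    delta0=0.5, a=0.5, sigma=1.5, G=2, q=10, n=n,
                    kappa2=2.0, s0=4, beta_star=np.array([3.0, 1.0, 0.0, 2.0]),
                )
            )[1]
            for n in (100, 400, 1600)
        ]
        assert bounds[0] > bounds[1] > bounds[2]

    def test_zero_beta_fatal(self):
        with pytest.raises(ValueError, match="beta_star"):
            theoretical_bound(
                BoundInputs(
                    delta0=1.0, a=1.0, sigma=1.0, G=2, q=2, n=10,
                    kappa2=1.0, s0=1, beta_star=np.zeros(2),
                )
            )
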