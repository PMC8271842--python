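import numpy as np
import pytest
from scipy.stats import spearmanr

import hyperseed as hs
from hyperseed.exceptions import DomainError
from hyperseed.lasso import CVResult


def make_model(intercept, betas, lam=0.0):
    betas = np.asarray(betas, dtype=float)
    return hs.ModelCoefficients(
        intercept=intercept, betas=betas, lam=lam,
        centers=np.zeros_like(betas), scales=np.ones_like(betas),
    )


def per_sample_objective(beta0, betas, X, y, lam):
    """Independent evaluation of the per-sample penalized cost."""
    eta = beta0 + X @ betas
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    return nll + lam * np.abs(betas).sum()


def overlapping_data(seed=0, n=30, p=2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    eta = 0.3 + 1.2 * X[:, 0] - 0.8 * X[:, -1]
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
    if y.min() == y.max():  # pragma: no cover - seed chosen to avoid this
        raise AssertionError("degenerate fixture")
    return X, y


def irls_unpenalized(X, y, iters=100):
    """Independent Newton (IRLS) fit of unpenalized logistic regression."""
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(A.shape[1])
    for _ in range(iters):
        eta = A @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        H = A.T @ (A * W[:, None])
        g = A.T @ (y - p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


class TestLikelihood:
    def test_null_model_is_n_log_two(self):
        X = np.zeros((7, 3))
        y = np.array([1, 0, 1, 0, 1, 0, 1])
        model = make_model(0.0, np.zeros(3))
        assert hs.log_likelihood(model, X, y) == pytest.approx(-7 * np.log(2))

    def test_single_sample_at_even_odds(self):
        model = make_model(0.0, [0.0])
        assert hs.log_likelihood(model, np.zeros((1, 1)), np.array([1])) == (
            pytest.approx(np.log(0.5))
        )

    def test_matches_direct_summation(self):
        X = np.array([[1.0], [-1.0], [0.0]])
        model = make_model(0.0, [1.0])  # eta = (1, -1, 0)
        y = np.array([1, 0, 1])
        expected = sum(
            yi * e - np.log(1 + np.exp(e)) for yi, e in zip(y, [1.0, -1.0, 0.0])
        )
        assert hs.log_likelihood(model, X, y) == pytest.approx(expected)

    def test_non_binary_labels_rejected(self):
        model = make_model(0.0, [1.0])
        with pytest.raises(DomainError):
            hs.log_likelihood(model, np.zeros((2, 1)), np.array([0, 2]))


class TestPenalizedObjective:
    def test_zero_lambda_equals_negative_likelihood(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.integers(0, 2, size=10)
        model = make_model(0.3, [0.5, -1.0, 0.2], lam=0.0)
        assert hs.penalized_objective(model, X, y) == pytest.approx(
            -hs.log_likelihood(model, X, y)
        )

    def test_linear_in_lambda(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.integers(0, 2, size=10)
        betas = [0.5, -1.0, 0.2]
        s1 = hs.penalized_objective(make_model(0.3, betas, lam=0.1), X, y)
        s2 = hs.penalized_objective(make_model(0.3, betas, lam=0.2), X, y)
        assert s2 - s1 == pytest.approx(0.1 * np.abs(betas).sum())

    def test_matches_independent_evaluation(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.integers(0, 2, size=12)
        betas = np.array([0.4, 0.0, -0.7, 1.1])
        model = make_model(-0.2, betas, lam=0.05)
        expected = -hs.log_likelihood(model, X, y) + 0.05 * np.abs(betas).sum()
        assert hs.penalized_objective(model, X, y) == pytest.approx(expected)


class TestSolver:
    def test_above_lambda_max_gives_null_model(self):
        X, y = overlapping_data(seed=1)
        lam_max = hs.lambda_max(X, y)
        model = hs.fit_lasso_logistic(X, y, lam_max * 1.01)
        np.testing.assert_array_equal(model.betas, 0.0)
        ybar = y.mean()
        assert model.intercept == pytest.approx(np.log(ybar / (1 - ybar)))

    def test_matches_brute_force_grid_minimum(self):
        X, y = overlapping_data(seed=2, n=20, p=2)
        lam = 0.05
        model = hs.fit_lasso_logistic(X, y, lam)
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        # brute force over standardized coefficients, refined twice
        center, width, step = np.zeros(3), 3.0, 0.1
        best = (np.inf, None)
        for _ in range(3):
            g0 = np.arange(center[0] - width, center[0] + width + step / 2, step)
            g1 = np.arange(center[1] - width, center[1] + width + step / 2, step)
            g2 = np.arange(center[2] - width, center[2] + width + step / 2, step)
            for b0 in g0:
                eta0 = b0 + np.zeros(len(y))
                for b1 in g1:
                    eta1 = eta0 + Z[:, 0] * b1
                    for b2 in g2:
                        eta = eta1 + Z[:, 1] * b2
                        f = float(
                            np.mean(np.logaddexp(0.0, eta) - y * eta)
                            + lam * (abs(b1) + abs(b2))
                        )
                        if f < best[0]:
                            best = (f, np.array([b0, b1, b2]))
            center, width, step = best[1], 2.5 * step, step / 10
        f_grid = best[0]
        f_solver = per_sample_objective(
            float(
                model.intercept + model.betas @ X.mean(axis=0)
            ),
            model.betas_standardized, Z, y, lam,
        )
        assert f_solver <= f_grid + 1e-4
        assert abs(f_solver - f_grid) <= 1e-4

    def test_zero_lambda_matches_irls_oracle(self):
        X, y = overlapping_data(seed=3, n=40, p=3)
        model = hs.fit_lasso_logistic(X, y, 0.0, tol=1e-12)
        ref = irls_unpenalized(X, y)
        np.testing.assert_allclose(model.intercept, ref[0], atol=1e-5)
        np.testing.assert_allclose(model.betas, ref[1:], atol=1e-5)

    def test_matches_sklearn_l1_oracle(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y = overlapping_data(seed=4, n=60, p=4)
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        lam = 0.03
        model = hs.fit_lasso_logistic(Z, y, lam)
        clf = sklearn.LogisticRegression(
            l1_ratio=1.0, C=1.0 / (len(y) * lam), solver="saga",
            tol=1e-8, max_iter=50_000,
        ).fit(Z, y)
        f_ours = per_sample_objective(model.intercept, model.betas, Z, y, lam)
        f_sk = per_sample_objective(
            float(clf.intercept_[0]), clf.coef_[0], Z, y, lam
        )
        assert f_ours <= f_sk + 1e-6
        assert abs(f_ours - f_sk) < 1e-4

    def test_kkt_residual_small_at_solution(self):
        X, y = overlapping_data(seed=5, n=50, p=6)
        for lam in (0.01, 0.05, 0.1):
            model = hs.fit_lasso_logistic(X, y, lam)
            assert hs.kkt_residual(model, X, y) < 1e-5

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(DomainError):
            hs.fit_lasso_logistic(X, np.ones(10, dtype=int), 0.1)

    def test_negative_lambda_rejected(self):
        X, y = overlapping_data()
        with pytest.raises(DomainError):
            hs.fit_lasso_logistic(X, y, -0.1)

    def test_nonconvergence_flagged(self):
        # separable data at lambda 0 cannot converge: expect a warning flag
        X = np.vstack([np.full((5, 1), -2.0), np.full((5, 1), 2.0)])
        X = X + np.linspace(0, 0.1, 10)[:, None]
        y = np.repeat([0, 1], 5)
        with pytest.warns(RuntimeWarning):
            model = hs.fit_lasso_logistic(X, y, 0.0, max_iter=200)
        assert not model.converged


class TestPath:
    def test_null_model_at_top_of_grid(self):
        X, y = overlapping_data(seed=6, n=40, p=3)
        lam_max = hs.lambda_max(X, y)
        grid = np.geomspace(lam_max * 2, 1e-3, 30)
        path = hs.regularization_path(X, y, grid)
        assert path[0].n_nonzero == 0
        assert path[-1].n_nonzero >= path[0].n_nonzero

    def test_kkt_holds_along_path(self):
        X, y = overlapping_data(seed=7, n=50, p=5)
        path = hs.regularization_path(X, y, np.geomspace(0.2, 1e-3, 25))
        for model in path:
            assert hs.kkt_residual(model, X, y) < 1e-5

    def test_empirical_lambda_max_matches_analytic(self):
        # weak effects keep the null threshold inside the default grid
        ds, _ = hs.generate_feature_data(
            n_per_class=30, n_bands=40, effect_sizes=(0.03, -0.03) * 3, seed=0
        )
        lam_analytic = hs.lambda_max(ds.X, ds.y)
        grid = hs.default_lambda_grid(100, hi=0.5)
        assert grid[-1] < lam_analytic < grid[0]
        path = hs.regularization_path(ds.X, ds.y, grid)
        nz = np.array([m.n_nonzero for m in path])
        lam_empirical = grid[np.flatnonzero(nz == 0)[-1]]  # smallest all-zero lambda
        step = grid[0] / grid[1]  # grid ratio
        assert lam_empirical / lam_analytic < step
        assert lam_analytic / lam_empirical < step**2

    def test_sparsity_decreases_with_lambda(self):
        ds, _ = hs.generate_feature_data(n_per_class=40, n_bands=60, seed=1)
        grid = hs.default_lambda_grid(40)
        path = hs.regularization_path(ds.X, ds.y, grid)
        nz = np.array([m.n_nonzero for m in path])
        rho = spearmanr(grid, nz).statistic
        assert rho <= -0.8

    def test_unsorted_grid_rejected(self):
        X, y = overlapping_data()
        with pytest.raises(DomainError):
            hs.regularization_path(X, y, np.array([0.01, 0.1]))


class TestCrossValidation:
    def test_fold_assignment_partitions_samples(self):
        ds, _ = hs.generate_feature_data(n_per_class=30, n_bands=20, seed=2)
        cv = hs.cross_validate(ds.X, ds.y, hs.default_lambda_grid(20), folds=5, seed=0)
        assert cv.fold_assignment.shape == (60,)
        assert set(cv.fold_assignment) == set(range(5))
        # stratified: each fold holds both classes at these sizes
        for f in range(5):
            assert np.unique(ds.y[cv.fold_assignment == f]).size == 2

    def test_separable_data_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(-3, 0.2, size=(30, 5)), rng.normal(3, 0.2, size=(30, 5))]
        )
        y = np.repeat([0, 1], 30)
        cv = hs.cross_validate(X, y, hs.default_lambda_grid(30), folds=5, seed=1)
        assert cv.cv_accuracy.max() == pytest.approx(1.0)

    def test_shuffled_labels_near_majority_rate(self):
        accs = []
        for rep in range(25):
            rng = np.random.default_rng(100 + rep)
            X = rng.normal(size=(60, 20))
            y = np.repeat([0, 1], 30)
            rng.shuffle(y)
            cv = hs.cross_validate(
                X, y, hs.default_lambda_grid(15), folds=5, seed=rep
            )
            accs.append(cv.cv_accuracy.mean())
        # majority rate is 0.5 by construction
        assert abs(np.mean(accs) - 0.5) < 0.06

    def test_deterministic_given_seed(self):
        ds, _ = hs.generate_feature_data(n_per_class=25, n_bands=15, seed=3)
        grid = hs.default_lambda_grid(15)
        a = hs.cross_validate(ds.X, ds.y, grid, folds=5, seed=9)
        b = hs.cross_validate(ds.X, ds.y, grid, folds=5, seed=9)
        np.testing.assert_array_equal(a.cv_error, b.cv_error)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)

    def test_result_vectors_align_with_grid(self):
        ds, _ = hs.generate_feature_data(n_per_class=20, n_bands=10, seed=4)
        grid = hs.default_lambda_grid(12)
        cv = hs.cross_validate(ds.X, ds.y, grid, folds=4, seed=0)
        for vec in (cv.cv_error, cv.cv_error_sd, cv.n_nonzero, cv.cv_accuracy):
            assert vec.shape == grid.shape
        assert len(cv.models) == grid.size


class TestLambdaSelection:
    def _cv(self, acc, err=None):
        grid = np.geomspace(0.2, 0.001, len(acc))
        acc = np.asarray(acc, dtype=float)
        err = np.asarray(err if err is not None else 1 - acc, dtype=float)
        return CVResult(
            lambda_grid=grid, cv_error=err, cv_error_sd=np.zeros_like(err),
            n_nonzero=np.arange(len(acc)), cv_accuracy=acc,
            fold_assignment=np.zeros(1, dtype=np.int64), seed=0,
        )

    def test_unique_maximum(self):
        cv = self._cv([0.8, 0.95, 0.9])
        assert hs.select_lambda(cv) == cv.lambda_grid[1]

    def test_tie_prefers_larger_lambda(self):
        cv = self._cv([0.8, 0.95, 0.95, 0.9])
        assert hs.select_lambda(cv) == cv.lambda_grid[1]

    def test_all_equal_gives_largest(self):
        cv = self._cv([0.9, 0.9, 0.9])
        assert hs.select_lambda(cv) == cv.lambda_grid[0]

    def test_min_error_rule(self):
        cv = self._cv([0.8, 0.9, 0.9], err=[0.3, 0.2, 0.1])
        assert hs.select_lambda(cv, rule="min_error") == cv.lambda_grid[2]

    def test_unknown_rule_rejected(self):
        with pytest.raises(DomainError):
            hs.select_lambda(self._cv([0.9]), rule="aicc")


class TestBandsAndPrediction:
    def test_selected_bands_example(self):
        model = make_model(0.0, [0.0, 0.3, 0.0, -0.1])
        sel = hs.selected_bands(model, np.array([500.0, 550.0, 600.0, 650.0]))
        np.testing.assert_array_equal(sel.indices, [2, 4])
        np.testing.assert_allclose(sel.wavelengths_nm, [550.0, 650.0])
        np.testing.assert_allclose(sel.coefficients, [0.3, -0.1])

    def test_null_model_selects_nothing(self):
        model = make_model(0.1, np.zeros(5))
        sel = hs.selected_bands(model, np.linspace(450, 950, 5))
        assert sel.indices.size == 0

    def test_path_selection_sizes_consistent(self):
        X, y = overlapping_data(seed=8, n=40, p=4)
        path = hs.regularization_path(X, y, np.geomspace(0.2, 0.001, 20))
        wl = np.linspace(450, 950, 4)
        for model in path:
            assert hs.selected_bands(model, wl).indices.size == model.n_nonzero

    def test_probability_at_zero_eta(self):
        model = make_model(0.0, [0.0])
        assert hs.predict_proba(model, np.array([[3.0]]))[0] == 0.5
        assert hs.predict(model, np.array([[3.0]]))[0] == 0  # tie -> non-target

    def test_probability_symmetry(self, rng):
        model = make_model(0.0, [1.0])
        X = rng.normal(size=(20, 1))
        p_pos = hs.predict_proba(model, X)
        p_neg = hs.predict_proba(model, -X)
        np.testing.assert_allclose(p_pos + p_neg, 1.0, atol=1e-12)

    def test_extreme_eta_saturates_without_overflow(self):
        model = make_model(0.0, [1.0])
        p = hs.predict_proba(model, np.array([[1e4], [-1e4]]))
        assert 0.0 < p[1] < p[0] < 1.0 or (p[0] == 1.0 and p[1] == 0.0)
        assert np.isfinite(p).all()

    def test_dimension_mismatch_rejected(self):
        model = make_model(0.0, [1.0, 2.0])
        with pytest.raises(DomainError):
            hs.predict_proba(model, np.ones((3, 3)))
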