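import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epistab import scadglm
from epistab.scadglm import (
    PenaltySpec,
    cv_auc_select,
    fit_path,
    lambda_max,
    make_lambda_grid,
    penalty_deriv,
    penalty_value,
    threshold_update,
)

LASSO = PenaltySpec("lasso")
SCAD = PenaltySpec("scad", a=3.7)


def brute_force_threshold(z, lam, spec, c=1.0, lo=None, hi=None, coarse=1e-3, fine=1e-5):
    """Scalar-objective grid minimizer: coarse pass then 1e-5 refinement."""
    lo = -abs(z) - 1.0 if lo is None else lo
    hi = abs(z) + 1.0 if hi is None else hi

    def obj(t):
        return 0.5 * c * (t - z) ** 2 + np.array(
            [penalty_value(ti, lam, spec) for ti in np.atleast_1d(t)]
        )

    grid = np.arange(lo, hi + coarse, coarse)
    best = grid[np.argmin(obj(grid))]
    grid = np.arange(best - 2 * coarse, best + 2 * coarse, fine)
    return grid[np.argmin(obj(grid))]


class TestPenaltyFunctions:
    def test_lasso_value(self):
        assert penalty_value(2.0, 0.1, LASSO) == pytest.approx(0.2)

    @pytest.mark.parametrize(
        "theta, lam, expected",
        [
            (0.3, 0.5, 0.15),  # linear region: lam*|theta|
            (10.0, 1.0, 0.5 * 4.7),  # plateau: (a+1)*lam^2/2
        ],
    )
    def test_scad_value_regions(self, theta, lam, expected):
        assert penalty_value(theta, lam, SCAD) == pytest.approx(expected)

    def test_scad_value_matches_integrated_derivative(self):
        # independent oracle: numeric integration of the derivative from 0
        lam, a = 0.8, 3.7
        for theta in (0.3, 1.2, 2.5, 3.5):
            grid = np.linspace(0, theta, 20001)
            integral = np.trapezoid(
                [penalty_deriv(t, lam, SCAD) for t in grid], grid
            )
            assert penalty_value(theta, lam, SCAD) == pytest.approx(integral, abs=1e-6)

    @pytest.mark.parametrize(
        "theta, lam, expected",
        [
            (0.5, 1.0, 1.0),  # |theta| <= lam branch
            (2.0, 1.0, (3.7 - 2.0) / 2.7),  # taper branch (a*lam-|theta|)/(a-1)
            (5.0, 1.0, 0.0),  # beyond a*lam, positive part is zero
        ],
    )
    def test_scad_deriv_branches(self, theta, lam, expected):
        assert penalty_deriv(theta, lam, SCAD) == pytest.approx(expected)

    def test_scad_deriv_matches_finite_difference(self):
        lam = 1.0
        for theta in (0.4, 1.5, 2.7):
            h = 1e-6
            fd = (penalty_value(theta + h, lam, SCAD) - penalty_value(theta - h, lam, SCAD)) / (2 * h)
            assert penalty_deriv(theta, lam, SCAD) == pytest.approx(fd, abs=1e-6)

    def test_scad_even_monotone_plateau(self):
        lam, a = 0.7, 3.7
        thetas = np.linspace(0, 5, 200)
        vals = np.array([penalty_value(t, lam, SCAD) for t in thetas])
        assert (np.diff(vals) >= -1e-12).all()  # non-decreasing in |theta|
        for t in thetas:
            assert penalty_value(-t, lam, SCAD) == pytest.approx(penalty_value(t, lam, SCAD))
        plateau = [penalty_value(t, lam, SCAD) for t in (a * lam, a * lam + 1, 10)]
        assert np.ptp(plateau) < 1e-12


class TestThresholdUpdate:
    @pytest.mark.parametrize(
        "z, lam, spec, expected",
        [
            (0.5, 1.0, LASSO, 0.0),  # |z| <= lam soft-thresholds to zero
            (10.0, 1.0, SCAD, 10.0),  # beyond the plateau, unshrunk
        ],
    )
    def test_known_points(self, z, lam, spec, expected):
        assert threshold_update(z, lam, spec, 1.0) == pytest.approx(expected)

    def test_scad_taper_region_against_grid(self):
        got = threshold_update(3.0, 1.0, SCAD, 1.0)
        ref = brute_force_threshold(3.0, 1.0, SCAD)
        assert got == pytest.approx(ref, abs=1e-4)
        assert got == pytest.approx(2.5882, abs=1e-3)

    def test_sign_matches_z(self, rng):
        for _ in range(50):
            z = rng.normal(scale=3)
            lam = rng.uniform(0.05, 2)
            t = threshold_update(z, lam, SCAD, rng.uniform(0.5, 5))
            assert t == 0 or np.sign(t) == np.sign(z)

    def test_random_cases_match_brute_force(self, rng):
        # both penalties, random (z, lam, a, curvature)
        for _ in range(200):
            z = rng.uniform(-6, 6)
            lam = rng.uniform(0.05, 2.0)
            c = rng.uniform(0.5, 5.0)
            spec = PenaltySpec("scad", a=rng.uniform(2.2, 6.0)) if rng.random() < 0.7 else LASSO
            got = threshold_update(z, lam, spec, c)
            ref = brute_force_threshold(z, lam, spec, c)
            assert got == pytest.approx(ref, abs=1e-4)


class TestFitPath:
    def _data(self, rng, n=200, p=5, signal=True):
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        if signal:
            beta = np.zeros(p)
            beta[: min(p, 4)] = [1.0, -0.6, 0.0, 0.4][: min(p, 4)]
        else:
            beta = np.zeros(p)
        eta = 0.3 + X @ beta
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        return X, y

    def test_null_model_at_lambda_max(self, rng):
        X, y = self._data(rng, signal=False)
        fit = fit_path(X, y, spec=LASSO, n_lambda=20)
        assert fit.active_set(0).size == 0
        assert fit.intercepts[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-4)

    @pytest.mark.parametrize("spec", [LASSO, SCAD], ids=["lasso", "scad"])
    def test_lambda_to_zero_matches_newton_mle(self, rng, spec):
        # independent Newton-Raphson MLE oracle
        X, y = self._data(rng)
        D = np.column_stack([np.ones(len(y)), X])
        coef = np.zeros(D.shape[1])
        for _ in range(100):
            mu = 1 / (1 + np.exp(-(D @ coef)))
            W = mu * (1 - mu)
            step = np.linalg.solve((D * W[:, None]).T @ D, D.T @ (y - mu))
            coef += step
            if np.abs(step).max() < 1e-12:
                break
        lams = make_lambda_grid(lambda_max(X, y), 60, 1e-5)
        fit = fit_path(X, y, spec=spec, lambdas=lams)
        ours = np.r_[fit.intercepts[-1], fit.coefs[-1]]
        np.testing.assert_allclose(ours, coef, atol=1e-4)

    def test_kkt_conditions_along_path(self, rng):
        X, y = self._data(rng, n=300, p=12)
        for spec in (LASSO, SCAD):
            fit = fit_path(X, y, spec=spec, n_lambda=40)
            for l, lam in enumerate(fit.lambda_grid):
                coefs = fit.coefs[l]
                eta = fit.intercepts[l] + X @ coefs
                mu = 1 / (1 + np.exp(-eta))
                grad = (2 / len(y)) * (X.T @ (mu - y))  # grad of -(2/n) log L
                tol = 1e-3
                for j in range(X.shape[1]):
                    if coefs[j] == 0:
                        assert abs(grad[j]) <= lam + tol
                    else:
                        stat = grad[j] + np.sign(coefs[j]) * penalty_deriv(coefs[j], lam, spec)
                        assert abs(stat) <= tol

    def test_warm_equals_cold_start(self, rng):
        X, y = self._data(rng, n=150, p=8)
        lams = make_lambda_grid(lambda_max(X, y), 15, 0.1)
        warm = fit_path(X, y, spec=SCAD, lambdas=lams)
        for l in (4, 9, 14):
            cold = fit_path(X, y, spec=SCAD, lambdas=lams[: l + 1])
            np.testing.assert_allclose(cold.coefs[l], warm.coefs[l], atol=1e-5)

    def test_q_budget_truncation(self, rng):
        X, y = self._data(rng, n=200, p=10)
        fit = fit_path(X, y, spec=LASSO, n_lambda=50, q_stop=3)
        assert fit.ever_active.sum() <= 3
        assert fit.n_lambda <= 50

    def test_deviance_nonincreasing_along_lasso_path(self, rng):
        X, y = self._data(rng, n=200, p=8)
        fit = fit_path(X, y, spec=LASSO, n_lambda=30)
        assert (np.diff(fit.deviance) <= 1e-6).all()

    def test_unpenalized_covariates_kept(self, rng):
        X, y = self._data(rng, n=300, p=6)
        C = rng.standard_normal((300, 2))
        fit = fit_path(X, y, C, spec=LASSO, n_lambda=10)
        # covariate coefficients are free even when all features are zero
        assert fit.active_set(0).size == 0
        assert np.abs(fit.covariate_coefs[0]).max() > 0 or np.abs(
            fit.covariate_coefs
        ).max() == 0


class TestCVSelect:
    def test_null_data_auc_near_half(self, rng):
        X, y = self._null(rng)
        cv = cv_auc_select(X, y, spec=LASSO, folds=5, seed=1, n_lambda=20)
        assert abs(cv.cv_auc.max() - 0.5) < 0.12
        assert cv.best_index <= 8  # selected near lambda_max

    def _null(self, rng, n=300, p=10):
        X = rng.standard_normal((n, p))
        y = rng.binomial(1, 0.5, n).astype(float)
        return X, y

    def test_strong_effect_recovered(self, main_effect_dataset):
        F, y, causal = main_effect_dataset
        hits = 0
        for seed in range(5):
            cv = cv_auc_select(F, y, spec=SCAD, folds=5, seed=seed, n_lambda=30, lambda_min_ratio=0.1)
            fit = fit_path(F, y, spec=SCAD, lambdas=cv.lambda_grid)
            hits += causal in fit.active_set(min(cv.best_index, fit.n_lambda - 1))
        assert hits >= 4

    def test_fold_counts_both_valid(self, rng):
        X, y = self._null(rng)
        for folds in (2, 10):
            cv = cv_auc_select(X, y, spec=LASSO, folds=folds, seed=0, n_lambda=15)
            assert np.isfinite(cv.cv_auc).all()
            assert 0 <= cv.best_index < 15

    def test_unstratifiable_raises(self, rng):
        X = rng.standard_normal((10, 4))
        y = np.r_[np.ones(2), np.zeros(8)]
        with pytest.raises(ValueError, match="stratify"):
            cv_auc_select(X, y, spec=LASSO, folds=5)


@given(
    z=st.floats(-8, 8),
    lam=st.floats(0.01, 3),
    a=st.floats(2.1, 8),
    c=st.floats(0.2, 6),
)
@settings(max_examples=60, deadline=None)
def test_threshold_update_never_overshoots(z, lam, a, c):
    """|update| <= |z| and the objective at the update <= objective at 0 and z."""
    spec = PenaltySpec("scad", a=a)
    t = threshold_update(z, lam, spec, c)
    assert abs(t) <= abs(z) + 1e-12

    def obj(u):
        return 0.5 * c * (u - z) ** 2 + penalty_value(u, lam, spec)

    assert obj(t) <= min(obj(0.0), obj(z)) + 1e-9
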