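"""Penalized logistic regression with LASSO and SCAD penalties.

Fits the model

    logit P(y=1 | x) = beta0 + c'gamma + x'theta

by minimizing -(2/n) log L + sum_j p_lambda(theta_j) over a decreasing
lambda grid, with the intercept and covariates always unpenalized.  (The
deviance is normalized by the sample size, as in glmnet/ncvreg, so that
lambda lives on the standardized-coefficient scale and the SCAD taper
engages for realistic effect sizes.)  The SCAD
penalty uses the conventional shape constant a = 3.7; solutions along the
path are stationary points reached by IRLS + exact coordinate descent with
warm starts (see :mod:`._solver`).

Tuning-parameter selection uses cross-validated predictive AUC: per
lambda, out-of-fold predicted probabilities are pooled over stratified
folds and the lambda maximizing the pooled ROC AUC is returned (ties
toward larger lambda, i.e. the sparser model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import _solver
from .featexp import FeatureMatrix
from .genio import CovariateMatrix, PhenotypeVector

__all__ = [
    "PenaltySpec",
    "ModelCoefficients",
    "PathFit",
    "CVResult",
    "penalty_value",
    "penalty_deriv",
    "threshold_update",
    "lambda_max",
    "make_lambda_grid",
    "fit_path",
    "cv_auc_select",
]

#: coefficients below this magnitude are reported as zero in active sets
ZERO_TOL = 1e-8


@dataclass
class PenaltySpec:
    """Penalty choice: ``kind`` in {"lasso", "scad"}; ``a`` is the SCAD
    shape constant (> 2, default 3.7, ignored for lasso)."""

    kind: str = "scad"
    a: float = 3.7

    def __post_init__(self) -> None:
        if self.kind not in ("lasso", "scad"):
            raise ValueError(f"unknown penalty kind {self.kind!r}")
        if self.kind == "scad" and self.a <= 2.0:
            raise ValueError("SCAD shape constant a must exceed 2")

    @property
    def code(self) -> int:
        return _solver.LASSO if self.kind == "lasso" else _solver.SCAD


@dataclass
class ModelCoefficients:
    intercept: float
    covariate_coefs: np.ndarray
    feature_coefs: np.ndarray

    def active_set(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.feature_coefs) >= ZERO_TOL)

    def linear_predictor(
        self, F_values: np.ndarray, C_values: np.ndarray | None = None
    ) -> np.ndarray:
        eta = self.intercept + F_values @ self.feature_coefs
        if C_values is not None and C_values.shape[1]:
            eta = eta + C_values @ self.covariate_coefs
        return eta


@dataclass
class PathFit:
    """Coefficients over a decreasing lambda grid for one penalized fit."""

    lambda_grid: np.ndarray
    coefs: np.ndarray  # (n_lambda, p) feature coefficients
    intercepts: np.ndarray
    covariate_coefs: np.ndarray  # (n_lambda, c)
    converged: np.ndarray
    deviance: np.ndarray
    ever_active: np.ndarray  # bool (p,), union of active sets over the grid
    separation_flag: np.ndarray
    penalty: PenaltySpec

    @property
    def n_lambda(self) -> int:
        return len(self.lambda_grid)

    def coefficients(self, l: int) -> ModelCoefficients:
        return ModelCoefficients(
            float(self.intercepts[l]),
            self.covariate_coefs[l],
            self.coefs[l],
        )

    def active_set(self, l: int) -> np.ndarray:
        return np.flatnonzero(np.abs(self.coefs[l]) >= ZERO_TOL)

    @property
    def active_sets(self) -> list[np.ndarray]:
        return [self.active_set(l) for l in range(self.n_lambda)]

    def active_matrix(self) -> np.ndarray:
        """Boolean (n_lambda, p) selection indicators."""
        return np.abs(self.coefs) >= ZERO_TOL

    def predict_proba(
        self, F_values: np.ndarray, C_values: np.ndarray | None = None
    ) -> np.ndarray:
        """(n, n_lambda) predicted case probabilities."""
        eta = self.intercepts[None, :] + F_values @ self.coefs.T
        if C_values is not None and C_values.shape[1]:
            eta = eta + C_values @ self.covariate_coefs.T
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))

    def export(self, feature_ids: list[str]) -> pd.DataFrame:
        """Nonzero path entries as (lambda, feature_id, coefficient) rows."""
        rows = []
        for l, lam in enumerate(self.lambda_grid):
            for j in self.active_set(l):
                rows.append((lam, feature_ids[j], self.coefs[l, j]))
        return pd.DataFrame(rows, columns=["lambda", "feature_id", "coefficient"])


# ---------------------------------------------------------------------------
# scalar penalty functions


def penalty_value(theta: float, lam: float, spec: PenaltySpec) -> float:
    """p_lambda(theta): lambda*|theta| for lasso; for SCAD the integral of
    the SCAD derivative from 0 (linear, quadratic taper, then the plateau
    (a+1) lambda^2 / 2 for |theta| >= a*lambda)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return float(_solver.penalty_value_kernel(float(theta), lam, spec.code, spec.a))


def penalty_deriv(theta: float, lam: float, spec: PenaltySpec) -> float:
    """d p_lambda / d|theta|; at theta = 0 this is the subgradient bound
    lambda for both penalties."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return float(_solver.penalty_deriv_kernel(float(theta), lam, spec.code, spec.a))


def threshold_update(
    z: float, lam: float, spec: PenaltySpec, curvature: float = 1.0
) -> float:
    """Exact minimizer of curvature/2 * (theta - z)^2 + p_lambda(theta)."""
    if curvature <= 0:
        raise ValueError("curvature must be positive")
    return float(_solver.threshold_kernel(float(z), lam, curvature, spec.code, spec.a))


# ---------------------------------------------------------------------------
# path fitting


def _as_arrays(
    F: FeatureMatrix | np.ndarray,
    y: PhenotypeVector | np.ndarray,
    C: CovariateMatrix | np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    X = np.asfortranarray(X, dtype=np.float64)
    yv = y.y if isinstance(y, PhenotypeVector) else np.asarray(y)
    yv = yv.astype(np.float64)
    if C is None:
        Xc = np.zeros((X.shape[0], 0))
    else:
        Xc = C.values if isinstance(C, CovariateMatrix) else np.asarray(C, dtype=float)
    Xc = np.asfortranarray(Xc, dtype=np.float64)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if yv.min() == yv.max():
        raise ValueError("y must contain both cases and controls")
    return X, yv, Xc


def _null_mu(y: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    """Fitted probabilities of the covariates-only (null) logistic model."""
    n = len(y)
    if Xc.shape[1] == 0:
        return np.full(n, y.mean())
    D = np.column_stack([np.ones(n), Xc])
    coef = np.zeros(D.shape[1])
    for _ in range(50):
        eta = np.clip(D @ coef, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = D.T @ (y - mu)
        H = (D * w[:, None]).T @ D + 1e-10 * np.eye(D.shape[1])
        step = np.linalg.solve(H, grad)
        coef += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(D @ coef, -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


def lambda_max(
    F: FeatureMatrix | np.ndarray,
    y: PhenotypeVector | np.ndarray,
    C: CovariateMatrix | np.ndarray | None = None,
) -> float:
    """Smallest lambda at which every penalized coefficient is zero.

    From the zero-coefficient optimality condition at the covariates-only
    null fit: lambda_max = max_j |(2/n) X_j'(y - mu0)| (inflated slightly
    so the first grid point is strictly inside the all-zero region).
    """
    X, yv, Xc = _as_arrays(F, y, C)
    mu0 = _null_mu(yv, Xc)
    score = (2.0 / len(yv)) * (X.T @ (yv - mu0))
    return float(np.max(np.abs(score))) * 1.000001


def make_lambda_grid(
    lam_max: float, n_lambda: int = 100, lambda_min_ratio: float = 0.05
) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to ratio*lambda_max."""
    if lam_max <= 0:
        raise ValueError("lambda_max must be positive")
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def fit_path(
    F: FeatureMatrix | np.ndarray,
    y: PhenotypeVector | np.ndarray,
    C: CovariateMatrix | np.ndarray | None = None,
    spec: PenaltySpec | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.05,
    lambdas: np.ndarray | None = None,
    q_stop: int | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    max_irls: int = 30,
) -> PathFit:
    """Fit the penalized logistic path over a decreasing lambda grid.

    Parameters
    ----------
    F, y, C
        Standardized feature matrix, binary phenotype, optional covariates.
    spec
        Penalty specification; default SCAD with a = 3.7.
    lambdas
        Explicit decreasing grid; computed from the data when omitted.
    q_stop
        Optional budget on the cumulative ever-active set: the path stops
        before the first grid point at which the union of active sets
        would exceed ``q_stop``.  ``None`` fits the whole grid.

    Notes
    -----
    Grid points whose inner loops exhaust their iteration budgets are
    flagged non-converged and the path continues.  Complete separation is
    flagged per lambda when a coefficient hits the solver bound.
    """
    spec = spec or PenaltySpec()
    X, yv, Xc = _as_arrays(F, y, C)
    if lambdas is None:
        lambdas = make_lambda_grid(lambda_max(X, yv, Xc), n_lambda, lambda_min_ratio)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    p = X.shape[1]
    q = p + 1 if q_stop is None else int(q_stop)
    (beta_path, b0_path, gamma_path, conv, dev, n_used, ever, capped) = (
        _solver.fit_path_kernel(
            X, Xc, yv, lambdas, spec.code, spec.a, tol, max_sweeps, max_irls, q
        )
    )
    n_used = int(n_used)
    return PathFit(
        lambda_grid=lambdas[:n_used],
        coefs=beta_path[:n_used],
        intercepts=b0_path[:n_used],
        covariate_coefs=gamma_path[:n_used],
        converged=conv[:n_used].astype(bool),
        deviance=dev[:n_used],
        ever_active=ever.astype(bool),
        separation_flag=capped[:n_used].astype(bool),
        penalty=spec,
    )


@dataclass
class CVResult:
    lambda_grid: np.ndarray
    cv_auc: np.ndarray
    best_index: int

    @property
    def best_lambda(self) -> float:
        return float(self.lambda_grid[self.best_index])


def cv_auc_select(
    F: FeatureMatrix | np.ndarray,
    y: PhenotypeVector | np.ndarray,
    C: CovariateMatrix | np.ndarray | None = None,
    spec: PenaltySpec | None = None,
    folds: int = 5,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.05,
    **fit_kwargs,
) -> CVResult:
    """Choose lambda by pooled out-of-fold predictive ROC AUC.

    Folds are stratified by case status; per lambda the held-out predicted
    probabilities from all folds are pooled and a single AUC computed.
    Ties are broken toward the larger lambda (sparser model).
    """
    spec = spec or PenaltySpec()
    X, yv, Xc = _as_arrays(F, y, C)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    counts = np.bincount(yv.astype(int))
    if counts.min() < folds:
        raise ValueError(
            f"cannot stratify {folds} folds with class counts {counts.tolist()}"
        )
    lambdas = make_lambda_grid(lambda_max(X, yv, Xc), n_lambda, lambda_min_ratio)
    oof = np.full((len(yv), len(lambdas)), np.nan)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, yv):
        fit = fit_path(
            np.asfortranarray(X[train]),
            yv[train],
            np.asfortranarray(Xc[train]),
            spec=spec,
            lambdas=lambdas,
            **fit_kwargs,
        )
        probs = fit.predict_proba(X[test], Xc[test])
        if fit.n_lambda < len(lambdas):  # q-truncated path: carry the last model
            pad = np.repeat(probs[:, -1:], len(lambdas) - fit.n_lambda, axis=1)
            probs = np.hstack([probs, pad])
        oof[test] = probs
    aucs = np.array([roc_auc_score(yv, oof[:, l]) for l in range(len(lambdas))])
    # argmax returns the first (largest-lambda) maximizer: the sparser model
    best = int(np.argmax(aucs))
    return CVResult(lambda_grid=lambdas, cv_auc=aucs, best_index=best)
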