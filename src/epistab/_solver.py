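"""Numba kernels for penalized logistic regression by coordinate descent.

The objective is the sample-size-normalized penalized deviance

    l(theta) = -(2/n) log L(theta) + sum_j p_lambda(theta_j)

with an L1 (lasso) or SCAD penalty on the feature coefficients and no
penalty on the intercept or covariates.  Normalizing the deviance by n
(the glmnet/ncvreg convention) puts lambda on the same scale as the
standardized coefficients, so the SCAD taper region lambda < |theta| <=
a*lambda is actually reached by real effect sizes; without it lambda at
selection scale is O(sqrt(n)) and SCAD degenerates to lasso everywhere.  The solver is the standard
IRLS-plus-cyclic-coordinate-descent scheme: at each lambda a quadratic
(weighted least squares) surrogate of the deviance is refreshed from the
current linear predictor and minimized coordinate-wise with the *exact*
univariate penalized update (soft-thresholding for lasso, the three-region
closed form for SCAD), warm-starting from the previous lambda.  A
working-set strategy keeps the per-lambda cost near O(n * |active|): the
subproblem is solved on the current working set, then a single full
gradient pass adds any feature violating its zero-coefficient optimality
condition, repeating until no violations remain.

For SCAD the solutions are stationary points of a nonconvex objective, not
certified global minima; warm starts along the decreasing lambda grid give
the conventional ncvreg-style path.
"""

import numpy as np
from numba import njit

LASSO = 0
SCAD = 1

#: cap on |coefficient| used to keep complete-separation fits finite
COEF_BOUND = 50.0


@njit(cache=True)
def scad_value(theta, lam, a):
    """SCAD penalty value: L1 near 0, quadratic taper, plateau beyond a*lam."""
    t = abs(theta)
    if t <= lam:
        return lam * t
    if t <= a * lam:
        return (2.0 * a * lam * t - t * t - lam * lam) / (2.0 * (a - 1.0))
    return 0.5 * (a + 1.0) * lam * lam


@njit(cache=True)
def penalty_value_kernel(theta, lam, kind, a):
    if kind == LASSO:
        return lam * abs(theta)
    return scad_value(theta, lam, a)


@njit(cache=True)
def penalty_deriv_kernel(theta, lam, kind, a):
    """d p_lambda / d|theta| (the lasso value at 0 is the subgradient bound)."""
    if kind == LASSO:
        return lam
    t = abs(theta)
    if t <= lam:
        return lam
    r = (a * lam - t) / (a - 1.0)
    return r if r > 0.0 else 0.0


@njit(cache=True)
def threshold_kernel(z, lam, c, kind, a):
    """Exact global minimizer of  c/2 * (t - z)^2 + p_lambda(t).

    For lasso this is soft-thresholding at lam/c.  For SCAD the objective
    is piecewise quadratic in |t| over [0, lam], [lam, a*lam] and
    [a*lam, inf); the candidate minimizer of each piece (clipped to its
    region) is evaluated and the best kept, which is exact even when the
    middle piece is concave (its minimum then sits at a region boundary,
    which clipping covers).
    """
    if lam <= 0.0:
        return z
    if kind == LASSO:
        t = abs(z) - lam / c
        if t <= 0.0:
            return 0.0
        return t if z > 0.0 else -t
    az = abs(z)
    sgn = 1.0 if z >= 0.0 else -1.0
    # region 1: |t| <= lam, penalty lam*|t|
    t1 = az - lam / c
    if t1 < 0.0:
        t1 = 0.0
    elif t1 > lam:
        t1 = lam
    f1 = 0.5 * c * (t1 - az) ** 2 + lam * t1
    best_t, best_f = t1, f1
    # region 2: lam <= |t| <= a*lam, stationary point of the taper quadratic
    denom = c * (a - 1.0) - 1.0
    if denom > 0.0:
        t2 = (c * (a - 1.0) * az - a * lam) / denom
    else:
        t2 = lam  # concave piece: boundary minima, both covered by clipping
    if t2 < lam:
        t2 = lam
    elif t2 > a * lam:
        t2 = a * lam
    f2 = 0.5 * c * (t2 - az) ** 2 + scad_value(t2, lam, a)
    if f2 < best_f:
        best_t, best_f = t2, f2
    # region 3: |t| >= a*lam, constant penalty
    t3 = az if az > a * lam else a * lam
    f3 = 0.5 * c * (t3 - az) ** 2 + 0.5 * (a + 1.0) * lam * lam
    if f3 < best_f:
        best_t, best_f = t3, f3
    return sgn * best_t


@njit(cache=True)
def _refresh_quadratic(eta, y, mu, w, r):
    """Recompute mu, IRLS weights and working residual from eta.

    Weights are w_i = (2/n) mu (1 - mu) (the factor 2/n carries the
    -(2/n) log L scaling) with a floor to keep the quadratic well posed;
    the working residual r_i = z_i - eta_i = (y_i - mu_i)/(mu_i (1 - mu_i))
    is scale-free.
    """
    n = eta.shape[0]
    inv_n = 1.0 / n
    for i in range(n):
        e = eta[i]
        if e > 30.0:
            e = 30.0
        elif e < -30.0:
            e = -30.0
        m = 1.0 / (1.0 + np.exp(-e))
        if m < 1e-8:
            m = 1e-8
        elif m > 1.0 - 1e-8:
            m = 1.0 - 1e-8
        mu[i] = m
        wi = 2.0 * m * (1.0 - m)
        if wi < 1e-10:
            wi = 1e-10
        r[i] = 2.0 * (y[i] - m) / wi
        w[i] = wi * inv_n


@njit(cache=True)
def _cd_sweep(X, Xc, beta, gamma, b0, eta, w, r, work, lam, kind, a):
    """One cyclic pass over intercept, covariates and working-set features.

    Returns the largest absolute coefficient change of the pass.  eta and
    the weighted residual r are kept consistent incrementally.
    """
    n, p = X.shape
    nc = Xc.shape[1]
    maxd = 0.0
    # intercept (unpenalized)
    c0 = 0.0
    num = 0.0
    for i in range(n):
        c0 += w[i]
        num += w[i] * r[i]
    d = num / c0
    if d != 0.0:
        b0[0] += d
        for i in range(n):
            eta[i] += d
            r[i] -= d
        if abs(d) > maxd:
            maxd = abs(d)
    # covariates (unpenalized)
    for j in range(nc):
        cj = 0.0
        num = 0.0
        for i in range(n):
            xw = w[i] * Xc[i, j]
            cj += xw * Xc[i, j]
            num += xw * r[i]
        if cj <= 1e-12:
            continue
        d = num / cj
        if d != 0.0:
            gamma[j] += d
            for i in range(n):
                eta[i] += Xc[i, j] * d
                r[i] -= Xc[i, j] * d
            if abs(d) > maxd:
                maxd = abs(d)
    # penalized features in the working set
    for j in range(p):
        if work[j] == 0:
            continue
        bj = beta[j]
        cj = 0.0
        num = 0.0
        for i in range(n):
            xw = w[i] * X[i, j]
            cj += xw * X[i, j]
            num += xw * r[i]
        if cj <= 1e-12:
            continue
        zstar = num / cj + bj
        bnew = threshold_kernel(zstar, lam, cj, kind, a)
        if bnew > COEF_BOUND:
            bnew = COEF_BOUND
        elif bnew < -COEF_BOUND:
            bnew = -COEF_BOUND
        d = bnew - bj
        if d != 0.0:
            beta[j] = bnew
            for i in range(n):
                eta[i] += X[i, j] * d
                r[i] -= X[i, j] * d
            if abs(d) > maxd:
                maxd = abs(d)
    return maxd


@njit(cache=True)
def _solve_working(
    X, Xc, y, beta, gamma, b0, eta, work, lam, kind, a, tol, max_sweeps, max_irls
):
    """IRLS outer loop restricted to the working set; True if converged."""
    n = X.shape[0]
    mu = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)
    for _ in range(max_irls):
        _refresh_quadratic(eta, y, mu, w, r)
        maxd_irls = 0.0
        for _ in range(max_sweeps):
            maxd = _cd_sweep(X, Xc, beta, gamma, b0, eta, w, r, work, lam, kind, a)
            if maxd > maxd_irls:
                maxd_irls = maxd
            if maxd < tol:
                break
        if maxd_irls < tol:
            return True
    return False


@njit(cache=True)
def _kkt_violations(X, y, eta, work, lam, tol):
    """Add zero features whose score exceeds the penalty subgradient bound.

    The zero-coefficient optimality condition is |(2/n) X_j'(y - mu)| <=
    lam (identical for lasso and SCAD since p'(0+) = lam for both).
    """
    n, p = X.shape
    resid2 = np.empty(n)
    inv_n = 1.0 / n
    for i in range(n):
        e = eta[i]
        if e > 30.0:
            e = 30.0
        elif e < -30.0:
            e = -30.0
        m = 1.0 / (1.0 + np.exp(-e))
        resid2[i] = 2.0 * (y[i] - m) * inv_n
    n_new = 0
    for j in range(p):
        if work[j] == 1:
            continue
        g = 0.0
        for i in range(n):
            g += X[i, j] * resid2[i]
        if abs(g) > lam * (1.0 + 1e-4) + tol:
            work[j] = 1
            n_new += 1
    return n_new


@njit(cache=True)
def _deviance(y, eta):
    n = y.shape[0]
    dev = 0.0
    for i in range(n):
        e = eta[i]
        if e > 30.0:
            e = 30.0
        elif e < -30.0:
            e = -30.0
        m = 1.0 / (1.0 + np.exp(-e))
        if m < 1e-12:
            m = 1e-12
        elif m > 1.0 - 1e-12:
            m = 1.0 - 1e-12
        if y[i] == 1.0:
            dev -= 2.0 * np.log(m)
        else:
            dev -= 2.0 * np.log(1.0 - m)
    return dev


@njit(cache=True)
def fit_path_kernel(X, Xc, y, lambdas, kind, a, tol, max_sweeps, max_irls, q_stop):
    """Fit the full regularization path with warm starts.

    Parameters are raw arrays: X (n, p) standardized penalized features in
    Fortran order, Xc (n, c) unpenalized covariates, y in {0, 1}, lambdas
    strictly decreasing.  ``q_stop`` truncates the path at the smallest
    lambda for which the cumulative ever-active set stays within the
    budget: grid points are recorded while |union of active sets| <= q_stop
    and the path stops at the first point that would exceed it (pass
    q_stop >= p to disable).

    Returns (beta_path, b0_path, gamma_path, converged, deviance, n_used,
    ever_active, capped); rows of beta_path beyond n_used are zero filler.
    """
    n, p = X.shape
    nc = Xc.shape[1]
    nlam = lambdas.shape[0]
    beta = np.zeros(p)
    gamma = np.zeros(nc)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    if ybar < 1e-8:
        ybar = 1e-8
    elif ybar > 1.0 - 1e-8:
        ybar = 1.0 - 1e-8
    b0 = np.empty(1)
    b0[0] = np.log(ybar / (1.0 - ybar))
    eta = np.empty(n)
    for i in range(n):
        eta[i] = b0[0]
    beta_path = np.zeros((nlam, p))
    b0_path = np.zeros(nlam)
    gamma_path = np.zeros((nlam, nc))
    converged = np.zeros(nlam, np.uint8)
    deviance = np.zeros(nlam)
    capped = np.zeros(nlam, np.uint8)
    ever = np.zeros(p, np.uint8)
    n_ever = 0
    work = np.zeros(p, np.uint8)
    n_used = 0
    for l in range(nlam):
        lam = lambdas[l]
        conv = False
        for _ in range(50):
            conv = _solve_working(
                X, Xc, y, beta, gamma, b0, eta, work, lam, kind, a,
                tol, max_sweeps, max_irls,
            )
            if _kkt_violations(X, y, eta, work, lam, tol) == 0:
                break
        # prospective ever-active count under the q budget
        n_new = 0
        for j in range(p):
            if beta[j] != 0.0 and ever[j] == 0:
                n_new += 1
        if n_ever + n_new > q_stop:
            break
        for j in range(p):
            if beta[j] != 0.0 and ever[j] == 0:
                ever[j] = 1
        n_ever += n_new
        for j in range(p):
            beta_path[l, j] = beta[j]
            if abs(beta[j]) >= COEF_BOUND:
                capped[l] = 1
        b0_path[l] = b0[0]
        for j in range(nc):
            gamma_path[l, j] = gamma[j]
        converged[l] = 1 if conv else 0
        deviance[l] = _deviance(y, eta)
        n_used = l + 1
        # keep only currently-active features in the warm-start working set
        for j in range(p):
            work[j] = 1 if beta[j] != 0.0 else 0
    return (
        beta_path, b0_path, gamma_path, converged, deviance,
        n_used, ever, capped,
    )
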