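"""Stability selection with an FDR bound for penalized logistic selection.

The procedure runs the penalized solver on B stratified subsamples (half
the cases and half the controls by default), records which features are
active at each point of a common lambda grid, and estimates each feature's
selection probability Pi_k as the maximum over the grid of its per-lambda
selection frequency.  The regularization region per subsample is set by a
variable budget q: each subsample's path is truncated at the smallest
lambda for which the cumulative set of ever-active features would exceed
q, so the per-subsample union size never exceeds q.

With q_Lambda the Monte Carlo estimate of the expected union size, the
exchangeability bound on falsely selected variables,

    E[V] <= q_Lambda^2 / ((2 pi_thr - 1) p),

gives an FDR bound q_Lambda / ((2 pi_thr - 1) p) after dividing by the
stable-set size (~ q_Lambda), and solving FDR <= alpha for the threshold
yields pi_thr = (1 + q_Lambda / (p alpha)) / 2.  Features with
Pi_k >= pi_thr form the stable set.

A permutation calibration (refitting on phenotype-permuted data and
checking the selection probability of the strongest marginal feature
against pi_thr) and a two-stage discovery/replication workflow with a
recalibrated budget and odds-ratio direction concordance are included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .featexp import FeatureMatrix
from .genio import CovariateMatrix, PhenotypeVector
from .scadglm import PathFit, PenaltySpec, fit_path, lambda_max, make_lambda_grid

__all__ = [
    "StabilityConfig",
    "StabilityResult",
    "TwoStageResult",
    "InfeasibleThresholdError",
    "default_q",
    "pi_threshold",
    "expected_false_bound",
    "fdr_bound",
    "subsample_indices",
    "run_stability",
    "permutation_calibration",
    "two_stage",
]


#: solver settings for per-subsample paths: stability selection consumes
#: active sets, not coefficient values, so subsample fits converge to
#: selection-level precision (Pi-hat shifts < the 1/B Monte Carlo grain)
#: rather than the tighter default coefficient tolerance
_SUBSAMPLE_FIT_KWARGS = dict(tol=1e-5, max_sweeps=500, max_irls=15)


class InfeasibleThresholdError(ValueError):
    """q_Lambda exceeds p*alpha, so no threshold in (1/2, 1] controls FDR at
    alpha; use a smaller q or a larger alpha."""


@dataclass
class StabilityConfig:
    """Subsampling and error-control settings.

    B subsamples, each holding ``subsample_fraction`` of the cases and of
    the controls (without replacement); ``q`` is the per-path variable
    budget (default floor(sqrt(p)) when None); ``alpha`` the target FDR.
    """

    B: int = 500
    subsample_fraction: float = 0.5
    q: int | None = None
    alpha: float = 0.2
    seed: int = 0
    n_lambda: int = 100
    lambda_min_ratio: float = 0.05

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.subsample_fraction < 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1)")
        if self.q is not None and self.q < 1:
            raise ValueError("q must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class StabilityResult:
    """Selection probabilities and the FDR-bound stable set."""

    selection_prob: np.ndarray  # Pi_k: max over the lambda grid
    union_freq: np.ndarray  # diagnostic: per-subsample-union frequency
    q_lambda_hat: float
    pi_thr: float
    stable_set: np.ndarray
    per_subsample_unions: np.ndarray
    sign_summary: np.ndarray
    q: int
    alpha: float
    B: int
    degenerate_threshold: bool = False

    def table(self, F: FeatureMatrix) -> pd.DataFrame:
        man = F.manifest()
        man["selection_prob"] = self.selection_prob
        man["union_freq"] = self.union_freq
        stable = np.zeros(len(self.selection_prob), dtype=bool)
        stable[self.stable_set] = True
        man["stable_flag"] = stable
        man["mean_sign"] = self.sign_summary
        return man.sort_values("selection_prob", ascending=False, kind="stable")


@dataclass
class TwoStageResult:
    discovery: StabilityResult
    replication: StabilityResult | None
    pi_thr1: float
    pi_thr2: float | None
    confirmed_pairs: np.ndarray
    replication_skipped: bool = False


# ---------------------------------------------------------------------------
# threshold algebra


def default_q(p: int) -> int:
    """Conservative variable budget: floor(sqrt(p)), at least 1."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return max(1, math.isqrt(p))


def pi_threshold(q_lambda: float, p: int, alpha: float) -> float:
    """Selection-probability threshold controlling the FDR bound at alpha:
    pi_thr = (1 + q_Lambda / (p alpha)) / 2, valid while q_Lambda <= p*alpha.
    """
    if q_lambda < 0:
        raise ValueError("q_lambda must be non-negative")
    budget = p * alpha
    if q_lambda > budget:
        raise InfeasibleThresholdError(
            f"q_lambda={q_lambda:.3g} exceeds p*alpha={budget:.3g}; "
            "use a smaller q or a larger alpha"
        )
    return 0.5 * (1.0 + q_lambda / budget)


def expected_false_bound(q_lambda: float, p: int, pi_thr: float) -> float:
    """Bound on the expected number of falsely selected variables:
    E[V] <= q_Lambda^2 / ((2 pi_thr - 1) p)."""
    if not 0.5 < pi_thr <= 1.0:
        raise ValueError("pi_thr must lie in (0.5, 1]")
    return q_lambda * q_lambda / ((2.0 * pi_thr - 1.0) * p)


def fdr_bound(q_lambda: float, p: int, pi_thr: float) -> float:
    """FDR bound E[V] / |stable set| ~ q_Lambda / ((2 pi_thr - 1) p)."""
    if q_lambda <= 0:
        raise ValueError("q_lambda must be positive for the FDR bound")
    return expected_false_bound(q_lambda, p, pi_thr) / q_lambda


# ---------------------------------------------------------------------------
# subsampling and the main procedure


def subsample_indices(
    y: PhenotypeVector | np.ndarray, config: StabilityConfig
) -> list[np.ndarray]:
    """B stratified without-replacement subsamples of the sample indices.

    Each subsample holds round(fraction * n_cases) cases and
    round(fraction * n_controls) controls.  Subsample b uses its own
    deterministic generator seeded with ``config.seed + b`` so the B draws
    are reproducible and order-independent.
    """
    yv = y.y if isinstance(y, PhenotypeVector) else np.asarray(y)
    cases = np.flatnonzero(yv == 1)
    ctrls = np.flatnonzero(yv == 0)
    if len(cases) < 2 or len(ctrls) < 2:
        raise ValueError("both classes need at least 2 members")
    n_case = round(config.subsample_fraction * len(cases))
    n_ctrl = round(config.subsample_fraction * len(ctrls))
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("subsample_fraction yields an empty class")
    out = []
    for b in range(config.B):
        rng = np.random.default_rng(config.seed + b)
        pick = np.concatenate(
            [
                rng.choice(cases, size=n_case, replace=False),
                rng.choice(ctrls, size=n_ctrl, replace=False),
            ]
        )
        pick.sort()
        out.append(pick)
    return out


def _representative_coefs(path: PathFit) -> np.ndarray:
    """Per-feature mean of the nonzero coefficients along the used region."""
    active = path.active_matrix()
    n_active = active.sum(axis=0)
    sums = np.where(active, path.coefs, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        rep = np.where(n_active > 0, sums / np.maximum(n_active, 1), 0.0)
    return rep


def run_stability(
    F: FeatureMatrix,
    y: PhenotypeVector | np.ndarray,
    C: CovariateMatrix | None = None,
    spec: PenaltySpec | None = None,
    config: StabilityConfig | None = None,
    lambdas: np.ndarray | None = None,
) -> StabilityResult:
    """Stability selection over B subsamples with the q-budget region rule.

    The lambda grid is computed once from the full sample (so selection
    indicators are comparable across subsamples) and each subsample's path
    is truncated at its own q boundary.  Covariates are refit unpenalized
    within every subsample.
    """
    spec = spec or PenaltySpec()
    config = config or StabilityConfig()
    yv = y.y if isinstance(y, PhenotypeVector) else np.asarray(y)
    p = F.n_features
    q = config.q if config.q is not None else default_q(p)
    if q > p:
        raise ValueError("q cannot exceed the number of features")
    Xc = C.values if C is not None else np.zeros((F.n_samples, 0))
    if lambdas is None:
        lambdas = make_lambda_grid(
            lambda_max(F, yv, Xc), config.n_lambda, config.lambda_min_ratio
        )
    nlam = len(lambdas)
    counts = np.zeros((nlam, p), dtype=np.int32)
    union_counts = np.zeros(p, dtype=np.int32)
    sign_acc = np.zeros(p)
    unions = np.zeros(config.B, dtype=np.int64)
    for b, idx in enumerate(subsample_indices(yv, config)):
        fit = fit_path(
            F.subset_samples(idx),
            yv[idx],
            np.asfortranarray(Xc[idx]),
            spec=spec,
            lambdas=lambdas,
            q_stop=q,
            **_SUBSAMPLE_FIT_KWARGS,
        )
        active = fit.active_matrix()
        counts[: active.shape[0]] += active
        union = fit.ever_active
        union_counts += union
        unions[b] = int(union.sum())
        sign_acc += np.sign(_representative_coefs(fit))
    selection_prob = counts.max(axis=0) / config.B
    union_freq = union_counts / config.B
    q_lambda_hat = float(unions.mean())
    degenerate = q_lambda_hat == 0.0
    pi_thr = pi_threshold(q_lambda_hat, p, config.alpha) if not degenerate else 0.5
    stable = np.flatnonzero(
        selection_prob >= pi_thr if not degenerate else selection_prob > 0.5
    )
    return StabilityResult(
        selection_prob=selection_prob,
        union_freq=union_freq,
        q_lambda_hat=q_lambda_hat,
        pi_thr=pi_thr,
        stable_set=stable,
        per_subsample_unions=unions,
        sign_summary=sign_acc / config.B,
        q=q,
        alpha=config.alpha,
        B=config.B,
        degenerate_threshold=degenerate,
    )


# ---------------------------------------------------------------------------
# permutation calibration


def _marginal_score_stats(F: FeatureMatrix, yv: np.ndarray) -> np.ndarray:
    """Single-feature score-test chi-square statistics on the standardized
    features (covariates ignored for this scan)."""
    X = F.values
    ybar = yv.mean()
    resid = yv - ybar
    Xc = X - X.mean(axis=0)
    U = Xc.T @ resid
    V = ybar * (1 - ybar) * (Xc**2).sum(axis=0)
    V = np.maximum(V, 1e-300)
    return U * U / V


def permutation_calibration(
    F: FeatureMatrix,
    y: PhenotypeVector | np.ndarray,
    C: CovariateMatrix | None = None,
    spec: PenaltySpec | None = None,
    config: StabilityConfig | None = None,
    n_perm: int = 10,
) -> pd.DataFrame:
    """Conservativeness check of the FDR-bound threshold under permutation.

    For each permutation the phenotype vector is shuffled, the feature with
    the largest marginal association statistic on the permuted data is
    located, stability selection is rerun, and that feature's selection
    probability is reported next to pi_thr.  Under the null the selection
    probability should fall below the threshold in nearly all permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    config = config or StabilityConfig()
    yv = y.y if isinstance(y, PhenotypeVector) else np.asarray(y)
    rows = []
    for t in range(n_perm):
        rng = np.random.default_rng(config.seed + 100_000 + t)
        y_perm = rng.permutation(yv)
        stats = _marginal_score_stats(F, y_perm)
        top = int(np.argmax(stats))
        res = run_stability(F, y_perm, C, spec, config)
        rows.append(
            {
                "permutation": t,
                "feature_id": F.feature_ids[top],
                "feature_index": top,
                "max_statistic": float(stats[top]),
                "selection_prob": float(res.selection_prob[top]),
                "pi_thr": res.pi_thr,
                "exceeds_threshold": bool(res.selection_prob[top] >= res.pi_thr),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-stage discovery / replication


def _sign_concordant(res1: StabilityResult, res2: StabilityResult,
                     F: FeatureMatrix, col: int) -> bool:
    """OR-direction concordance for an interaction feature across stages.

    The interaction term must carry the same nonzero sign in both stages;
    the two main-effect columns must not carry opposite signs (a main
    effect never selected averages to sign 0, which is not treated as a
    contradiction).
    """
    s1, s2 = np.sign(res1.sign_summary[col]), np.sign(res2.sign_summary[col])
    if s1 == 0 or s2 == 0 or s1 != s2:
        return False
    j, k = F.pair_index[col]
    for main_col in (int(j), int(k)):
        m1 = np.sign(res1.sign_summary[main_col])
        m2 = np.sign(res2.sign_summary[main_col])
        if m1 * m2 < 0:
            return False
    return True


def two_stage(
    F1: FeatureMatrix,
    y1: PhenotypeVector | np.ndarray,
    C1: CovariateMatrix | None,
    F2: FeatureMatrix,
    y2: PhenotypeVector | np.ndarray,
    C2: CovariateMatrix | None,
    spec: PenaltySpec | None = None,
    config: StabilityConfig | None = None,
    alpha: float | None = None,
) -> TwoStageResult:
    """Discovery/replication workflow with a recalibrated budget.

    Discovery runs with q = floor(sqrt(p)); replication reruns on the
    second cohort with q set to the discovery stable-set size (minimum 1).
    Confirmed pairs are interaction features stable in both stages whose
    odds-ratio directions agree across stages.
    """
    spec = spec or PenaltySpec()
    config = config or StabilityConfig()
    if F1.feature_ids != F2.feature_ids:
        raise ValueError("both stages must share the same feature manifest")
    if alpha is not None:
        config = StabilityConfig(
            B=config.B,
            subsample_fraction=config.subsample_fraction,
            q=config.q,
            alpha=alpha,
            seed=config.seed,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
        )
    p = F1.n_features
    cfg1 = StabilityConfig(
        B=config.B,
        subsample_fraction=config.subsample_fraction,
        q=default_q(p),
        alpha=config.alpha,
        seed=config.seed,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    discovery = run_stability(F1, y1, C1, spec, cfg1)
    if len(discovery.stable_set) == 0:
        return TwoStageResult(
            discovery=discovery,
            replication=None,
            pi_thr1=discovery.pi_thr,
            pi_thr2=None,
            confirmed_pairs=np.array([], dtype=int),
            replication_skipped=True,
        )
    cfg2 = StabilityConfig(
        B=config.B,
        subsample_fraction=config.subsample_fraction,
        q=max(1, len(discovery.stable_set)),
        alpha=config.alpha,
        seed=config.seed + 1,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    replication = run_stability(F2, y2, C2, spec, cfg2)
    both = np.intersect1d(discovery.stable_set, replication.stable_set)
    confirmed = [
        int(c)
        for c in both
        if F1.kind[c] == "interaction"
        and _sign_concordant(discovery, replication, F1, int(c))
    ]
    return TwoStageResult(
        discovery=discovery,
        replication=replication,
        pi_thr1=discovery.pi_thr,
        pi_thr2=replication.pi_thr,
        confirmed_pairs=np.array(confirmed, dtype=int),
    )
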