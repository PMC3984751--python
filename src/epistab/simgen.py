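"""Synthetic case-control data with block-LD genotypes and epistatic risk.

Genotypes emulate a resequenced gene region organized in haplotype blocks:
each individual is the sum of two haplotypes drawn from a Gaussian copula
in which SNPs within a block share an AR(1) latent correlation
(rho^|distance|) and different blocks are independent; the latent variable
is thresholded at the normal quantile of the allele frequency, so
genotypes are in Hardy-Weinberg equilibrium with the target MAF.  The
default region has 327 common SNPs in 26 blocks with sizes from 2 to 64
markers and MAF >= 0.05, mirroring a typical pathway-scale LD map.

Phenotypes follow the logistic interaction model

    logit pi_i = beta0 + sum_j beta_j x_ij + sum_{j<k} xi_jk x_ij x_ik

with three canonical sparse scenarios: A (a single pure interaction with
no main effects), B (one main effect on one member of the causal pair
plus the interaction) and C (main effects on both pair members plus the
interaction), at designed odds ratios 1.3 / 1.4 / 1.5 applied to every
causal term.

``run_benchmark`` is the replication harness: per replicate a fresh
population is generated, a balanced case-control sample drawn, each
requested selection method run, and the four evaluation indexes computed
against the known causal features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, toeplitz
from scipy.stats import norm

from . import evalmetrics, featexp, stabsel
from .featexp import FeatureMatrix, expand_interactions, standardize
from .genio import GenotypeMatrix, PhenotypeVector
from .scadglm import PenaltySpec, cv_auc_select, fit_path
from .stabsel import StabilityConfig, run_stability

__all__ = [
    "BlockLDSpec",
    "ScenarioConfig",
    "draw_mafs",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_population",
    "sample_case_control",
    "run_benchmark",
]

#: 26 block sizes (min 2, max 64) summing to 327 markers — the default
#: pathway-scale region emulated by the generator
_DEFAULT_BLOCKS_327 = (
    2, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7, 8, 8, 9, 10, 10, 11, 12, 14,
    16, 20, 24, 28, 44, 64,
)

#: canonical causal positions (1-based SNP numbers in the 327-SNP region):
#: scenario -> (main-effect SNPs, interacting pair)
_CANONICAL_CAUSAL = {
    "A": ((), (33, 197)),
    "B": ((18,), (18, 134)),
    "C": ((33, 134), (33, 134)),
}


@dataclass
class BlockLDSpec:
    """Block-structured LD layout for the genotype generator.

    ``within_block_rho`` is the AR(1) decay of the latent haplotype
    correlation between adjacent SNPs of a block (0 = independent SNPs).
    """

    n_snps: int = 327
    block_sizes: tuple[int, ...] = _DEFAULT_BLOCKS_327
    maf_range: tuple[float, float] = (0.05, 0.5)
    within_block_rho: float = 0.8

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_snps:
            raise ValueError(
                f"block sizes sum to {sum(self.block_sizes)}, expected {self.n_snps}"
            )
        if min(self.block_sizes) < 1:
            raise ValueError("block sizes must be >= 1")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.within_block_rho < 1.0:
            raise ValueError("within_block_rho must lie in [0, 1)")

    @classmethod
    def scaled(cls, n_snps: int, **kwargs) -> "BlockLDSpec":
        """Deterministic scaled-down region: cycle through small block
        sizes until ``n_snps`` markers are placed."""
        cycle = (2, 3, 4, 5, 6, 7, 8)
        sizes: list[int] = []
        total = 0
        i = 0
        while total < n_snps:
            s = min(cycle[i % len(cycle)], n_snps - total)
            if n_snps - total - s == 1:  # avoid a trailing singleton
                s += 1
            sizes.append(s)
            total += s
            i += 1
        return cls(n_snps=n_snps, block_sizes=tuple(sizes), **kwargs)

    def block_of(self, snp: int) -> int:
        """Block index (0-based) containing 0-based SNP ``snp``."""
        edge = 0
        for b, size in enumerate(self.block_sizes):
            edge += size
            if snp < edge:
                return b
        raise IndexError(snp)


@dataclass
class ScenarioConfig:
    """Causal architecture of one simulation scenario.

    ``causal_main`` and ``causal_pair`` are 0-based SNP indices; every
    causal term (main or interaction) carries coefficient log(or_effect).
    ``beta0`` is the population log-odds intercept (0 gives ~50%
    prevalence, matching a balanced sampled population).
    """

    scenario: str
    or_effect: float
    causal_main: tuple[int, ...]
    causal_pair: tuple[int, int]
    beta0: float = 0.0

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B", "C"):
            raise ValueError("scenario must be one of A, B, C")
        if self.or_effect <= 0:
            raise ValueError("or_effect must be positive")
        j, k = self.causal_pair
        if not j < k:
            raise ValueError("causal_pair must be ordered (j, k) with j < k")
        n_main = {"A": 0, "B": 1, "C": 2}[self.scenario]
        if len(self.causal_main) != n_main:
            raise ValueError(
                f"scenario {self.scenario} requires {n_main} main effect(s)"
            )
        if self.scenario == "B" and self.causal_main[0] not in self.causal_pair:
            raise ValueError("scenario B main effect must sit on the causal pair")
        if self.scenario == "C" and set(self.causal_main) != set(self.causal_pair):
            raise ValueError("scenario C main effects must be the causal pair")

    @classmethod
    def from_scenario(
        cls,
        scenario: str,
        or_effect: float,
        spec: BlockLDSpec | None = None,
        beta0: float = 0.0,
    ) -> "ScenarioConfig":
        """Canonical causal positions for a region.

        For the default 327-SNP region the positions are SNP33 x SNP197
        (A), SNP18 + SNP18 x SNP134 (B) and SNP33 + SNP134 + SNP33 x
        SNP134 (C).  For a scaled region the positions are mapped
        proportionally and must land in distinct blocks.
        """
        spec = spec or BlockLDSpec()
        mains, pair = _CANONICAL_CAUSAL[scenario]

        def _map(snp_1based: int) -> int:
            if spec.n_snps == 327:
                return snp_1based - 1
            pos = round(snp_1based * spec.n_snps / 327)
            return int(np.clip(pos, 1, spec.n_snps)) - 1

        pair0 = tuple(sorted(_map(s) for s in pair))
        mains0 = tuple(_map(s) for s in mains)
        if spec.block_of(pair0[0]) == spec.block_of(pair0[1]):
            raise ValueError("causal pair members must come from distinct blocks")
        return cls(scenario, or_effect, mains0, pair0, beta0=beta0)

    def causal_feature_columns(self, m: int) -> np.ndarray:
        """Design-matrix columns of all causal terms (truth set)."""
        cols = [int(j) for j in self.causal_main]
        cols.append(featexp.interaction_column(m, *self.causal_pair))
        return np.array(sorted(cols), dtype=int)


# ---------------------------------------------------------------------------
# genotype and phenotype generation


def draw_mafs(spec: BlockLDSpec, seed: int) -> np.ndarray:
    """Per-SNP target minor allele frequencies (uniform over maf_range).

    Uses the same generator stream as :func:`simulate_genotypes`, so the
    targets of a simulated matrix can be recovered from its seed.
    """
    rng = np.random.default_rng(seed)
    return rng.uniform(*spec.maf_range, size=spec.n_snps)


def simulate_genotypes(
    spec: BlockLDSpec, n: int, seed: int = 0
) -> GenotypeMatrix:
    """Draw n individuals from the Gaussian-copula haplotype model.

    Each haplotype's latent vector has AR(1) correlation rho^|i-j| within
    a block; the allele indicator is latent < Phi^{-1}(MAF) and the
    genotype is the sum of two independent haplotypes, so each SNP is
    Binomial(2, MAF) marginally (HWE holds by construction).
    """
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*spec.maf_range, size=spec.n_snps)
    geno = np.empty((n, spec.n_snps), dtype=float)
    start = 0
    for size in spec.block_sizes:
        thr = norm.ppf(mafs[start : start + size])
        if size == 1 or spec.within_block_rho == 0.0:
            z = rng.standard_normal((n, 2, size))
        else:
            corr = toeplitz(spec.within_block_rho ** np.arange(size))
            L = cholesky(corr, lower=True)
            z = rng.standard_normal((n, 2, size)) @ L.T
        geno[:, start : start + size] = (z < thr).sum(axis=1)
        start += size
    snp_ids = [f"snp{i + 1}" for i in range(spec.n_snps)]
    sample_ids = [f"s{i + 1}" for i in range(n)]
    return GenotypeMatrix(geno, snp_ids, sample_ids)


def true_linear_predictor(G: GenotypeMatrix, config: ScenarioConfig) -> np.ndarray:
    """Log-odds of disease under the scenario's interaction model."""
    X = G.values
    m = G.n_snps
    j, k = config.causal_pair
    if max((*config.causal_main, j, k)) >= m:
        raise ValueError("causal SNP index out of range")
    coef = np.log(config.or_effect)
    eta = np.full(G.n_samples, float(config.beta0))
    for jm in config.causal_main:
        eta += coef * X[:, jm]
    eta += coef * X[:, j] * X[:, k]
    return eta


def simulate_phenotype(
    G: GenotypeMatrix, config: ScenarioConfig, seed: int = 0
) -> PhenotypeVector:
    """Bernoulli phenotypes from the logistic interaction model."""
    eta = true_linear_predictor(G, config)
    pi = 1.0 / (1.0 + np.exp(-eta))
    rng = np.random.default_rng(seed)
    y = rng.binomial(1, pi)
    return PhenotypeVector(y, sample_ids=list(G.sample_ids))


def simulate_population(
    spec: BlockLDSpec,
    config: ScenarioConfig,
    n: int = 20_000,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Genotypes and phenotypes for a source population of size n."""
    G = simulate_genotypes(spec, n, seed=seed)
    y = simulate_phenotype(G, config, seed=seed + 1)
    return G, y


def sample_case_control(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    n_case: int,
    n_ctrl: int,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Uniform without-replacement draw of cases and controls."""
    cases = np.flatnonzero(y.y == 1)
    ctrls = np.flatnonzero(y.y == 0)
    if len(cases) < n_case or len(ctrls) < n_ctrl:
        raise ValueError(
            f"population holds {len(cases)} cases / {len(ctrls)} controls; "
            f"requested {n_case} / {n_ctrl} — simulate a larger population"
        )
    rng = np.random.default_rng(seed)
    rows = np.concatenate(
        [
            rng.choice(cases, size=n_case, replace=False),
            rng.choice(ctrls, size=n_ctrl, replace=False),
        ]
    )
    Gs = G.subset_samples(rows)
    ys = PhenotypeVector(y.y[rows], sample_ids=list(Gs.sample_ids))
    return Gs, ys


# ---------------------------------------------------------------------------
# benchmark harness

_STABILITY_METHODS = {"slasso": "lasso", "sscad": "scad"}
_PLAIN_METHODS = {"lasso": "lasso", "scad": "scad"}


def _run_plain(
    F: FeatureMatrix,
    y: PhenotypeVector,
    penalty: str,
    seed: int,
    cv_folds: int,
    n_lambda: int,
    lambda_min_ratio: float,
) -> tuple[np.ndarray, np.ndarray]:
    """CV-AUC tuned single fit: (selected columns, |coefficient| scores).

    Paths are capped at 200 ever-active features — far above any
    CV-selected model size — to bound the dense small-lambda tail.
    """
    spec = PenaltySpec(kind=penalty)
    cap = min(200, F.n_features)
    cv = cv_auc_select(
        F, y, None, spec,
        folds=cv_folds, seed=seed,
        n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
        q_stop=cap,
    )
    fit = fit_path(F, y, None, spec=spec, lambdas=cv.lambda_grid, q_stop=cap)
    l = min(cv.best_index, fit.n_lambda - 1)
    coefs = fit.coefs[l]
    return fit.active_set(l), np.abs(coefs)


def run_benchmark(
    spec: BlockLDSpec,
    scenarios: list[ScenarioConfig],
    n_replicates: int = 200,
    methods: tuple[str, ...] = ("lasso", "scad", "slasso", "sscad"),
    config: StabilityConfig | None = None,
    seed: int = 0,
    n_case: int = 1000,
    n_ctrl: int = 1000,
    population: int = 20_000,
    cv_folds: int = 5,
    cv_n_lambda: int = 50,
    cv_lambda_min_ratio: float = 0.1,
    return_replicates: bool = False,
) -> pd.DataFrame:
    """Replicated comparison of selection methods under known truth.

    Per replicate: simulate a population, draw a balanced case-control
    sample, expand and standardize the interaction design, run every
    requested method and score its selected set against the causal
    features.  Returns the tidy summary table (method, scenario, metric,
    mean, se, replicates); with ``return_replicates`` the per-replicate
    records are returned alongside.

    Stability methods share the subsampling settings in ``config``; plain
    LASSO/SCAD are tuned by cross-validated predictive AUC on a coarser
    grid (their selected-model scores are |coefficients|).
    """
    config = config or StabilityConfig(B=100)
    unknown = set(methods) - set(_STABILITY_METHODS) - set(_PLAIN_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    records: list[dict] = []
    n_failed = 0
    for s_idx, scen in enumerate(scenarios):
        truth = scen.causal_feature_columns(spec.n_snps)
        label = f"{scen.scenario}(OR={scen.or_effect})"
        for r in range(n_replicates):
            rep_seed = seed + 10_000 * s_idx + 17 * r
            try:
                G, y = simulate_population(
                    spec, scen, n=population, seed=rep_seed
                )
                Gs, ys = sample_case_control(
                    G, y, n_case, n_ctrl, seed=rep_seed + 2
                )
                F = standardize(expand_interactions(Gs))
                for method in methods:
                    if method in _PLAIN_METHODS:
                        selected, scores = _run_plain(
                            F, ys, _PLAIN_METHODS[method], rep_seed + 3,
                            cv_folds, cv_n_lambda, cv_lambda_min_ratio,
                        )
                    else:
                        cfg = StabilityConfig(
                            B=config.B,
                            subsample_fraction=config.subsample_fraction,
                            q=config.q,
                            alpha=config.alpha,
                            seed=rep_seed + 5,
                            n_lambda=config.n_lambda,
                            lambda_min_ratio=config.lambda_min_ratio,
                        )
                        res = run_stability(
                            F, ys, None,
                            PenaltySpec(kind=_STABILITY_METHODS[method]), cfg,
                        )
                        selected, scores = res.stable_set, res.selection_prob
                    rep = evalmetrics.score_selection(
                        selected, scores, truth, F.n_features
                    )
                    records.append(
                        {
                            "method": method,
                            "scenario": label,
                            "replicate": r,
                            "tpr": rep.tpr,
                            "mcc": rep.mcc,
                            "auc": rep.auc,
                            "fdr_hat": rep.fdr_hat,
                        }
                    )
            except Exception as exc:  # noqa: BLE001 — record and move on
                n_failed += 1
                warnings.warn(
                    f"replicate {r} of scenario {label} failed: {exc!r}",
                    stacklevel=2,
                )
    reps = pd.DataFrame(records)
    if reps.empty:
        raise RuntimeError("every benchmark replicate failed")
    long = reps.melt(
        id_vars=["method", "scenario", "replicate"],
        value_vars=["tpr", "mcc", "auc", "fdr_hat"],
        var_name="metric",
    )
    grouped = long.groupby(["method", "scenario", "metric"])["value"]
    table = grouped.agg(
        mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)), replicates="count"
    ).reset_index()
    table.attrs["n_failed"] = n_failed
    if return_replicates:
        return table, reps
    return table
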