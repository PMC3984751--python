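"""Main-effect plus pairwise-interaction design matrix construction.

The logistic interaction model regresses case-control status on all m
allele-count columns and all m(m-1)/2 pairwise products x_j * x_k (j < k),
so a genotype matrix with m SNPs expands to p = m + m(m-1)/2 features.
Interaction columns use the raw allele-count product (multiplicative coding
on counts); the whole design is then standardized column-wise so that a
single penalty scale applies to every feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

__all__ = [
    "FeatureMatrix",
    "expand_interactions",
    "standardize",
    "n_interaction_terms",
    "interaction_column",
]

MAIN = "main"
INTERACTION = "interaction"


def n_interaction_terms(m: int) -> int:
    """Number of unordered SNP pairs, C(m, 2)."""
    return m * (m - 1) // 2


def interaction_column(m: int, j: int, k: int) -> int:
    """Design-matrix column of the (j, k) product term, 0-based, j < k.

    Columns are ordered: m main effects first, then pairs in lexicographic
    (j, k) order, so pair (j, k) sits at m + C(m,2) - C(m-j,2) + (k-j-1).
    """
    if not 0 <= j < k < m:
        raise ValueError(f"need 0 <= j < k < m, got j={j}, k={k}, m={m}")
    return m + n_interaction_terms(m) - n_interaction_terms(m - j) + (k - j - 1)


@dataclass
class FeatureMatrix:
    """Dense n x p design with per-feature bookkeeping.

    ``pair_index`` holds, for interaction columns, the 0-based (j, k) SNP
    pair with j < k; main-effect rows carry (j, -1).  ``center``/``scale``
    record the standardization applied (identity until
    :func:`standardize` is called) so coefficients can be mapped back to
    the raw allele-count scale.
    """

    values: np.ndarray
    feature_ids: list[str]
    kind: np.ndarray  # array of {"main", "interaction"}
    pair_index: np.ndarray  # (p, 2) int
    snp_ids: list[str]
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    constant_mask: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def is_standardized(self) -> bool:
        return self.center is not None

    def column_of_pair(self, j: int, k: int) -> int:
        return interaction_column(self.n_snps, j, k)

    def subset_samples(self, rows: np.ndarray) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(
            self.values[rows],
            self.feature_ids,
            self.kind,
            self.pair_index,
            self.snp_ids,
            self.center,
            self.scale,
            self.constant_mask,
        )

    def manifest(self) -> pd.DataFrame:
        """Feature manifest: (feature_id, kind, snp1, snp2)."""
        snp1 = [self.snp_ids[j] for j in self.pair_index[:, 0]]
        snp2 = [
            self.snp_ids[k] if k >= 0 else "" for k in self.pair_index[:, 1]
        ]
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "kind": self.kind,
                "snp1": snp1,
                "snp2": snp2,
            }
        )


def expand_interactions(G: GenotypeMatrix, dtype=np.float64) -> FeatureMatrix:
    """Build the main-effect + pairwise-product design from genotypes.

    Requires a complete matrix (impute missing calls upstream).  Columns
    are ordered with the m main effects first (input SNP order) followed by
    interactions in lexicographic (j, k) order; interaction ids are
    ``"snpj:snpk"``.
    """
    X = np.asarray(G.values, dtype=dtype)
    if np.isnan(X).any():
        raise ValueError("missing genotypes present; impute before expansion")
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least 2 SNPs to form interaction pairs")
    p = m + n_interaction_terms(m)
    values = np.empty((n, p), dtype=dtype, order="F")
    values[:, :m] = X
    feature_ids = list(G.snp_ids)
    kind = np.array([MAIN] * m + [INTERACTION] * n_interaction_terms(m))
    pair_index = np.full((p, 2), -1, dtype=np.int64)
    pair_index[:m, 0] = np.arange(m)
    col = m
    for j in range(m - 1):
        nk = m - j - 1
        values[:, col : col + nk] = X[:, j : j + 1] * X[:, j + 1 :]
        for k in range(j + 1, m):
            feature_ids.append(f"{G.snp_ids[j]}:{G.snp_ids[k]}")
            pair_index[col, 0] = j
            pair_index[col, 1] = k
            col += 1
    assert col == p
    return FeatureMatrix(values, feature_ids, kind, pair_index, list(G.snp_ids))


def standardize(F: FeatureMatrix) -> FeatureMatrix:
    """Center each column to mean 0 and scale to unit (population) variance.

    Constant columns are centered but left unscaled (scale 1) and flagged
    in ``constant_mask``.  The stored center/scale permit exact
    back-transformation of fitted coefficients:

        theta_raw_j = theta_std_j / scale_j,
        intercept_raw = intercept_std - sum_j theta_std_j * center_j / scale_j.
    """
    if F.n_samples < 2:
        raise ValueError("need n >= 2 samples to standardize")
    if F.is_standardized:
        return F
    center = F.values.mean(axis=0)
    scale = F.values.std(axis=0)  # ddof=0
    constant = scale == 0.0
    scale = np.where(constant, 1.0, scale)
    values = np.asfortranarray((F.values - center) / scale)
    return FeatureMatrix(
        values,
        F.feature_ids,
        F.kind,
        F.pair_index,
        F.snp_ids,
        center=center,
        scale=scale,
        constant_mask=constant,
    )


def back_transform(
    F: FeatureMatrix, intercept: float, feature_coefs: np.ndarray
) -> tuple[float, np.ndarray]:
    """Map coefficients fitted on the standardized design to the raw scale."""
    if not F.is_standardized:
        return intercept, feature_coefs
    raw = feature_coefs / F.scale
    b0 = intercept - float(np.sum(feature_coefs * F.center / F.scale))
    return b0, raw
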