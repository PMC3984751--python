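"""Genotype, phenotype and covariate I/O plus per-SNP quality control.

Genotypes are additively coded: each entry is the count (0, 1 or 2) of a
designated allele, with missing calls stored as NaN.  Two text dialects are
supported: PLINK ``--recode A`` output (``.raw``) and a plain delimited
matrix with a leading sample-id column.  QC follows standard GWAS practice:
minor-allele-frequency, call-rate and Hardy-Weinberg-equilibrium filters,
with an optional greedy variance-inflation-factor (VIF) pruning pass for
near-collinear markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "CovariateMatrix",
    "QCConfig",
    "GenotypeCodingError",
    "SampleAlignmentError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "read_covariates",
    "align_samples",
    "hwe_test",
    "qc_filter",
    "vif_prune",
    "mean_impute",
]

#: leading non-genotype columns of a PLINK additive-recode (.raw) file
_PLINK_RAW_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


class GenotypeCodingError(ValueError):
    """Raised when a genotype entry is numeric but not in {0, 1, 2}."""


class SampleAlignmentError(ValueError):
    """Raised when phenotype/covariate sample ids do not match the genotypes."""


@dataclass
class GenotypeMatrix:
    """An n-samples x m-SNPs additive genotype matrix.

    ``values`` is float so that missing calls can be carried as NaN; all
    non-missing entries are 0.0, 1.0 or 2.0.
    """

    values: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, m = self.values.shape
        if n < 1 or m < 2:
            raise ValueError(f"need n >= 1 samples and m >= 2 SNPs, got {n} x {m}")
        if len(self.snp_ids) != m or len(self.sample_ids) != n:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids must be unique")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise GenotypeCodingError(
                f"genotype entries must be 0/1/2 or missing, found {bad!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def minor_allele_freq(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls."""
        af = np.nanmean(self.values, axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.values).mean(axis=0)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_AA, n_Aa, n_aa) counts for SNP ``j`` over non-missing calls."""
        col = self.values[:, j]
        col = col[~np.isnan(col)]
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeMatrix(
            self.values[:, idx], [self.snp_ids[i] for i in idx], self.sample_ids
        )

    def subset_samples(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return GenotypeMatrix(
            self.values[rows], self.snp_ids, [self.sample_ids[i] for i in rows]
        )


@dataclass
class PhenotypeVector:
    """Binary case-control status: 1 = case, 0 = control."""

    y: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("phenotype values must be 0 (control) or 1 (case)")
        self.y = self.y.astype(np.int64)

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return int((self.y == 0).sum())

    def require_both_classes(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("need at least one case and one control")


@dataclass
class CovariateMatrix:
    """Numeric covariates (age, sex, pack-years, principal components, ...)."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if not self.names:
            self.names = [f"cov{i + 1}" for i in range(self.values.shape[1])]
        if np.isnan(self.values).any():
            raise ValueError("covariates must not contain missing values")

    @classmethod
    def empty(cls, n: int) -> "CovariateMatrix":
        return cls(np.zeros((n, 0)), [])

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]


@dataclass
class QCConfig:
    """Thresholds for per-SNP quality control.

    Defaults correspond to the usual GWAS screen: MAF >= 0.05, call rate
    >= 95% and an HWE exact-fit p-value floor of 1e-4.  ``vif_max`` enables
    the collinearity pruning pass when set (e.g. 2.0); it is off by default.
    """

    maf_min: float = 0.05
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-4
    vif_max: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not 0.0 < self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must lie in (0, 1]")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise ValueError("hwe_p_min must lie in [0, 1]")
        if self.vif_max is not None and self.vif_max <= 0:
            raise ValueError("vif_max must be positive")


# ---------------------------------------------------------------------------
# file I/O


def _check_entries(df: pd.DataFrame, path: str) -> np.ndarray:
    vals = df.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
    if bad.size:
        raise GenotypeCodingError(
            f"{path}: genotype entries must be 0/1/2 or missing, found {bad[0]!r}"
        )
    return vals


def read_genotypes(path, format: str = "delimited") -> GenotypeMatrix:
    """Read an additive genotype matrix from text.

    Parameters
    ----------
    path
        File path (or readable buffer) of the genotype table.
    format
        ``"plink_raw"`` for PLINK ``--recode A`` output (whitespace
        separated, six leading metadata columns, SNP columns named
        ``rsID_allele``) or ``"delimited"`` for a comma/tab table whose
        first column holds sample ids and whose header holds SNP ids.

    Missing genotypes (``NA`` or blank) are kept as NaN, never imputed here.
    """
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"], dtype=str)
        missing_meta = [c for c in _PLINK_RAW_META if c not in df.columns]
        if missing_meta:
            raise ValueError(f"{path}: not a PLINK .raw file, missing {missing_meta}")
        sample_ids = df["IID"].astype(str).tolist()
        geno = df.drop(columns=list(_PLINK_RAW_META))
        # allele suffix ("rs123_A" -> "rs123") stripped at the last underscore
        snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno.columns]
        values = _check_entries(geno.apply(pd.to_numeric), str(path))
    elif format == "delimited":
        df = pd.read_csv(path, sep=None, engine="python", na_values=["NA", ""])
        sample_ids = df.iloc[:, 0].astype(str).tolist()
        geno = df.iloc[:, 1:]
        snp_ids = [str(c) for c in geno.columns]
        values = _check_entries(geno, str(path))
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return GenotypeMatrix(values, snp_ids, sample_ids)


def write_genotypes(G: GenotypeMatrix, path, sep: str = "\t") -> None:
    """Write the delimited dialect read back by :func:`read_genotypes`."""
    df = pd.DataFrame(G.values, columns=G.snp_ids)
    # keep integer appearance for non-missing entries
    df = df.astype("Int64")
    df.insert(0, "sample_id", G.sample_ids)
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_phenotype(path) -> PhenotypeVector:
    """Read a two-column (sample_id, y) delimited phenotype file."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: phenotype file needs (sample_id, y) columns")
    return PhenotypeVector(
        df.iloc[:, 1].to_numpy(), sample_ids=df.iloc[:, 0].astype(str).tolist()
    )


def read_covariates(path) -> CovariateMatrix:
    """Read a delimited covariate table with a leading sample-id column."""
    df = pd.read_csv(path, sep=None, engine="python")
    return CovariateMatrix(
        df.iloc[:, 1:].to_numpy(dtype=float),
        [str(c) for c in df.columns[1:]],
        sample_ids=df.iloc[:, 0].astype(str).tolist(),
    )


def align_samples(
    G: GenotypeMatrix,
    pheno: PhenotypeVector,
    cov: CovariateMatrix | None = None,
) -> tuple[PhenotypeVector, CovariateMatrix]:
    """Reorder phenotype (and covariates) to the genotype sample order.

    Alignment is by sample_id join; any id mismatch is an error rather than
    a silent reorder or drop.
    """
    if pheno.sample_ids is None:
        if len(pheno.y) != G.n_samples:
            raise SampleAlignmentError("phenotype length does not match genotypes")
        y_al = pheno
    else:
        pos = {s: i for i, s in enumerate(pheno.sample_ids)}
        missing = [s for s in G.sample_ids if s not in pos]
        if missing or len(pos) != G.n_samples:
            raise SampleAlignmentError(
                f"phenotype sample ids do not match genotypes (e.g. {missing[:3]})"
            )
        order = [pos[s] for s in G.sample_ids]
        y_al = PhenotypeVector(pheno.y[order], sample_ids=list(G.sample_ids))
    if cov is None:
        return y_al, CovariateMatrix.empty(G.n_samples)
    if cov.sample_ids is None:
        if cov.values.shape[0] != G.n_samples:
            raise SampleAlignmentError("covariate rows do not match genotypes")
        return y_al, cov
    pos = {s: i for i, s in enumerate(cov.sample_ids)}
    missing = [s for s in G.sample_ids if s not in pos]
    if missing or len(pos) != G.n_samples:
        raise SampleAlignmentError(
            f"covariate sample ids do not match genotypes (e.g. {missing[:3]})"
        )
    order = [pos[s] for s in G.sample_ids]
    return y_al, CovariateMatrix(
        cov.values[order], cov.names, sample_ids=list(G.sample_ids)
    )


# ---------------------------------------------------------------------------
# quality control


def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """1-df chi-square goodness-of-fit test for Hardy-Weinberg equilibrium.

    Compares observed (AA, Aa, aa) counts against the expected proportions
    (p^2, 2pq, q^2) at the observed allele frequency.  Monomorphic SNPs
    (one allele absent) return p = 1 by convention.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    G: GenotypeMatrix, config: QCConfig | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply call-rate, MAF and HWE filters, returning (kept, report).

    The report lists each removed SNP with the first failing rule (rules
    checked in the order call_rate, maf, hwe) and the offending statistic.
    """
    config = config or QCConfig()
    call = G.call_rate()
    maf = G.minor_allele_freq()
    removed: list[tuple[str, str, float]] = []
    keep = np.ones(G.n_snps, dtype=bool)
    for j in range(G.n_snps):
        if call[j] < config.call_rate_min:
            removed.append((G.snp_ids[j], "call_rate", call[j]))
            keep[j] = False
            continue
        if np.isnan(maf[j]) or maf[j] < config.maf_min:
            removed.append((G.snp_ids[j], "maf", maf[j]))
            keep[j] = False
            continue
        p_hwe = hwe_test(G.genotype_counts(j))
        if p_hwe < config.hwe_p_min:
            removed.append((G.snp_ids[j], "hwe", p_hwe))
            keep[j] = False
    report = pd.DataFrame(removed, columns=["snp_id", "reason", "statistic"])
    if keep.sum() == 0:
        raise ValueError("QC removed every SNP; relax the thresholds")
    if keep.all():
        return G, report
    kept = GenotypeMatrix(
        G.values[:, keep],
        [s for s, k in zip(G.snp_ids, keep) if k],
        G.sample_ids,
    )
    return kept, report


def mean_impute(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the per-SNP mean genotype.

    Returns a new matrix whose values are no longer restricted to {0,1,2};
    downstream feature expansion accepts the fractional dosages.
    """
    vals = G.values.copy()
    if np.isnan(vals).any():
        col_mean = np.nanmean(vals, axis=0)
        idx = np.where(np.isnan(vals))
        vals[idx] = col_mean[idx[1]]
    out = object.__new__(GenotypeMatrix)
    out.values = vals
    out.snp_ids = list(G.snp_ids)
    out.sample_ids = list(G.sample_ids)
    return out


def _vif_all(X: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """VIF of every column from the inverse correlation matrix."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = Xc / sd
    R = (Xs.T @ Xs) / Xs.shape[0]
    R = R + ridge * np.eye(R.shape[0])
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        Rinv = np.linalg.inv(R + 1e-8 * np.eye(R.shape[0]))
    return np.diag(Rinv).copy()


def vif_prune(
    G: GenotypeMatrix, vif_max: float = 2.0
) -> tuple[GenotypeMatrix, list[str]]:
    """Greedily drop SNPs whose variance inflation factor exceeds ``vif_max``.

    At each pass the SNP with the largest VIF (ties broken by column order)
    is removed until all remaining VIFs are within bound.  When n <= m the
    full regression is ill-posed, so the VIFs are computed on a
    ridge-stabilized correlation matrix.
    """
    work = mean_impute(G)
    X = work.values
    n, m = X.shape
    ridge = 0.0 if n > m else 1e-6
    active = list(range(m))
    removed: list[str] = []
    while len(active) >= 2:
        vifs = _vif_all(X[:, active], ridge=ridge)
        worst = int(np.argmax(vifs))
        if vifs[worst] <= vif_max:
            break
        removed.append(G.snp_ids[active[worst]])
        del active[worst]
    keep_idx = np.array(active, dtype=int)
    kept = GenotypeMatrix(
        G.values[:, keep_idx], [G.snp_ids[i] for i in active], G.sample_ids
    )
    return kept, removed


def write_qc_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
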