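"""Linkage-disequilibrium and statistic correlation matrices.

Constructors for the correlation matrices the gene-level tests consume:
sample LD from 0/1/2 genotype dosages, LD from haplotype frequencies,
covariate (Schur-complement) adjustment, equicorrelation and perturbed
equicorrelation scaffolds for simulation, random positive-definite
correlation matrices, and reference-panel resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationMatrix",
    "HaplotypeTable",
    "nearest_pd_correlation",
    "ld_from_genotypes",
    "ld_from_haplotypes",
    "covariate_adjusted_correlation",
    "equicorrelation",
    "perturbed_equicorrelation",
    "random_pd_correlation",
    "sample_panel_ld",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_genotypes",
    "read_haplotypes",
]

#: relative eigenvalue floor below which a matrix is treated as singular
PD_EIGENVALUE_FLOOR = 1e-10

#: relative eigenvalue floor used when repairing an indefinite matrix;
#: matches the default tolerance of R's Matrix::nearPD and keeps repaired
#: matrices clear of the singularity floor after re-standardization
REPAIR_EIGENVALUE_TOL = 1e-6


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal positive-definite correlation matrix.

    Parameters
    ----------
    values : (L, L) ndarray
        Correlations; symmetric, unit diagonal, off-diagonals in [-1, 1].
    labels : list of str, optional
        SNP identifiers, one per row/column.
    rank_deficient : bool
        Set by :func:`sample_panel_ld` when the panel sample size did not
        exceed the number of SNPs, so the raw estimate was singular.
    """

    values: np.ndarray
    labels: list[str] | None = None
    rank_deficient: bool = field(default=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("correlation matrix must be square")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("labels length does not match matrix dimension")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    def validate(self, require_pd: bool = True) -> None:
        """Raise ValueError if any invariant is violated."""
        v = self.values
        if not np.allclose(v, v.T, atol=1e-12, rtol=0):
            raise ValueError("matrix is not symmetric (tolerance 1e-12)")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12, rtol=0):
            raise ValueError("diagonal is not unit")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal correlations outside [-1, 1]")
        if require_pd:
            w = np.linalg.eigvalsh(v)
            if w.min() <= PD_EIGENVALUE_FLOOR * max(w.max(), 1.0):
                raise ValueError("matrix is not positive definite")

    def restrict(self, which) -> "CorrelationMatrix":
        """Submatrix for the given labels (if strings) or integer indices."""
        if len(which) and isinstance(which[0], str):
            if self.labels is None:
                raise ValueError("matrix has no labels to restrict by")
            lookup = {lab: i for i, lab in enumerate(self.labels)}
            idx = [lookup[w] for w in which]
        else:
            idx = list(which)
        sub = self.values[np.ix_(idx, idx)]
        labs = [self.labels[i] for i in idx] if self.labels is not None else None
        return CorrelationMatrix(sub, labs)


def _standardize(cov: np.ndarray) -> np.ndarray:
    d = 1.0 / np.sqrt(np.diag(cov))
    out = cov * d[:, None] * d[None, :]
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


def nearest_pd_correlation(values: np.ndarray, labels=None) -> CorrelationMatrix:
    """Repair a symmetric matrix into a valid correlation matrix.

    Eigenvalues below ``REPAIR_EIGENVALUE_TOL`` times the largest are
    clipped to that floor, the matrix is reconstructed and re-standardized
    to unit diagonal.  Deterministic, and the identity on matrices already
    valid.
    """
    a = np.asarray(values, dtype=float)
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    floor = REPAIR_EIGENVALUE_TOL * max(w.max(), 1e-300)
    if w.min() < floor:
        w = np.clip(w, floor, None)
        a = (v * w) @ v.T
    return CorrelationMatrix(_standardize(a), labels)


def ld_from_genotypes(genotypes, labels=None) -> CorrelationMatrix:
    """Sample LD matrix: Pearson correlation of 0/1/2 dosage columns.

    Missing entries are rejected — imputation is the caller's duty, since a
    correlation computed over incomplete genotypes no longer reflects the
    sample correlation among the predictors.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotype matrix must be 2-dimensional (individuals x SNPs)")
    if g.shape[0] < 2:
        raise ValueError("at least two individuals are required")
    if labels is None and isinstance(genotypes, pd.DataFrame):
        labels = list(genotypes.columns)
    names = labels if labels is not None else [f"snp{i}" for i in range(g.shape[1])]
    if np.isnan(g).any():
        bad = [names[j] for j in np.where(np.isnan(g).any(axis=0))[0]]
        raise ValueError(f"missing genotypes in SNP(s) {bad}; impute upstream")
    sd = g.std(axis=0)
    if np.any(sd == 0):
        bad = [names[j] for j in np.where(sd == 0)[0]]
        raise ValueError(f"constant genotype column(s): {bad}")
    r = np.corrcoef(g, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix((r + r.T) / 2.0, labels)


@dataclass
class HaplotypeTable:
    """Haplotype frequency table over L biallelic SNPs.

    ``haplotypes`` are strings over {0, 1} with 1 coding the minor allele;
    ``frequencies`` are nonnegative and sum to one.
    """

    haplotypes: list[str]
    frequencies: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.haplotypes) != self.frequencies.size:
            raise ValueError("one frequency per haplotype is required")
        if np.any(self.frequencies < 0):
            raise ValueError("haplotype frequencies must be nonnegative")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1 (tolerance 1e-9)")
        lengths = {len(h) for h in self.haplotypes}
        if len(lengths) != 1:
            raise ValueError("all haplotype strings must have equal length")
        if not all(set(h) <= {"0", "1"} for h in self.haplotypes):
            raise ValueError("haplotypes must be strings over {0, 1}")

    @property
    def n_snps(self) -> int:
        return len(self.haplotypes[0])


def ld_from_haplotypes(table: HaplotypeTable) -> CorrelationMatrix:
    """LD correlations from haplotype frequencies.

    D_ij = P_ij - p_i p_j with P_ij the di-locus frequency (haplotypes
    carrying both minor alleles) and p_i the minor-allele frequency;
    r_ij = D_ij / sqrt(p_i(1-p_i) p_j(1-p_j)).
    """
    carries = np.array([[c == "1" for c in h] for h in table.haplotypes], dtype=float)
    f = table.frequencies
    p = f @ carries                      # minor-allele frequencies
    if np.any(p <= 0) or np.any(p >= 1):
        bad = np.where((p <= 0) | (p >= 1))[0].tolist()
        raise ValueError(f"monomorphic SNP(s) at position(s) {bad}")
    pij = (carries * f[:, None]).T @ carries   # di-locus frequencies
    d = pij - np.outer(p, p)
    denom = np.sqrt(np.outer(p * (1 - p), p * (1 - p)))
    r = d / denom
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix((r + r.T) / 2.0, table.labels)


def covariate_adjusted_correlation(full: CorrelationMatrix, snp_indices) -> CorrelationMatrix:
    """Correlation among SNP statistics adjusted for covariates.

    Invert the full predictor correlation matrix (SNPs + covariates),
    select the SNP submatrix of the inverse, invert it back and standardize
    to correlation — the Schur complement of the covariate block.
    """
    a = np.asarray(full, dtype=float)
    idx = list(snp_indices)
    if len(set(idx)) != len(idx):
        raise ValueError("snp_indices must be distinct")
    try:
        prec = np.linalg.inv(a)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "full predictor matrix is singular; consider a ridge repair "
            "(add a small multiple of the identity) before adjusting"
        ) from exc
    sub = prec[np.ix_(idx, idx)]
    cov = np.linalg.inv(sub)
    labels = None
    if isinstance(full, CorrelationMatrix) and full.labels is not None:
        labels = [full.labels[i] for i in idx]
    return CorrelationMatrix(_standardize(cov), labels)


def equicorrelation(L: int, rho: float, labels=None) -> CorrelationMatrix:
    """Equicorrelation matrix (1-rho) I + rho 11'.

    Positive definite for -1/(L-1) < rho < 1, with eigenvalues
    1 + rho(L-1) (once) and 1 - rho (L-1 times).
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    lo = -1.0 / (L - 1) if L > 1 else -1.0
    if not (lo < rho < 1.0):
        raise ValueError(f"rho must lie in ({lo}, 1) for positive definiteness")
    r = np.full((L, L), float(rho))
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, labels)


def perturbed_equicorrelation(L, rho, u_low, u_high, seed=None) -> CorrelationMatrix:
    """Rank-one perturbation of the equicorrelation matrix.

    B = R_rho + U U' with U i.i.d. uniform(u_low, u_high), standardized
    back to unit diagonal.  The perturbation keeps the matrix positive
    definite while spreading the pairwise correlations.
    """
    if u_low > u_high:
        raise ValueError("u_low must not exceed u_high")
    base = equicorrelation(L, rho).values
    rng = np.random.default_rng(seed)
    u = rng.uniform(u_low, u_high, size=L)
    b = base + np.outer(u, u)
    return CorrelationMatrix(_standardize(b))


def random_pd_correlation(L: int, seed=None) -> CorrelationMatrix:
    """Random positive-definite correlation matrix.

    A symmetric matrix of uniform(-1, 1) entries with unit diagonal is
    repaired to the nearest valid correlation matrix by eigenvalue
    clipping and re-standardization.
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1.0, 1.0, size=(L, L))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return nearest_pd_correlation(a)


def sample_panel_ld(population: CorrelationMatrix, n_panel: int, seed=None) -> CorrelationMatrix:
    """Reference-panel LD estimate: sample correlation of n_panel draws.

    Draws Gaussian genotype surrogates from MVN(0, population) and returns
    their sample correlation matrix — the estimate an external panel of
    that size would deliver.  If n_panel <= L the raw estimate is singular;
    it is PD-repaired and flagged ``rank_deficient`` for callers.
    """
    pop = np.asarray(population, dtype=float)
    L = pop.shape[0]
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(pop)
    draws = rng.standard_normal((n_panel, L)) @ chol.T
    est = np.corrcoef(draws, rowvar=False)
    labels = population.labels if isinstance(population, CorrelationMatrix) else None
    if n_panel <= L:
        warnings.warn(
            f"panel size {n_panel} <= number of SNPs {L}: singular LD estimate, "
            "PD-repaired", RuntimeWarning)
        out = nearest_pd_correlation(est, labels)
        out.rank_deficient = True
        return out
    return CorrelationMatrix(_standardize(est), labels)


# ---------------------------------------------------------------------------
# plain-text file formats

def write_ld_matrix(path, matrix: CorrelationMatrix) -> None:
    """Write a square LD matrix as whitespace-delimited text.

    10 significant digits; optional header row of SNP ids when labels are
    present.  Round-trips exactly with :func:`read_ld_matrix` in decimal
    text.
    """
    with open(path, "w") as fh:
        if matrix.labels is not None:
            fh.write("\t".join(matrix.labels) + "\n")
        for row in matrix.values:
            fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def read_ld_matrix(path) -> CorrelationMatrix:
    """Read a square numeric LD matrix, optional header row of SNP ids."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    labels = None
    first = lines[0].split()
    try:
        [float(x) for x in first]
    except ValueError:
        labels = first
        lines = lines[1:]
    values = np.array([[float(x) for x in ln.split()] for ln in lines])
    values = (values + values.T) / 2.0
    return CorrelationMatrix(values, labels)


def read_genotypes(path) -> pd.DataFrame:
    """Read a genotype dosage TSV (rows = individuals, header of SNP ids)."""
    df = pd.read_csv(path, sep="\t")
    bad = ~df.isin([0, 1, 2]).all(axis=0)
    if bad.any():
        raise ValueError(f"non-0/1/2 entries in column(s): {list(df.columns[bad])}")
    return df


def read_haplotypes(path) -> HaplotypeTable:
    """Read a haplotype TSV with columns ``haplotype`` and ``frequency``."""
    df = pd.read_csv(path, sep="\t", dtype={"haplotype": str})
    return HaplotypeTable(list(df["haplotype"]), df["frequency"].to_numpy())
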