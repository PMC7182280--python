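"""Gene-level combination tests on correlated summary statistics.

DOT decorrelates the Z-score vector with the symmetric inverse square root
of the correlation matrix and sums squares (central chi-square null with L
degrees of freedom); TQ sums raw squares (weighted chi-square mixture
null); ACAT averages Cauchy-transformed P-values; min-P is a Bonferroni
bound; RTP combines the k smallest decorrelated P-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._quadform import mixture_tail, null_quantile
from .ld import PD_EIGENVALUE_FLOOR, CorrelationMatrix

__all__ = [
    "StatVector",
    "TransformMatrix",
    "TestResult",
    "decorrelation_transform",
    "pvalues_to_z",
    "dot_test",
    "tq_test",
    "quadform_tail",
    "acat_test",
    "minp_test",
    "rtp_decorrelated",
]


@dataclass
class StatVector:
    """Per-SNP association Z-scores with optional ids and weights."""

    z: np.ndarray
    ids: list[str] | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if not np.all(np.isfinite(self.z)):
            raise ValueError("Z-scores must be finite")
        if self.ids is not None and len(self.ids) != self.z.size:
            raise ValueError("ids length does not match z")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.size != self.z.size:
                raise ValueError("weights length does not match z")
            if np.any(self.weights < 0) or not np.any(self.weights > 0):
                raise ValueError("weights must be nonnegative and not all zero")

    def __len__(self):
        return self.z.size


@dataclass
class TransformMatrix:
    """Decorrelating transform H = E diag(1/sqrt(lambda)) E'.

    ``eigenvalues`` are sorted descending; columns of ``eigenvectors`` are
    the matching orthonormal eigenvectors of the source correlation matrix.
    H is the unique symmetric inverse square root, so H R H = I and the
    transform is invariant to the ordering of the input variables.
    """

    H: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class TestResult:
    """Outcome of one combination test."""

    method: str
    statistic: float
    p_value: float
    df_or_mixture: object = None
    decorrelated: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _as_z(z) -> StatVector:
    return z if isinstance(z, StatVector) else StatVector(np.asarray(z, dtype=float))


def _eigh_sorted(R: np.ndarray):
    w, v = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    # fix eigenvector signs: largest-magnitude entry positive
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return w, v * signs


def decorrelation_transform(R) -> TransformMatrix:
    """Symmetric inverse square root of a positive-definite correlation matrix.

    Of the many transforms that whiten a correlated Gaussian vector, only
    the symmetric root H = E diag(1/sqrt(lambda)) E' leaves the multiset of
    decorrelated values unchanged under a permutation of exchangeable
    inputs ("invariance to order"); Cholesky and plain eigenvector
    whitening do not.
    """
    Rv = np.asarray(R, dtype=float)
    w, v = _eigh_sorted(Rv)
    if w[-1] <= PD_EIGENVALUE_FLOOR * max(w[0], 1.0):
        raise ValueError(
            "correlation matrix is numerically singular; apply a PD repair "
            "(e.g. ld.nearest_pd_correlation) before decorrelating")
    H = (v / np.sqrt(w)) @ v.T
    return TransformMatrix((H + H.T) / 2.0, w, v)


def pvalues_to_z(p, signs=None) -> StatVector:
    """Convert P-values to normal scores.

    Without signs, Z_i is the square root of the one-df chi-square upper
    quantile at p_i (two-sided magnitude); with signs, the magnitude is
    given the stated direction.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(p <= 0):
        raise ValueError("p = 0 maps to an infinite score; clamp upstream")
    if np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    z = np.sqrt(stats.chi2.isf(p, 1))
    if signs is not None:
        signs = np.asarray(signs, dtype=float)
        if signs.shape != p.shape:
            raise ValueError("signs length does not match p")
        z = np.sign(signs) * z
    return StatVector(z)


def dot_test(z, R) -> TestResult:
    """Decorrelation by orthogonal transformation.

    X = H z with H the symmetric inverse square root of R; the statistic
    sum X_i^2 equals z' R^{-1} z and is central chi-square with L degrees
    of freedom under the null.  The decorrelated vector is stored for
    contributor analysis.
    """
    sv = _as_z(z)
    transform = R if isinstance(R, TransformMatrix) else decorrelation_transform(R)
    if transform.H.shape[0] != len(sv):
        raise ValueError("dimension mismatch between z and R")
    x = transform.H @ sv.z
    statistic = float(x @ x)
    p = float(stats.chi2.sf(statistic, len(sv)))
    return TestResult("dot", statistic, p, df_or_mixture=len(sv), decorrelated=x)


def tq_test(z, R, pvalue="analytic", n_null=10**5, seed=None) -> TestResult:
    """Sum of squared Z-scores (VEGAS-style quadratic form).

    The null distribution is the weighted sum of independent one-df
    chi-squares with weights equal to the eigenvalues of R (of the weighted
    covariance diag(sqrt(w)) R diag(sqrt(w)) when per-SNP weights are
    given, absorbing Y_i^2 = w_i Z_i^2).  ``pvalue="analytic"`` inverts
    that distribution numerically; ``pvalue="empirical"`` simulates
    ``n_null`` zero-mean MVN vectors and reports the add-one-corrected
    exceedance proportion, as reference-panel web services do.  The two
    agree within Monte-Carlo error.
    """
    sv = _as_z(z)
    Rv = np.asarray(R, dtype=float)
    if Rv.shape[0] != len(sv):
        raise ValueError("dimension mismatch between z and R")
    y = sv.z
    if sv.weights is not None:
        rw = np.sqrt(sv.weights)
        y = rw * y
        Rv = Rv * np.outer(rw, rw)
    statistic = float(y @ y)
    lam = np.linalg.eigvalsh(Rv)
    lam = lam[lam > PD_EIGENVALUE_FLOOR * max(lam.max(), 1.0)]
    if pvalue == "analytic":
        p = quadform_tail(lam, np.zeros_like(lam), statistic)
    elif pvalue == "empirical":
        rng = np.random.default_rng(seed)
        exceed = 0
        chunk = max(1, min(n_null, 10**7 // max(lam.size, 1)))
        done = 0
        while done < n_null:
            m = min(chunk, n_null - done)
            null_stats = (lam * rng.chisquare(1.0, size=(m, lam.size))).sum(axis=1)
            exceed += int(np.sum(null_stats >= statistic))
            done += m
        p = (exceed + 1.0) / (n_null + 1.0)
    else:
        raise ValueError("pvalue must be 'analytic' or 'empirical'")
    return TestResult("tq", statistic, p, df_or_mixture=lam)


def quadform_tail(lambdas, gammas, t, dfs=None) -> float:
    """P(sum lambda_i chi2(1, gamma_i) > t), absolute accuracy 1e-9.

    Numerical characteristic-function inversion (Imhof), with a
    high-replicate Monte-Carlo fallback on non-convergence.  ``dfs``
    allows grouped components (e.g. the two-eigenvalue equicorrelation
    reduction).
    """
    return mixture_tail(lambdas, gammas, t, dfs=dfs, epsabs=1e-9)


def acat_test(p, weights=None) -> TestResult:
    """Aggregated Cauchy association test.

    P-values are mapped to standard Cauchy variates tan((0.5 - p) pi),
    averaged with the given weights (equal by default), and the average is
    referred back to the standard Cauchy upper tail.  Valid under
    correlation because the Cauchy has no moments.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("degenerate p-values clamped to [1e-300, 1 - 1e-16]", RuntimeWarning)
        p = np.clip(p, 1e-300, 1 - 1e-16)
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    statistic = float(np.sum(w * np.tan((0.5 - p) * np.pi)))
    return TestResult("acat", statistic, float(stats.cauchy.sf(statistic)))


def minp_test(p) -> TestResult:
    """Bonferroni-style minimum-P test: p = min(1, L * min(p))."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = float(p.min())
    return TestResult("minp", m, min(1.0, p.size * m))


def rtp_decorrelated(z, R, k, n_null=10**5, seed=None) -> TestResult:
    """Rank truncated product on decorrelated statistics.

    The Z-vector is decorrelated with H, each X_i^2 converted to a one-df
    P-value, and the statistic is the sum of -ln of the k smallest.  The
    null distribution (k smallest of L independent uniforms) has no simple
    closed form, so the P-value is the Monte-Carlo exceedance proportion
    with add-one correction (r + 1)/(n_null + 1).
    """
    sv = _as_z(z)
    L = len(sv)
    if not 1 <= k <= L:
        raise ValueError(f"k must lie in [1, {L}]")
    if n_null < 10**4:
        raise ValueError("n_null must be at least 10^4")
    transform = R if isinstance(R, TransformMatrix) else decorrelation_transform(R)
    x = transform.H @ sv.z
    p1 = stats.chi2.sf(x**2, 1)
    observed = float(np.sum(-np.log(np.sort(p1)[:k])))
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_null, 10**7 // max(L, 1)))
    done = 0
    while done < n_null:
        m = min(chunk, n_null - done)
        u = rng.uniform(size=(m, L))
        u.sort(axis=1)
        stat_null = -np.log(u[:, :k]).sum(axis=1)
        exceed += int(np.sum(stat_null >= observed))
        done += m
    p = (exceed + 1.0) / (n_null + 1.0)
    return TestResult("rtp", observed, p, df_or_mixture=k, decorrelated=x)
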