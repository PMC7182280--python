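"""Alternative-hypothesis distribution theory and analytic power.

Given marginal regression effect sizes beta, predictor correlations Sigma
and sample size N, the vector of per-SNP association statistics is
asymptotically MVN(mu, R) with mu_j = sqrt(N) b_j, b_j = cor(y, SNP_j) =
Sigma_j beta / sqrt(beta' Sigma beta + 1), and R the delta-method
correlation of the sample correlations sharing the outcome.  The DOT
statistic is then noncentral chi-square with L degrees of freedom and
noncentrality gamma_c = mu' R^{-1} mu, while TQ follows a weighted mixture
of noncentral one-df chi-squares.  Closed forms for the equicorrelation
case (via the Helmert basis) and one-df approximations to TQ are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._quadform import mixture_tail, null_quantile
from .ld import CorrelationMatrix, equicorrelation, nearest_pd_correlation

__all__ = [
    "EffectModel",
    "AltParams",
    "MixtureSpec",
    "PowerEstimate",
    "binary_attenuation",
    "standardized_effect_correlations",
    "noncentrality_from_effects",
    "alt_statistic_correlation",
    "alt_params",
    "tq_alt_mixture",
    "dot_power",
    "tq_power",
    "equicorr_noncentralities",
    "tq_equicorr_power",
    "tq_onedf_null_approx",
    "tq_onedf_power",
    "tq_power_approx",
    "tq_ceiling_noncentrality",
    "tq_asymptotic_power",
    "rms_correlation",
]


@dataclass
class EffectModel:
    """Trait model y = beta0 + sum_j beta_j SNP_j + eps, eps ~ N(0, 1).

    ``trait`` is ``continuous`` or ``binary``; a binary trait arises by
    thresholding the liability at ``threshold``, which attenuates the
    noncentralities by d = phi(l)/sqrt(Phi(l)(1 - Phi(l))).
    """

    beta: np.ndarray
    sigma: CorrelationMatrix | np.ndarray
    n: int
    trait: str = "continuous"
    threshold: float | None = None

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        sig = np.asarray(self.sigma, dtype=float)
        if sig.shape[0] != self.beta.size:
            raise ValueError("sigma dimension does not match beta")
        if self.n < 1:
            raise ValueError("sample size must be at least 1")
        if self.trait not in ("continuous", "binary"):
            raise ValueError("trait must be 'continuous' or 'binary'")
        if self.trait == "binary" and self.threshold is None:
            raise ValueError("binary trait requires a liability threshold")

    @property
    def L(self) -> int:
        return self.beta.size


@dataclass
class AltParams:
    """Mean vector and correlation of statistics under the alternative."""

    mu: np.ndarray
    r_alt: CorrelationMatrix


@dataclass
class MixtureSpec:
    """Weighted noncentral chi-square mixture sum lambda_i chi2(df_i, gamma_i)."""

    lambdas: np.ndarray
    gammas: np.ndarray
    dfs: np.ndarray | None = None
    helmert_deltas: np.ndarray | None = None
    delta_s: float | None = None
    gamma_c: float = 0.0


@dataclass
class PowerEstimate:
    method: str
    alpha: float
    power: float
    mode: str = "exact"          # exact | approx | asymptotic | empirical
    mc_se: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power outside [0, 1]")
        if (self.mode == "empirical") != (self.mc_se is not None):
            raise ValueError("mc_se present iff mode is 'empirical'")


def binary_attenuation(threshold: float) -> float:
    """Attenuation d = phi(l) / sqrt(Phi(l) (1 - Phi(l))) of a thresholded liability."""
    l = float(threshold)
    return float(stats.norm.pdf(l) / np.sqrt(stats.norm.cdf(l) * stats.norm.sf(l)))


def standardized_effect_correlations(model: EffectModel) -> np.ndarray:
    """b_j = cor(y, SNP_j) = Sigma_j beta / sqrt(beta' Sigma beta + 1)."""
    sig = np.asarray(model.sigma, dtype=float)
    denom = float(model.beta @ sig @ model.beta) + 1.0
    if denom <= 0:
        raise ValueError("beta' Sigma beta + 1 must be positive")
    return (sig @ model.beta) / np.sqrt(denom)


def noncentrality_from_effects(model: EffectModel) -> np.ndarray:
    """Noncentral means mu_j = sqrt(N) b_j (times d for a binary trait)."""
    b = standardized_effect_correlations(model)
    mu = np.sqrt(model.n) * b
    if model.trait == "binary":
        mu = mu * binary_attenuation(model.threshold)
    return mu


def alt_statistic_correlation(model: EffectModel) -> CorrelationMatrix:
    """Correlation among association statistics under the alternative.

    Delta-method (Olkin-Siotani) covariance of two sample correlations
    r(y, SNP_i), r(y, SNP_j) sharing the outcome, standardized to
    correlation:

        R_ij = [sigma_ij (1 - b_i^2 - b_j^2)
                - b_i b_j (1 - b_i^2 - b_j^2 - sigma_ij^2) / 2]
               / [(1 - b_i^2)(1 - b_j^2)]

    Reduces to Sigma when beta = 0; the -b_i b_j term correlates the
    statistics of associated SNPs even with no LD between them.
    """
    sig = np.asarray(model.sigma, dtype=float)
    b = standardized_effect_correlations(model)
    if np.any(np.abs(b) >= 1):
        raise ValueError("standardized correlations must satisfy |b| < 1")
    bi2 = b[:, None] ** 2
    bj2 = b[None, :] ** 2
    bb = np.outer(b, b)
    num = sig * (1 - bi2 - bj2) - 0.5 * bb * (1 - bi2 - bj2 - sig**2)
    den = (1 - bi2) * (1 - bj2)
    r = num / den
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    w = np.linalg.eigvalsh(r)
    if w.min() <= 0:
        warnings.warn("alternative correlation not PD; applying nearest-PD repair",
                      RuntimeWarning)
        return nearest_pd_correlation(r)
    labels = model.sigma.labels if isinstance(model.sigma, CorrelationMatrix) else None
    return CorrelationMatrix(r, labels)


def alt_params(model: EffectModel) -> AltParams:
    """Joint MVN parameters (mu, R) of the statistics under the alternative."""
    return AltParams(noncentrality_from_effects(model), alt_statistic_correlation(model))


def tq_alt_mixture(mu, R) -> MixtureSpec:
    """Eigen-decomposed alternative distribution of TQ.

    lambda = eigenvalues of R (descending); gamma_i = (E_i' mu)^2 /
    lambda_i, so that sum gamma_i = mu' R^{-1} mu = gamma_c.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    Rv = np.asarray(R, dtype=float)
    w, v = np.linalg.eigh(Rv)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if w[-1] <= 0:
        raise ValueError("R must be positive definite")
    proj = v.T @ mu
    gammas = proj**2 / w
    return MixtureSpec(lambdas=w, gammas=gammas, gamma_c=float(gammas.sum()))


def dot_power(mu, R, alpha: float) -> PowerEstimate:
    """Exact DOT power: noncentral chi-square(L, mu' R^{-1} mu) upper tail
    at the central chi-square(L) 1 - alpha quantile."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    Rv = np.asarray(R, dtype=float)
    gamma_c = float(mu @ np.linalg.solve(Rv, mu))
    L = mu.size
    crit = stats.chi2.isf(alpha, L)
    power = float(stats.ncx2.sf(crit, L, gamma_c)) if gamma_c > 0 else float(alpha)
    return PowerEstimate("dot", alpha, power, mode="exact")


def tq_power(mu, R, alpha: float) -> PowerEstimate:
    """Exact TQ power from the weighted noncentral chi-square mixture.

    The null 1 - alpha quantile of sum lambda_i chi2_1 is root-found to
    1e-9; power is the alternative mixture's upper tail there.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    spec = tq_alt_mixture(mu, R)
    q = null_quantile(spec.lambdas, alpha)
    power = mixture_tail(spec.lambdas, spec.gammas, q, epsabs=1e-9)
    return PowerEstimate("tq", alpha, float(power), mode="exact")


def _pairwise_mean_sq_diff(mu: np.ndarray) -> float:
    # mean over pairs i<j of (mu_i - mu_j)^2 equals 2 * SS / (L - 1)
    L = mu.size
    if L < 2:
        return 0.0
    ss = float(np.sum((mu - mu.mean()) ** 2))
    return 2.0 * ss / (L - 1)


def equicorr_noncentralities(mu, rho: float) -> MixtureSpec:
    """Helmert closed-form DOT noncentralities under equicorrelation.

    delta_1 = L mubar^2 / (1 + (L-1) rho); the remaining Helmert contrasts
    give delta_j = (v_j' mu)^2 / (1 - rho) summing to delta_s =
    (L-1) dbar / (2 (1-rho)) with dbar the mean pairwise squared
    difference of the means; gamma_c = delta_1 + delta_s = mu' R^{-1} mu.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    L = mu.size
    lo = -1.0 / (L - 1) if L > 1 else -1.0
    if not (lo < rho < 1.0):
        raise ValueError("rho outside the positive-definite range")
    lam1 = 1.0 + (L - 1) * rho
    lam2 = 1.0 - rho
    delta1 = L * mu.mean() ** 2 / lam1
    deltas = [delta1]
    for j in range(2, L + 1):
        v = np.zeros(L)
        v[: j - 1] = 1.0
        v[j - 1] = -(j - 1)
        v /= np.sqrt(j * (j - 1))
        deltas.append(float((v @ mu) ** 2) / lam2)
    deltas = np.array(deltas)
    delta_s = (L - 1) * _pairwise_mean_sq_diff(mu) / (2.0 * lam2) if L > 1 else 0.0
    gamma_c = delta1 + delta_s
    lambdas = np.array([lam1, lam2]) if L > 1 else np.array([1.0])
    gammas = np.array([delta1, delta_s]) if L > 1 else np.array([delta1])
    dfs = np.array([1.0, L - 1.0]) if L > 1 else np.array([1.0])
    return MixtureSpec(lambdas=lambdas, gammas=gammas, dfs=dfs,
                       helmert_deltas=deltas, delta_s=float(delta_s),
                       gamma_c=float(gamma_c))


def tq_equicorr_power(mu, rho: float, alpha: float) -> PowerEstimate:
    """Exact TQ power via the two-distinct-eigenvalue reduction.

    Under equicorrelation the mixture collapses to
    (1+(L-1)rho) chi2(1, delta_1) + (1-rho) chi2(L-1, delta_s).
    """
    spec = equicorr_noncentralities(mu, rho)
    q = null_quantile(spec.lambdas, alpha, dfs=spec.dfs)
    power = mixture_tail(spec.lambdas, spec.gammas, q, dfs=spec.dfs, epsabs=1e-9)
    return PowerEstimate("tq", alpha, float(power), mode="exact")


def tq_onedf_null_approx(L: int, rho_star: float, tq_value: float, alpha: float):
    """Location-scale one-df chi-square approximation to the TQ null.

    The statistic (TQ - (L-1)(1-rho*)) / ((L-1) rho* + 1) is referred to a
    one-df chi-square; returns (approximate p-value, reject-at-alpha).
    """
    if L < 2:
        raise ValueError("L must be at least 2")
    scaled = (tq_value - (L - 1) * (1.0 - rho_star)) / ((L - 1) * rho_star + 1.0)
    p = float(stats.chi2.sf(max(scaled, 0.0), 1))
    return p, p < alpha


def tq_onedf_power(mu, rho: float, alpha: float) -> PowerEstimate:
    """Power of the one-df location-scale TQ approximation ("P-approx.").

    Rejection region TQ > chi2_1(alpha) ((L-1) rho + 1) + (L-1)(1 - rho),
    evaluated exactly under the alternative two-component mixture.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    L = mu.size
    spec = equicorr_noncentralities(mu, rho)
    thr = stats.chi2.isf(alpha, 1) * ((L - 1) * rho + 1.0) + (L - 1) * (1.0 - rho)
    power = mixture_tail(spec.lambdas, spec.gammas, thr, dfs=spec.dfs, epsabs=1e-9)
    return PowerEstimate("tq", alpha, float(power), mode="approx")


def rms_correlation(R) -> float:
    """rho* = sqrt(mean of squared off-diagonal correlations)."""
    Rv = np.asarray(R, dtype=float)
    off = Rv[~np.eye(Rv.shape[0], dtype=bool)]
    return float(np.sqrt(np.mean(off**2)))


def tq_power_approx(mu, R, alpha: float) -> PowerEstimate:
    """One-df noncentral chi-square approximation to TQ power.

    With mu* = (mean |mu_i|)^2 and rho* the root-mean-square off-diagonal
    correlation, the leading mixture component carries noncentrality
    L mu* / ((L-1) rho* + 1).  The remaining components shift the
    alternative relative to the null by dbar/(2 rho*) (the limit of the
    scaled (L-1)-df component's extra mean), so

        power = P(chi2(1, ncp) > chi2_1(alpha) - dbar / (2 rho*)).
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    L = mu.size
    if L < 2:
        raise ValueError("L must be at least 2")
    if np.isscalar(R):
        rho_star = float(R)
    else:
        rho_star = rms_correlation(R)
    mu_star = float(np.mean(np.abs(mu))) ** 2
    ncp = L * mu_star / ((L - 1) * rho_star + 1.0)
    dbar = _pairwise_mean_sq_diff(mu)
    thr = stats.chi2.isf(alpha, 1) - dbar / (2.0 * rho_star)
    power = float(stats.ncx2.sf(max(thr, 0.0), 1, ncp)) if ncp > 0 else float(alpha)
    return PowerEstimate("tq", alpha, power, mode="approx")


def tq_ceiling_noncentrality(mu_star: float, rho_star: float) -> float:
    """Ceiling noncentrality gamma* = mu*/rho* of TQ as L grows without bound."""
    if rho_star <= 0:
        raise ValueError("no power ceiling for rho* <= 0: TQ power grows with L")
    return float(mu_star) / float(rho_star)


def tq_asymptotic_power(mu_star: float, rho_star: float, alpha: float) -> PowerEstimate:
    """Asymptotic (L -> infinity) TQ power from the ceiling noncentrality."""
    if mu_star == 0:
        return PowerEstimate("tq", alpha, float(alpha), mode="asymptotic")
    gamma_star = tq_ceiling_noncentrality(mu_star, rho_star)
    power = float(stats.ncx2.sf(stats.chi2.isf(alpha, 1), 1, gamma_star))
    return PowerEstimate("tq", alpha, power, mode="asymptotic")
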