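"""Monte-Carlo engine for power and type-I error of the combination tests.

Statistics are sampled directly from their joint MVN distribution (the
alternative-hypothesis theory supplies the mean vector and correlation),
or computed from simulated regression data sets when validating that
theory.  All methods are evaluated on common simulated vectors, which
sharpens method comparisons at a given replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._quadform import null_quantile, tail_rejections
from .combine import decorrelation_transform
from .ld import (REPAIR_EIGENVALUE_TOL, CorrelationMatrix, equicorrelation,
                 perturbed_equicorrelation, random_pd_correlation)
from .theory import EffectModel, alt_params

__all__ = [
    "SimDesign",
    "MonteCarloResult",
    "sample_statistics",
    "simulate_regression_statistics",
    "estimate_power",
    "estimate_type1",
    "reference_panel_experiment",
]

_CHUNK = 20_000


@dataclass
class SimDesign:
    """Declarative simulation design.

    ``mu_spec`` is one of ``("null",)``, ``("equispaced", lo, hi)``,
    ``("explicit", vector)``, ``("uniform", lo, hi)`` (redrawn each
    replicate), or ``("beta_model", EffectModel)``.  ``correlation_spec``
    is one of ``("equicorrelation", rho)``, ``("perturbed", rho, u_low,
    u_high)``, ``("random_pd",)`` (fresh matrix each replicate), or
    ``("matrix", CorrelationMatrix)``.
    """

    L: int
    mu_spec: tuple = ("null",)
    correlation_spec: tuple = ("equicorrelation", 0.0)
    n_reps: int = 10**5
    alpha: tuple = (0.05,)
    seed: int | None = None
    noise: str = "normal"
    n_individuals: int | None = None

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if self.L < 1:
            raise ValueError("L must be at least 1")
        self.alpha = tuple(float(a) for a in np.atleast_1d(self.alpha))
        if any(not 0 < a < 1 for a in self.alpha):
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.noise not in ("normal", "laplace"):
            raise ValueError("noise must be 'normal' or 'laplace'")


@dataclass
class MonteCarloResult:
    """Per-method, per-alpha rejection proportions with MC standard errors."""

    table: pd.DataFrame
    n_reps: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def proportion(self, method: str, alpha: float | None = None) -> float:
        t = self.table[self.table["method"] == method]
        if alpha is not None:
            t = t[np.isclose(t["alpha"], alpha)]
        if len(t) != 1:
            raise KeyError(f"no unique row for {method!r} at alpha={alpha}")
        return float(t["estimate"].iloc[0])

    def mc_se(self, method: str, alpha: float | None = None) -> float:
        t = self.table[self.table["method"] == method]
        if alpha is not None:
            t = t[np.isclose(t["alpha"], alpha)]
        return float(t["mc_se"].iloc[0])


def sample_statistics(mu, R, n_reps: int, seed=None) -> np.ndarray:
    """Draw n_reps vectors of statistics from MVN(mu, R); rows are replicates."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    chol = np.linalg.cholesky(np.asarray(R, dtype=float))
    rng = np.random.default_rng(seed)
    return mu + rng.standard_normal((n_reps, mu.size)) @ chol.T


def simulate_regression_statistics(model: EffectModel, noise: str = "normal",
                                   seed=None, n_reps: int = 1) -> np.ndarray:
    """Marginal association statistics from simulated regression data sets.

    Each replicate draws X ~ MVN(0, Sigma) for N individuals, forms
    y = X beta + eps with unit-variance noise (Laplace scale 1/sqrt(2)
    when requested), and returns the normal-score marginal statistics
    Z_j = sqrt(N) * cor(y, X_j), one row per replicate.
    """
    N = model.n
    L = model.L
    if N < L + 2:
        raise ValueError("need at least L + 2 individuals")
    chol = np.linalg.cholesky(np.asarray(model.sigma, dtype=float))
    rng = np.random.default_rng(seed)
    out = np.empty((n_reps, L))
    chunk = max(1, int(2e7 / (N * L)))
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        x = rng.standard_normal((m, N, L)) @ chol.T
        if noise == "laplace":
            eps = rng.laplace(scale=1.0 / np.sqrt(2.0), size=(m, N))
        else:
            eps = rng.standard_normal((m, N))
        y = np.einsum("mnl,l->mn", x, model.beta) + eps
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        sxy = np.einsum("mnl,mn->ml", xc, yc)
        sxx = np.einsum("mnl,mnl->ml", xc, xc)
        syy = np.einsum("mn,mn->m", yc, yc)
        r = sxy / np.sqrt(sxx * syy[:, None])
        out[done:done + m] = np.sqrt(N) * r
        done += m
    return out


def _acat_stats(z: np.ndarray) -> np.ndarray:
    p = stats.chi2.sf(z**2, 1)
    p = np.clip(p, 1e-300, 1 - 1e-16)
    return np.tan((0.5 - p) * np.pi).mean(axis=1)


def _minp(z: np.ndarray) -> np.ndarray:
    return stats.chi2.sf((z**2).max(axis=1), 1)


def _resolve_mu(design: SimDesign):
    kind = design.mu_spec[0]
    if kind == "null":
        return np.zeros(design.L), False
    if kind == "equispaced":
        return np.linspace(design.mu_spec[1], design.mu_spec[2], design.L), False
    if kind == "explicit":
        mu = np.asarray(design.mu_spec[1], dtype=float)
        if mu.size != design.L:
            raise ValueError("explicit mu length does not match L")
        return mu, False
    if kind == "uniform":
        return (float(design.mu_spec[1]), float(design.mu_spec[2])), True
    if kind == "beta_model":
        return design.mu_spec[1], False
    raise ValueError(f"unknown mu_spec {kind!r}")


def _resolve_correlation(design: SimDesign, rng):
    kind = design.correlation_spec[0]
    if kind == "equicorrelation":
        return equicorrelation(design.L, design.correlation_spec[1])
    if kind == "perturbed":
        _, rho, u_lo, u_hi = design.correlation_spec
        return perturbed_equicorrelation(design.L, rho, u_lo, u_hi,
                                         seed=rng.integers(2**31))
    if kind == "matrix":
        return design.correlation_spec[1]
    if kind == "random_pd":
        return None     # redrawn each replicate
    raise ValueError(f"unknown correlation_spec {kind!r}")


def _random_pd_batch(rng, m: int, L: int) -> np.ndarray:
    """Batch of random PD correlation matrices (vectorised eigenvalue clipping)."""
    a = rng.uniform(-1.0, 1.0, size=(m, L, L))
    a = (a + a.transpose(0, 2, 1)) / 2.0
    np.einsum("mii->mi", a)[:] = 1.0
    w, v = np.linalg.eigh(a)
    w = np.clip(w, REPAIR_EIGENVALUE_TOL * w.max(axis=1, keepdims=True).clip(min=1.0), None)
    b = (v * w[:, None, :]) @ v.transpose(0, 2, 1)
    d = 1.0 / np.sqrt(np.einsum("mii->mi", b))
    return b * d[:, :, None] * d[:, None, :]


def estimate_power(design: SimDesign, methods=("dot", "tq", "acat", "minp")) -> MonteCarloResult:
    """Empirical rejection proportions of the requested methods.

    Fixed-correlation designs precompute the decorrelation transform and
    the exact per-alpha null quantiles, so each replicate costs O(L)
    vector work.  The random-PD mode regenerates the correlation (and its
    test thresholds) every replicate.
    """
    rng = np.random.default_rng(design.seed)
    mu_info, redraw_mu = _resolve_mu(design)
    if isinstance(mu_info, EffectModel):
        ap = alt_params(mu_info)
        mu_fixed, R = np.asarray(ap.mu), ap.r_alt
    else:
        mu_fixed = None if redraw_mu else np.asarray(mu_info)
        R = _resolve_correlation(design, rng)
    alphas = design.alpha
    L = design.L

    counts = {(meth, a): 0 for meth in methods for a in alphas}
    if R is not None:
        Rv = np.asarray(R, dtype=float)
        chol = np.linalg.cholesky(Rv)
        H = decorrelation_transform(Rv).H if "dot" in methods or "rtp" in methods else None
        lam = np.linalg.eigvalsh(Rv)
        tq_crit = {a: null_quantile(lam, a) for a in alphas} if "tq" in methods else {}
        dot_crit = {a: stats.chi2.isf(a, L) for a in alphas}
        cauchy_crit = {a: stats.cauchy.isf(a) for a in alphas}
        done = 0
        while done < design.n_reps:
            m = min(_CHUNK, design.n_reps - done)
            z = rng.standard_normal((m, L)) @ chol.T
            if redraw_mu:
                z += rng.uniform(mu_info[0], mu_info[1], size=(m, L))
            elif mu_fixed is not None:
                z += mu_fixed
            for a in alphas:
                if "tq" in methods:
                    counts[("tq", a)] += int(np.sum((z**2).sum(axis=1) > tq_crit[a]))
                if "dot" in methods:
                    x = z @ H.T
                    counts[("dot", a)] += int(np.sum((x**2).sum(axis=1) > dot_crit[a]))
                if "acat" in methods:
                    counts[("acat", a)] += int(np.sum(_acat_stats(z) > cauchy_crit[a]))
                if "minp" in methods:
                    counts[("minp", a)] += int(np.sum(L * _minp(z) < a))
            done += m
    else:
        dot_crit = {a: stats.chi2.isf(a, L) for a in alphas}
        cauchy_crit = {a: stats.cauchy.isf(a) for a in alphas}
        done = 0
        while done < design.n_reps:
            m = min(5_000, design.n_reps - done)
            Rb = _random_pd_batch(rng, m, L)
            cholb = np.linalg.cholesky(Rb)
            z = np.einsum("mij,mj->mi", cholb, rng.standard_normal((m, L)))
            if redraw_mu:
                z += rng.uniform(mu_info[0], mu_info[1], size=(m, L))
            elif mu_fixed is not None:
                z += mu_fixed
            tq_stat = (z**2).sum(axis=1)
            dot_stat = np.einsum("mi,mi->m", z, np.linalg.solve(Rb, z[..., None])[..., 0])
            lam = np.linalg.eigvalsh(Rb)
            for a in alphas:
                if "tq" in methods:
                    counts[("tq", a)] += int(np.sum(tail_rejections(lam, tq_stat, a)))
                if "dot" in methods:
                    counts[("dot", a)] += int(np.sum(dot_stat > dot_crit[a]))
                if "acat" in methods:
                    counts[("acat", a)] += int(np.sum(_acat_stats(z) > cauchy_crit[a]))
                if "minp" in methods:
                    counts[("minp", a)] += int(np.sum(L * _minp(z) < a))
            done += m

    rows = []
    for (meth, a), c in counts.items():
        p = c / design.n_reps
        rows.append({"method": meth, "alpha": a, "estimate": p,
                     "mc_se": np.sqrt(p * (1 - p) / design.n_reps),
                     "n_reps": design.n_reps})
    return MonteCarloResult(pd.DataFrame(rows), design.n_reps, design.seed)


def estimate_type1(L: int, n_reps: int, alpha, correlation_mode=("random_pd",),
                   seed=None, methods=("dot", "tq")) -> MonteCarloResult:
    """Null rejection proportions (beta = 0) under the given LD mode."""
    design = SimDesign(L=L, mu_spec=("null",), correlation_spec=tuple(correlation_mode),
                       n_reps=n_reps, alpha=tuple(np.atleast_1d(alpha)), seed=seed)
    return estimate_power(design, methods=methods)


def reference_panel_experiment(population_R, panel_multiplier: int, alpha,
                               n_reps: int = 10**5, seed=None,
                               methods=("tq", "dot", "acat")) -> MonteCarloResult:
    """Type-I error when LD is estimated from an external reference panel.

    Each replicate draws null statistics from MVN(0, population LD) and a
    fresh panel of N = k L Gaussian genotype surrogates; the tests are
    computed with the panel's sample correlation matrix in place of the
    true one.  Singular panel estimates (N <= L) are eigenvalue-repaired
    and counted in ``extra['n_repaired']``.
    """
    if panel_multiplier < 2:
        raise ValueError("panel multiplier must be at least 2")
    pop = np.asarray(population_R, dtype=float)
    L = pop.shape[0]
    N = panel_multiplier * L
    alphas = tuple(float(a) for a in np.atleast_1d(alpha))
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(pop)
    counts = {(meth, a): 0 for meth in methods for a in alphas}
    n_repaired = 0
    chunk = max(200, min(5_000, int(2e7 / (N * L))))
    done = 0
    dot_crit = {a: stats.chi2.isf(a, L) for a in alphas}
    cauchy_crit = {a: stats.cauchy.isf(a) for a in alphas}
    while done < n_reps:
        m = min(chunk, n_reps - done)
        z = rng.standard_normal((m, L)) @ chol.T
        panel = rng.standard_normal((m, N, L)) @ chol.T
        pc = panel - panel.mean(axis=1, keepdims=True)
        cov = np.einsum("mnl,mnk->mlk", pc, pc)
        d = 1.0 / np.sqrt(np.einsum("mll->ml", cov))
        Rb = cov * d[:, :, None] * d[:, None, :]
        w, v = np.linalg.eigh(Rb)
        floor = REPAIR_EIGENVALUE_TOL * w.max(axis=1, keepdims=True).clip(min=1.0)
        bad = (w <= floor).any(axis=1)
        if bad.any():
            n_repaired += int(bad.sum())
            w = np.clip(w, floor, None)
            Rb2 = (v * w[:, None, :]) @ v.transpose(0, 2, 1)
            d2 = 1.0 / np.sqrt(np.einsum("mll->ml", Rb2))
            Rb = Rb2 * d2[:, :, None] * d2[:, None, :]
            w, v = np.linalg.eigh(Rb)
        tq_stat = (z**2).sum(axis=1)
        dot_stat = np.einsum("mi,mi->m", z, np.linalg.solve(Rb, z[..., None])[..., 0])
        for a in alphas:
            if "tq" in methods:
                counts[("tq", a)] += int(np.sum(tail_rejections(w, tq_stat, a)))
            if "dot" in methods:
                counts[("dot", a)] += int(np.sum(dot_stat > dot_crit[a]))
            if "acat" in methods:
                counts[("acat", a)] += int(np.sum(_acat_stats(z) > cauchy_crit[a]))
        done += m
    rows = []
    for (meth, a), c in counts.items():
        p = c / n_reps
        rows.append({"method": meth, "alpha": a, "estimate": p,
                     "mc_se": np.sqrt(p * (1 - p) / n_reps), "n_reps": n_reps})
    return MonteCarloResult(pd.DataFrame(rows), n_reps, seed,
                            extra={"n_repaired": n_repaired, "panel_size": N})
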