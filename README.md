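# dotgsa

Gene-set association testing from GWAS summary statistics by
**decorrelation of association Z-scores** (the DOT statistic), together
with the classical sum-of-squares test (TQ, as implemented in VEGAS),
the Cauchy combination test (ACAT), the Bonferroni minimum-P bound, and
the rank truncated product on decorrelated scores.

## Who this is for

Statistical geneticists who have per-SNP summary statistics (Z-scores or
P-values) for a gene or region, plus an LD matrix — from the same sample,
from haplotype frequencies, or from a reference panel — and want a single
well-calibrated gene-level P-value, an account of which SNPs drive it, and
analytic power calculations for study design.

## The statistics

For `L` SNPs with association scores `Z ~ MVN(μ, R)` (under the null
`μ = 0` and `R` is the LD correlation matrix):

- **TQ** `= Σ Z_i²`, with null distribution the weighted sum
  `Σ λ_i χ²₁` over the eigenvalues `λ_i` of `R` (evaluated by exact
  characteristic-function inversion or Ruben's series).
- **DOT** `= Σ X_i²` where `X = H Z` and `H = E diag(1/√λ) E′` is the
  *symmetric* inverse square root of `R`. Then `H R H = I`, so DOT is
  `χ²_L` under the null, and the multiset `{X_i}` is invariant to the
  ordering of exchangeable inputs (Cholesky whitening is not).

Under the alternative, `μ_j = √N · b_j` with `b_j = cor(y, SNP_j) =
Σ_j β / √(β′Σβ + 1)`, and the correlation of the statistics is the
delta-method (Olkin–Siotani) covariance of sample correlations sharing
the outcome. DOT is then noncentral `χ²_L` with noncentrality
`γ_c = μ′R⁻¹μ`, which **grows with L** whenever effect sizes or pairwise
LD are heterogeneous, while the TQ noncentrality is dominated by its
leading eigencomponent and its power saturates at a ceiling governed by
`γ* = μ*/ρ*` (`μ*` the squared mean absolute effect, `ρ*` the
root-mean-square LD). That contrast — steady DOT gains versus a TQ
plateau — is the core phenomenon this package computes, simulates and
exploits.

## Worked example

One block of 8 SNPs with heterogeneous LD (pairwise correlations 0.45 to
0.86); the only associated SNP is `rs6`:

```python
import numpy as np
from dotgsa import GeneSetTest, perturbed_equicorrelation, sample_statistics

R = perturbed_equicorrelation(8, 0.6, 0.0, 1.5, seed=42)
R.labels = [f"rs{i}" for i in range(8)]
mu = np.zeros(8); mu[6] = 3.2                  # signal on rs6
z = sample_statistics(mu, R, 1, seed=7)[0]

res = GeneSetTest(z=z, corr=R).fit(methods=("dot", "tq", "acat", "minp"))
print(res.summary())
print(res.top_contributors(n_components=2))
```

```
Gene-set association (8 SNPs)
=========================
method statistic p-value
-------------------------
   dot   52.7407 1.21e-08
    tq    9.7834     0.26
  acat  -26.9055    0.988
  minp    0.0027   0.0216
-------------------------

 component_rank  component_value snp      term
              1         6.572322 rs6  6.358616
              2        -2.283458 rs5 -1.223376
              2        -2.283458 rs6 -1.050982
```

The raw scores barely move TQ (p = 0.26) because the signal sits against
the dominant LD eigencomponent, but after decorrelation the same data give
DOT p ≈ 1.2e-8, and the contributor decomposition points at `rs6`: its
term `h_j Z_j = 6.36` carries essentially all of the leading component
`X₍₁₎ = 6.57`. This is the same qualitative pattern as the discordant
gene-level calls that motivate decorrelation in real GWAS follow-ups.

Analytic power for a design, from the same theory:

```python
from dotgsa import dot_power, tq_equicorr_power, equicorrelation
mu = np.linspace(1.0, 2.3, 100)                 # heterogeneous effects
print(tq_equicorr_power(mu, 0.7, 0.05).power)   # 0.5242
print(dot_power(mu, equicorrelation(100, 0.7), 0.05).power)  # 0.9196
```

A command-line interface mirrors the library: `dotgsa gene-test`,
`dotgsa power`, `dotgsa simulate`, `dotgsa scan` (anchor-SNP blocks with
per-gene contributor tables). See `dotgsa --help`.

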