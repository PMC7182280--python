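# Methods

## Model

A quantitative trait follows `y = β₀ + Σ_j β_j SNP_j + ε` with unit-variance
errors; SNPs are coded 0/1/2 and correlated according to the LD matrix `Σ`.
Marginal (single-SNP) association statistics are modelled jointly as
`Z ~ MVN(μ, R)`:

- `μ_j = √N b_j`, where `b_j = cor(y, SNP_j) = Σ_j β / √(β′Σβ + 1)` is the
  standardized marginal effect. For a binary trait obtained by thresholding
  a normal liability at `l`, the means attenuate multiplicatively by
  `d = φ(l)/√(Φ(l)(1 − Φ(l)))`; no higher-order liability correction is
  applied.
- Under the null, `R = Σ` (or the Schur-complement adjustment of `Σ` when
  covariates correlate with SNPs). Under the alternative the statistics are
  sample correlations sharing the outcome `y`, so their correlation is the
  delta-method (Olkin–Siotani) form

  `R_ij = [σ_ij(1 − b_i² − b_j²) − ½ b_i b_j (1 − b_i² − b_j² − σ_ij²)]
  / [(1 − b_i²)(1 − b_j²)]`,

  which reduces to `σ_ij` at `β = 0` and correlates associated SNPs (sign
  opposite to `b_i b_j`) even without LD. This covariance assumes joint
  normality of `(y, SNPs)`; with heavy-tailed errors (e.g. Laplace,
  excess kurtosis 3) the means are unaffected but the statistic
  correlation shifts by a few hundredths at `b ≈ 0.3` — the validation
  oracle for the correlation therefore uses normal errors, while the
  mean-structure oracle is run under Laplace errors as a robustness check.

Weighted statistics `Y_i² = w_i Z_i²` are absorbed by rescaling the mean and
covariance, so every result below applies to weighted sums unchanged.

## Tests

- **TQ** = `Σ Z_i²`; null and alternative distributions are weighted sums of
  one-df (non)central chi-squares with weights the eigenvalues of `R` and
  noncentralities `γ_i = (E_i′μ)²/λ_i`, so `Σγ_i = μ′R⁻¹μ`.
- **DOT** = `‖HZ‖²` with `H = E diag(λ^{-1/2}) E′` the symmetric inverse
  square root. `H` is the unique whitening transform that is invariant to
  the ordering of exchangeable inputs, which also makes downstream
  order-statistic combiners (RTP) well defined. DOT is `χ²(L, γ_c)` with
  `γ_c = μ′R⁻¹μ`.
- **ACAT**: equal-weight average of `tan((0.5 − p_i)π)` referred to the
  standard Cauchy; degenerate P-values are clamped to `[1e-300, 1 − 1e-16]`.
  Its null is approximate under correlation: the bulk of its P-value
  distribution is visibly non-uniform, and at α = 0.05 its size can reach
  ≈ 7% under strong LD, improving at smaller α. Tests assert its tail
  behaviour, not bulk uniformity.
- **min-P**: `min(1, L·min p)`.
- **RTP on decorrelated scores**: `Σ_{i≤k} −ln P_(i)` of the one-df
  P-values of `X_i²`; the null is simulated from independent uniforms with
  the add-one correction `(r+1)/(n_null+1)` (default `n_null = 1e5`).

## Equicorrelation closed forms and approximations

For `R_ρ = (1−ρ)I + ρ11′` the spectrum is `{1+(L−1)ρ, (1−ρ)×(L−1)}` and the
Helmert basis gives `δ₁ = Lμ̄²/(1+(L−1)ρ)` and
`δ_s = Σ_{j≥2} δ_j = (L−1)d̄/(2(1−ρ)) = Σ(μ_i−μ̄)²/(1−ρ)`, with
`γ_c = δ₁ + δ_s`. TQ reduces to a two-component mixture, evaluated exactly.

Two one-df approximations to TQ are provided:

- a **null location-scale approximation**: refer
  `(TQ − (L−1)(1−ρ*)) / ((L−1)ρ* + 1)` to `χ²₁`;
- a **power approximation**: `P(χ²(1, ncp) > χ²₁(α) − d̄/(2ρ*))` with
  `ncp = Lμ*/((L−1)ρ*+1)`, `μ* = (mean|μ_i|)²`, and
  `ρ* = √(mean ρ_ij²)` (root-mean-square off-diagonal). The `d̄` shift is
  the limit of the extra mean the `(L−1)`-df component acquires under the
  alternative; only the RMS choice of `ρ*` reproduces the asymptotic
  ceiling `γ* = μ*/ρ*` consistently with the exact theory. As `L → ∞`,
  TQ power tends to `P(χ²(1, μ*/ρ*) > χ²₁(α))` — the power ceiling —
  whereas the DOT noncentrality `γ_c` keeps growing linearly in `L`
  whenever `d̄ > 0`.

## Numerical evaluation of mixture tails

`quadform_tail` targets 1e-9 absolute accuracy and dispatches:

1. components with identical weights are merged (chi-squares add), so
   equicorrelation collapses to two components and a single distinct weight
   is evaluated by the exact (non)central chi-square;
2. total df ≤ 10: Ruben's series — a nonnegative mixture of central
   chi-square CDFs with `β = λ_min`, truncated when the missing coefficient
   mass is below half the tolerance (the Imhof integrand decays only like
   `u^{-(Σdf/2+1)}` there, too slowly for oscillatory quadrature);
3. otherwise: Imhof characteristic-function inversion via adaptive
   quadrature;
4. a high-replicate Monte-Carlo fallback exists for non-convergence but is
   not reached by any tested configuration.

Null quantiles are Brent-root-found on the tail to 1e-9. The Monte-Carlo
engines need ~1e5 per-replicate TQ decisions with replicate-specific
eigenvalues; these use a vectorised Lugannani–Rice saddlepoint screen, with
every replicate whose screened p lies within a factor 4 of the threshold
re-evaluated by exact batched Imhof inversion (all rows share one adaptive
grid), so threshold decisions are exact.

## LD construction

Sample LD is the Pearson correlation of dosage columns; missing genotypes
are rejected (imputation is upstream — a correlation over incomplete
genotypes no longer reflects the predictor correlation). Haplotype-table LD
uses `r_ij = (P_ij − p_i p_j)/√(p_i(1−p_i)p_j(1−p_j))`. Covariate
adjustment inverts the full predictor correlation, extracts the SNP block
of the inverse, re-inverts and standardizes. Indefinite matrices are
repaired by clipping eigenvalues below `1e-6·λ_max` (the default tolerance
of the standard nearest-PD conversion) and re-standardizing; matrices with
`λ_min ≤ 1e-10·λ_max` are treated as singular by the tests and the
decorrelation transform.

## Synthetic-data generator

The simulation engine emulates the study conditions the theory addresses:

- statistics drawn directly from `MVN(μ, R)` (the fast path the joint
  theory licenses), with mean patterns *equispaced* (e.g. 2.3–2.4 or
  1–2.3), *explicit*, *uniform redrawn per replicate* (±0.15), or derived
  from a regression `EffectModel`;
- correlations: equicorrelation `ρ`, rank-one-perturbed equicorrelation
  `standardize(R_ρ + UU′)` with `U ~ uniform`, a fresh random
  positive-definite correlation per replicate (symmetric uniform(−1,1)
  entries, PD-repaired, standardized), or a user matrix;
- a regression mode that simulates individual-level data (`X ~ MVN(0, Σ)`,
  normal or unit-variance Laplace errors, scale `1/√2`) and returns the
  normal-score marginal statistics `√N·r̂_j` — the object whose moments the
  delta-method theory describes; the t-ratio differs at `O(b²)` and is not
  used;
- a reference-panel experiment drawing, per replicate, `N = kL` Gaussian
  genotype surrogates to form the panel LD estimate used in place of the
  truth (a Wishart-equivalent shortcut: only the sampling distribution of
  the sample correlation matters to first order).

What the generator does **not** emulate: discrete genotypes with fixed
target LD, allele-frequency spectra, genotyping error, population
stratification, or real haplotype block structure. Passing tests therefore
demonstrate the distributional theory and the operating characteristics of
the tests under correctly specified (or panel-estimated) Gaussian LD, not
robustness to those data artefacts.

Default replicate count is 1e5 for empirical operating characteristics;
per-method comparisons share the same simulated vectors (common random
numbers). All paths are reproducible from a single integer seed.

## Gene-scan workflow

A gene is the block of SNPs whose |LD| with a named anchor SNP reaches a
threshold (default 0.25; absolute value, since the sign of r flips with
allele coding). The block is tested by all methods; when both Z and P
columns exist, Z wins (consistency checked to 1e-6 with a warning).
Contributor mining ranks the decorrelated components by `X_i²` (ties to the
lower index) and reports, per component, the terms `h_j Z_j` sharing the
sign of `X_i` with magnitude at least 25% of the largest term (both the
number of components, default 3, and the cutoff are configurable and
written to the output). Contributors are association signals or their LD
proxies; the decomposition cannot separate causal from proxy SNPs.

## Known limitations

- DOT requires the LD matrix to match the data that produced the
  statistics. With a panel estimate its type-I error inflates unless the
  panel is ~50–100× larger than `L` (the package's panel experiment
  reproduces this inflation and its decay); TQ and ACAT are robust to
  panel misspecification.
- ACAT's size is approximate under strong correlation at conventional α.
- The alternative-hypothesis correlation assumes joint normality (see
  above); means are first-order robust to the error distribution.
- Simulation problem sizes default to 1e5 replicates, chosen so a full
  verification run completes on a single CPU in minutes; Monte-Carlo
  tolerances in the tests are stated as multiples of the binomial standard
  error at that scale.
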