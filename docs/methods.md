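# Methods

## The model

The package tests, feature by feature, whether the cells of case subjects
express at a different level than the cells of control subjects, using a
two-stage construction.

**Stage 1.** For case subject *i* (cells y₁ᵢ₁ … y₁ᵢK₁ᵢ) and control subject
*j*, the pairwise difference is the probabilistic index

d_ij = (1 / K₁ᵢK₀ⱼ) Σₖ Σₖ′ [ I(y₁ᵢₖ > y₀ⱼₖ′) + ½ I(y₁ᵢₖ = y₀ⱼₖ′) ],

the rescaled Mann–Whitney U statistic with half-weighted ties. It is the
empirical probability that a random case cell exceeds a random control
cell, equals the ROC AUC of the feature as a classifier of the two
subjects' cells, and depends on the data only through ranks, so it is
robust to outliers, monotone normalization choices, and non-normality. The
implementation uses midranks of the pooled sample, which reproduces the
double-sum kernel exactly (including heavy zero-inflation ties) in
O((K₁+K₀) log(K₁+K₀)); the test suite checks it against the explicit
double loop. Alternative separable metrics (mean/median difference,
mean-indicator) are provided; they turn the framework into the familiar
pseudobulk t and subject-level rank tests.

**Stage 2.** The m × n matrix D = (d_ij) is modeled with one latent level
per subject:

d_ij = a_i − b_j + ε_ij, a_i ~ N(μ, σ₁²), b_j ~ N(0, σ₀²), ε_ij ~ N(0, σ²),

a two-way crossed random-effects layout with one observation per cell of
the design. Pairs sharing a subject are correlated through the shared
latent level — this is exactly the dependence that makes the mn pairwise
indices non-independent. The estimand μ is the population-level
case-vs-control difference; H₀: μ = 0.5 on the PI scale, μ = 0 on the
logit scale. Levels are *relative*: adding a constant to every a and b
changes nothing, which is why only the difference μ is identified.

### Closed form (no covariates, no weights)

μ̂ is the grand mean d̄··. With s²_rows the sample variance of the m row
means and s²_cols that of the n column means,

t = (d̄·· − μ₀) / √(s²_rows/m + s²_cols/n),

referred to t(m+n−2), two-sided. The row-mean variance estimates
σ₁² + σ²/n (cases) and the column-mean variance σ₀² + σ²/m (controls), so
the denominator estimates var(μ̂) = σ₁²/m + σ₀²/n + σ²/(mn) up to one
σ²/(mn) — `variance_of_mu_hat` returns both the three-term estimate and
this two-term approximation. The statistic is algebraically the Welch
two-sample t comparing the least-squares latent levels of cases and
controls, which the suite verifies to 1e-10.

Least-squares levels themselves are unique up to a common constant; two
representatives are provided: Σb̂ⱼ = 0 (â_i = d̄ᵢ·, b̂ⱼ = d̄·· − d̄·ⱼ, the
one consistent with the model's zero-centered controls) and the
minimum-norm (Moore–Penrose) solution, which subtracts m/(m+n) · d̄·· from
both. For separable metrics the fit is exact (zero residuals).

A constant difference matrix (e.g. a feature at a single value everywhere)
has no estimable variance; such fits return a `degenerate_variance` status
with a NaN p-value and are excluded from the FDR denominator, never
crashing the run.

### Likelihood fits (covariates, weights, multiple groups)

With p subject covariates the fixed-effects part becomes
μ + βᵀ(Xᵢ − Xⱼ); with unequal cluster sizes the latent variances are
scaled as σ₁²/K₁ᵢ and σ₀²/K₀ⱼ (a PI computed from more cells is less
noisy, its sampling variance being proportional to 1/K₁ᵢ + 1/K₀ⱼ); with
M+1 conditions, every non-reference condition m gets its own mean μ_m and
variance σ_m² against shared reference levels b₀ⱼ, and H₀: μ₁ = … = μ_M =
μ₀ is a χ²(M) likelihood-ratio or Wald test.

These fits maximize the Gaussian likelihood on the explicit mn × mn
marginal covariance V = Z_a G_a Z_aᵀ + Z_b G_b Z_bᵀ + σ²I with the fixed
effects profiled out. Numerical choices:

- Variance components are optimized on the log scale (Nelder–Mead,
  likelihood tolerance 1e-8, floor 1e-10) from sums-of-squares starting
  values.
- **REML by default for Wald inference.** On this balanced layout REML
  reproduces the sums-of-squares components that the closed form uses;
  plain ML shrinks them and makes the Wald t anti-conservative. Likelihood
  ratio tests always refit both mean structures with plain ML (REML
  likelihoods are not comparable across fixed-effects structures).
- **Null fits are multimodal.** With the mean pinned at μ₀, a residual
  level offset can be absorbed by either the case or the control variance
  component; the optimizer is started from moment-based candidates for
  each mode and keeps the best optimum. (A single-start version reproduces
  a plausible-looking but wrong LRT.)
- Wald degrees of freedom: t(m+n−2−p) by default — matching the closed
  form at p = 0 — with a standard-normal reference and per-contrast
  Satterthwaite df (moment matching on the curvature of the restricted
  likelihood, lmerTest-style) available via `df_method`.

The implementation is validated against lme4/lmerTest on frozen datasets:
log-likelihoods, fixed effects, variance components, the multigroup LRT,
and a Satterthwaite t/df/p agree to at least four decimals.

### Known small-sample behavior

With 5 subjects per group, tests whose reference distribution is
asymptotic are measurably liberal even in the correctly specified model:
the multigroup χ²(M) LRT rejects ~12–17% at α = 0.05 (the statistic is
identical to lme4's, so this is intrinsic, not an implementation artifact;
at 10 subjects per group it drops to ~9%), and the Wald t on a
subject-level covariate rejects ~10% with Satterthwaite df (~15–18% with
residual df; lmerTest shows the same pattern on the identical simulation).
The two-group closed form, by contrast, is exactly calibrated in the
latent model (its t(m+n−2) reference is the Welch/Satterthwaite df under
equal component contributions) and holds its size on ZINB data. Practical
guidance: for two unadjusted groups the closed form is the default and
needs no asymptotics; treat multigroup and covariate-adjusted p-values
near the threshold with caution below ~10 subjects per group.

The latent-variable LRT has a second idiosyncrasy: because the case levels
are a zero-mean random effect under the null, a genuine mean shift can be
partially absorbed into σ₁², making the LRT *less* powerful than the Wald
t under strong alternatives. Wald is therefore the default two-group test.

## Pipeline

Per feature: PI matrix → latent fit (closed form when unadjusted and
unweighted, REML otherwise) → two-sided p. Across features:
Benjamini–Hochberg step-up (Benjamini–Yekutieli optional); a feature is
called differentially expressed when q < 0.1 *and* its PI lies outside
[0.45, 0.55]. The PI window is a practical-equivalence guard: with many
subjects a PI of 0.52 can be significant yet biologically negligible.
Both thresholds are configurable and independently disableable.

QC (defaults): drop subjects with ≤ 50 cells first, then features detected
in ≤ 10% of the evaluation group's cells (default: the case group, where
disease-specific markers are expressed). Normalization: centered log-ratio
per cell (pseudocount 1) for compositional protein panels; a
median-library-size scaling followed by log1p as a simple RNA option —
deliberately a lightweight substitute for pool-based size-factor methods,
since the PI depends only on within-feature ranks across cells and is
unchanged by any per-cell monotone transform that preserves between-cell
ordering within a feature. Raw passthrough is supported for externally
normalized data.

Balanced label permutations for null calibration on a fixed dataset:
group 1 takes g₁ cases + g₂ controls, group 2 the rest; mirror assignments
are identified when the split is exactly half of each pool (16 cases and
4 controls split (8, 2) give C(16,8)·C(4,2)/2 = 38,610 distinct splits).
Sampling without replacement is seeded and reproducible.

## The simulator

`simulate_counts` generates multi-subject counts from a zero-inflated
negative binomial: for feature i, subject j, cell k,

μ_ijk ~ N(μ_ij, σ_ij²) (truncated below at 0.01), Y_ijk = 0 with
probability z_ij, else NB(mean μ_ijk, size φ_ij) — variance μ + μ²/φ.

The subject-level perturbation is specified on the natural scale, so a
small positive floor keeps the NB mean valid — a documented choice for the
rare draws that would go negative. Differential expression multiplies the
case mean by a fold change r via μ′ = μr, φ′ = φμ / (μ + (1−r)φ), which
preserves the mean–variance relationship; the reparameterization requires
r < 1 + μ/φ and the generator refuses inadmissible combinations rather
than silently capping. Covariates act on the log mean (log μ* = log μ +
βx) with fixed, equally spaced per-subject grids (cases on [−0.9, 1.1],
controls on [−1, 1]) — deterministic because 5–10 subjects cannot estimate
a covariate distribution. Unequal cluster sizes are drawn from a discrete
uniform (default 50 … N_max).

Parameter grids mimic resampling per-person estimates from a small
reference panel: a pool of 100 features draws feature-level μ
(log-uniform [0.1, 20]), φ (log-uniform [0.5, 10]) and dropout z (uniform
[0, 0.7]); each subject then varies the feature's mean by a lognormal
factor (sd 0.3, ≈ ±35%) and its dropout slightly, and σ_ij is uniform on
[0, 0.3 μ_ij]. The within-feature between-person correlation matters: it
is what real per-person estimates of the same gene look like, it keeps a
2-fold effect visible against between-person variation, and it leaves the
between-person heterogeneity that breaks cell-level tests. Feature rows
are then resampled with replacement to the requested size. The power
harness additionally restricts draws to the fold-change-admissible region
by rejection sampling. One child random stream per subject makes every
dataset bit-reproducible from its seed.

What the simulator does *not* emulate: batch effects, library-size
gradients between conditions, correlated features (each feature is drawn
independently given its parameters), empirically estimated reference
parameters, or cell-type mixture structure. Passing benchmarks here shows
correct behavior under clustered ZINB heterogeneity — not robustness to
confounded real-world designs.

## Benchmark studies and problem sizes

The type-I-error study simulates null data (r = 1) and records, per
replicate and method, the fraction of features with p below each of
α ∈ {0.001, 0.01, 0.05, 0.2}. The shipped studies use 1,000 features ×
100 replicates with 5+5 subjects and 100 cells each for calibration, and
500 features × 10 replicates with cluster sizes uniform on {50…200} for
power at r ∈ {1.5, 2} — sizes chosen so the full suite reruns in a few
minutes while keeping the Monte-Carlo error of a rate near 0.05 below
±0.015 per replicate. Comparators: the pooled cell-level Wilcoxon
(`wilcoxon_sc`, the anti-pattern that treats cells as independent — kept
only to demonstrate its inflation) and the subject-mean Wilcoxon
(`wilcoxon_pseudobulk`, exact by enumeration with tie half-weights when
m+n ≤ 12, normal approximation with tie correction otherwise). Calibration
tests in the suite use exact binomial bands; two bands are deliberately
non-uniform guards (multigroup LRT, covariate Wald) for the documented
small-sample liberality above.

## Limitations

- The stage-2 normality of latent levels is an approximation; PIs are
  bounded, and with very few cells per subject their discreteness is not
  modeled (the logit scale with its half-count clamp at 1/(2K₁K₀) is the
  provided mitigation).
- Multigroup and covariate-adjusted inference rely on asymptotic
  references (see small-sample behavior above).
- The weighted variant assumes latent variance exactly inversely
  proportional to cluster size, a heuristic borrowed from the U-statistic
  variance formula.
- PIs are not transitive across multiple groups: comparisons are always
  against one chosen reference; comparing two non-reference conditions
  requires its own two-group run.
- No cross-feature dependence modeling; BH-FDR is applied as if features
  were exchangeable.
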