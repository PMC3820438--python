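# Methods

## Statistics

For gene *g* with group means X̄₁, X̄₂, unbiased variances s₁², s₂² and group
sizes n₁, n₂, the package computes the Welch two-sample t-statistic
t = (X̄₁ − X̄₂)/√(s₁²/n₁ + s₂²/n₂) and the SAM s-statistic
s = (X̄₁ − X̄₂)/(δ + √(s₁²/n₁ + s₂²/n₂)). The stabilizing constant δ is a
percentile of the gene-wise t-denominators — families s30/s50/s70/s90 use
the 30/50/70/90th percentile — computed with the linear-interpolation
percentile convention (the p-th percentile of n points interpolates at rank
1 + (n−1)p/100). With δ = 0 the s-statistic equals the t-statistic exactly.
Only the Welch (unequal-variance) form is implemented; pooled-variance and
paired designs are out of scope.

Because δ > 0 pulls every statistic toward zero, s-statistics are rescaled
before being handed to the empirical-null machinery: multiply by
spread(t)/spread(s), where spread is the SD (ddof = 1) or IQR across genes
of the *signed* statistics. Rescaling preserves ranks, so it leaves ROC
behaviour untouched.

Genes whose statistic is undefined (both sample variances zero, δ = 0) are
set to NaN, counted, excluded from percentile/spread computations and from
all downstream estimation, and reported via a warning. Silent propagation
would poison the rescaling factor; dropping with a count is the least
surprising alternative.

## Pooled permutation null

`permutation_labels` draws B distinct non-identity arrangements of the
group labels (exhaustive when C(n₁+n₂, n₁) − 1 ≤ B, otherwise uniform
rejection sampling without replacement, reproducible from the seed). For
each arrangement the statistic is recomputed for every gene — for
s-families δ is recomputed from that permutation's own t-denominators, so
each permuted statistic vector is self-contained — and all G × B values are
pooled into a single null. Two-sided P-values use an add-one rule,

p_g = (#{|null| ≥ |obs_g|} + 1) / (G·B + 1),

which guarantees p ∈ (0, 1] as the density estimators downstream require;
the deviation from the raw empirical fraction is negligible at
G·B ≥ 10⁵. Ties count toward the null (conservative). B defaults to 100.

## Estimators of pi0

**Smoother method.** π̂₀(λ) = #{p > λ}/((1−λ)G) on the grid λ = 0, 0.05, …,
0.90; a natural cubic smoothing spline with 3 effective degrees of freedom
is fitted to (λ, π̂₀(λ)) and evaluated at λ = 0.90, clipped to [0, 1]. The
spline comes from `scipy.interpolate.make_smoothing_spline`; its smoothing
parameter is calibrated by bisection so that the trace of the smoother
matrix equals the requested df. A single-λ grid skips smoothing and returns
the plug-in estimate.

**Convex decreasing density NPMLE.** The P-value density is modelled as a
mixture of the uniform and triangular densities f_θ(p) = 2(θ−p)/θ² on
(0, θ); any such mixture is convex, nonincreasing and has unit mass, and
f(1) equals the uniform weight w₀ — which is π̂₀. Fitting is greedy
Frank–Wolfe: starting from the uniform, each iteration picks the candidate
component maximizing the mean likelihood ratio Σᵢ f_θ(pᵢ)/f(pᵢ)/G (ties
toward the smaller θ, i.e. the steeper signal density) and mixes it in with
a step size found by golden-section search (tolerance 1e−6) on the
log-likelihood; iteration stops after 100 rounds or when no direction
improves the likelihood to first order. Two details matter:

* the *uniform itself* is kept in the candidate set — without it w₀ can
  only shrink along the greedy path and π̂₀ systematically undershoots the
  NPMLE (on 0.9·U(0,1) + 0.1·Beta(0.1,1) mixtures the fit agrees with an
  independent R implementation of the same estimator class to ~10⁻³ once
  the uniform direction is included);
* candidate support points θ are the unique P-values when there are at most
  300, otherwise 300 quantiles of the P-values, always including 1.0.

**Empirical-null method.** Operates on (rescaled) statistics directly.
The null for |S| is half-normal(σ) under the z input specification and
σ·|t(df)| under the t specification, with df = n₁ + n₂ − 2 for the whole
vector (per-gene Welch df varies; the null model needs one number). The
scale is fitted by censored maximum likelihood on the central region
[0, x₀]: statistics inside contribute their null density, statistics
outside only the censoring probability through a null fraction
η₀(σ) = min(1, N₀/(G·F(x₀;σ))), profiled in closed form. The censoring
point x₀ is the smallest |statistic| quantile on the grid 10%, …, 90%, 99%
whose fit is self-consistent: the fitted null must predict, within the
central 95% binomial band, the observed count inside a *distant* check
region (the 80% quantile; a check near x₀ is circular because the count
there was effectively fitted, and the (σ, η₀) likelihood has a ridge of
shrunken solutions that mimic the truth wherever the null CDF is still
near-linear). The profile likelihood is scanned on a coarse log-σ grid
before local refinement because that ridge also creates local optima. If no
threshold passes, the least-inconsistent one is used and flagged in the
diagnostics rather than raising, so a study run records the cell instead of
aborting. Statistics are then converted to two-sided null P-values under
the fitted null and π̂₀ is the Grenander density of those P-values read off
near p = 1 — specifically at the step containing p = 0.8, because the
literal terminal step of the Grenander estimator is boundary-inconsistent
(its slope on the last segment is biased toward zero; for exact-uniform
samples of size 10⁴ the median terminal positive slope is ≈ 0.62, while the
density at p = 0.8 sits within a few percent of 1).

**Grenander density.** The left derivative of the least concave majorant
of the empirical CDF on [0, 1], computed by a monotone-chain upper hull;
equivalently the weighted antitonic regression of the ECDF slopes, which is
how the tests cross-check it. The estimate is a nonincreasing step function
integrating to exactly 1.

**FDR.** FDR̂(α) = min(1, α·π̂₀/F̂(α)) with F̂(α) = #{p < α}/G (strict "<"
by default, matching the rule "call genes with P-values *less than* α
significant"; "≤" is a flag — it matters only for discrete pooled-null
P-values with ties at α). F̂(α) = 0 returns a flagged no-discoveries result
instead of dividing by zero.

## Synthetic data generator

The generator emulates a two-population expression study (lymphoblastoid
cell lines, 60 + 45 donors, ~47k transcripts) whose per-gene parameter
table is not redistributable. Per gene: baseline mean ~ Normal(7, 1.5)
(log₂-expression-like), rounded to the nearest 0.1 so that equality of
means is exact; two population SDs drawn independently as
exp(Normal(−0.7, 0.6)) (median SD ≈ 0.50); exactly round(π₁·G) genes are
flagged DE and receive μ₂ = round(μ₁ + Δ, 0.1) with Δ = sign·|Normal(0,
0.5)|, redrawn until the rounded means differ. Data are independent
normals per gene and sample; the variance regimes are EV (both groups use
sd_A), UV1 (sd_A, sd_B) and UV2 (sd_B, sd_A). Users with a real parameter
table can supply it as a TSV (gene_id, mu1, mu2, sd_A, sd_B).

What the generator does **not** emulate: gene–gene correlation (all genes
independent), non-normal noise, mean–variance coupling, and the empirical
joint distribution of effect sizes and variances in real data (effects and
SDs are drawn independently per gene). Benchmark results therefore speak to
estimator behaviour under clean two-group normal sampling with exact truth
labels, not to robustness against correlated or heavy-tailed expression
data.

The scenario factorial is 3 sample sizes (60,45)/(16,12)/(8,6) — all at the
4:3 ratio of the emulated study — × π₁ ∈ {0.01, 0.05, 0.10, 0.25} × 3
variance regimes × 2 rescaling factors × 2 input specifications = 144
initial scenarios, plus an EV-only extension π₁ ∈ {0.005, 0.02, 0.03,
0.04} (48 scenarios), 192 in total, nominally 20 replicates each.
Reproducibility: every replicate's random stream derives from
SeedSequence([master_seed, crc32(scenario_key), replicate]), so any single
result row can be regenerated in isolation.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the pipeline at the design's
native gene count (G = 10,000, B = 100 permutations) but with reduced
replicate counts (5–20 depending on the check) and a reduced scenario
subset (EV at the three anchor π₁ values), chosen so the whole suite
completes in minutes while medians over replicates remain stable. The
complete 192 × 20 factorial is available through
`run_study(scenario_grid("full"), replicates=20, ...)` or
`pi1bench study --stage full --replicates 20` and is a long-running mode.

## Known limitations

* The empirical-null scale fit assumes the signal lies mostly outside the
  central 80% of |statistics|; with dense weak signal the scale inflates
  and the method turns conservative (this mirrors its behaviour in the
  literature — conservative bias at high π₁ is the expected failure mode,
  and the benchmark reproduces it).
* Pooled-null P-values are only approximately uniform per gene under
  heteroscedasticity across genes; the add-one correction makes them
  (harmlessly) conservative at the far tail.
* `estimate_pi0_empirical_null` refuses inputs with fewer than 200 finite
  statistics; the censored fit is unstable below that.
* The smoother method's π̂₀ can reach the clip bounds on tiny inputs; the
  NPMLE is the more stable default.
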