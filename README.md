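# pi1bench

Estimating **π₁ — the proportion of differentially expressed (DE) genes** —
and hence the false discovery rate, in two-group expression studies, plus
the simulation machinery to benchmark the estimators against each other.

## The problem

A two-group microarray-style study tests every gene for a difference in mean
expression. FDR estimators of the mixture-model family all reduce to

> FDR̂(α) = α · π̂₀ / F̂(α),  π̂₀ = 1 − π̂₁,

where F̂(α) is the observed fraction of P-values below the threshold α. The
whole game is estimating π₀. This package implements and compares two routes:

1. **Statistic-based (empirical-null):** work directly on test statistics,
   skipping P-values. Per-gene SAM s-statistics
   s = (X̄₁ − X̄₂) / (δ + √(s₁²/n₁ + s₂²/n₂)) — the Welch t-statistic with a
   stabilizing constant δ (a percentile of the t-denominators: families s30,
   s50, s70, s90) — are rescaled by SD or IQR to the t-statistic spread,
   a null scale σ̂ is fitted to the central bulk of |statistics| by censored
   maximum likelihood (half-normal null for a z input specification, scaled
   t(df) for a t specification), and π̂₀ is read off the Grenander
   (nonincreasing-density NPMLE) estimate of the resulting null P-values
   near p = 1.
2. **P-value-based (mixture models):** pool the permutation statistics of
   *all* genes into one empirical null; the resulting "pooled null"
   two-sided P-values are monotone in |statistic|. Then estimate π₀ by
   either the smoother method (π̂₀(λ) = #{p > λ}/((1−λ)G) smoothed over a λ
   grid by a df-3 natural cubic spline) or the convex decreasing density
   NPMLE (π̂₀ = f̂(1) of the maximum-likelihood mixture of the uniform and
   triangular densities).

A synthetic two-population gene-parameter generator (means rounded to the
nearest 0.1 so "differentially expressed" is exact; log-normal per-gene
standard deviations) drives the benchmark factorial: sample sizes
(60,45)/(16,12)/(8,6), variance regimes EV/UV1/UV2, a π₁ grid, two rescaling
factors and two input specifications — 144 initial + 48 extended = 192
scenarios, 20 replicates each.

## Worked example

```python
from pi1bench import (ScenarioConfig, synth_parameter_table, simulate_dataset,
                      group_summaries, statistics_for_family, permutation_labels,
                      pooled_null_statistics, pooled_null_pvalues,
                      estimate_pi0_convest)

params = synth_parameter_table(G=5000, pi1=0.10, seed=11)
cfg = ScenarioConfig(sim_type="EV", n1=60, n2=45, pi1=0.10, G=5000)
sim = simulate_dataset(params, cfg, seed=12)
s50 = statistics_for_family(group_summaries(sim.data), 60, 45, "s50")
labels = permutation_labels(60, 45, B=100, seed=13)
null = pooled_null_statistics(sim.data, family="s50", labels=labels)
pvals = pooled_null_pvalues(s50, null)
print(estimate_pi0_convest(pvals)[0].pi1)
```

prints `0.0908...`: the convex-density NPMLE recovers the simulated
π₁ = 0.10 to about one point. `examples/` walks through each capability
(statistics and rescaling, pooled nulls, the three estimators, FDR and ROC,
a miniature study); `examples/03_estimate_pi1.py` prints, for the same
dataset,

```
true pi1 = 0.1
storey  pi1-hat = 0.1145
convest pi1-hat = 0.0908
empirical-null pi1-hat = 0.1257 (fitted null scale 0.928)
```

— three routes to the same target, with the P-value-based NPMLE typically
the least biased and least variable across the factorial.

A thin CLI mirrors the library for shell use:

```bash
pi1bench simulate --sim-type EV --n1 16 --n2 12 --pi1 0.1 --genes 2000 \
    --seed 7 --out data.tsv --truth truth.tsv
pi1bench pvalues --input data.tsv --group-sizes 16,12 --family s50 \
    --permutations 100 --seed 7 --out pvals.csv
pi1bench pi1 --pvals pvals.csv --method convest
```

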