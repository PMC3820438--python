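"""Run a miniature estimator-comparison study and summarize bias.

One EV scenario, a few replicates: simulate, compute all five statistic
families, build pooled nulls, run all three estimators, and report
median / IQR / bias of the pi1 estimates per (family, estimator) cell.
"""

import pandas as pd

from pi1bench import ScenarioConfig, run_study, summarize_bias

grid = [ScenarioConfig(sim_type="EV", n1=16, n2=12, pi1=0.10, G=1000)]
results = run_study(grid, replicates=3, B=100, master_seed=42)
summary = summarize_bias(results)

pd.set_option("display.width", 120)
cols = ["family", "estimator", "median_pi1_hat", "iqr_pi1_hat", "bias", "direction"]
print(summary[cols].to_string(index=False))
# Negative bias = conservative (pi1 underestimated).  With only 3
# replicates and 1,000 genes this is a smoke-scale picture of the full
# 192-scenario x 20-replicate factorial.
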