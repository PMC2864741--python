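"""Fit a presence-only maximum-entropy niche model and evaluate it.

Presences are drawn from a known strong niche; the model is fitted against
a uniform background sample, evaluated by 10-fold cross-validated AUC, and
interrogated through permutation variable importance and a response curve.
AUC ~0.87 means a presence cell outranks a random background cell 87% of
the time; the Spearman correlation against the generating truth shows how
faithfully the suitability ranking was recovered.
"""

import numpy as np
from scipy import stats

import landuse_enm as le

cfg = le.LandscapeConfig(n_rows=200, n_cols=200, seed=1)
stack, _, s_true = le.synth_landscape(cfg, le.strong_niche())
points = le.sample_presences(s_true, 200, seed=11)
presences = le.extract_at_points(stack, points)
presences = presences[presences["valid"]].reset_index(drop=True)
background = le.build_background(stack, 10_000, seed=21)

model = le.fit_maxent(presences, background)
raw = le.predict_raw(model, stack)
logistic = le.to_logistic(raw)

evaluation = le.crossval_auc(presences, background, k=10, seed=31)
print(f"10-fold mean AUC: {evaluation.mean_auc:.3f}")

mask = ~s_true.mask_nodata()
rho = stats.spearmanr(logistic.grid.values[mask], s_true.values[mask]).statistic
print(f"Spearman(fitted, true suitability): {rho:.3f}")

contrib = le.variable_contributions(presences, background, n_runs=5, seed=41)
print("permutation importance:",
      {k: round(v, 3) for k, v in sorted(contrib.items(), key=lambda kv: -kv[1])})

curve = le.response_curve(model, "precipitation", n_steps=7)
print("\npartial response to precipitation (logistic suitability):")
print(curve.round(3).to_string(index=False))

# cumulative output is the thresholding currency: a cell at cumulative 0.18
# outranks all background cells holding the lowest 18% of total probability
cumulative = le.to_cumulative(raw)
binary = le.apply_threshold(cumulative, 0.18)
print(f"\npredicted presence at threshold 0.18: "
      f"{100 * binary.valid_values().mean():.1f}% of cells")
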