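"""Map shared suitability (ISS) between two landuse types and compare a
binary model prediction against a reference classification.

ISS is high only where both landuse types are well suited AND similar —
the zones where competition over the "best" use of the land is plausible.
The deviation map cross-tabulates model presence/absence against the
reference: codes 2 (model-only) and 3 (reference-only) mark disagreement.
"""

import numpy as np

import landuse_enm as le

cfg = le.LandscapeConfig(n_rows=100, n_cols=100, seed=5)
stack, _, _ = le.synth_landscape(cfg)

names = list(stack.continuous)
agriculture = le.TrueNiche(linear={names[0]: 1.5, names[1]: 2.0},
                           quadratic={names[1]: -0.8}, intercept=-1.0)
pastoralism = le.TrueNiche(linear={names[0]: 1.8, names[1]: -1.0}, intercept=-1.0)

s_agr = agriculture.suitability(stack)
s_pas = pastoralism.suitability(stack)

from landuse_enm.niche import SuitabilitySurface
iss = le.compute_iss(SuitabilitySurface(s_agr, "logistic"),
                     SuitabilitySurface(s_pas, "logistic"),
                     lut1_name="agriculture", lut2_name="pastoralism")
v = iss.grid.valid_values()
print(f"ISS ({iss.formula}): mean={v.mean():.3f}, max={v.max():.3f}, "
      f"share above 0.5: {100 * (v > 0.5).mean():.1f}%")
print("high-ISS cells are candidates for landuse conflict zones")

model_binary = s_agr.like((s_agr.values >= 0.5).astype(float))
reference = s_pas.like((s_pas.values >= 0.5).astype(float))
dev = le.deviation_map(model_binary, reference)
labels = {0: "agree-absence", 1: "agree-presence", 2: "model-only", 3: "reference-only"}
print("\ndeviation counts:")
for code, count in dev.counts.items():
    print(f"  {labels[code]:>15}: {count}")
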