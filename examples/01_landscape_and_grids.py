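"""Generate a synthetic landscape and move rasters through ESRI ASCII files.

The landscape is the package's stand-in for a climate + soil covariate
stack: spatially autocorrelated continuous fields and a patchy categorical
soil layer, plus a known "true" suitability surface for one landuse type.
"""

import tempfile
from pathlib import Path

import landuse_enm as le

cfg = le.LandscapeConfig(n_rows=80, n_cols=80, seed=42)
stack, niche, s_true = le.synth_landscape(cfg)

print("covariates:", ", ".join(stack.variable_names))
print(f"soil classes: {sorted(set(stack.categorical.valid_values()))}")
print(f"true suitability: mean={s_true.valid_values().mean():.3f}, "
      f"max={s_true.valid_values().max():.3f}")

with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "suitability.asc"
    le.write_ascii_grid(s_true, path)
    back = le.read_ascii_grid(path)
    exact = (back.values == s_true.values).all()
    print(f"wrote {path.name} ({path.stat().st_size} bytes); "
          f"round trip exact: {exact}")

# A sample of random cells is the raw material for background points and
# for the regression sample; values are cell-center coordinates plus the
# covariates at each cell.
sample = le.sample_random_cells(stack, 5, seed=7)
print("\nfive random cells:")
print(sample.round(3).to_string(index=False))
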