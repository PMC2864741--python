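import numpy as np
import pytest

import landuse_enm as le


@pytest.fixture(scope="session")
def small_world():
    """A 60x60 landscape with the canonical strong niche, presences and
    background — shared by model-level tests."""
    cfg = le.LandscapeConfig(n_rows=60, n_cols=60, seed=11)
    stack, niche, strue = le.synth_landscape(cfg, le.strong_niche())
    pts = le.sample_presences(strue, 150, 12)
    pres = le.extract_at_points(stack, pts)
    pres = pres[pres["valid"]].reset_index(drop=True)
    bg = le.build_background(stack, 2000, 13)
    return {"stack": stack, "niche": niche, "true": strue,
            "presences": pres, "background": bg}


@pytest.fixture(scope="session")
def fitted_model(small_world):
    model = le.fit_maxent(small_world["presences"], small_world["background"])
    raw = le.predict_raw(model, small_world["stack"])
    return {"model": model, "raw": raw}


def random_grid(rng, max_side=12, with_nodata=True, integers=False):
    nr = int(rng.integers(1, max_side))
    nc = int(rng.integers(1, max_side))
    if integers:
        vals = rng.integers(-50, 50, size=(nr, nc)).astype(float)
    else:
        vals = rng.normal(0, 10, size=(nr, nc))
    nodata = -9999.0
    if with_nodata and nr * nc > 1 and rng.random() < 0.7:
        k = int(rng.integers(1, nr * nc))
        idx = rng.choice(nr * nc, k, replace=False)
        vals.ravel()[idx] = nodata
    return le.Grid(vals, x_ll=float(rng.uniform(-180, 90)),
                   y_ll=float(rng.uniform(-60, 30)),
                   cell_size=float(rng.uniform(0.01, 2.0)), nodata=nodata)
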