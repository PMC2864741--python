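"""Synthetic landscapes with known ground truth.

Generates everything the analysis consumes — spatially autocorrelated
continuous covariates, a patchy categorical soil layer, presence records
drawn from a known suitability surface, population surfaces following a
two-segment (breakpoint) relation on the log10(x+1) scale, and conflict
points whose occurrence probability rises with shared suitability — so
that every downstream estimator can be tested for parameter recovery.

Continuous fields are built by convolving white noise with a Gaussian
kernel of bandwidth ``range_param`` (in cell units) on a padded array, so
autocorrelation decays with distance at that scale without wrap-around
artifacts. Soil classes come from quantile-slicing an auxiliary random
field, which yields spatially coherent patches rather than i.i.d. codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .grids import CovariateStack, Grid

__all__ = [
    "FieldSpec",
    "LandscapeConfig",
    "TrueNiche",
    "PopulationParams",
    "ConflictParams",
    "gaussian_random_field",
    "synth_landscape",
    "sample_presences",
    "synth_population",
    "synth_conflicts",
]


@dataclass
class FieldSpec:
    """One continuous covariate: name, autocorrelation range (cells), mean, sd."""

    name: str
    autocorrelation_range: float = 8.0
    mean: float = 0.0
    sd: float = 1.0


@dataclass
class LandscapeConfig:
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 0.05
    seed: int = 0
    continuous_fields: list[FieldSpec] = field(
        default_factory=lambda: [FieldSpec("temperature", 8.0, 15.0, 8.0),
                                 FieldSpec("precipitation", 8.0, 1000.0, 400.0)]
    )
    n_soil_classes: int = 4
    soil_range: float = 12.0

    def __post_init__(self) -> None:
        if self.n_soil_classes < 2:
            raise ValueError("n_soil_classes must be >= 2")
        for f in self.continuous_fields:
            if f.autocorrelation_range < 0:
                raise ValueError("autocorrelation_range must be >= 0")


@dataclass
class TrueNiche:
    """Ground-truth suitability: logistic(linear predictor) over the stack.

    ``linear`` and ``quadratic`` hold per-covariate coefficients applied to
    the standardized covariate (z-score over valid cells); ``soil_offsets``
    maps soil codes to additive offsets; unlisted codes contribute 0.
    """

    linear: dict[str, float] = field(default_factory=dict)
    quadratic: dict[str, float] = field(default_factory=dict)
    soil_offsets: dict[int, float] = field(default_factory=dict)
    intercept: float = 0.0

    def suitability(self, stack: CovariateStack) -> Grid:
        """Evaluate true suitability s* in (0,1) on every valid cell."""
        ref = stack.reference
        eta = np.full(ref.values.shape, self.intercept, dtype=float)
        for name, g in stack.continuous.items():
            valid = g.valid_values()
            z = (g.values - valid.mean()) / valid.std()
            eta += self.linear.get(name, 0.0) * z
            eta += self.quadratic.get(name, 0.0) * z**2
        if stack.categorical is not None and self.soil_offsets:
            codes = stack.categorical.values
            offs = np.zeros_like(eta)
            for code, off in self.soil_offsets.items():
                offs[codes == code] = off
            eta += offs
        s = expit(eta)
        out = ref.like(s)
        out.values[stack.mask_nodata()] = out.nodata
        return out


@dataclass
class PopulationParams:
    """Breakpoint relation on the log10(population + 1) scale.

    y = a + b*min(s, c) + d*max(s - c, 0) + Normal(0, sigma); the mean
    function is continuous at the knot c.
    """

    a: float = 0.2
    b: float = 6.0
    c: float = 0.3
    d: float = 0.5
    sigma: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 < self.c < 1.0):
            raise ValueError("breakpoint c must lie strictly inside (0,1)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def mean_log10(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.a + self.b * np.minimum(s, self.c) + self.d * np.maximum(s - self.c, 0.0)


@dataclass
class ConflictParams:
    """Logistic model for conflict occurrence given shared suitability."""

    alpha: float = -2.5
    beta: float = 5.0
    n_points: int = 500

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


def strong_niche(covariates: list[str] | None = None, n_soil_classes: int = 4) -> TrueNiche:
    """A concentrated ground-truth niche for recovery experiments.

    Strong linear effects on both covariates, a unimodal (negative
    quadratic) response on the second, alternating soil offsets, and a low
    intercept so that high suitability is confined to a small fraction of
    the landscape — the regime in which presence-only modelling is
    informative (background prevalence ~0.15).
    """
    covariates = covariates or ["temperature", "precipitation"]
    c0, c1 = covariates[0], covariates[-1]
    return TrueNiche(
        linear={c0: 3.0, c1: 3.5},
        quadratic={c1: -1.5},
        soil_offsets={i: (1.0 if i % 2 == 0 else -1.0) for i in range(1, n_soil_classes + 1)},
        intercept=-3.5,
    )


def gaussian_random_field(n_rows: int, n_cols: int, range_param: float, seed: int,
                          template: Grid | None = None) -> Grid:
    """Zero-mean, unit-variance random field with autocorrelation scale
    ``range_param`` (cells). ``range_param = 0`` gives independent cells.

    The field is white noise convolved with a Gaussian kernel of standard
    deviation ``range_param / 2`` on a padded array (no wrap-around), which
    gives the field itself the correlation function exp(-(d/range)^2):
    correlation falls to 1/e at distance ``range_param``.
    """
    if range_param < 0:
        raise ValueError("range_param must be >= 0")
    rng = np.random.default_rng(seed)
    if range_param == 0:
        vals = rng.standard_normal((n_rows, n_cols))
    else:
        sigma = range_param / 2.0
        pad = int(np.ceil(4 * sigma))
        noise = rng.standard_normal((n_rows + 2 * pad, n_cols + 2 * pad))
        smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="constant")
        vals = smooth[pad:pad + n_rows, pad:pad + n_cols]
        vals = (vals - vals.mean()) / vals.std()
    if template is not None:
        return template.like(vals)
    return Grid(vals)


def synth_landscape(config: LandscapeConfig,
                    niche: TrueNiche | None = None) -> tuple[CovariateStack, TrueNiche, Grid]:
    """Generate a covariate stack plus ground-truth suitability.

    Returns ``(stack, niche, true_suitability)``. If no niche is supplied a
    default strong niche is used: positive linear + negative quadratic on
    the first covariate (unimodal response), positive linear on the second,
    and alternating soil offsets.
    """
    rng = np.random.default_rng(config.seed)
    template = Grid(np.zeros((config.n_rows, config.n_cols)), cell_size=config.cell_size)
    continuous: dict[str, Grid] = {}
    for spec in config.continuous_fields:
        sub = int(rng.integers(0, 2**31 - 1))
        f = gaussian_random_field(config.n_rows, config.n_cols, spec.autocorrelation_range,
                                  sub, template)
        continuous[spec.name] = template.like(spec.mean + spec.sd * f.values)
    soil_seed = int(rng.integers(0, 2**31 - 1))
    aux = gaussian_random_field(config.n_rows, config.n_cols, config.soil_range, soil_seed)
    qs = np.quantile(aux.values, np.linspace(0, 1, config.n_soil_classes + 1)[1:-1])
    codes = np.digitize(aux.values, qs) + 1  # codes 1..n_soil_classes
    categorical = template.like(codes.astype(float))
    stack = CovariateStack(continuous=continuous, categorical=categorical,
                           category_labels={i: f"soil_{i}" for i in range(1, config.n_soil_classes + 1)})
    if niche is None:
        names = list(continuous)
        niche = TrueNiche(
            linear={names[0]: 1.5} | ({names[1]: 1.0} if len(names) > 1 else {}),
            quadratic={names[0]: -1.0},
            soil_offsets={i: (0.6 if i % 2 == 0 else -0.6) for i in range(1, config.n_soil_classes + 1)},
            intercept=-0.5,
        )
    return stack, niche, niche.suitability(stack)


def sample_presences(true_suitability: Grid, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` presence cells without replacement, with probability
    proportional to suitability. Points are placed at cell centers."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = true_suitability.mask_nodata()
    rows, cols = np.nonzero(~mask)
    weights = true_suitability.values[rows, cols].astype(float)
    positive = weights > 0
    if n > positive.sum():
        raise ValueError(f"requested {n} presences but only {int(positive.sum())} cells have weight > 0")
    rng = np.random.default_rng(seed)
    p = weights / weights.sum()
    idx = rng.choice(rows.size, size=n, replace=False, p=p)
    lon, lat = true_suitability.cell_centers(rows[idx], cols[idx])
    return pd.DataFrame({"lon": lon, "lat": lat, "label": "presence"})


def synth_population(suitability: Grid, p: PopulationParams, seed: int) -> Grid:
    """Population surface from the breakpoint relation, back-transformed.

    Per valid cell: y = mean_log10(s) + Normal(0, sigma) on the log10(x+1)
    scale; the returned grid holds 10**y - 1, floored at 0 (zero-population
    cells are retained, not masked).
    """
    rng = np.random.default_rng(seed)
    mask = suitability.mask_nodata()
    y = p.mean_log10(suitability.values)
    if p.sigma > 0:
        y = y + rng.normal(0.0, p.sigma, size=y.shape)
    pop = np.maximum(10.0**y - 1.0, 0.0)
    out = suitability.like(pop)
    out.values[mask] = out.nodata
    return out


def synth_conflicts(iss: Grid, p: ConflictParams, seed: int) -> pd.DataFrame:
    """Sample localities uniformly and label them conflict / no-conflict.

    Each of ``n_points`` uniformly drawn valid cells is labeled "conflict"
    with probability logistic(alpha + beta * ISS(cell)).
    """
    rng = np.random.default_rng(seed)
    mask = iss.mask_nodata()
    rows, cols = np.nonzero(~mask)
    if p.n_points > rows.size:
        raise ValueError(f"requested {p.n_points} points but only {rows.size} valid cells exist")
    idx = rng.choice(rows.size, size=p.n_points, replace=False)
    iss_vals = iss.values[rows[idx], cols[idx]]
    prob = expit(p.alpha + p.beta * iss_vals)
    labels = np.where(rng.random(p.n_points) < prob, "conflict", "no_conflict")
    lon, lat = iss.cell_centers(rows[idx], cols[idx])
    return pd.DataFrame({"lon": lon, "lat": lat, "label": labels, "iss": iss_vals})
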