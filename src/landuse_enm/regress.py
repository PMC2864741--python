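"""Linear, breakpoint, and logistic regression with AIC comparison.

Population and wealth responses are analysed on the log10(x+1) scale. The
breakpoint (segmented) model is the continuous two-segment mean function

    y = a + b*min(x, c) + d*max(x - c, 0),

with four mean parameters (a, b, c, d); the knot c is found by exhaustive
grid search over the predictor's [5th, 95th] percentile range, which is
deterministic and, because the conditional fit given c is ordinary least
squares, exact up to the grid resolution. AIC uses the Gaussian
likelihood with the error variance counted as a parameter (k = 3 for the
linear model, k = 5 for the breakpoint model), so nested fits on the same
response are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import Grid
from .niche import SuitabilitySurface

__all__ = [
    "LinearFit",
    "BreakpointFit",
    "LogisticFit",
    "log10p1",
    "inv_log10p1",
    "linear_fit",
    "breakpoint_fit",
    "compare_aic",
    "logistic_fit",
    "predict_surface",
    "residual_map",
]


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    # profile Gaussian log-likelihood; k counts mean parameters + variance
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return float(2 * k - 2 * ll)


@dataclass
class LinearFit:
    intercept: float
    slope: float
    r2: float
    aic: float
    n: int
    residuals: np.ndarray = field(repr=False)
    k: int = 3

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class BreakpointFit:
    a: float  # intercept
    b: float  # slope below the knot
    c: float  # knot location
    d: float  # slope above the knot
    r2: float
    aic: float
    n: int
    residuals: np.ndarray = field(repr=False)
    k: int = 5

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a + self.b * np.minimum(x, self.c) + self.d * np.maximum(x - self.c, 0.0)


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    chi2: float          # model chi-square, 2*(LL_model - LL_null)
    chi2_p: float
    accuracy: float      # fraction correct at probability 0.5
    n: int
    converged: bool
    separation_flag: bool = False

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xc = sm.add_constant(X, has_constant="add")
        eta = Xc.to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def log10p1(values: np.ndarray) -> np.ndarray:
    """Elementwise log10(x + 1); the transform used for population and GDP."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("log10p1 requires non-negative input")
    return np.log10(v + 1.0)


def inv_log10p1(values: np.ndarray) -> np.ndarray:
    """Back-transform: 10**y - 1."""
    return 10.0 ** np.asarray(values, dtype=float) - 1.0


def linear_fit(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least squares of y on x with Gaussian AIC (k = 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: singular design")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return LinearFit(float(beta[0]), float(beta[1]), r2, _gaussian_aic(rss, n, 3), n, resid)


def _segment_design(x: np.ndarray, c: float) -> np.ndarray:
    return np.column_stack([np.ones(x.size), np.minimum(x, c), np.maximum(x - c, 0.0)])


def breakpoint_fit(x: np.ndarray, y: np.ndarray,
                   c_grid: np.ndarray | str = "auto",
                   resolution: float = 0.005,
                   min_side: int = 3) -> BreakpointFit:
    """Continuous two-segment regression with grid-searched knot.

    ``c_grid='auto'`` scans the [5th, 95th] percentile range of x at the
    given resolution; ties in residual sum of squares resolve to the
    smallest candidate knot. Candidates with fewer than ``min_side``
    observations strictly on either side are skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if isinstance(c_grid, str):
        lo, hi = np.quantile(x, [0.05, 0.95])
        c_grid = np.arange(lo, hi + resolution / 2, resolution)
    else:
        c_grid = np.asarray(c_grid, dtype=float)
    best: tuple[float, float, np.ndarray] | None = None  # (rss, c, beta)
    for c in c_grid:
        if (x < c).sum() < min_side or (x > c).sum() < min_side:
            continue
        X = _segment_design(x, c)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        if best is None or rss < best[0] - 1e-12:
            best = (rss, float(c), beta)
    if best is None:
        raise ValueError("no identifiable knot: too few points on either side "
                         "of every candidate")
    rss, c, beta = best
    resid = y - _segment_design(x, c) @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return BreakpointFit(float(beta[0]), float(beta[1]), c, float(beta[2]),
                         r2, _gaussian_aic(rss, n, 5), n, resid)


def compare_aic(fits: list) -> pd.DataFrame:
    """Rank fits on the same response by AIC; reports delta-AIC to the best."""
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits use different sample sizes: {sorted(ns)}")
    rows = [{"model": type(f).__name__, "k": f.k, "aic": f.aic, "r2": f.r2,
             "index": i} for i, f in enumerate(fits)]
    out = pd.DataFrame(rows).sort_values(["aic", "index"], kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    return out


def logistic_fit(X: pd.DataFrame, y: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald tests.

    Perfect separation is flagged on the result rather than raised.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    X = pd.DataFrame(X)
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception:
            # perfect (or quasi-) separation: fall back to the IRLS fit GLM
            # uses, which walks toward the boundary instead of raising
            separation = True
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100)
    if not separation and np.any(~np.isfinite(res.bse)):
        separation = True
    null_ll = sm.Logit(y, np.ones_like(y)).fit(disp=0).llf
    chi2 = float(2.0 * (res.llf - null_ll))
    from scipy.stats import chi2 as chi2_dist
    chi2_p = float(chi2_dist.sf(chi2, df=X.shape[1]))
    pred = (res.predict(Xc) >= 0.5).astype(float)
    acc = float((pred == y).mean())
    bse = pd.Series(res.bse, index=Xc.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = pd.Series(res.params, index=Xc.columns) / bse
    from scipy.stats import norm
    pvals = pd.Series(2 * norm.sf(np.abs(z)), index=Xc.columns)
    return LogisticFit(pd.Series(res.params, index=Xc.columns), bse, z, pvals,
                       chi2, chi2_p, acc, y.size,
                       bool(getattr(res, "mle_retvals", {}).get("converged", True)),
                       separation)


def predict_surface(fit: LinearFit | BreakpointFit,
                    suitability: SuitabilitySurface | Grid) -> Grid:
    """Extrapolate a fit (trained on the log10(x+1) scale) to a suitability
    grid, re-exponentiate, and floor at zero people per cell."""
    grid = suitability.grid if isinstance(suitability, SuitabilitySurface) else suitability
    mask = grid.mask_nodata()
    pred_log = fit.predict(grid.values)
    pred = np.maximum(inv_log10p1(pred_log), 0.0)
    out = grid.like(pred)
    out.values[mask] = out.nodata
    return out


def residual_map(observed: Grid, predicted: Grid) -> Grid:
    """Observed minus predicted on the natural (people per km^2) scale.

    Because the mean model was fitted to log-transformed data, the
    back-transformed residual distribution is asymmetric (larger positive
    than negative residuals); that is a property of the scale, not a bias.
    """
    if not observed.congruent_with(predicted):
        raise ValueError("grids are not congruent")
    mask = observed.mask_nodata() | predicted.mask_nodata()
    out = observed.like(observed.values - predicted.values)
    out.values[mask] = out.nodata
    return out
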