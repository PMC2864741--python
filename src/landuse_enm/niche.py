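"""Presence-only maximum-entropy suitability modelling.

The model is the Gibbs distribution over a background sample of cells,

    q_lambda(i) = exp(lambda . f(i)) / Z(lambda),

whose feature weights ``lambda`` minimize the regularized negative mean
log-likelihood of the presence cells,

    -mean_p [lambda . f(p)] + log Z(lambda) + sum_j beta_j |lambda_j|,

a convex problem solved here by L-BFGS-B on the split lambda = lambda+ -
lambda- with non-negativity bounds. Features are linear and quadratic
terms of each continuous covariate rescaled to [0,1] on the background,
plus one indicator per observed class of the categorical covariate.
Per-feature penalties follow the standard Maxent convention
``beta_j = beta * s_j / sqrt(m)`` with ``s_j`` the background standard
deviation of feature j and ``m`` the number of presences, so ``beta`` is
a single dimensionless regularization knob (default 1.0).

Three output flavors are provided: *raw* (Gibbs probabilities summing to
one over the background), *cumulative* (the summed raw probability of all
background cells scoring at or below a cell, a rank-like [0,1] score used
for thresholding), and *logistic* (``e^H r / (1 + e^H r)`` with H the
entropy of the fitted distribution, which maps a typical background cell
to 0.5 and is read as a probability of occurrence, i.e. "suitability").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grids import CovariateStack, Grid, sample_random_cells

__all__ = [
    "FeatureExpansion",
    "MaxentModel",
    "SuitabilitySurface",
    "ModelEvaluation",
    "build_background",
    "fit_maxent",
    "predict_raw",
    "to_cumulative",
    "to_logistic",
    "auc_score",
    "crossval_auc",
    "variable_contributions",
    "response_curve",
    "apply_threshold",
]

_META_COLS = {"row", "col", "lon", "lat", "label", "inside", "valid"}


@dataclass
class FeatureExpansion:
    """Deterministic covariate -> feature mapping, frozen at fit time.

    Continuous covariates are min-max rescaled to [0,1] on the background
    (values outside the background range are clamped) and expanded into a
    linear and a quadratic feature; the categorical covariate becomes one
    indicator per class observed in the background or presences.
    """

    continuous_vars: list[str]
    categorical_var: str | None
    mins: dict[str, float]
    maxs: dict[str, float]
    classes: list[int] = field(default_factory=list)
    background_means: dict[str, float] = field(default_factory=dict)
    categorical_mode: int | None = None

    @classmethod
    def from_tables(cls, background: pd.DataFrame, presences: pd.DataFrame,
                    categorical_var: str | None = "soil") -> "FeatureExpansion":
        cont = [c for c in background.columns
                if c not in _META_COLS and c != categorical_var]
        if categorical_var is not None and categorical_var not in background.columns:
            categorical_var = None
        mins = {c: float(background[c].min()) for c in cont}
        maxs = {c: float(background[c].max()) for c in cont}
        classes: list[int] = []
        mode = None
        if categorical_var is not None:
            observed = np.union1d(background[categorical_var].to_numpy(),
                                  presences[categorical_var].to_numpy())
            classes = [int(v) for v in observed]
            counts = background[categorical_var].value_counts()
            mode = int(counts.idxmax())
        means = {c: float(background[c].mean()) for c in cont}
        return cls(cont, categorical_var, mins, maxs, classes, means, mode)

    @property
    def feature_names(self) -> list[str]:
        names = []
        for c in self.continuous_vars:
            names += [f"{c}:linear", f"{c}:quadratic"]
        names += [f"{self.categorical_var}=={k}" for k in self.classes]
        return names

    @property
    def variables(self) -> list[str]:
        out = list(self.continuous_vars)
        if self.categorical_var is not None:
            out.append(self.categorical_var)
        return out

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Feature matrix (n, k); all features lie in [0,1]."""
        cols = []
        for c in self.continuous_vars:
            lo, hi = self.mins[c], self.maxs[c]
            span = hi - lo if hi > lo else 1.0
            u = np.clip((table[c].to_numpy(dtype=float) - lo) / span, 0.0, 1.0)
            cols += [u, u**2]
        if self.categorical_var is not None:
            v = table[self.categorical_var].to_numpy()
            known = set(self.classes)
            seen = set(int(x) for x in np.unique(v[np.isfinite(v)]))
            unseen = seen - known
            if unseen:
                warnings.warn(f"unseen categorical class(es) {sorted(unseen)}: "
                              "indicators fall back to all-zero baseline")
            for k in self.classes:
                cols.append((v == k).astype(float))
        return np.column_stack(cols) if cols else np.zeros((len(table), 0))


@dataclass
class MaxentModel:
    """Fitted maximum-entropy niche model."""

    expansion: FeatureExpansion
    lam: np.ndarray
    beta: float
    log_z: float            # log normalizer over the fitted background
    entropy: float          # entropy H of the fitted Gibbs distribution
    n_background: int
    bg_raw_sorted: np.ndarray  # sorted raw probabilities over the background
    converged: bool = True
    n_iter: int = 0

    def raw_scores(self, table: pd.DataFrame) -> np.ndarray:
        """Raw Gibbs probability exp(lambda.f - log Z) per table row."""
        F = self.expansion.transform(table)
        return np.exp(F @ self.lam - self.log_z)

    def logistic_scores(self, table: pd.DataFrame) -> np.ndarray:
        r = self.raw_scores(table) * np.exp(self.entropy)
        return r / (1.0 + r)

    # -- persistence (structured text) -----------------------------------
    def to_dict(self) -> dict:
        e = self.expansion
        return {
            "expansion": {
                "continuous_vars": e.continuous_vars,
                "categorical_var": e.categorical_var,
                "mins": e.mins, "maxs": e.maxs, "classes": e.classes,
                "background_means": e.background_means,
                "categorical_mode": e.categorical_mode,
            },
            "lambda": self.lam.tolist(),
            "beta": self.beta,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "n_background": self.n_background,
            "bg_raw_sorted": self.bg_raw_sorted.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "MaxentModel":
        with open(path) as fh:
            d = json.load(fh)
        e = d["expansion"]
        expansion = FeatureExpansion(
            e["continuous_vars"], e["categorical_var"], e["mins"], e["maxs"],
            e["classes"], e["background_means"], e["categorical_mode"])
        return cls(expansion, np.asarray(d["lambda"]), d["beta"], d["log_z"],
                   d["entropy"], d["n_background"], np.asarray(d["bg_raw_sorted"]),
                   d["converged"], d["n_iter"])


@dataclass
class SuitabilitySurface:
    """A suitability grid plus the flavor it is expressed in.

    Raw surfaces carry the background raw-score distribution and entropy
    needed by the cumulative and logistic transforms.
    """

    grid: Grid
    flavor: str  # "raw" | "cumulative" | "logistic"
    bg_raw_sorted: np.ndarray | None = None
    entropy: float | None = None

    def __post_init__(self) -> None:
        if self.flavor not in ("raw", "cumulative", "logistic"):
            raise ValueError(f"unknown flavor {self.flavor!r}")


@dataclass
class ModelEvaluation:
    fold_aucs: list[float]
    mean_auc: float
    contributions: dict[str, float] | None = None
    n_runs: int = 0


def build_background(stack: CovariateStack, n_background: int = 10_000,
                     seed: int = 0) -> pd.DataFrame:
    """Uniform random sample of non-nodata cells (or all of them if fewer
    than ``n_background`` exist)."""
    rows, cols = stack.valid_indices()
    n = min(n_background, rows.size)
    return sample_random_cells(stack, n, seed)


def _nll_and_grad(theta: np.ndarray, Fp_mean: np.ndarray, Fb: np.ndarray,
                  penalty: np.ndarray) -> tuple[float, np.ndarray]:
    k = Fp_mean.size
    lam = theta[:k] - theta[k:]
    eta = Fb @ lam
    lz = logsumexp(eta)
    q = np.exp(eta - lz)
    nll = -(Fp_mean @ lam) + lz
    grad = -Fp_mean + Fb.T @ q
    obj = nll + penalty @ (theta[:k] + theta[k:])
    g = np.concatenate([grad + penalty, -grad + penalty])
    return obj, g


def fit_maxent(presences: pd.DataFrame, background: pd.DataFrame,
               beta: float = 1.0, max_iter: int = 500, tol: float = 1e-8,
               categorical_var: str | None = "soil",
               x0: np.ndarray | None = None) -> MaxentModel:
    """Fit the L1-regularized maximum-entropy model.

    ``presences`` and ``background`` are covariate tables (as produced by
    :func:`~landuse_enm.grids.extract_at_points` and
    :func:`build_background`); metadata columns are ignored.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if len(presences) < 5:
        raise ValueError("need at least 5 presence records")
    expansion = FeatureExpansion.from_tables(background, presences, categorical_var)
    Fp = expansion.transform(presences)
    Fb = expansion.transform(background)
    if not (np.isfinite(Fp).all() and np.isfinite(Fb).all()):
        raise ValueError("non-finite covariate values in presences or background")
    k = Fp.shape[1]
    m = len(presences)
    s = Fb.std(axis=0)
    penalty = beta * np.maximum(s, 1e-3) / np.sqrt(m)
    Fp_mean = Fp.mean(axis=0)
    theta0 = np.zeros(2 * k) if x0 is None else np.concatenate(
        [np.maximum(x0, 0), np.maximum(-x0, 0)])
    res = minimize(_nll_and_grad, theta0, args=(Fp_mean, Fb, penalty),
                   jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * k),
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10})
    # restarting from the solution resets the Hessian approximation and
    # escapes the flat-progress stalls L-BFGS-B is prone to near kinks
    for _ in range(2):
        res2 = minimize(_nll_and_grad, res.x, args=(Fp_mean, Fb, penalty),
                        jac=True, method="L-BFGS-B",
                        bounds=[(0, None)] * (2 * k),
                        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10})
        if res2.fun >= res.fun - tol:
            res = res2 if res2.fun < res.fun else res
            break
        res = res2
    lam = res.x[:k] - res.x[k:]
    if not res.success:
        warnings.warn(f"maxent fit did not converge in {max_iter} iterations: {res.message}")
    eta = Fb @ lam
    log_z = float(logsumexp(eta))
    q = np.exp(eta - log_z)
    entropy = float(-(q * np.log(np.maximum(q, 1e-300))).sum())
    return MaxentModel(expansion, lam, beta, log_z, entropy, len(background),
                       np.sort(q), converged=bool(res.success), n_iter=int(res.nit))


def predict_raw(model: MaxentModel, stack: CovariateStack) -> SuitabilitySurface:
    """Raw Gibbs suitability per cell, normalized over the fit background."""
    mask = stack.mask_nodata()
    rows, cols = np.nonzero(~mask)
    tab = stack.table_at(rows, cols)
    raw = model.raw_scores(tab)
    ref = stack.reference
    out = ref.like(np.full(ref.values.shape, ref.nodata))
    out.values[rows, cols] = raw
    return SuitabilitySurface(out, "raw", bg_raw_sorted=model.bg_raw_sorted,
                              entropy=model.entropy)


def to_cumulative(raw: SuitabilitySurface) -> SuitabilitySurface:
    """Cumulative output: for each cell, the total raw probability of all
    background cells whose raw value is <= the cell's (ties included)."""
    if raw.flavor != "raw":
        raise ValueError("to_cumulative expects a raw-flavor surface")
    if raw.bg_raw_sorted is None:
        raise ValueError("raw surface lacks its background raw distribution")
    g = raw.grid
    mask = g.mask_nodata()
    srt = raw.bg_raw_sorted
    csum = np.concatenate([[0.0], np.cumsum(srt)])
    # tolerance so background cells find their own value despite float noise
    idx = np.searchsorted(srt, g.values[~mask] * (1 + 1e-12), side="right")
    cum = np.minimum(csum[idx] / csum[-1], 1.0)
    out = g.like(np.full(g.values.shape, g.nodata))
    out.values[~mask] = cum
    return SuitabilitySurface(out, "cumulative")


def to_logistic(raw: SuitabilitySurface, entropy: float | None = None) -> SuitabilitySurface:
    """Logistic output c*r/(1+c*r) with c = e^H; a cell whose raw value sits
    at the entropy level of the fitted distribution maps to 0.5."""
    if raw.flavor != "raw":
        raise ValueError("to_logistic expects a raw-flavor surface")
    H = raw.entropy if entropy is None else entropy
    if H is None:
        raise ValueError("entropy required for the logistic transform")
    g = raw.grid
    mask = g.mask_nodata()
    r = g.values[~mask] * np.exp(H)
    out = g.like(np.full(g.values.shape, g.nodata))
    out.values[~mask] = r / (1.0 + r)
    return SuitabilitySurface(out, "logistic")


def auc_score(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney U / (n_pos * n_neg)), ties counted half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    from scipy.stats import rankdata
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def crossval_auc(presences: pd.DataFrame, background: pd.DataFrame, k: int = 10,
                 seed: int = 0, beta: float = 1.0,
                 categorical_var: str | None = "soil") -> ModelEvaluation:
    """k-fold cross-validated AUC (presences folded, background shared)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(presences)
    if n < k:
        raise ValueError(f"cannot split {n} presences into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    aucs = []
    for fold in folds:
        if fold.size == 0:
            raise ValueError("empty cross-validation fold")
        test = presences.iloc[fold]
        train = presences.iloc[np.setdiff1d(order, fold)]
        model = fit_maxent(train, background, beta=beta, categorical_var=categorical_var)
        aucs.append(auc_score(model.raw_scores(test), model.raw_scores(background)))
    return ModelEvaluation(fold_aucs=aucs, mean_auc=float(np.mean(aucs)))


def variable_contributions(presences: pd.DataFrame, background: pd.DataFrame,
                           n_runs: int = 10, seed: int = 0, beta: float = 1.0,
                           categorical_var: str | None = "soil",
                           holdout_frac: float = 0.2) -> dict[str, float]:
    """Permutation importance per covariate, normalized to sum to one.

    Each run holds out a fraction of presences, fits on the rest, then for
    every variable permutes that variable's values across the evaluation
    rows (held-out presences and background jointly) and records the drop
    in AUC; drops are clipped at zero, averaged over runs and renormalized.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(presences)
    n_hold = max(1, int(round(holdout_frac * n)))
    drops: dict[str, list[float]] = {}
    for _ in range(n_runs):
        order = rng.permutation(n)
        test = presences.iloc[order[:n_hold]]
        train = presences.iloc[order[n_hold:]]
        model = fit_maxent(train, background, beta=beta, categorical_var=categorical_var)
        base = auc_score(model.raw_scores(test), model.raw_scores(background))
        for var in model.expansion.variables:
            test_p = test.copy()
            bg_p = background.copy()
            pooled = np.concatenate([test_p[var].to_numpy(), bg_p[var].to_numpy()])
            perm = rng.permutation(pooled)
            test_p[var] = perm[: len(test_p)]
            bg_p[var] = perm[len(test_p):]
            a = auc_score(model.raw_scores(test_p), model.raw_scores(bg_p))
            drops.setdefault(var, []).append(max(base - a, 0.0))
    mean_drop = {v: float(np.mean(d)) for v, d in drops.items()}
    total = sum(mean_drop.values())
    if total <= 0:
        return {v: 1.0 / len(mean_drop) for v in mean_drop}
    return {v: d / total for v, d in mean_drop.items()}


def response_curve(model: MaxentModel, variable: str, n_steps: int = 100) -> pd.DataFrame:
    """Partial response: vary one variable over its background range with
    all other continuous variables at their background means and the
    categorical at its mode; reports logistic-flavor suitability."""
    e = model.expansion
    if variable not in e.variables:
        raise ValueError(f"unknown variable {variable!r}")
    if variable == e.categorical_var:
        values = np.asarray(e.classes, dtype=float)
    else:
        values = np.linspace(e.mins[variable], e.maxs[variable], n_steps)
    tab = pd.DataFrame({c: np.full(values.size, e.background_means[c])
                        for c in e.continuous_vars})
    if e.categorical_var is not None:
        tab[e.categorical_var] = float(e.categorical_mode)
    tab[variable] = values
    return pd.DataFrame({"value": values, "suitability": model.logistic_scores(tab)})


def apply_threshold(cumulative: SuitabilitySurface, t: float) -> Grid:
    """Binary presence map: 1 where cumulative >= t, else 0; nodata kept."""
    if cumulative.flavor != "cumulative":
        raise ValueError("apply_threshold expects a cumulative-flavor surface")
    if not (0.0 <= t <= 1.0):
        raise ValueError("threshold must lie in [0,1]")
    g = cumulative.grid
    mask = g.mask_nodata()
    out = g.like(np.where(g.values >= t, 1.0, 0.0))
    out.values[mask] = g.nodata
    return out
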