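"""Spatial autocorrelation machinery.

Implements the three spatial tools the analysis relies on:

* **Moran's I** and distance-class correlograms, the basic descriptors of
  spatial autocorrelation;
* **Dutilleul's modified test** of the correlation between two spatially
  autocorrelated variables, which replaces the nominal sample size by an
  effective one estimated from the variables' spatial covariance matrices
  (built piecewise-constant over distance classes from the correlogram),
  and tests r on F(1, df_adj) with df_adj = n_eff - 2;
* **Moran eigenvector maps (MEM)**: eigenvectors of the double-centered
  spatial connectivity matrix, used as regression covariates that absorb
  spatial structure, with a forward-selection rule that greedily minimizes
  the absolute Moran's I of model residuals.

All distances are planar Euclidean on the supplied coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SpatialWeights",
    "SpatialCorrelation",
    "EigenvectorBasis",
    "distance_band_weights",
    "grid_contiguity_weights",
    "morans_i",
    "morans_i_test",
    "correlogram",
    "dutilleul_correlation",
    "mem_basis",
    "select_eigenvectors",
]


@dataclass
class SpatialWeights:
    """Symmetric, zero-diagonal, non-negative pairwise weights."""

    w: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        np.fill_diagonal(w, 0.0)
        self.w = w

    @property
    def n(self) -> int:
        return self.w.shape[0]


@dataclass
class SpatialCorrelation:
    """Pearson correlation with Dutilleul-adjusted inference."""

    r: float
    r2: float
    f_adj: float
    df_adj: float
    p: float
    n: int
    n_eff: float


@dataclass
class EigenvectorBasis:
    """Moran eigenvector map basis over a set of sample locations."""

    vectors: np.ndarray     # (n, k), columns orthonormal, positive eigenvalues
    eigenvalues: np.ndarray  # non-increasing
    morans_i: np.ndarray     # Moran's I of each vector on the connectivity
    weights: SpatialWeights
    truncation: float


def distance_band_weights(coords: np.ndarray, band: float) -> SpatialWeights:
    """Binary weights: 1 for pairs within Euclidean distance ``band``."""
    coords = np.asarray(coords, dtype=float)
    d = squareform(pdist(coords))
    w = ((d > 0) & (d <= band)).astype(float)
    return SpatialWeights(w, coords)


def grid_contiguity_weights(n_rows: int, n_cols: int, rule: str = "queen") -> SpatialWeights:
    """Contiguity weights for the cells of an (n_rows, n_cols) lattice in
    row-major order; ``rule`` is "rook" (edge neighbors) or "queen" (edge
    plus corner neighbors)."""
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    coords = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
    dr = np.abs(coords[:, 1][:, None] - coords[:, 1][None, :])
    dc = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
    if rule == "rook":
        w = ((dr + dc) == 1).astype(float)
    elif rule == "queen":
        w = ((np.maximum(dr, dc) == 1)).astype(float)
    else:
        raise ValueError("rule must be 'rook' or 'queen'")
    return SpatialWeights(w, coords)


def morans_i(values: np.ndarray, weights: SpatialWeights) -> float:
    """Global Moran's I = (n / sum(w)) * (z' W z) / (z' z)."""
    z = np.asarray(values, dtype=float)
    if z.size < 3:
        raise ValueError("need at least 3 observations")
    if z.size != weights.n:
        raise ValueError("values and weights disagree in length")
    s0 = weights.w.sum()
    if s0 == 0:
        raise ValueError("weights are all zero")
    z = z - z.mean()
    denom = (z**2).sum()
    if denom == 0:
        return float("nan")  # constant input: Moran's I undefined
    return float(z.size / s0 * (z @ weights.w @ z) / denom)


def morans_i_test(values: np.ndarray, weights: SpatialWeights, n_perm: int = 199,
                  seed: int = 0) -> tuple[float, float]:
    """Two-sided permutation test of Moran's I; returns (I, p)."""
    rng = np.random.default_rng(seed)
    obs = morans_i(values, weights)
    if not np.isfinite(obs):
        return obs, 1.0
    vals = np.asarray(values, dtype=float)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = morans_i(rng.permutation(vals), weights)
    p = (1 + np.sum(np.abs(null - null.mean()) >= abs(obs - null.mean()))) / (n_perm + 1)
    return obs, float(p)


def correlogram(values: np.ndarray, coords: np.ndarray, n_classes: int = 10
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moran's I per equal-frequency distance class.

    Returns ``(class_i, class_upper, pair_counts)``: the per-class Moran's
    I, the upper distance bound of each class, and the number of pairs per
    class. Classes with fewer than 2 pairs are merged into their left
    neighbor.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    coords = np.asarray(coords, dtype=float)
    d = pdist(coords)
    edges = np.quantile(d, np.linspace(0, 1, n_classes + 1))
    edges = np.unique(edges)  # merge degenerate classes (ties in distances)
    dm = squareform(d)
    z = np.asarray(values, dtype=float)
    zc = z - z.mean()
    denom = (zc**2).sum()
    n = z.size
    class_i, upper, counts = [], [], []
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        if k == 0:
            sel = (dm > 0) & (dm >= lo) & (dm <= hi)
        else:
            sel = (dm > lo) & (dm <= hi)
        npairs = sel.sum() // 2
        if npairs < 2:
            continue
        s0 = sel.sum()
        class_i.append(n / s0 * (zc @ sel @ zc) / denom)
        upper.append(hi)
        counts.append(npairs)
    return np.asarray(class_i), np.asarray(upper), np.asarray(counts, dtype=int)


def _class_covariance(values: np.ndarray, dm: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Piecewise-constant spatial correlation matrix: each off-diagonal
    entry gets its distance class's Moran's I; diagonal is 1."""
    z = np.asarray(values, dtype=float)
    zc = z - z.mean()
    denom = (zc**2).sum()
    n = z.size
    sigma = np.eye(n)
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        if k == 0:
            sel = (dm > 0) & (dm >= lo) & (dm <= hi)
        else:
            sel = (dm > lo) & (dm <= hi)
        s0 = sel.sum()
        if s0 < 4:
            continue
        i_k = n / s0 * (zc @ sel @ zc) / denom
        sigma[sel] = i_k
    return sigma


def _double_center(s: np.ndarray) -> np.ndarray:
    rm = s.mean(axis=1, keepdims=True)
    cm = s.mean(axis=0, keepdims=True)
    return s - rm - cm + s.mean()


def dutilleul_correlation(x: np.ndarray, y: np.ndarray, coords: np.ndarray,
                          n_classes: int | str = "auto") -> SpatialCorrelation:
    """Pearson correlation with Dutilleul's adjusted degrees of freedom.

    The effective sample size is the trace formula

        n_eff = 1 + tr(B Sx) tr(B Sy) / tr(B Sx B Sy),

    with B the centering matrix and Sx, Sy the spatial correlation
    matrices of x and y estimated piecewise-constant over equal-frequency
    distance classes. For white noise Sx = Sy = I and n_eff = n, so the
    test reduces to the ordinary one; positive autocorrelation shrinks
    n_eff. df_adj = n_eff - 2; the test statistic is
    F_adj = r^2 df_adj / (1 - r^2) on F(1, df_adj).

    ``n_classes='auto'`` uses n//2 classes (clipped to [10, 100]): the
    piecewise-constant covariance approximation needs distance classes
    narrow relative to the autocorrelation range, and with n(n-1)/2 pairs
    even 100 classes keep hundreds of pairs per class at n = 200.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = x.size
    if y.size != n or coords.shape[0] != n:
        raise ValueError("x, y and coords must have equal length")
    if n < 10:
        raise ValueError("need at least 10 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if n_classes == "auto":
        n_classes = int(np.clip(n // 2, 10, 100))
    r = float(np.corrcoef(x, y)[0, 1])
    d = pdist(coords)
    edges = np.unique(np.quantile(d, np.linspace(0, 1, n_classes + 1)))
    dm = squareform(d)
    sx = _class_covariance(x, dm, edges)
    sy = _class_covariance(y, dm, edges)
    # Centered matrices via row/column mean subtraction (O(n^2), no matmul):
    # B S B = S - rowmeans - colmeans + grandmean, and
    # tr(B Sx B Sy) = tr((B Sx B)(B Sy B)) = elementwise sum since both sym.
    cx = _double_center(sx)
    cy = _double_center(sy)
    num = np.trace(cx) * np.trace(cy)
    den = float((cx * cy).sum())
    n_eff = 1.0 + num / den if den > 0 else float(n)
    n_eff = float(np.clip(n_eff, 3.0, n))
    df_adj = n_eff - 2.0
    r2 = r * r
    f_adj = df_adj * r2 / max(1.0 - r2, 1e-15)
    p = float(stats.f.sf(f_adj, 1, df_adj))
    return SpatialCorrelation(r=r, r2=r2, f_adj=float(f_adj), df_adj=float(df_adj),
                              p=p, n=n, n_eff=n_eff)


def mem_basis(coords: np.ndarray, truncation: float | str = "auto") -> EigenvectorBasis:
    """Moran eigenvector map basis.

    Builds a binary distance-band connectivity (``truncation='auto'`` uses
    the longest edge of the minimum spanning tree, which guarantees a
    connected graph), double-centers it, and eigendecomposes. Eigenvectors
    with positive eigenvalues (positively autocorrelated patterns) are
    returned in non-increasing eigenvalue order.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 10:
        raise ValueError("need at least 10 locations")
    d = squareform(pdist(coords))
    if d[np.triu_indices(n, 1)].max() == 0:
        raise ValueError("all points are coincident")
    if truncation == "auto":
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst.max())
    weights = distance_band_weights(coords, float(truncation))
    a = weights.w
    b = np.eye(n) - np.ones((n, n)) / n
    g = b @ a @ b
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-9 * max(abs(evals[0]), 1.0)
    evals, evecs = evals[pos], evecs[:, pos]
    mi = np.array([morans_i(evecs[:, j], weights) for j in range(evecs.shape[1])])
    return EigenvectorBasis(evecs, evals, mi, weights, float(truncation))


def select_eigenvectors(basis: EigenvectorBasis, residuals: np.ndarray,
                        max_k: int = 10, alpha: float = 0.05, n_perm: int = 199,
                        seed: int = 0) -> list[int]:
    """Forward-select eigenvectors that whiten regression residuals.

    Greedily adds the basis vector whose inclusion (as an extra OLS
    regressor) most reduces |Moran's I| of the residuals; stops when the
    residual autocorrelation is no longer significant (permutation test at
    ``alpha``) or ``max_k`` vectors are selected. Returns column indices
    into ``basis.vectors``.
    """
    if max_k > basis.vectors.shape[1]:
        max_k = basis.vectors.shape[1]
    rng = np.random.default_rng(seed)
    res = np.asarray(residuals, dtype=float)
    selected: list[int] = []
    current = res.copy()
    for _ in range(max_k):
        i_now, p = morans_i_test(current, basis.weights,
                                 n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        if not np.isfinite(i_now) or p > alpha:
            break
        best_j, best_abs, best_res = None, abs(i_now), None
        for j in range(basis.vectors.shape[1]):
            if j in selected:
                continue
            cols = selected + [j]
            x = np.column_stack([np.ones(res.size), basis.vectors[:, cols]])
            beta, *_ = np.linalg.lstsq(x, res, rcond=None)
            trial = res - x @ beta
            i_trial = morans_i(trial, basis.weights)
            if np.isfinite(i_trial) and abs(i_trial) < best_abs:
                best_j, best_abs, best_res = j, abs(i_trial), trial
        if best_j is None:
            break
        selected.append(best_j)
        current = best_res
    return selected
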