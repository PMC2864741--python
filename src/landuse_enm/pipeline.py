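"""End-to-end study orchestration.

Runs the whole landuse "null model" analysis from one configuration:
niche models for each landuse type, suitability surfaces in the three
flavors, ISS conflict-potential maps, deviation maps against a reference
classification, breakpoint/linear regressions of log-population (and,
with a second response grid, GDP) on agricultural suitability with
Dutilleul-corrected inference, re-exponentiated prediction and residual
surfaces, and a conflict logistic regression with ISS plus forward-
selected Moran eigenvectors.

By default everything is generated synthetically with known ground truth;
each configuration key can instead point at user-supplied ESRI ASCII
grids and point tables. A master seed is hashed with the stage name to
give every stochastic stage an independent, reproducible substream, so
adding a stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grids as G
from . import niche as N
from . import overlap as O
from . import regress as R
from . import spatial as S
from . import synthetic as Y

__all__ = ["StudyConfig", "StudyReport", "validate_config", "run_study", "stage_seed"]

log = logging.getLogger("landuse_enm.pipeline")

DEFAULT_LANDUSE = {
    # presence counts span the compiled-record range (47-290 per type)
    "agriculture": {"n_presences": 290, "threshold": 0.18},
    "sedentary_husbandry": {"n_presences": 150, "threshold": 0.13},
    "nomadic_pastoralism": {"n_presences": 100, "threshold": 0.09},
    "hunting_gathering": {"n_presences": 47, "threshold": 0.10},
}

DEFAULT_ISS_PAIRS = [
    ["agriculture", "nomadic_pastoralism"],
    ["agriculture", "hunting_gathering"],
    ["nomadic_pastoralism", "hunting_gathering"],
]


@dataclass
class StudyConfig:
    seed: int = 0
    output_dir: str | None = None
    landscape: dict = field(default_factory=lambda: {
        "n_rows": 100, "n_cols": 100, "cell_size": 0.05, "n_soil_classes": 4})
    landuse: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LANDUSE.items()})
    model: dict = field(default_factory=lambda: {
        "beta": 1.0, "k_folds": 10, "n_background": 10_000, "n_runs": 10})
    iss_pairs: list = field(default_factory=lambda: [list(p) for p in DEFAULT_ISS_PAIRS])
    iss_formula: str = "min_minus_gap"
    population: dict = field(default_factory=lambda: {
        "a": 0.2, "b": 6.0, "c": 0.3, "d": 0.5, "sigma": 0.4, "n_sample": 2000})
    conflict: dict = field(default_factory=lambda: {
        "alpha": -2.5, "beta": 5.0, "n_points": 500, "max_eigenvectors": 5})
    # optional user-supplied inputs (paths); when present they replace the
    # corresponding synthetic stage
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict) \
                    and key in ("landscape", "model", "population", "conflict"):
                merged = dict(getattr(cfg, key))
                merged.update(value)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class StudyReport:
    config: dict
    landuse: dict          # per-landuse AUC, contributions, fit info
    iss: dict              # per-pair summary stats
    deviation: dict        # per-landuse code counts
    regression: dict       # linear/breakpoint tables, delta-AIC, Dutilleul
    conflict: dict         # logistic summary
    manifest: list         # files written
    wall_time_s: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def stage_seed(master: int, stage: str) -> int:
    """Independent per-stage seed: master seed hashed with the stage name."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def validate_config(config: StudyConfig) -> list[str]:
    """Check run_study's preconditions; each problem names the offending key."""
    problems: list[str] = []
    ls = config.landscape
    if ls.get("n_rows", 0) < 10 or ls.get("n_cols", 0) < 10:
        problems.append("landscape.n_rows/n_cols: must both be >= 10")
    if ls.get("n_soil_classes", 2) < 2:
        problems.append("landscape.n_soil_classes: must be >= 2")
    if not config.landuse:
        problems.append("landuse: at least one landuse type is required")
    for name, spec in config.landuse.items():
        t = spec.get("threshold", 0.5)
        if not (0.0 <= t <= 1.0):
            problems.append(f"landuse.{name}.threshold: {t} outside [0,1]")
        if spec.get("n_presences", 0) < 5 and f"presences.{name}" not in config.inputs:
            problems.append(f"landuse.{name}.n_presences: must be >= 5")
    if config.model.get("beta", 0) < 0:
        problems.append("model.beta: must be >= 0")
    if config.model.get("k_folds", 2) < 2:
        problems.append("model.k_folds: must be >= 2")
    if config.iss_formula not in O.ISS_FORMULAS:
        problems.append(f"iss_formula: unknown formula {config.iss_formula!r}")
    for pair in config.iss_pairs:
        if len(pair) != 2 or any(p not in config.landuse for p in pair):
            problems.append(f"iss_pairs: {pair} does not name two configured landuse types")
    p = config.population
    if not (0.0 < p.get("c", 0.3) < 1.0):
        problems.append("population.c: breakpoint must lie strictly inside (0,1)")
    if p.get("sigma", 0) < 0:
        problems.append("population.sigma: must be >= 0")
    if p.get("n_sample", 1) < 10:
        problems.append("population.n_sample: must be >= 10")
    if config.conflict.get("n_points", 1) < 10:
        problems.append("conflict.n_points: must be >= 10")
    for key, path in config.inputs.items():
        if not Path(path).exists():
            problems.append(f"inputs.{key}: file not found: {path}")
    return problems


def _default_niches(landuse_names: list[str], covariates: list[str],
                    n_soil: int) -> dict[str, Y.TrueNiche]:
    """Distinct ground-truth niches: each landuse type prefers a different
    part of covariate space, mimicking the contrasting real responses
    (e.g. agriculture wet and thermally stable, pastoralism dry uplands)."""
    c0 = covariates[0]
    c1 = covariates[1] if len(covariates) > 1 else covariates[0]
    presets = [
        Y.TrueNiche(linear={c0: 1.2, c1: 1.8}, quadratic={c1: -0.8},
                    soil_offsets={i: 0.5 if i % 2 == 0 else -0.5 for i in range(1, n_soil + 1)},
                    intercept=-0.5),
        Y.TrueNiche(linear={c0: 1.5, c1: 0.6}, quadratic={c0: -1.0},
                    soil_offsets={i: 0.4 if i <= n_soil // 2 else -0.4 for i in range(1, n_soil + 1)},
                    intercept=-0.3),
        Y.TrueNiche(linear={c0: -1.2, c1: -1.5}, quadratic={},
                    soil_offsets={i: 0.8 if i == 1 else -0.2 for i in range(1, n_soil + 1)},
                    intercept=-0.4),
        Y.TrueNiche(linear={c0: -0.6, c1: 1.2}, quadratic={c0: -0.5},
                    soil_offsets={i: 0.5 if i == n_soil else -0.3 for i in range(1, n_soil + 1)},
                    intercept=-0.4),
    ]
    return {name: presets[i % len(presets)] for i, name in enumerate(landuse_names)}


def run_study(config: StudyConfig, output_dir: str | None = None) -> StudyReport:
    """Execute the full study; see the module docstring for the stages.

    Deterministic for a fixed master seed. Intermediate surfaces are
    written (as ESRI ASCII) only when an output directory is configured.
    """
    t0 = time.time()
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    outdir = Path(output_dir or config.output_dir) if (output_dir or config.output_dir) else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def emit(grid: G.Grid, name: str) -> None:
        if outdir is not None:
            path = outdir / f"{name}.asc"
            G.write_ascii_grid(grid, path)
            manifest.append(str(path))

    master = config.seed
    # -- stage: landscape -------------------------------------------------
    log.info("stage=landscape seed=%d", stage_seed(master, "landscape"))
    stack, niches, true_suit = _build_landscape(config, stage_seed(master, "landscape"))
    for name, g in stack.continuous.items():
        emit(g, f"covariate_{name}")
    if stack.categorical is not None:
        emit(stack.categorical, "covariate_soil")

    # -- stage: background ------------------------------------------------
    background = N.build_background(stack, config.model.get("n_background", 10_000),
                                    stage_seed(master, "background"))

    # -- stage: niche models ----------------------------------------------
    landuse_report: dict[str, dict] = {}
    logistic_surfaces: dict[str, N.SuitabilitySurface] = {}
    binary_maps: dict[str, G.Grid] = {}
    for name, spec in config.landuse.items():
        sseed = stage_seed(master, f"niche:{name}")
        log.info("stage=niche landuse=%s seed=%d", name, sseed)
        presences_pts = _presences_for(config, name, true_suit, sseed)
        pres = G.extract_at_points(stack, presences_pts)
        pres = pres[pres["valid"]].reset_index(drop=True)
        beta = config.model.get("beta", 1.0)
        model = N.fit_maxent(pres, background, beta=beta,
                             categorical_var=stack.categorical_name)
        raw = N.predict_raw(model, stack)
        logi = N.to_logistic(raw)
        cum = N.to_cumulative(raw)
        logistic_surfaces[name] = logi
        emit(logi.grid, f"suitability_{name}_logistic")
        emit(cum.grid, f"suitability_{name}_cumulative")
        ev = N.crossval_auc(pres, background, k=config.model.get("k_folds", 10),
                            seed=sseed, beta=beta,
                            categorical_var=stack.categorical_name)
        contrib = N.variable_contributions(pres, background,
                                           n_runs=config.model.get("n_runs", 10),
                                           seed=sseed, beta=beta,
                                           categorical_var=stack.categorical_name)
        binary = N.apply_threshold(cum, spec.get("threshold", 0.5))
        binary_maps[name] = binary
        emit(binary, f"binary_{name}")
        entry = {"n_presences": int(len(pres)), "mean_auc": ev.mean_auc,
                 "fold_aucs": ev.fold_aucs, "contributions": contrib,
                 "converged": model.converged}
        if name in true_suit:
            from scipy.stats import spearmanr
            mask = ~true_suit[name].mask_nodata()
            rho = spearmanr(logi.grid.values[mask], true_suit[name].values[mask]).statistic
            entry["spearman_vs_truth"] = float(rho)
        landuse_report[name] = entry

    # -- stage: ISS -------------------------------------------------------
    iss_report: dict[str, dict] = {}
    iss_grids: dict[tuple[str, str], O.ISSGrid] = {}
    for lut1, lut2 in config.iss_pairs:
        iss = O.compute_iss(logistic_surfaces[lut1], logistic_surfaces[lut2],
                            formula=config.iss_formula, lut1_name=lut1, lut2_name=lut2)
        iss_grids[(lut1, lut2)] = iss
        vals = iss.grid.valid_values()
        iss_report[f"{lut1}|{lut2}"] = {
            "mean": float(vals.mean()), "max": float(vals.max()),
            "frac_above_0.5": float((vals > 0.5).mean())}
        emit(iss.grid, f"iss_{lut1}_{lut2}")

    # -- stage: deviation maps -------------------------------------------
    deviation_report: dict[str, dict] = {}
    reference = _reference_binary(config, true_suit)
    for name, binary in binary_maps.items():
        if name not in reference:
            continue
        dev = O.deviation_map(binary, reference[name])
        deviation_report[name] = {str(k): v for k, v in dev.counts.items()}
        emit(dev.grid, f"deviation_{name}")

    # -- stage: population regression ------------------------------------
    agr = config.iss_pairs[0][0] if config.iss_pairs else next(iter(config.landuse))
    if "agriculture" in config.landuse:
        agr = "agriculture"
    regression_report = _population_analysis(config, stack, logistic_surfaces[agr],
                                             true_suit.get(agr), master, emit)

    # -- stage: conflict --------------------------------------------------
    conflict_report: dict = {}
    pair = tuple(config.iss_pairs[0]) if config.iss_pairs else None
    if pair is not None:
        conflict_report = _conflict_analysis(config, iss_grids[pair], master)

    report = StudyReport(
        config=asdict(config), landuse=landuse_report, iss=iss_report,
        deviation=deviation_report, regression=regression_report,
        conflict=conflict_report, manifest=manifest,
        wall_time_s=time.time() - t0)
    if outdir is not None:
        report.save(outdir / "report.json")
        manifest.append(str(outdir / "report.json"))
    return report


# -- stage helpers --------------------------------------------------------

def _build_landscape(config: StudyConfig, seed: int):
    """Synthetic landscape plus per-landuse ground-truth suitability, or
    user-supplied grids (with no truth) when inputs are configured."""
    if any(k.startswith("continuous.") for k in config.inputs):
        continuous = {k.split(".", 1)[1]: G.read_ascii_grid(v)
                      for k, v in config.inputs.items() if k.startswith("continuous.")}
        categorical = (G.read_ascii_grid(config.inputs["categorical"])
                       if "categorical" in config.inputs else None)
        stack = G.CovariateStack(continuous=continuous, categorical=categorical)
        return stack, {}, {}
    ls = config.landscape
    lcfg = Y.LandscapeConfig(n_rows=ls["n_rows"], n_cols=ls["n_cols"],
                             cell_size=ls.get("cell_size", 0.05), seed=seed,
                             n_soil_classes=ls.get("n_soil_classes", 4))
    stack, _, _ = Y.synth_landscape(lcfg)
    names = list(config.landuse)
    niches = _default_niches(names, list(stack.continuous), lcfg.n_soil_classes)
    true_suit = {name: niches[name].suitability(stack) for name in names}
    return stack, niches, true_suit


def _presences_for(config: StudyConfig, name: str, true_suit: dict, seed: int) -> pd.DataFrame:
    key = f"presences.{name}"
    if key in config.inputs:
        return G.read_point_table(config.inputs[key])
    n = config.landuse[name].get("n_presences", 100)
    return Y.sample_presences(true_suit[name], n, seed)


def _reference_binary(config: StudyConfig, true_suit: dict) -> dict[str, G.Grid]:
    """Reference classification: a supplied binary grid, or (synthetic
    branch) truth thresholded at 0.5 — "reality" as the generator knows it."""
    out: dict[str, G.Grid] = {}
    for name in config.landuse:
        key = f"reference.{name}"
        if key in config.inputs:
            out[name] = G.read_ascii_grid(config.inputs[key])
        elif name in true_suit:
            g = true_suit[name]
            binary = g.like(np.where(g.values >= 0.5, 1.0, 0.0))
            binary.values[g.mask_nodata()] = g.nodata
            out[name] = binary
    return out


def _population_analysis(config: StudyConfig, stack, suit_surface, true_surface,
                         master: int, emit) -> dict:
    p = config.population
    seed = stage_seed(master, "population")
    if "population" in config.inputs:
        pop_grid = G.read_ascii_grid(config.inputs["population"])
    else:
        params = Y.PopulationParams(p["a"], p["b"], p["c"], p["d"], p["sigma"])
        source = true_surface if true_surface is not None else suit_surface.grid
        pop_grid = Y.synth_population(source, params, seed)
    emit(pop_grid, "population")
    sample = G.sample_random_cells(stack, min(p.get("n_sample", 2000),
                                              int((~stack.mask_nodata()).sum())),
                                   stage_seed(master, "population_sample"))
    rows = sample["row"].to_numpy()
    cols = sample["col"].to_numpy()
    x = suit_surface.grid.values[rows, cols]
    pop = pop_grid.values[rows, cols]
    keep = (pop != pop_grid.nodata) & (x != suit_surface.grid.nodata)
    x, pop = x[keep], pop[keep]
    y = R.log10p1(pop)
    lin = R.linear_fit(x, y)
    brk = R.breakpoint_fit(x, y)
    ranking = R.compare_aic([lin, brk])
    coords = sample.loc[keep, ["lon", "lat"]].to_numpy()
    dut = S.dutilleul_correlation(x, y, coords)
    # conditional (given the chosen knot) inference on the slope contrast
    X = np.column_stack([np.ones(x.size), np.minimum(x, brk.c), np.maximum(x - brk.c, 0)])
    sigma2 = float(brk.residuals @ brk.residuals) / (x.size - 3)
    xtx_inv = np.linalg.inv(X.T @ X)
    contrast = np.array([0.0, 1.0, -1.0])
    se_bd = float(np.sqrt(sigma2 * contrast @ xtx_inv @ contrast))
    t_bd = (brk.b - brk.d) / se_bd if se_bd > 0 else np.inf
    pred = R.predict_surface(brk, suit_surface)
    emit(pred, "population_predicted")
    resid = R.residual_map(pop_grid, pred)
    emit(resid, "population_residuals")
    return {
        "n_sample": int(x.size),
        "linear": {"intercept": lin.intercept, "slope": lin.slope,
                   "r2": lin.r2, "aic": lin.aic},
        "breakpoint": {"a": brk.a, "b": brk.b, "c": brk.c, "d": brk.d,
                       "r2": brk.r2, "aic": brk.aic,
                       "slope_contrast_t": float(t_bd)},
        "delta_aic_linear_minus_breakpoint": float(lin.aic - brk.aic),
        "ranking": ranking.to_dict(orient="records"),
        "dutilleul": {"r": dut.r, "r2": dut.r2, "f_adj": dut.f_adj,
                      "df_adj": dut.df_adj, "p": dut.p},
    }


def _conflict_analysis(config: StudyConfig, iss: O.ISSGrid, master: int) -> dict:
    c = config.conflict
    seed = stage_seed(master, "conflict")
    if "conflicts" in config.inputs:
        pts = G.read_point_table(config.inputs["conflicts"])
        ext = G.extract_at_points(
            G.CovariateStack(continuous={"iss": iss.grid}), pts)
        ext = ext[ext["valid"]]
        tab = pd.DataFrame({"lon": ext["lon"], "lat": ext["lat"],
                            "label": ext["label"], "iss": ext["iss"]})
    else:
        params = Y.ConflictParams(c["alpha"], c["beta"], c["n_points"])
        tab = Y.synth_conflicts(iss.grid, params, seed)
    y = (tab["label"] == "conflict").astype(float).to_numpy()
    coords = tab[["lon", "lat"]].to_numpy()
    base = R.logistic_fit(tab[["iss"]], y)
    resid = y - base.predict(tab[["iss"]])
    basis = S.mem_basis(coords)
    sel = S.select_eigenvectors(basis, resid, max_k=c.get("max_eigenvectors", 5),
                                seed=stage_seed(master, "conflict_mem"))
    X = tab[["iss"]].copy()
    for j in sel:
        X[f"mem_{j + 1}"] = basis.vectors[:, j]
    fit = R.logistic_fit(X, y)
    return {
        "n": int(y.size),
        "n_conflict": int(y.sum()),
        "eigenvectors_selected": [int(j) for j in sel],
        "chi2": fit.chi2, "chi2_p": fit.chi2_p,
        "iss_coef": float(fit.params["iss"]),
        "iss_z": float(fit.zvalues["iss"]),
        "iss_p": float(fit.pvalues["iss"]),
        "accuracy": fit.accuracy,
        "separation_flag": fit.separation_flag,
    }
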