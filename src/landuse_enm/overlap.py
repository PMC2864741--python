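"""Shared-suitability (ISS) maps and categorical deviation maps.

The index of shared suitability (ISS) scores each cell for how strongly
two landuse types are *both* well suited there: it approaches 1 where both
suitabilities are high and similar, and 0 where one type clearly dominates
or both are poor. High-ISS cells flag potential conflict zones between
peoples with different landuse traditions.

Several formulas satisfy those boundary requirements; the default is

    ISS = max(0, min(s1, s2) - |s1 - s2|),

with a harmonic-mean variant ``2*s1*s2/(s1+s2)`` and a damped-product
variant ``s1*s2*(1-|s1-s2|)`` selectable by name. All are symmetric and
map [0,1]x[0,1] into [0,1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Grid
from .niche import SuitabilitySurface

__all__ = ["ISSGrid", "DeviationGrid", "ISS_FORMULAS", "compute_iss", "deviation_map"]


def _iss_min_minus_gap(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, np.minimum(s1, s2) - np.abs(s1 - s2))


def _iss_harmonic(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    tot = s1 + s2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, 2.0 * s1 * s2 / np.where(tot > 0, tot, 1.0), 0.0)
    return out


def _iss_product(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    return s1 * s2 * (1.0 - np.abs(s1 - s2))


ISS_FORMULAS = {
    "min_minus_gap": _iss_min_minus_gap,
    "harmonic": _iss_harmonic,
    "product": _iss_product,
}


@dataclass
class ISSGrid:
    grid: Grid
    lut1_name: str
    lut2_name: str
    formula: str


@dataclass
class DeviationGrid:
    """Agreement map between a binary model prediction and a binary
    reference: 0 agree-absence, 1 agree-presence, 2 model-only, 3
    reference-only."""

    grid: Grid
    counts: dict[int, int]


def compute_iss(s1: SuitabilitySurface, s2: SuitabilitySurface,
                formula: str = "min_minus_gap",
                lut1_name: str = "lut1", lut2_name: str = "lut2") -> ISSGrid:
    """ISS map for a pair of congruent same-flavor suitability surfaces.

    Logistic-flavor surfaces are recommended (values read as probability
    of occurrence); any [0,1]-valued flavor pair is accepted as long as
    the two flavors match.
    """
    if formula not in ISS_FORMULAS:
        raise ValueError(f"unknown ISS formula {formula!r}; choose from {sorted(ISS_FORMULAS)}")
    if s1.flavor != s2.flavor:
        raise ValueError(f"flavor mismatch: {s1.flavor} vs {s2.flavor}")
    g1, g2 = s1.grid, s2.grid
    if not g1.congruent_with(g2):
        raise ValueError("suitability surfaces are not congruent")
    mask = g1.mask_nodata() | g2.mask_nodata()
    v1 = np.clip(g1.values, 0.0, 1.0)
    v2 = np.clip(g2.values, 0.0, 1.0)
    iss = ISS_FORMULAS[formula](v1, v2)
    out = g1.like(iss)
    out.values[mask] = out.nodata
    return ISSGrid(out, lut1_name, lut2_name, formula)


def deviation_map(model_binary: Grid, reference_binary: Grid) -> DeviationGrid:
    """Cell-wise agreement codes between model and reference presence maps,
    with per-code counts."""
    if not model_binary.congruent_with(reference_binary):
        raise ValueError("grids are not congruent")
    mask = model_binary.mask_nodata() | reference_binary.mask_nodata()
    m = model_binary.values
    r = reference_binary.values
    for name, v in (("model", m[~mask]), ("reference", r[~mask])):
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError(f"{name} grid is not binary")
    codes = np.where(m == 1,
                     np.where(r == 1, 1.0, 2.0),
                     np.where(r == 1, 3.0, 0.0))
    out = model_binary.like(codes)
    out.values[mask] = out.nodata
    valid = codes[~mask]
    counts = {k: int((valid == k).sum()) for k in (0, 1, 2, 3)}
    return DeviationGrid(out, counts)
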