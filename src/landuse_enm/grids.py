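"""Raster data model and plain-text spatial I/O.

The universal spatial currency of the package is the :class:`Grid`: a
row-major raster (northernmost row first) of real values with a nodata
sentinel, georeferenced by its lower-left corner and a square cell size in
degrees. Grids are read and written as ESRI ASCII (.asc) files; point data
travel as delimited tables with ``lon,lat,label`` columns.

Coordinates are geographic degrees treated as planar throughout: the
synthetic worlds this package analyses are abstract, and no projection
handling is attempted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "CovariateStack",
    "GridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_point_table",
    "write_point_table",
    "sample_random_cells",
    "extract_at_points",
]


class GridFormatError(ValueError):
    """Raised for malformed ESRI ASCII grid files."""


@dataclass
class Grid:
    """A single-band raster.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Cell values, row-major with the northernmost row first. Cells may
        hold the ``nodata`` sentinel; all other entries must be finite.
    x_ll, y_ll : float
        Longitude / latitude of the lower-left corner, in degrees.
    cell_size : float
        Side length of a (square) cell, in degrees. Must be positive.
    nodata : float
        Sentinel marking cells outside the analysis mask.
    """

    values: np.ndarray
    x_ll: float = 0.0
    y_ll: float = 0.0
    cell_size: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        finite_or_nodata = np.isfinite(self.values) | self.mask_nodata()
        if not finite_or_nodata.all():
            raise ValueError("Grid values must be finite or the nodata sentinel")

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the grid's outer edges."""
        return (
            self.x_ll,
            self.x_ll + self.n_cols * self.cell_size,
            self.y_ll,
            self.y_ll + self.n_rows * self.cell_size,
        )

    def mask_nodata(self) -> np.ndarray:
        """Boolean array, True where a cell holds the nodata sentinel."""
        v = self.values
        with np.errstate(invalid="ignore"):
            return (v == self.nodata) | ~np.isfinite(v)

    def valid_values(self) -> np.ndarray:
        """1-D array of all non-nodata cell values."""
        return self.values[~self.mask_nodata()]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col); row 0 is northernmost."""
        lon = self.x_ll + (col + 0.5) * self.cell_size
        lat = self.y_ll + (self.n_rows - row - 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        lon = self.x_ll + (cols + 0.5) * self.cell_size
        lat = self.y_ll + (self.n_rows - rows - 0.5) * self.cell_size
        return lon, lat

    def locate(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) indices.

        Cells are half-open: ``[x, x+cell_size)`` in longitude and
        ``(y, y+cell_size]`` in latitude, so a point on a shared edge is
        assigned to the cell to its east / south. Returns
        ``(rows, cols, inside)`` where ``inside`` flags points within the
        grid extent; out-of-extent points get row/col of -1.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        cols = np.floor((lon - self.x_ll) / self.cell_size).astype(int)
        # latitude: row 0 is the top; the (y, y+cs] half-open rule means a
        # point exactly on a horizontal edge belongs to the cell below it,
        # which floor((top - lat)/cs) delivers (top - lat integral -> lower).
        rows = np.floor((self.y_ll + self.n_rows * self.cell_size - lat) / self.cell_size).astype(int)
        x0, x1, y0, y1 = self.extent
        inside = (lon >= x0) & (lon < x1) & (lat > y0) & (lat <= y1)
        rows = np.where(inside, rows, -1)
        cols = np.where(inside, cols, -1)
        return rows, cols, inside

    def congruent_with(self, other: "Grid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.x_ll, other.x_ll)
            and np.isclose(self.y_ll, other.y_ll)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """A new Grid with this grid's geometry and the given values."""
        return replace(self, values=np.asarray(values, dtype=float),
                       nodata=self.nodata if nodata is None else nodata)


@dataclass
class CovariateStack:
    """Congruent set of named continuous grids plus one optional categorical grid.

    A cell that is nodata in any member is treated as nodata in all members
    (intersection mask).
    """

    continuous: dict[str, Grid]
    categorical: Grid | None = None
    categorical_name: str = "soil"
    category_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.continuous.values())
        if self.categorical is not None:
            grids.append(self.categorical)
        if not grids:
            raise ValueError("CovariateStack needs at least one grid")
        ref = grids[0]
        for g in grids[1:]:
            if not ref.congruent_with(g):
                raise ValueError("all stack members must share geometry")

    @property
    def reference(self) -> Grid:
        return next(iter(self.continuous.values())) if self.continuous else self.categorical

    @property
    def variable_names(self) -> list[str]:
        names = list(self.continuous)
        if self.categorical is not None:
            names.append(self.categorical_name)
        return names

    def mask_nodata(self) -> np.ndarray:
        """Intersection nodata mask: True where any member is nodata."""
        mask = np.zeros(self.reference.values.shape, dtype=bool)
        for g in self.continuous.values():
            mask |= g.mask_nodata()
        if self.categorical is not None:
            mask |= self.categorical.mask_nodata()
        return mask

    def valid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(~self.mask_nodata())

    def table_at(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Covariate values at the given cell indices, one row per cell."""
        data = {name: g.values[rows, cols] for name, g in self.continuous.items()}
        if self.categorical is not None:
            data[self.categorical_name] = self.categorical.values[rows, cols]
        lon, lat = self.reference.cell_centers(rows, cols)
        out = pd.DataFrame({"lon": lon, "lat": lat, **data})
        return out


# -- ESRI ASCII I/O -------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII grid: six header lines then row-major values,
    northernmost row first."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2:
                raise GridFormatError(f"malformed header line: {line.strip()!r}")
            key = parts[0].lower()
            if key not in _HEADER_KEYS:
                raise GridFormatError(f"unexpected header key in line: {line.strip()!r}")
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"non-numeric header value in line: {line.strip()!r}") from exc
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise GridFormatError(f"missing header keys: {', '.join(missing)}")
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        body = fh.read()
    values = np.loadtxt(io.StringIO(body), ndmin=1).ravel()
    if values.size != nrows * ncols:
        raise GridFormatError(
            f"value count mismatch: expected {nrows * ncols} ({nrows}x{ncols}), got {values.size}"
        )
    return Grid(
        values=values.reshape(nrows, ncols),
        x_ll=header["xllcorner"],
        y_ll=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=header["nodata_value"],
    )


def write_ascii_grid(grid: Grid, path, precision: int | None = None) -> None:
    """Write a Grid as ESRI ASCII.

    By default real values are printed in their shortest exactly
    round-trippable decimal form, so write -> read reproduces the grid
    bit-for-bit; pass ``precision`` to truncate to that many significant
    digits instead. Integral values (and the nodata sentinel) are written
    verbatim without a decimal point.
    """
    vals = grid.values
    is_int = np.all(vals[~grid.mask_nodata()] == np.round(vals[~grid.mask_nodata()])) if vals.size else True
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_ll!r}\n")
        fh.write(f"yllcorner {grid.y_ll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        nd = grid.nodata
        fh.write(f"NODATA_value {int(nd) if float(nd).is_integer() else nd!r}\n")
        nodata_mask = grid.mask_nodata()
        for r in range(grid.n_rows):
            row = vals[r]
            cells = []
            for c in range(grid.n_cols):
                if nodata_mask[r, c]:
                    v = nd
                    cells.append(str(int(v)) if float(v).is_integer() else repr(v))
                elif is_int:
                    cells.append(str(int(row[c])))
                elif precision is None:
                    cells.append(repr(float(row[c])))
                else:
                    cells.append(np.format_float_positional(
                        row[c], precision=precision, unique=False, fractional=False, trim="-"))
            fh.write(" ".join(cells) + "\n")


# -- point tables ---------------------------------------------------------

def read_point_table(path) -> pd.DataFrame:
    """Read a delimited point table with columns lon, lat, label."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"lon", "lat"}
    if not required.issubset(df.columns):
        raise ValueError(f"point table must have columns lon,lat (got {list(df.columns)})")
    if "label" not in df.columns:
        df["label"] = ""
    return df[["lon", "lat", "label"]]


def write_point_table(points: pd.DataFrame, path) -> None:
    points[["lon", "lat", "label"]].to_csv(path, index=False)


# -- sampling & extraction ------------------------------------------------

def sample_random_cells(stack: CovariateStack, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` distinct non-nodata cells uniformly without replacement.

    Returns a table with cell-center coordinates and the covariate values,
    reproducible for a fixed seed.
    """
    rows, cols = stack.valid_indices()
    if n > rows.size:
        raise ValueError(f"requested {n} cells but only {rows.size} valid cells exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False)
    out = stack.table_at(rows[idx], cols[idx])
    out.insert(0, "col", cols[idx])
    out.insert(0, "row", rows[idx])
    return out


def extract_at_points(stack: CovariateStack, points: pd.DataFrame) -> pd.DataFrame:
    """Covariate values at the cells containing each point.

    Output mirrors the input order and adds ``row``/``col`` indices plus
    boolean flags: ``inside`` (within extent) and ``valid`` (inside and not
    on a nodata cell). Out-of-extent points are flagged, never fatal.
    """
    ref = stack.reference
    rows, cols, inside = ref.locate(points["lon"].to_numpy(), points["lat"].to_numpy())
    mask = stack.mask_nodata()
    safe_r = np.where(inside, rows, 0)
    safe_c = np.where(inside, cols, 0)
    tab = stack.table_at(safe_r, safe_c)
    tab["lon"] = points["lon"].to_numpy()
    tab["lat"] = points["lat"].to_numpy()
    if "label" in points.columns:
        tab["label"] = points["label"].to_numpy()
    tab.insert(0, "col", cols)
    tab.insert(0, "row", rows)
    tab["inside"] = inside
    tab["valid"] = inside & ~mask[safe_r, safe_c]
    for name in stack.variable_names:
        tab.loc[~tab["valid"], name] = np.nan
    return tab
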