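"""Island-area forcing: area time series, hypsometric areas from DEMs, and
coastline-retreat metrics.

The population model is driven by the number of breeding territories
K(t) = A(t)/territory_km2, where A(t) is the subaerial (above-sea-level)
island area through a glacial cycle.  This module

* reads/writes area and sea-level time series as CSV (``time_ky_bp`` plus a
  value column; internal canonical units are years BP, km² and metres),
* linearly interpolates coarse forcing (typically 500- or 1000-year steps)
  down to the annual resolution of the model,
* computes subaerial area hypsometrically from a gridded topo-bathymetry
  (a cell is land iff its elevation is strictly above the sea level; cells
  exactly at the datum count as sea), with cos(latitude) cell-area scaling
  for geographic grids,
* derives the standard area statistics (percent of the Last Glacial Maximum
  maximum; percent area change per thousand years), and
* measures the maximum coastline retreat between two sea-level stands as
  the largest Euclidean distance from a flooded old-coastline cell to the
  nearest new-coastline cell.

Enclosed depressions below sea level count as sea (no lagoon/connectivity
handling) — a deliberate simplification relative to a full coastline
reconstruction.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import TerritorySeries, territories_from_area
from .params import ModelParams

__all__ = [
    "AreaSeries",
    "SeaLevelCurve",
    "ElevationGrid",
    "read_area_series",
    "read_sea_level_curve",
    "interpolate_series",
    "subaerial_area",
    "area_history",
    "relative_area_stats",
    "max_coastline_retreat",
    "annual_territories",
    "read_esri_ascii",
    "write_esri_ascii",
]

#: km per degree of latitude (spherical Earth, mean radius)
_KM_PER_DEG = 111.32


def _validate_series(times: np.ndarray, values: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.ndim != 1 or times.size == 0:
        raise ValueError(f"{what}: times and values must be equal-length 1-D arrays")
    if np.any(times < 0):
        raise ValueError(f"{what}: times are years BP and must be >= 0")
    if np.unique(times).size != times.size:
        raise ValueError(f"{what}: duplicate times")
    order = np.argsort(times)[::-1]  # strictly decreasing toward present
    return times[order], values[order]


@dataclasses.dataclass(frozen=True)
class AreaSeries:
    """Island area (km²) on a strictly decreasing years-BP time axis."""

    times_ybp: np.ndarray
    areas_km2: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        t, a = _validate_series(self.times_ybp, self.areas_km2, "AreaSeries")
        if np.any(~np.isfinite(a)) or np.any(a < 0):
            raise ValueError("AreaSeries: areas must be finite and >= 0")
        object.__setattr__(self, "times_ybp", t)
        object.__setattr__(self, "areas_km2", a)

    def __len__(self) -> int:
        return self.times_ybp.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_ky_bp": self.times_ybp / 1000.0, "area_km2": self.areas_km2}
        ).to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class SeaLevelCurve:
    """Sea level (m relative to the present datum; negative = lower) vs years BP."""

    times_ybp: np.ndarray
    levels_m: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        t, s = _validate_series(self.times_ybp, self.levels_m, "SeaLevelCurve")
        if np.any(~np.isfinite(s)):
            raise ValueError("SeaLevelCurve: levels must be finite")
        object.__setattr__(self, "times_ybp", t)
        object.__setattr__(self, "levels_m", s)

    def __len__(self) -> int:
        return self.times_ybp.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_ky_bp": self.times_ybp / 1000.0, "sea_level_m": self.levels_m}
        ).to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class ElevationGrid:
    """Rectangular topo-bathymetry grid (metres relative to the present datum).

    ``cell_size`` is in km for projected grids (``unit='km'``) or degrees for
    geographic grids (``unit='deg'``).  Cells are cell-centre registered,
    row 0 is the northernmost row, and ``yll`` is the y/latitude of the
    *lower-left corner* (only consulted for geographic grids, where cell
    area shrinks with cos(latitude)).  ``nodata`` cells are treated as sea.
    """

    elevations: np.ndarray
    cell_size: float
    unit: str = "km"
    yll: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        z = np.asarray(self.elevations, dtype=float)
        if z.ndim != 2 or z.size == 0:
            raise ValueError("elevations must be a non-empty 2-D array")
        if not (self.cell_size > 0):
            raise ValueError("cell size must be > 0")
        if self.unit not in ("km", "deg"):
            raise ValueError("unit must be 'km' or 'deg'")
        object.__setattr__(self, "elevations", z)

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    def cell_areas_km2(self) -> np.ndarray:
        """Per-row cell areas in km² (column vector broadcastable over the grid)."""
        nrows = self.shape[0]
        if self.unit == "km":
            return np.full((nrows, 1), self.cell_size**2)
        # geographic: row i centre latitude, rows counted from the north
        lat_top = self.yll + self.shape[0] * self.cell_size
        lat_centers = lat_top - (np.arange(nrows) + 0.5) * self.cell_size
        a = (self.cell_size * _KM_PER_DEG) ** 2 * np.cos(np.radians(lat_centers))
        return a[:, None]

    def cell_width_km(self) -> float:
        """Nominal cell width in km (at the grid's mean latitude for 'deg' grids)."""
        if self.unit == "km":
            return self.cell_size
        lat_mid = self.yll + 0.5 * self.shape[0] * self.cell_size
        return self.cell_size * _KM_PER_DEG * math.cos(math.radians(lat_mid))


def read_area_series(path: str | Path) -> AreaSeries:
    """Read an area CSV with header ``time_ky_bp,area_km2`` (sorted on read)."""
    df = _read_forcing_csv(path, "area_km2")
    bad = df.index[df["area_km2"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative area at data row {int(bad[0])}")
    return AreaSeries(
        times_ybp=df["time_ky_bp"].to_numpy() * 1000.0,
        areas_km2=df["area_km2"].to_numpy(),
        source=str(path),
    )


def read_sea_level_curve(path: str | Path) -> SeaLevelCurve:
    """Read a sea-level CSV with header ``time_ky_bp,sea_level_m``."""
    df = _read_forcing_csv(path, "sea_level_m")
    return SeaLevelCurve(
        times_ybp=df["time_ky_bp"].to_numpy() * 1000.0,
        levels_m=df["sea_level_m"].to_numpy(),
        source=str(path),
    )


def _read_forcing_csv(path: str | Path, value_col: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("time_ky_bp", value_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    for col in ("time_ky_bp", value_col):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column '{col}' at data row {int(bad[0])}")
        df[col] = coerced
    return df


def interpolate_series(series: AreaSeries, dt_years: float = 1.0) -> AreaSeries:
    """Linearly interpolate an area series to a uniform time step.

    Endpoints are preserved exactly; the final (most recent) time is always
    included even if the window length is not a multiple of ``dt_years``.
    """
    if dt_years < 1.0:
        raise ValueError("dt must be >= 1 year")
    if len(series) < 2:
        raise ValueError("need at least two points to interpolate")
    t0, t1 = series.times_ybp[0], series.times_ybp[-1]
    n = int(math.floor((t0 - t1) / dt_years + 1e-9))
    times = t0 - dt_years * np.arange(n + 1)
    if abs(times[-1] - t1) > 1e-9:
        times = np.append(times, t1)
    times[-1] = t1  # exact endpoint
    # np.interp wants an increasing abscissa; flip both axes
    areas = np.interp(times[::-1], series.times_ybp[::-1], series.areas_km2[::-1])[::-1]
    return AreaSeries(times_ybp=times, areas_km2=areas, source=series.source)


def annual_territories(series: AreaSeries, params: ModelParams) -> TerritorySeries:
    """Annual K(t) forcing: interpolate to 1-year steps and convert area to territories."""
    annual = interpolate_series(series, 1.0)
    return TerritorySeries(
        times_ybp=annual.times_ybp,
        K=territories_from_area(annual.areas_km2, params),
    )


def subaerial_area(grid: ElevationGrid, sea_level_m: float) -> float:
    """Subaerial island area (km²) at a given sea level.

    Hypsometric rule: a cell is land iff its elevation is strictly above the
    sea level; nodata cells are sea.  Cell areas are summed (with
    cos(latitude) weighting on geographic grids).
    """
    z = grid.elevations
    land = (z > sea_level_m) & (z != grid.nodata) & np.isfinite(z)
    return float(np.sum(land * grid.cell_areas_km2()))


def area_history(grid: ElevationGrid, curve: SeaLevelCurve) -> AreaSeries:
    """Evaluate the island's subaerial area at every time of a sea-level curve."""
    areas = np.array([subaerial_area(grid, s) for s in curve.levels_m])
    return AreaSeries(times_ybp=curve.times_ybp.copy(), areas_km2=areas, source=curve.source)


def relative_area_stats(
    series: AreaSeries,
    lgm_window_ky: tuple[float, float] = (24.0, 20.0),
) -> pd.DataFrame:
    """Area statistics relative to the Last Glacial Maximum, at 1-ky resolution.

    Returns a DataFrame with columns ``time_ky_bp``, ``pct_of_lgm_max``
    (100*A(t)/max A over the LGM window) and ``pct_change_per_ky``
    (100*(A(t) - A(t-1ky))/A(t-1ky), where t-1ky is the step 1000 years
    older; NaN for the oldest step).
    """
    hi, lo = max(lgm_window_ky), min(lgm_window_ky)
    t_ky = series.times_ybp / 1000.0
    if not (t_ky[0] >= hi and t_ky[-1] <= lo):
        raise ValueError(f"series does not cover the LGM window [{hi}, {lo}] ky BP")
    ky = interpolate_series(series, 1000.0)
    tk = ky.times_ybp / 1000.0
    in_window = (tk <= hi) & (tk >= lo)
    lgm_max = float(ky.areas_km2[in_window].max())
    if lgm_max <= 0:
        raise ValueError("island fully submerged throughout the LGM window")
    pct = 100.0 * ky.areas_km2 / lgm_max
    rate = np.full_like(pct, np.nan)
    prev = ky.areas_km2[:-1]  # 1 ky older than the next entry
    with np.errstate(divide="ignore", invalid="ignore"):
        rate[1:] = 100.0 * (ky.areas_km2[1:] - prev) / prev
    return pd.DataFrame({"time_ky_bp": tk, "pct_of_lgm_max": pct, "pct_change_per_ky": rate})


def _coastline_mask(land: np.ndarray) -> np.ndarray:
    """Land cells with at least one sea 4-neighbour (grid border counts as sea)."""
    sea = ~land
    nb_sea = np.zeros_like(land)
    nb_sea[1:, :] |= sea[:-1, :]
    nb_sea[:-1, :] |= sea[1:, :]
    nb_sea[:, 1:] |= sea[:, :-1]
    nb_sea[:, :-1] |= sea[:, 1:]
    nb_sea[0, :] = nb_sea[-1, :] = nb_sea[:, 0] = nb_sea[:, -1] = True
    return land & nb_sea


def max_coastline_retreat(grid: ElevationGrid, sl_old_m: float, sl_new_m: float) -> float:
    """Maximum coastline retreat (metres) during a transgression sl_old -> sl_new.

    For every old-coastline cell that is flooded at the new stand, the
    Euclidean centre-to-centre distance to the nearest new-coastline cell is
    computed; the maximum is returned (0 if nothing floods).  Requires
    ``sl_new_m > sl_old_m``.
    """
    if sl_new_m <= sl_old_m:
        raise ValueError("retreat is defined for a transgression: sl_new must exceed sl_old")
    z = grid.elevations
    valid = (z != grid.nodata) & np.isfinite(z)
    land_old = (z > sl_old_m) & valid
    land_new = (z > sl_new_m) & valid
    coast_old = _coastline_mask(land_old)
    flooded = coast_old & ~land_new
    if not flooded.any():
        return 0.0
    coast_new = _coastline_mask(land_new)
    cell_km = grid.cell_width_km()
    if not coast_new.any():
        raise ValueError("island fully submerged at the new stand; retreat undefined")
    tree = cKDTree(np.argwhere(coast_new).astype(float))
    d, _ = tree.query(np.argwhere(flooded).astype(float))
    return float(d.max() * cell_km * 1000.0)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text DEM exchange format)

def read_esri_ascii(path: str | Path, unit: str = "km") -> ElevationGrid:
    """Read a DEM from an ESRI ASCII grid (.asc).

    The standard 6-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
    NODATA_value) is followed by nrows lines of ncols values, northernmost
    row first.  ``unit`` declares whether cellsize is km (projected) or
    degrees (geographic).
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip() and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, val = lines[i].split()[:2]
        header[key.lower()] = float(val)
        i += 1
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: malformed ESRI ASCII header (missing {req})")
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"{path}: expected {nrows}x{ncols} values, got {data.shape}")
    return ElevationGrid(
        elevations=data,
        cell_size=header["cellsize"],
        unit=unit,
        yll=header.get("yllcorner", 0.0),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_esri_ascii(grid: ElevationGrid, path: str | Path, xll: float = 0.0) -> None:
    """Write a DEM as an ESRI ASCII grid (.asc), northernmost row first."""
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\nxllcorner {xll}\nyllcorner {grid.yll}\n"
            f"cellsize {grid.cell_size}\nNODATA_value {grid.nodata}\n"
        )
        np.savetxt(fh, grid.elevations, fmt="%.3f")
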