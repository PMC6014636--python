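"""Raster handling and spatial interpolation over the elevation transect.

Station-level index values are spread over the digital elevation model
with a thin-plate spline on (lon, lat) plus a fixed linear elevation
term::

    value(x) = a + b · elev(x) + Σ_j w_j φ(‖x − x_j‖),   φ(r) = r² log r

subject to the usual TPS side conditions (weights orthogonal to the
polynomial part).  With smoothing 0 the surface interpolates the
stations exactly.  Rasters are plain north-up WGS84 grids, readable and
writable as Arc/Info ASCII grids and as GeoTIFF (via tifffile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "DEMGrid",
    "RasterMap",
    "ElevationTPS",
    "fit_interpolator",
    "interpolate",
    "sample_points",
    "band_sample",
    "density_map_from_glm",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
]

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """North-up grid geometry; origin is the top-left (NW) cell corner."""

    nrows: int
    ncols: int
    x_origin: float
    y_origin: float
    cell: float
    crs: str = "EPSG:4326"

    def __post_init__(self):
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell-centre coordinates, shape (nrows, ncols)."""
        lon = self.x_origin + (np.arange(self.ncols) + 0.5) * self.cell
        lat = self.y_origin - (np.arange(self.nrows) + 0.5) * self.cell
        return np.meshgrid(lon, lat)

    def index_of(self, lon: float, lat: float) -> Tuple[int, int]:
        """Nearest-cell (row, col); raises ``IndexError`` out of bounds."""
        col = int(np.floor((lon - self.x_origin) / self.cell))
        row = int(np.floor((self.y_origin - lat) / self.cell))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"coordinate ({lon}, {lat}) outside raster bounds")
        return row, col


@dataclass(frozen=True)
class DEMGrid:
    """Digital elevation model: elevation (m asl) on a :class:`GridSpec`."""

    grid: GridSpec
    elevation: np.ndarray
    nodata: float = NODATA

    def __post_init__(self):
        elev = np.asarray(self.elevation, dtype=float)
        object.__setattr__(self, "elevation", elev)
        if elev.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError("elevation array does not match grid shape")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return self.elevation != self.nodata


@dataclass(frozen=True)
class RasterMap:
    """A value grid aligned cell-for-cell with a DEM."""

    grid: GridSpec
    values: np.ndarray
    name: str = "value"
    units: str = ""
    nodata: float = NODATA

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError("value array does not match grid shape")

    @property
    def mask(self) -> np.ndarray:
        return self.values != self.nodata


# ---------------------------------------------------------------------------
# Thin-plate spline with a fixed linear elevation term


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        k = r * r * np.log(r)
    return np.where(r > 0.0, k, 0.0)


class ElevationTPS:
    """value = a + b·elev + thin-plate spline in (lon, lat)."""

    def __init__(self, lon, lat, elev, values, smoothing: float = 0.0):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        elev = np.asarray(elev, dtype=float)
        values = np.asarray(values, dtype=float)
        n = lon.size
        if n < 4:
            raise ValueError(f"need at least 4 stations, got {n}")
        if smoothing < 0:
            raise ValueError("smoothing must be non-negative")

        # Scale coordinates isotropically and centre covariates for
        # conditioning; the fitted surface is expressed in scaled space.
        self._x0, self._y0 = lon.mean(), lat.mean()
        span = max(lon.max() - lon.min(), lat.max() - lat.min())
        self._s = span if span > 0 else 1.0
        self._e0 = elev.mean()
        self._es = elev.std() if elev.std() > 0 else 1.0

        x = (lon - self._x0) / self._s
        y = (lat - self._y0) / self._s
        e = (elev - self._e0) / self._es
        pts = np.column_stack([x, y])
        r = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        K = _tps_kernel(r) + smoothing * np.eye(n)
        P = np.column_stack([np.ones(n), x, y, e])
        if np.linalg.matrix_rank(P) < P.shape[1]:
            raise ValueError(
                "rank-deficient design: stations are collinear in "
                "(lon, lat, elevation); spread stations or drop the covariate"
            )
        A = np.zeros((n + 4, n + 4))
        A[:n, :n] = K
        A[:n, n:] = P
        A[n:, :n] = P.T
        rhs = np.concatenate([values, np.zeros(4)])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular TPS system ({err}); check for "
                             "duplicate station coordinates") from err
        self._pts = pts
        self._w = sol[:n]
        self._c = sol[n:]
        self.smoothing = smoothing
        self._train = (lon, lat, elev, values)

    def predict(self, lon, lat, elev) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        shape = lon.shape
        x = ((lon - self._x0) / self._s).ravel()
        y = ((np.asarray(lat, dtype=float) - self._y0) / self._s).ravel()
        e = ((np.asarray(elev, dtype=float) - self._e0) / self._es).ravel()
        pts = np.column_stack([x, y])
        r = np.linalg.norm(pts[:, None, :] - self._pts[None, :, :], axis=-1)
        out = _tps_kernel(r) @ self._w + self._c[0] + self._c[1] * x + self._c[2] * y + self._c[3] * e
        return out.reshape(shape)

    @property
    def elevation_slope(self) -> float:
        """Fitted linear elevation coefficient, per metre."""
        return float(self._c[3] / self._es)

    def training_residuals(self) -> np.ndarray:
        lon, lat, elev, values = self._train
        return values - self.predict(lon, lat, elev)


def fit_interpolator(
    stations: pd.DataFrame,
    value_col: str,
    smoothing: float = 0.0,
) -> ElevationTPS:
    """Fit the elevation-covariate TPS to one column of a station table.

    ``stations`` needs columns ``lon``, ``lat``, ``elevation_m`` and
    ``value_col`` (the layout produced by
    :func:`antestia.risk_indices.indices_at_stations`).
    """
    for col in ("lon", "lat", "elevation_m", value_col):
        if col not in stations.columns:
            raise ValueError(f"station table lacks column {col!r}")
    return ElevationTPS(
        stations["lon"].to_numpy(), stations["lat"].to_numpy(),
        stations["elevation_m"].to_numpy(), stations[value_col].to_numpy(),
        smoothing=smoothing,
    )


def interpolate(
    interp: ElevationTPS,
    dem: DEMGrid,
    name: str = "value",
    units: str = "",
    clip: Tuple[float, float] | None = None,
) -> RasterMap:
    """Evaluate a fitted interpolator on every valid DEM cell."""
    lon, lat = dem.grid.cell_centers()
    mask = dem.mask
    train_elev = interp._train[2]
    dem_elev = dem.elevation[mask]
    if dem_elev.size and (
        dem_elev.min() < train_elev.min() - 50 or dem_elev.max() > train_elev.max() + 50
    ):
        warnings.warn(
            "DEM elevations extend well beyond the station elevation range; "
            "interpolated values are extrapolations there",
            stacklevel=2,
        )
    values = np.full(dem.elevation.shape, NODATA)
    values[mask] = interp.predict(lon[mask], lat[mask], dem.elevation[mask])
    if clip is not None:
        values[mask] = np.clip(values[mask], clip[0], clip[1])
    return RasterMap(grid=dem.grid, values=values, name=name, units=units)


# ---------------------------------------------------------------------------
# Point and band sampling


def sample_points(raster: RasterMap, coords: Sequence[Tuple[float, float]]) -> pd.DataFrame:
    """Nearest-cell raster values at (lon, lat) coordinates.

    Returns one row per coordinate with ``value`` (NaN when missing),
    ``ok`` and a ``reason`` for per-point failures.
    """
    rows = []
    for lon, lat in coords:
        try:
            r, c = raster.grid.index_of(lon, lat)
        except IndexError:
            rows.append({"lon": lon, "lat": lat, "value": np.nan,
                         "ok": False, "reason": "out of bounds"})
            continue
        v = raster.values[r, c]
        if v == raster.nodata:
            rows.append({"lon": lon, "lat": lat, "value": np.nan,
                         "ok": False, "reason": "nodata"})
        else:
            rows.append({"lon": lon, "lat": lat, "value": float(v),
                         "ok": True, "reason": ""})
    return pd.DataFrame(rows)


def band_sample(
    dem: DEMGrid,
    rasters: Dict[str, RasterMap],
    band_centres: Sequence[float],
    n_per_band: int = 20,
    seed: int = 0,
    half_width: float = 50.0,
) -> pd.DataFrame:
    """Randomly sample the same cells from every raster in elevation bands.

    Each band is ``centre − half_width <= elev < centre + half_width``
    (half-open above, so adjacent 100-m bands never share a cell).  The
    identical cell set per band is sampled from every raster, keeping
    current/future values paired.
    """
    for nm, rast in rasters.items():
        if rast.grid != dem.grid:
            raise ValueError(f"raster {nm!r} is not aligned with the DEM")
    rng = np.random.default_rng(seed)
    lon, lat = dem.grid.cell_centers()
    rows = []
    for centre in band_centres:
        in_band = dem.mask & (dem.elevation >= centre - half_width) \
            & (dem.elevation < centre + half_width)
        idx = np.flatnonzero(in_band.ravel())
        if idx.size < n_per_band:
            raise ValueError(
                f"elevation band {centre:g} m has only {idx.size} cells, "
                f"need {n_per_band}"
            )
        chosen = rng.choice(idx, size=n_per_band, replace=False)
        r, c = np.unravel_index(chosen, dem.elevation.shape)
        for ri, ci in zip(r, c):
            row = {"band_m": float(centre), "row": int(ri), "col": int(ci),
                   "lon": float(lon[ri, ci]), "lat": float(lat[ri, ci]),
                   "elevation_m": float(dem.elevation[ri, ci])}
            for nm, rast in rasters.items():
                v = rast.values[ri, ci]
                row[nm] = np.nan if v == rast.nodata else float(v)
            rows.append(row)
    return pd.DataFrame(rows)


def density_map_from_glm(fit, dem: DEMGrid, trees_per_farm: int = 15) -> RasterMap:
    """Per-tree bug density raster from an elevation GLM fit.

    The GLM predicts the per-farm count (totals over ``trees_per_farm``
    trees) on a log link; the cell value is the per-tree mean
    ``exp(intercept + slope · elev) / trees_per_farm``.
    """
    if getattr(fit, "predictor", None) != "elevation":
        raise ValueError("density mapping requires a GLM fitted on elevation")
    b0, b1 = fit.params
    values = np.full(dem.elevation.shape, NODATA)
    mask = dem.mask
    values[mask] = np.exp(b0 + b1 * dem.elevation[mask]) / trees_per_farm
    return RasterMap(grid=dem.grid, values=values,
                     name="density", units="bugs per tree")


# ---------------------------------------------------------------------------
# Raster I/O


def write_ascii_grid(raster, path) -> None:
    """Arc/Info ASCII grid, 6 significant digits (bit-exact round trip)."""
    grid = raster.grid
    values = raster.elevation if isinstance(raster, DEMGrid) else raster.values
    nodata = raster.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_origin - grid.nrows * grid.cell!r}\n")
        fh.write(f"cellsize {grid.cell!r}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in values:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path, as_dem: bool = False):
    header: Dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    cell = header["cellsize"]
    grid = GridSpec(
        nrows=nrows, ncols=ncols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cell,
        cell=cell,
    )
    nodata = header["nodata_value"]
    if as_dem:
        return DEMGrid(grid=grid, elevation=data, nodata=nodata)
    return RasterMap(grid=grid, values=data, name=Path(path).stem, nodata=nodata)


def write_geotiff(raster, path) -> None:
    """GeoTIFF with ModelPixelScale/ModelTiepoint georeferencing tags."""
    import tifffile

    grid = raster.grid
    values = raster.elevation if isinstance(raster, DEMGrid) else raster.values
    extratags = [
        (33550, "d", 3, (grid.cell, grid.cell, 0.0)),            # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, grid.x_origin, grid.y_origin, 0.0)),
        (42113, "s", 0, f"{raster.nodata:g}"),                    # GDAL nodata
    ]
    tifffile.imwrite(path, values.astype(np.float64), extratags=extratags)


def read_geotiff(path, as_dem: bool = False):
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = page.tags
        scale = tags[33550].value
        tiepoint = tags[33922].value
        nodata = float(tags[42113].value) if 42113 in tags else NODATA
    cell = float(scale[0])
    grid = GridSpec(
        nrows=data.shape[0], ncols=data.shape[1],
        x_origin=float(tiepoint[3]), y_origin=float(tiepoint[4]), cell=cell,
    )
    if as_dem:
        return DEMGrid(grid=grid, elevation=data, nodata=nodata)
    return RasterMap(grid=grid, values=data, name=Path(path).stem, nodata=nodata)
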