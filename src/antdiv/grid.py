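"""Geographic grid specification, spherical cell areas, and plain-text raster I/O.

All rasters in this package are north-up numpy arrays tied to a
:class:`GridSpec` in geographic (WGS84 lon/lat) coordinates with
cell-center registration: row 0 is the northernmost row, column 0 the
westernmost column, and a cell ``(i, j)`` spans the half-open interval
``[lon_min + j*dx, lon_min + (j+1)*dx) x (lat_max - (i+1)*dy, lat_max - i*dy]``.

Cell areas are computed analytically on the sphere rather than by
reprojecting to an equal-area CRS: for a cell spanning ``dlon`` radians of
longitude between latitudes ``phi_bot`` and ``phi_top``,

    area = R^2 * dlon * (sin(phi_top) - sin(phi_bot)),   R = 6371 km.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid with land and exclusion masks.

    Parameters
    ----------
    resolution_arcmin : float
        Cell size in arc-minutes (square cells in degrees).
    lon_min, lon_max, lat_min, lat_max : float
        Grid bounds in degrees; must be exact multiples of the resolution.
    land_mask : ndarray of bool, shape (n_rows, n_cols)
        True on analysable (land) cells.
    exclusion_mask : ndarray of bool
        True on cells excluded from diversity-center and correlation
        analyses (the polar "Antarctica" analog). A subset of the grid,
        not necessarily of land.
    """

    resolution_arcmin: float
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    land_mask: np.ndarray = field(repr=False)
    exclusion_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.resolution_arcmin <= 0:
            raise ValueError("resolution_arcmin must be positive")
        for name, n in (("n_cols", self._span_cells(self.lon_min, self.lon_max)),
                        ("n_rows", self._span_cells(self.lat_min, self.lat_max))):
            if abs(n - round(n)) > 1e-9 or round(n) < 1:
                raise ValueError(f"grid bounds do not yield an integral {name}: {n}")
        shape = (self.n_rows, self.n_cols)
        if self.land_mask.shape != shape or self.exclusion_mask.shape != shape:
            raise ValueError(f"masks must have shape {shape}")

    def _span_cells(self, lo: float, hi: float) -> float:
        return (hi - lo) * 60.0 / self.resolution_arcmin

    @property
    def cell_deg(self) -> float:
        return self.resolution_arcmin / 60.0

    @property
    def n_cols(self) -> int:
        return round(self._span_cells(self.lon_min, self.lon_max))

    @property
    def n_rows(self) -> int:
        return round(self._span_cells(self.lat_min, self.lat_max))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lon_centers(self) -> np.ndarray:
        d = self.cell_deg
        return self.lon_min + d * (np.arange(self.n_cols) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, north to south (row 0 first)."""
        d = self.cell_deg
        return self.lat_max - d * (np.arange(self.n_rows) + 0.5)

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int):
        return self.lon_centers[np.asarray(col)], self.lat_centers[np.asarray(row)]

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col); half-open cells, clipped to bounds."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        d = self.cell_deg
        col = np.clip(np.floor((lon - self.lon_min) / d).astype(int), 0, self.n_cols - 1)
        row = np.clip(np.floor((self.lat_max - lat) / d).astype(int), 0, self.n_rows - 1)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= self.lon_min) & (lon < self.lon_max) & \
               (lat > self.lat_min) & (lat <= self.lat_max)

    @property
    def analysis_mask(self) -> np.ndarray:
        """Land cells not excluded (the cells diversity statistics use)."""
        return self.land_mask & ~self.exclusion_mask


def spherical_cell_areas(grid: GridSpec) -> np.ndarray:
    """Per-cell spherical area in km^2; depends on latitude band only."""
    d = np.deg2rad(grid.cell_deg)
    lat_top = np.deg2rad(grid.lat_max - grid.cell_deg * np.arange(grid.n_rows))
    lat_bot = lat_top - np.deg2rad(grid.cell_deg)
    band = EARTH_RADIUS_KM ** 2 * d * (np.sin(lat_top) - np.sin(lat_bot))
    return np.repeat(band[:, None], grid.n_cols, axis=1)


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in km; broadcasts over inputs."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray,
                     nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI ASCII grid (text) aligned to ``grid``."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    out = np.where(np.isfinite(values), values, nodata)
    header = (f"ncols {grid.n_cols}\nnrows {grid.n_rows}\n"
              f"xllcorner {grid.lon_min}\nyllcorner {grid.lat_min}\n"
              f"cellsize {grid.cell_deg}\nNODATA_value {nodata}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; NODATA becomes NaN. Returns (values, header)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline().split()
            key = line[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(line[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return values, header
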