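"""Richness / rarity stacking, diversity-center detection, and coarsening.

Richness of cell i is the stacked weight sum ``s_i = sum_j w_ij`` where
``w_ij`` is 1 inside a polygonal range estimate and the continuous
cloglog suitability for modeled species. Rarity dampens each species by
its range area: ``r_i = sum_j w_ij / (a_j + c)`` with a damping constant
``c`` (default 60,000 km^2, a circular range of radius ~138 km) that
keeps single-locality "sampling islands" from dominating the map.

Diversity centers are the cells holding the top fraction (default 10%)
of total analysed area ranked by the metric, with Antarctica-analog
cells excluded; the threshold is found by accumulating true spherical
cell areas, not by a value quantile on a reprojected grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, spherical_cell_areas
from .range_geometry import RangeEstimate

METRIC_RICHNESS = "richness"
METRIC_RARITY = "rarity"


@dataclass
class DiversityRaster:
    """Gridded diversity surface; NaN exactly on masked (non-analysis) cells."""

    grid: GridSpec
    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")

    def masked_to(self, mask: np.ndarray) -> "DiversityRaster":
        vals = np.where(mask, self.values, np.nan)
        return DiversityRaster(self.grid, self.metric, vals)


@dataclass(frozen=True)
class RarityParams:
    """Damping constant c (km^2) added to every range area in rarity."""

    c: float = 60000.0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be non-negative")

    @property
    def equivalent_radius_km(self) -> float:
        """Radius of the circular range with area c (the intuitive gloss
        of the damping constant)."""
        return math.sqrt(self.c / math.pi)


@dataclass
class CenterMask:
    """Cells holding the top ``fraction`` of analysed area by a metric."""

    grid: GridSpec
    member: np.ndarray = field(repr=False)
    fraction: float = 0.10
    realized_area_fraction: float = float("nan")

    def area_km2(self) -> float:
        return float(spherical_cell_areas(self.grid)[self.member].sum())


def _check_same_grid(ranges: list[RangeEstimate], grid: GridSpec) -> None:
    for r in ranges:
        if r.weight_raster.shape != grid.shape:
            raise ValueError(f"range {r.species_id} is not on the target grid")


def stack_richness(ranges: list[RangeEstimate], grid: GridSpec) -> DiversityRaster:
    """s_i = sum_j w_ij over all species; NaN off the land mask."""
    _check_same_grid(ranges, grid)
    s = np.zeros(grid.shape)
    for r in ranges:
        s += r.weight_raster
    s = np.where(grid.land_mask, s, np.nan)
    return DiversityRaster(grid=grid, metric=METRIC_RICHNESS, values=s)


def stack_rarity(ranges: list[RangeEstimate], params: RarityParams,
                 grid: GridSpec) -> DiversityRaster:
    """r_i = sum_j w_ij / (a_j + c); contributions shrink with range area."""
    _check_same_grid(ranges, grid)
    s = np.zeros(grid.shape)
    for r in ranges:
        if r.area_km2 is None or not np.isfinite(r.area_km2):
            raise ValueError(f"range {r.species_id} lacks a computed area")
        s += r.weight_raster / (r.area_km2 + params.c)
    s = np.where(grid.land_mask, s, np.nan)
    return DiversityRaster(grid=grid, metric=METRIC_RARITY, values=s)


def detect_centers(raster: DiversityRaster, fraction: float = 0.10) -> CenterMask:
    """Top-fraction-of-area diversity centers (exclusion zone removed).

    Cells are sorted by value (descending, ties broken by flat cell index
    so the result is deterministic) and accumulated by spherical area
    until ``fraction`` of the total analysed area is reached; the first
    cell crossing the threshold is included, so the realized fraction
    overshoots by at most one cell's area share.
    """
    grid = raster.grid
    analysis = grid.analysis_mask & np.isfinite(raster.values)
    if not analysis.any():
        raise ValueError("no analysable cells in raster")
    areas = spherical_cell_areas(grid)
    flat_idx = np.nonzero(analysis.ravel())[0]
    vals = raster.values.ravel()[flat_idx]
    cell_areas = areas.ravel()[flat_idx]
    order = np.lexsort((flat_idx, -vals))
    csum = np.cumsum(cell_areas[order])
    total = csum[-1]
    target = fraction * total
    n_in = int(np.searchsorted(csum, target, side="left") + 1)
    n_in = min(n_in, len(order))
    member = np.zeros(grid.shape, bool).ravel()
    member[flat_idx[order[:n_in]]] = True
    member = member.reshape(grid.shape)
    return CenterMask(grid=grid, member=member, fraction=fraction,
                      realized_area_fraction=float(csum[n_in - 1] / total))


def coarsen_max(values: np.ndarray, factor: int) -> np.ndarray:
    """Block-maximum coarsening: each coarse cell is the max of its
    factor x factor block (NaN-ignoring; all-NaN blocks stay NaN).

    A block of suitabilities {0.2, 0.45, 0.9, 0.1} coarsens to 0.9 (and a
    binary block {0, 0, 1, 0} to 1): any suitable area inside the larger
    cell marks the larger cell suitable.
    """
    v = np.asarray(values, dtype=float)
    if factor < 2:
        warnings.warn("factor < 2: coarsen_max is the identity")
        return v.copy()
    nr, nc = v.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    if pr or pc:
        v = np.pad(v, ((0, pr), (0, pc)), constant_values=np.nan)
    blocks = v.reshape(v.shape[0] // factor, factor, v.shape[1] // factor, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        return np.nanmax(blocks.transpose(0, 2, 1, 3).reshape(
            blocks.shape[0], blocks.shape[2], -1), axis=2)


def coarsen_raster(raster: DiversityRaster, factor: int) -> DiversityRaster:
    """Coarsen a diversity raster (values and masks) by block maximum."""
    vals = coarsen_max(raster.values, factor)
    grid = raster.grid
    land = coarsen_max(grid.land_mask.astype(float), factor) > 0
    excl = coarsen_max(grid.exclusion_mask.astype(float), factor) > 0
    coarse = GridSpec(grid.resolution_arcmin * factor, grid.lon_min,
                      grid.lon_min + land.shape[1] * grid.cell_deg * factor,
                      grid.lat_max - land.shape[0] * grid.cell_deg * factor,
                      grid.lat_max, land_mask=land, exclusion_mask=excl)
    return DiversityRaster(grid=coarse, metric=raster.metric, values=vals)
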