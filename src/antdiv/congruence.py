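"""Cross-taxon congruence, upper-bound checks, and protected-area coverage.

Agreement between taxa is quantified two ways: Spearman rank correlation
of diversity surfaces over jointly valid cells (zeros included,
Antarctica-analog excluded), and the spherical-area overlap fraction of
their diversity-center masks. Community-level point observations serve
as an upper-bound check on stacked richness: the highest observed
richness per (coarsened) cell is regressed on the modeled value and R^2
reported per resolution. Protected-area coverage dissolves the polygon
layer to a single union before measuring the covered center fraction, so
overlapping designations are never double-counted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.ops import unary_union

from .diversity_mapping import CenterMask, DiversityRaster, coarsen_max, detect_centers
from .grid import spherical_cell_areas


def spearman_between(a: DiversityRaster, b: DiversityRaster) -> float:
    """Spearman rho over jointly non-NA analysis cells (average-rank ties).

    All valid cells enter, zero or not; the exclusion zone is removed.
    """
    if a.grid.shape != b.grid.shape:
        raise ValueError("rasters must share a grid")
    mask = (a.grid.analysis_mask & np.isfinite(a.values) & np.isfinite(b.values))
    if mask.sum() < 3:
        raise ValueError("fewer than 3 jointly valid cells")
    rho, _ = stats.spearmanr(a.values[mask], b.values[mask])
    return float(rho)


def congruence_matrix(rasters: dict[str, DiversityRaster],
                      fraction: float = 0.10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman and center-overlap matrices across taxa."""
    taxa = list(rasters)
    rho = pd.DataFrame(np.eye(len(taxa)), index=taxa, columns=taxa)
    ov = pd.DataFrame(np.eye(len(taxa)), index=taxa, columns=taxa)
    centers = {t: detect_centers(rasters[t], fraction) for t in taxa}
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            r = spearman_between(rasters[t1], rasters[t2])
            rho.loc[t1, t2] = rho.loc[t2, t1] = r
            o = overlap_fraction(centers[t1], centers[t2])
            ov.loc[t1, t2] = ov.loc[t2, t1] = o
    return rho, ov


def overlap_fraction(a: CenterMask, b: CenterMask) -> float:
    """Spherical area of (a intersect b) / spherical area of a.

    With equal-fraction center masks the denominators match and the
    statistic is symmetric.
    """
    if a.grid.shape != b.grid.shape:
        raise ValueError("masks must share a grid")
    if not a.member.any():
        raise ValueError("first mask is empty")
    areas = spherical_cell_areas(a.grid)
    inter = float(areas[a.member & b.member].sum())
    return inter / float(areas[a.member].sum())


def upper_bound_comparison(model_richness: DiversityRaster,
                           community_obs: pd.DataFrame,
                           factors: tuple[int, ...] = (1, 2, 5, 10)
                           ) -> pd.DataFrame:
    """Per-resolution R^2 of max observed community richness vs modeled.

    ``community_obs`` columns: ``row``, ``col``, ``study``, ``richness``
    (never summed across studies in a cell — the maximum per cell is
    kept). For each coarsening factor the model raster is block-max
    coarsened, observations are re-binned and reduced to their per-cell
    maximum, and an OLS of observed on modeled gives R^2 together with the
    count of cells where the observation exceeds the model (upper-bound
    violations). Resolutions with < 3 matched cells report NA.
    """
    rows = []
    base = model_richness.values
    for f in factors:
        model = base if f == 1 else coarsen_max(base, f)
        obs = community_obs.copy()
        obs["r"] = obs["row"] // f
        obs["c"] = obs["col"] // f
        # per-study richness is never summed across studies or cells: the
        # coarse cell keeps the single highest observed value
        cellmax = obs.groupby(["r", "c"], as_index=False)["richness"].max()
        mvals = model[cellmax["r"].to_numpy(), cellmax["c"].to_numpy()]
        ok = np.isfinite(mvals)
        x, yv = mvals[ok], cellmax["richness"].to_numpy(float)[ok]
        if ok.sum() < 3 or np.ptp(x) == 0:
            rows.append(dict(factor=f, n_cells=int(ok.sum()), r2=np.nan,
                             violations=np.nan))
            continue
        res = stats.linregress(x, yv)
        rows.append(dict(factor=f, n_cells=int(ok.sum()),
                         r2=float(res.rvalue ** 2),
                         violations=int(np.sum(yv > x))))
    return pd.DataFrame(rows)


def dissolve(polygons: list) -> shapely.Geometry:
    """Union overlapping polygons into a single non-overlapping layer,
    repairing invalid geometries with a zero-width buffer."""
    fixed = []
    for p in polygons:
        if not p.is_valid:
            p = p.buffer(0)
            if p.is_empty or not p.is_valid:
                raise ValueError("polygon could not be repaired")
        fixed.append(p)
    return unary_union(fixed)


def protected_coverage(centers: CenterMask, protected: list) -> float:
    """Fraction of diversity-center area lying inside protected areas.

    The protection layer is dissolved first; per center cell, the covered
    fraction is the planar share of the cell rectangle inside the union,
    scaled by the cell's spherical area (exact as cells shrink).
    """
    union = dissolve(protected)
    grid = centers.grid
    areas = spherical_cell_areas(grid)
    rows, cols = np.nonzero(centers.member)
    if rows.size == 0:
        raise ValueError("empty center mask")
    total = 0.0
    covered = 0.0
    d = grid.cell_deg
    lon_c, lat_c = grid.lon_centers, grid.lat_centers
    for r, c in zip(rows.tolist(), cols.tolist()):
        cell = shapely.box(lon_c[c] - d / 2, lat_c[r] - d / 2,
                           lon_c[c] + d / 2, lat_c[r] + d / 2)
        a = areas[r, c]
        total += a
        if union.intersects(cell):
            covered += a * cell.intersection(union).area / cell.area
    return covered / total
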