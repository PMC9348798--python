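"""Polygonal range estimation: triage, thinning, buffering, alpha hulls.

Species are triaged by their count of unique occurrence localities:
fewer than 3 localities get 30-km buffered points, 3-4 get a buffered
alpha hull, and 5+ get a suitability model fitted inside their buffered
alpha hull (``sdm_in_hull``; the model itself lives in
:mod:`antdiv.sdm_engine`).

Geometric operations work in geographic coordinates except metric
buffering, which runs in a Lambert azimuthal equal-area frame centered on
the geometry being buffered — this keeps buffer distances true in km
while avoiding the edge cases of a single global projection near the
antimeridian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import GeometryCollection, MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .grid import EARTH_RADIUS_KM, GridSpec, great_circle_km, spherical_cell_areas

METHOD_BUFFERED_POINTS = "buffered_points"
METHOD_ALPHA_HULL = "alpha_hull"
METHOD_SDM_IN_HULL = "sdm_in_hull"


@dataclass(frozen=True)
class RangeMethod:
    """Range-estimation method chosen from the unique-locality count."""

    method: str
    alpha: float = 15.0       # alpha-hull parameter, degrees
    buffer_km: float = 30.0


@dataclass
class RangeEstimate:
    """Per-species range: polygon, per-cell weights w_j, and area a_j (km^2).

    ``weight_raster`` is binary (1 inside the polygon) for polygonal
    methods and the continuous cloglog suitability for SDM species;
    ``area_km2`` is the weight-integrated spherical area
    ``sum_i w_ij * area_i``.
    """

    species_id: str
    method: RangeMethod
    polygon: shapely.Geometry
    weight_raster: np.ndarray
    area_km2: float
    hull_fallback: str | None = None


def select_range_method(n_unique_localities: int, alpha: float = 15.0,
                        buffer_km: float = 30.0) -> RangeMethod:
    """Triage: <3 localities -> buffered points; 3-4 -> alpha hull; >=5 -> SDM."""
    n = int(n_unique_localities)
    if n <= 0:
        raise ValueError("species must have at least one locality")
    if n < 3:
        m = METHOD_BUFFERED_POINTS
    elif n < 5:
        m = METHOD_ALPHA_HULL
    else:
        m = METHOD_SDM_IN_HULL
    return RangeMethod(method=m, alpha=alpha, buffer_km=buffer_km)


# ---------------------------------------------------------------------------
# spatial thinning

def thin_points(points: np.ndarray, min_km: float, seed: int = 0,
                n_reps: int = 20) -> np.ndarray:
    """Thin points so all pairwise great-circle distances are >= ``min_km``.

    Runs ``n_reps`` seeded randomized greedy passes (random insertion
    order, keep a point iff it is far enough from everything already kept)
    and returns the largest retained set; an exact maximum independent set
    is NP-hard, and the repeated-greedy strategy is the standard practice
    for occurrence thinning. Deterministic under a fixed seed.
    """
    if min_km <= 0:
        raise ValueError("min_km must be positive")
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n <= 1:
        return pts.copy()
    d = great_circle_km(pts[:, None, 0], pts[:, None, 1], pts[None, :, 0], pts[None, :, 1])
    conflict = d < min_km
    np.fill_diagonal(conflict, False)
    if not conflict.any():
        return pts.copy()
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(n_reps):
        order = rng.permutation(n)
        kept: list[int] = []
        for i in order:
            if not conflict[i, kept].any():
                kept.append(i)
        if best is None or len(kept) > len(best):
            best = np.array(sorted(kept))
    return pts[best]


# ---------------------------------------------------------------------------
# local equal-area projection (Lambert azimuthal)

def _laea_forward(coords: np.ndarray, lon0: float, lat0: float) -> np.ndarray:
    lam = np.deg2rad(coords[:, 0] - lon0)
    phi = np.deg2rad(coords[:, 1])
    phi0 = np.deg2rad(lat0)
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
    k = np.sqrt(np.maximum(2.0 / np.maximum(denom, 1e-12), 0.0))
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(phi)
                               - np.sin(phi0) * np.cos(phi) * np.cos(lam))
    return np.column_stack([x, y])


def _laea_inverse(coords: np.ndarray, lon0: float, lat0: float) -> np.ndarray:
    x = coords[:, 0] / EARTH_RADIUS_KM
    y = coords[:, 1] / EARTH_RADIUS_KM
    phi0 = np.deg2rad(lat0)
    rho = np.hypot(x, y)
    c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(rho == 0, phi0,
                       np.arcsin(np.clip(np.cos(c) * np.sin(phi0)
                                         + y * np.sin(c) * np.cos(phi0) / np.where(rho == 0, 1, rho),
                                         -1, 1)))
        lam = np.where(rho == 0, 0.0,
                       np.arctan2(x * np.sin(c),
                                  rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c)))
    return np.column_stack([lon0 + np.rad2deg(lam), np.rad2deg(phi)])


def buffer_geometry(geom: shapely.Geometry, buffer_km: float,
                    quad_segs: int = 32) -> shapely.Geometry:
    """Buffer a geometry by a true metric distance.

    The geometry is projected into a Lambert azimuthal equal-area frame
    centered on its centroid, buffered in km there, and projected back, so
    point buffers are quasi-circular with area ~ pi * r^2.
    """
    if buffer_km <= 0:
        raise ValueError("buffer_km must be positive")
    if geom is None or geom.is_empty:
        raise ValueError("cannot buffer an empty geometry")
    cen = geom.centroid
    lon0, lat0 = cen.x, cen.y
    local = shapely.transform(geom, lambda c: _laea_forward(c, lon0, lat0))
    buf = local.buffer(buffer_km, quad_segs=quad_segs)
    return shapely.transform(buf, lambda c: _laea_inverse(c, lon0, lat0))


# ---------------------------------------------------------------------------
# alpha hulls

def _circumradius(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c), np.linalg.norm(a - b))
    s = 0.5 * (la + lb + lc)
    area2 = max(s * (s - la) * (s - lb) * (s - lc), 0.0)
    if area2 <= 0:
        return np.inf
    return la * lb * lc / (4.0 * np.sqrt(area2))


def alpha_hull(points: np.ndarray, alpha: float = 15.0
               ) -> tuple[shapely.Geometry, str]:
    """Alpha hull of lon/lat points; ``alpha`` is in coordinate degrees.

    Triangulates the points and keeps Delaunay triangles whose
    circumradius is at most ``alpha`` (the disc-radius construction of the
    alpha shape); large alpha recovers the convex hull, small alpha can
    split the hull into disjoint parts. Degenerate point sets fall back in
    order alpha shape -> convex hull -> buffered multipoint; the second
    return value records which path produced the geometry
    (``"alpha_hull"``, ``"convex_hull"``, or ``"buffered_multipoint"``).
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        raise ValueError("alpha hull requires at least 3 points")
    tri_polys: list[Polygon] = []
    try:
        from scipy.spatial import Delaunay, QhullError
        dela = Delaunay(pts)
        for simplex in dela.simplices:
            a, b, c = pts[simplex]
            if _circumradius(a, b, c) <= alpha:
                tri_polys.append(Polygon([a, b, c]))
    except (QhullError, ValueError):
        tri_polys = []
    if tri_polys:
        hull = unary_union(tri_polys)
        if not hull.is_empty and hull.area > 0:
            return hull, "alpha_hull"
    hull = MultiPoint([Point(p) for p in pts]).convex_hull
    if isinstance(hull, Polygon) and hull.area > 0:
        return hull, "convex_hull"
    # collinear or coincident points: quasi-metric buffer keeps it polygonal
    buffered = buffer_geometry(MultiPoint([Point(p) for p in pts]), 1.0)
    return buffered, "buffered_multipoint"


# ---------------------------------------------------------------------------
# rasterization and areas

def rasterize_range(polygon: shapely.Geometry, grid: GridSpec,
                    weights: np.ndarray | None = None,
                    land_only: bool = True) -> np.ndarray:
    """Per-cell weight raster: a cell belongs to the range iff its center
    lies inside the polygon (cell-center rule, WGS84, half-open cells).

    ``weights`` optionally supplies continuous values (e.g. suitability);
    otherwise cells get weight 1. With ``land_only`` the range is
    restricted to the grid's land mask.
    """
    if polygon is None or polygon.is_empty:
        raise ValueError("polygon is empty")
    out = np.zeros(grid.shape, dtype=float)
    x0, y0, x1, y1 = polygon.bounds
    if x1 < grid.lon_min or x0 > grid.lon_max or y1 < grid.lat_min or y0 > grid.lat_max:
        warnings.warn("polygon lies outside the grid; empty raster returned")
        return out
    lon_c, lat_c = np.meshgrid(grid.lon_centers, grid.lat_centers)
    bbox = ((lon_c >= x0 - grid.cell_deg) & (lon_c <= x1 + grid.cell_deg)
            & (lat_c >= y0 - grid.cell_deg) & (lat_c <= y1 + grid.cell_deg))
    idx = np.nonzero(bbox)
    inside = shapely.contains_xy(polygon, lon_c[idx], lat_c[idx])
    sel = (idx[0][inside], idx[1][inside])
    if weights is not None:
        out[sel] = weights[sel]
    else:
        out[sel] = 1.0
    if land_only:
        out[~grid.land_mask] = 0.0
    return out


def range_area_km2(weight_raster: np.ndarray, grid: GridSpec) -> float:
    """Weight-integrated spherical area a_j = sum_i w_ij * area_i."""
    return float(np.nansum(weight_raster * spherical_cell_areas(grid)))


def build_polygon_range(species_id: str, points: np.ndarray, grid: GridSpec,
                        alpha: float = 15.0, buffer_km: float = 30.0
                        ) -> RangeEstimate:
    """Triage a species by locality count and build its polygonal range.

    SDM-branch species also get their buffered alpha hull here (the study
    extent); the continuous suitability weights are attached later by the
    modeling stage.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    method = select_range_method(len(pts), alpha=alpha, buffer_km=buffer_km)
    fallback = None
    if method.method == METHOD_BUFFERED_POINTS:
        poly = unary_union([buffer_geometry(Point(p), buffer_km) for p in pts])
    else:
        hull, used = alpha_hull(pts, alpha=alpha)
        fallback = None if used == "alpha_hull" else used
        poly = buffer_geometry(hull, buffer_km)
    w = rasterize_range(poly, grid)
    if not w.any():
        # ensure non-empty occupancy: fall back to the cells holding points
        r, c = grid.cell_of(pts[:, 0], pts[:, 1])
        w[r, c] = np.where(grid.land_mask[r, c], 1.0, 1.0)
    return RangeEstimate(species_id=species_id, method=method, polygon=poly,
                         weight_raster=w, area_km2=range_area_km2(w, grid),
                         hull_fallback=fallback)
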