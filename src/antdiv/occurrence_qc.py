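"""Occurrence-record cleaning: pooling, coordinate validation, and resolution.

Raw records arrive as a pandas DataFrame (Darwin-Core-like columns, see
:data:`antdiv.synthetic_world.RECORD_COLUMNS`). The cleaning chain is:

1. :func:`pool_duplicates` — records sharing a normalized locality string,
   country, and coordinates rounded to four decimals (~11 m) form one
   locality group; geocoding happens once per group.
2. :func:`validate_coordinates` — coordinate sanity flags (out-of-range,
   (0,0), country mismatch against the gazetteer, missing/non-numeric).
   Problems are always flags, never exceptions.
3. :func:`resolve_coordinates` — a three-rule decision tree picks one
   coordinate per record, prioritizing original (metadata-derived)
   coordinates over geocodes and discarding geocodes whose precision
   radius exceeds 100 km.
4. :func:`flag_centroids` — records sitting on an admin-unit centroid whose
   locality names only that unit are flagged and excluded.
5. :func:`qc_summary` — bookkeeping report; retained = metadata-derived +
   geocoded, by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import great_circle_km
from .synthetic_world import SyntheticGazetteer

FLAG_OUT_OF_RANGE = "coord_out_of_range"
FLAG_ZERO_ZERO = "coord_zero_zero"
FLAG_COUNTRY_MISMATCH = "country_mismatch"
FLAG_COORD_MISSING = "coord_missing"
FLAG_CENTROID = "admin_centroid"

CLASS_METADATA = "metadata_derived"
CLASS_GEOCODED = "geocoded"
CLASS_UNRESOLVED = "unresolved"


def _norm_text(s: pd.Series) -> pd.Series:
    return s.fillna("").astype(str).str.strip().str.lower().str.replace(r"\s+", " ", regex=True)


def pool_duplicates(records: pd.DataFrame) -> pd.DataFrame:
    """Assign a locality ``group_key`` pooling duplicate collection events.

    The key is (normalized locality text, normalized country, original
    coordinates rounded to 4 decimal places); missing coordinates hash as
    the text key alone so textual duplicates without coordinates pool too.
    """
    out = records.copy()
    loc = _norm_text(out["locality_text"]) if "locality_text" in out else ""
    ctry = _norm_text(out["country_label"]) if "country_label" in out else ""
    lon = pd.to_numeric(out.get("orig_lon"), errors="coerce").round(4)
    lat = pd.to_numeric(out.get("orig_lat"), errors="coerce").round(4)
    lon_s = lon.map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    lat_s = lat.map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    out["group_key"] = loc + "|" + ctry + "|" + lon_s + "|" + lat_s
    return out


def _coord_flags(lon: pd.Series, lat: pd.Series) -> tuple[pd.Series, pd.Series, pd.Series]:
    missing = lon.isna() | lat.isna()
    out_of_range = (~missing) & ((lon.abs() > 180) | (lat.abs() > 90))
    zero_zero = (~missing) & (lon == 0) & (lat == 0)
    return missing, out_of_range, zero_zero


def validate_coordinates(records: pd.DataFrame,
                         gazetteer: SyntheticGazetteer) -> pd.DataFrame:
    """Attach per-candidate QC flag columns; never raises on bad values.

    Adds boolean columns ``orig_<flag>`` and ``geo_<flag>`` for the
    out-of-range, (0,0), missing, and country-mismatch checks. Country
    comparison is an exact match after case/whitespace normalization
    against the gazetteer's country at the candidate coordinate.
    """
    out = records.copy()
    ctry = _norm_text(out["country_label"])
    for prefix in ("orig", "geo"):
        lon = pd.to_numeric(out[f"{prefix}_lon"], errors="coerce")
        lat = pd.to_numeric(out[f"{prefix}_lat"], errors="coerce")
        missing, oor, zz = _coord_flags(lon, lat)
        mismatch = np.zeros(len(out), bool)
        ok = (~(missing | oor)).to_numpy()
        lon_ok = lon.to_numpy(dtype=float)[ok]
        lat_ok = lat.to_numpy(dtype=float)[ok]
        grid = gazetteer.grid
        on_grid = grid.contains(lon_ok, lat_ok)
        found = np.full(lon_ok.shape, "", dtype=object)
        if on_grid.any():
            r, c = grid.cell_of(lon_ok[on_grid], lat_ok[on_grid])
            found[on_grid] = np.char.lower(
                gazetteer.country_grid[r, c].astype(str))
        mismatch[ok] = found != ctry.to_numpy()[ok]
        out[f"{prefix}_{FLAG_COORD_MISSING}"] = missing.to_numpy()
        out[f"{prefix}_{FLAG_OUT_OF_RANGE}"] = oor.to_numpy()
        out[f"{prefix}_{FLAG_ZERO_ZERO}"] = zz.to_numpy()
        out[f"{prefix}_{FLAG_COUNTRY_MISMATCH}"] = mismatch
    return out


def resolve_coordinates(records: pd.DataFrame,
                        max_precision_km: float = 100.0) -> pd.DataFrame:
    """Pick one coordinate per record by the agreement decision tree.

    Rule 1: a present original coordinate with no out-of-range, (0,0), or
    country-mismatch flag wins (class ``metadata_derived``; originals are
    prioritized over geocodes).
    Rule 2: otherwise a geocode with no country mismatch and precision
    radius <= ``max_precision_km`` wins (class ``geocoded``).
    Rule 3: otherwise the record is ``unresolved`` and excluded downstream.

    Records with a mismatching original but a valid geocode fall through
    to rule 2.
    """
    out = records.copy()
    o_ok = (~out[f"orig_{FLAG_COORD_MISSING}"] & ~out[f"orig_{FLAG_OUT_OF_RANGE}"]
            & ~out[f"orig_{FLAG_ZERO_ZERO}"] & ~out[f"orig_{FLAG_COUNTRY_MISMATCH}"])
    radius = pd.to_numeric(out["precision_radius_km"], errors="coerce")
    g_ok = (~out[f"geo_{FLAG_COORD_MISSING}"] & ~out[f"geo_{FLAG_OUT_OF_RANGE}"]
            & ~out[f"geo_{FLAG_ZERO_ZERO}"] & ~out[f"geo_{FLAG_COUNTRY_MISMATCH}"]
            & (radius.fillna(0.0) <= max_precision_km))
    cls = np.where(o_ok, CLASS_METADATA, np.where(g_ok, CLASS_GEOCODED, CLASS_UNRESOLVED))
    out["provenance_class"] = cls
    out["resolved_lon"] = np.where(o_ok, out["orig_lon"],
                                   np.where(g_ok, out["geo_lon"], np.nan))
    out["resolved_lat"] = np.where(o_ok, out["orig_lat"],
                                   np.where(g_ok, out["geo_lat"], np.nan))
    return out


def flag_centroids(records: pd.DataFrame, gazetteer: SyntheticGazetteer,
                   tol_km: float = 1.0) -> pd.DataFrame:
    """Flag records resolved onto an admin-unit centroid they merely name.

    A record is flagged only when (a) its resolved coordinate lies within
    ``tol_km`` of an admin-unit or country centroid and (b) its locality
    text names that unit rather than a finer place.
    """
    out = records.copy()
    flagged = np.zeros(len(out), bool)
    loc = _norm_text(out["locality_text"])
    lon = pd.to_numeric(out["resolved_lon"], errors="coerce")
    lat = pd.to_numeric(out["resolved_lat"], errors="coerce")
    for name, (clon, clat) in gazetteer.admin_centroids.items():
        names_unit = loc == name.strip().lower()
        if not names_unit.any():
            continue
        d = great_circle_km(lon[names_unit], lat[names_unit], clon, clat)
        sub = np.zeros(len(out), bool)
        sub[np.nonzero(names_unit.to_numpy())[0]] = np.asarray(d) <= tol_km
        flagged |= sub
    out[FLAG_CENTROID] = flagged & (out["provenance_class"] != CLASS_UNRESOLVED)
    excl = out[FLAG_CENTROID]
    out.loc[excl, "provenance_class"] = CLASS_UNRESOLVED
    out.loc[excl, ["resolved_lon", "resolved_lat"]] = np.nan
    return out


@dataclass
class QCReport:
    """Cleaning bookkeeping. ``n_total_retained`` is the additive identity
    metadata-derived + geocoded — the two provenance classes that carry a
    usable coordinate."""

    n_input: int = 0
    n_pooled_localities: int = 0
    n_metadata_derived: int = 0
    n_geocoded: int = 0
    n_unresolved: int = 0
    n_flagged_by_flag: dict = dc_field(default_factory=dict)

    @property
    def n_total_retained(self) -> int:
        return self.n_metadata_derived + self.n_geocoded

    def to_json(self, path: str | Path | None = None) -> str:
        d = {k: getattr(self, k) for k in
             ("n_input", "n_pooled_localities", "n_metadata_derived",
              "n_geocoded", "n_unresolved")}
        d["n_total_retained"] = self.n_total_retained
        d["n_flagged_by_flag"] = self.n_flagged_by_flag
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def qc_summary(records: pd.DataFrame) -> QCReport:
    """Summarize a fully resolved record table into a :class:`QCReport`."""
    if len(records) == 0:
        return QCReport()
    cls = records["provenance_class"]
    flags = {}
    for col in records.columns:
        if any(col.endswith(f) for f in (FLAG_OUT_OF_RANGE, FLAG_ZERO_ZERO,
                                         FLAG_COUNTRY_MISMATCH, FLAG_COORD_MISSING)) \
                or col == FLAG_CENTROID:
            n = int(records[col].sum())
            if n:
                flags[col] = n
    return QCReport(
        n_input=int(len(records)),
        n_pooled_localities=int(records["group_key"].nunique()) if "group_key" in records else 0,
        n_metadata_derived=int((cls == CLASS_METADATA).sum()),
        n_geocoded=int((cls == CLASS_GEOCODED).sum()),
        n_unresolved=int((cls == CLASS_UNRESOLVED).sum()),
        n_flagged_by_flag=flags)


def run_qc(records: pd.DataFrame, gazetteer: SyntheticGazetteer,
           max_precision_km: float = 100.0,
           centroid_tol_km: float = 1.0) -> tuple[pd.DataFrame, QCReport]:
    """Full cleaning chain; returns the resolved table and its report."""
    df = pool_duplicates(records)
    df = validate_coordinates(df, gazetteer)
    df = resolve_coordinates(df, max_precision_km=max_precision_km)
    df = flag_centroids(df, gazetteer, tol_km=centroid_tol_km)
    return df, qc_summary(df)


def retained(records: pd.DataFrame) -> pd.DataFrame:
    """Records carrying a resolved coordinate (analysis subset)."""
    return records[records["provenance_class"] != CLASS_UNRESOLVED].copy()
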