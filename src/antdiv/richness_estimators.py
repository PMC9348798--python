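"""Moving-window incidence-based richness estimation (Chao2, Hill q = 0).

An alternative richness surface built directly from occurrence records,
independent of range polygons and suitability models. Occurrences inside
each moving window (default 60 x 60 cells) are summarized as incidence
frequencies — the number of distinct grid cells each species occupies,
not raw record counts — and the window's richness is estimated with the
bias-corrected Chao2 lower bound together with its incidence-based
sample-coverage estimate. Windows with fewer than two occupied cells, or
whose singletons account for every incidence, are omitted as unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity_mapping import DiversityRaster, METRIC_RICHNESS
from .grid import GridSpec


@dataclass
class IncidenceFreq:
    """Incidence summary for one window of T sampling units (cells)."""

    T: int
    Y: np.ndarray          # per-species incidence counts (cells with >= 1 record)
    n_occupied_cells: int  # distinct cells holding any incidence

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=int)
        if self.Y.size and (self.Y.min() < 1 or self.Y.max() > self.T):
            raise ValueError("incidences must satisfy 0 < Y_j <= T")

    @property
    def S_obs(self) -> int:
        return int(self.Y.size)

    @property
    def Q1(self) -> int:
        return int(np.sum(self.Y == 1))

    @property
    def Q2(self) -> int:
        return int(np.sum(self.Y == 2))

    @property
    def U(self) -> int:
        return int(self.Y.sum())


@dataclass(frozen=True)
class WindowSpec:
    window_cells: int = 60
    stride: int = 30

    def __post_init__(self) -> None:
        if self.window_cells < 2:
            raise ValueError("window_cells must be >= 2")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def window_incidence(cell_records: pd.DataFrame,
                     row_range: tuple[int, int],
                     col_range: tuple[int, int]) -> IncidenceFreq:
    """Incidence frequencies for records inside a window.

    ``cell_records`` columns: ``species_id``, ``row``, ``col`` (one row
    per record; duplicate records in a cell count once — incidences are
    distinct occupied cells per species). Ranges are half-open.
    """
    r0, r1 = row_range
    c0, c1 = col_range
    sel = cell_records[(cell_records["row"] >= r0) & (cell_records["row"] < r1)
                       & (cell_records["col"] >= c0) & (cell_records["col"] < c1)]
    uniq = sel[["species_id", "row", "col"]].drop_duplicates()
    Y = uniq.groupby("species_id").size().to_numpy()
    occupied = len(uniq[["row", "col"]].drop_duplicates())
    return IncidenceFreq(T=(r1 - r0) * (c1 - c0), Y=Y, n_occupied_cells=occupied)


def chao2_estimate(freq: IncidenceFreq) -> tuple[float, float]:
    """Bias-corrected Chao2 richness and incidence-based coverage.

    S_hat = S_obs + ((T-1)/T) * Q1^2 / (2 Q2)            if Q2 > 0
          = S_obs + ((T-1)/T) * Q1 (Q1 - 1) / 2          if Q2 = 0
    C_hat = 1 - (Q1/U) * [(T-1) Q1 / ((T-1) Q1 + 2 Q2)]

    Always S_hat >= S_obs. Returns (NaN, NaN) when there are no incidences.
    """
    if freq.U == 0 or freq.S_obs < 1:
        return (np.nan, np.nan)
    T, Q1, Q2, U = freq.T, freq.Q1, freq.Q2, freq.U
    k = (T - 1) / T
    if Q2 > 0:
        s_hat = freq.S_obs + k * Q1 ** 2 / (2 * Q2)
    else:
        s_hat = freq.S_obs + k * Q1 * (Q1 - 1) / 2
    denom = k * Q1 + 2 * Q2
    coverage = 1.0 - (Q1 / U) * (k * Q1 / denom) if denom > 0 else 1.0
    return float(s_hat), float(coverage)


def window_filters(freq: IncidenceFreq) -> bool:
    """True iff the window is reliable enough to estimate.

    Excluded: fewer than 2 grid cells containing incidences, or as many
    singletons as total incidences (Q1 == U, the undefined-extrapolation
    case).
    """
    if freq.n_occupied_cells < 2:
        return False
    if freq.U > 0 and freq.Q1 == freq.U:
        return False
    return freq.U > 0


def moving_window_map(cell_records: pd.DataFrame, grid: GridSpec,
                      spec: WindowSpec = WindowSpec()) -> DiversityRaster:
    """Chao2 richness surface from stride-spaced moving windows.

    Each admissible window writes its estimate onto its full footprint;
    cells covered by several overlapping windows take the average of
    their estimates, cells covered only by filtered windows stay NaN.
    """
    acc = np.zeros(grid.shape)
    cnt = np.zeros(grid.shape)
    w, s = spec.window_cells, spec.stride
    # unique (species, cell) incidences once; windows then reduce with numpy
    uniq = cell_records[["species_id", "row", "col"]].drop_duplicates()
    sp_codes = pd.factorize(uniq["species_id"])[0]
    n_sp = sp_codes.max() + 1 if len(sp_codes) else 0
    u_row = uniq["row"].to_numpy()
    u_col = uniq["col"].to_numpy()
    row_starts = list(range(0, max(grid.n_rows - w, 0) + 1, s)) or [0]
    col_starts = list(range(0, max(grid.n_cols - w, 0) + 1, s)) or [0]
    for r0 in row_starts:
        r1 = min(r0 + w, grid.n_rows)
        in_rows = (u_row >= r0) & (u_row < r1)
        for c0 in col_starts:
            c1 = min(c0 + w, grid.n_cols)
            sel = in_rows & (u_col >= c0) & (u_col < c1)
            if not sel.any():
                continue
            Y = np.bincount(sp_codes[sel], minlength=n_sp)
            Y = Y[Y > 0]
            occupied = len(np.unique(u_row[sel] * grid.n_cols + u_col[sel]))
            freq = IncidenceFreq(T=(r1 - r0) * (c1 - c0), Y=Y,
                                 n_occupied_cells=occupied)
            if not window_filters(freq):
                continue
            s_hat, _ = chao2_estimate(freq)
            if not np.isfinite(s_hat):
                continue
            acc[r0:r1, c0:c1] += s_hat
            cnt[r0:r1, c0:c1] += 1
    with np.errstate(invalid="ignore"):
        vals = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    vals = np.where(grid.land_mask, vals, np.nan)
    return DiversityRaster(grid=grid, metric=METRIC_RICHNESS, values=vals)
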