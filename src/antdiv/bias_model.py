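"""Sampling-bias counterfactual: spatially tuned Random Forest "treasure map".

Observed diversity surfaces confound true biogeography with collection
effort. To separate the two, a Random Forest regresses the empirical
richness or rarity surface on environment, a topography analog,
biogeographic realm, companion-taxon diversity, and — crucially — the
sampling-density surface. Model complexity (``mtry``, the number of
candidate predictors per split, grid 1-10) is tuned by five-fold spatial
cross-validation on a systematic 10 x 14 checkerboard so that validation
blocks are spatially separated from training blocks; the tuned model is
refit on all data.

The universal high-sampling counterfactual then re-predicts the surface
with the sampling-density predictor set to 1 (the highest observed
density) everywhere. Comparing diversity centers of the empirical and
counterfactual predictions classifies each cell as ``robust`` (center in
both), ``drop`` (center only empirically — apparent diversity inflated
by sampling), ``enter`` (center only counterfactually — predicted
undiscovered diversity), or ``noncenter``.

Rarity responses are log-transformed before fitting (tiny offset =
half the smallest positive value guards exact zeros) and predictions are
exponentiated back; the transform is monotone, so center detection is
unaffected by the back-transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

from .diversity_mapping import CenterMask, DiversityRaster, detect_centers
from .grid import GridSpec, spherical_cell_areas

CLASS_NONCENTER, CLASS_ROBUST, CLASS_DROP, CLASS_ENTER = 0, 1, 2, 3

DENSITY_LAYER = "sampling_density"
REALM_LAYER = "realm"


@dataclass
class PredictorStack:
    """Aligned predictor layers: continuous surfaces plus a categorical realm.

    ``continuous`` maps layer name -> (n_rows, n_cols) float array; the
    sampling-density layer must be named ``sampling_density``. ``realm``
    is a float array of integer realm codes with NaN where unknown (fill
    with :func:`fill_realms` before modeling).
    """

    grid: GridSpec
    continuous: dict[str, np.ndarray]
    realm: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, arr in self.continuous.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape mismatch")
        if self.realm is not None and self.realm.shape != self.grid.shape:
            raise ValueError("realm layer shape mismatch")

    def to_frame(self, mask: np.ndarray) -> pd.DataFrame:
        """Cell table over ``mask`` with a column per layer plus row/col."""
        rows, cols = np.nonzero(mask)
        data = {name: arr[rows, cols] for name, arr in self.continuous.items()}
        if self.realm is not None:
            data[REALM_LAYER] = self.realm[rows, cols]
        df = pd.DataFrame(data)
        df["row"] = rows
        df["col"] = cols
        return df


def screen_collinearity(stack: PredictorStack, threshold: float = 0.7,
                        exempt: tuple[str, ...] = (DENSITY_LAYER,)
                        ) -> list[str]:
    """Iteratively drop collinear continuous layers (|Pearson r| > threshold).

    While any screenable pair exceeds the threshold over analysis cells,
    the member of the worst pair with the larger variance inflation
    factor is dropped (ties: the later layer in the stack's ordering).
    The categorical realm layer and exempt layers (sampling density by
    default) are never dropped. Returns retained layer names in original
    order.
    """
    names = [n for n in stack.continuous if n not in exempt]
    mask = stack.grid.analysis_mask
    for name in names:
        mask = mask & np.isfinite(stack.continuous[name])
    retained = list(names)
    while len(retained) >= 2:
        X = np.column_stack([stack.continuous[n][mask] for n in retained])
        R = np.corrcoef(X, rowvar=False)
        A = np.abs(R - np.eye(len(retained)))
        worst = np.unravel_index(np.argmax(A), A.shape)
        if A[worst] <= threshold:
            break
        try:
            vif = np.diag(np.linalg.inv(R))
        except np.linalg.LinAlgError:
            vif = np.full(len(retained), np.inf)
        i, j = sorted(worst)
        drop = j if vif[j] >= vif[i] else i
        retained.pop(drop)
    return [n for n in stack.continuous if n in retained or n in exempt]


def fill_realms(realm: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Assign unlabeled cells the realm of the nearest labeled cell.

    Great-circle (haversine) nearest neighbor, k = 1 — the limiting
    "most proximal cell" classification.
    """
    out = np.asarray(realm, dtype=float).copy()
    labeled = np.isfinite(out)
    if not labeled.any():
        raise ValueError("no labeled realm cells")
    missing = ~labeled
    if not missing.any():
        return out
    lon, lat = np.meshgrid(grid.lon_centers, grid.lat_centers)
    src = np.deg2rad(np.column_stack([lat[labeled], lon[labeled]]))
    dst = np.deg2rad(np.column_stack([lat[missing], lon[missing]]))
    nn = NearestNeighbors(n_neighbors=1, metric="haversine").fit(src)
    _, idx = nn.kneighbors(dst)
    out[missing] = out[labeled][idx.ravel()]
    return out


def checkerboard_folds(grid: GridSpec, block_rows: int = 10,
                       block_cols: int = 14, k: int = 5) -> np.ndarray:
    """Systematic checkerboard spatial folds: the grid is cut into
    block_rows x block_cols equal blocks and block i (row-major) goes to
    fold ``i mod k``, so horizontally adjacent blocks always differ.

    Returns an integer fold index per cell (every cell assigned).
    """
    ri = np.minimum((np.arange(grid.n_rows) * block_rows) // grid.n_rows,
                    block_rows - 1)
    ci = np.minimum((np.arange(grid.n_cols) * block_cols) // grid.n_cols,
                    block_cols - 1)
    block = ri[:, None] * block_cols + ci[None, :]
    return (block % k).astype(int)


class SamplingBiasForest(BaseEstimator):
    """Random Forest on diversity with spatial-CV ``mtry`` tuning.

    scikit-learn estimator. ``fit(X, y, folds=...)`` takes a cell table
    (continuous predictors plus an optional categorical ``realm`` column,
    which is one-hot encoded internally), tunes ``mtry`` over the grid by
    k-fold spatial cross-validation (minimum average held-out MSE, ties
    to the smaller value), and refits on all cells. ``predict(X)``
    returns responses on the original scale (log responses are
    exponentiated back).

    Fitted attributes: ``mtry_``, ``cv_mse_`` (per-mtry table),
    ``model_`` (the refit RandomForestRegressor), ``feature_names_``,
    ``log_offset_``.
    """

    def __init__(self, mtry_grid: tuple[int, ...] = tuple(range(1, 11)),
                 n_trees: int = 500, response_transform: str = "identity",
                 seed: int = 0):
        self.mtry_grid = mtry_grid
        self.n_trees = n_trees
        self.response_transform = response_transform
        self.seed = seed

    def _encode(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X.drop(columns=[c for c in ("row", "col") if c in X], errors="ignore")
        if REALM_LAYER in X:
            dummies = pd.get_dummies(X[REALM_LAYER].astype(int), prefix=REALM_LAYER)
            X = pd.concat([X.drop(columns=[REALM_LAYER]), dummies], axis=1)
        if hasattr(self, "feature_names_"):
            X = X.reindex(columns=self.feature_names_, fill_value=0)
        return X.astype(float)

    def _transform_y(self, y: np.ndarray) -> np.ndarray:
        if self.response_transform == "log":
            return np.log(y + self.log_offset_)
        return y

    def fit(self, X: pd.DataFrame, y: np.ndarray,
            folds: np.ndarray | None = None) -> "SamplingBiasForest":
        y = np.asarray(y, float)
        if self.response_transform not in ("identity", "log"):
            raise ValueError("response_transform must be 'identity' or 'log'")
        pos = y[y > 0]
        self.log_offset_ = float(pos.min() / 2) if (self.response_transform == "log"
                                                    and pos.size) else 0.0
        Xe = self._encode_fit(X)
        yt = self._transform_y(y)
        rows = []
        if folds is not None:
            folds = np.asarray(folds)
            fold_ids = np.unique(folds)
            for mtry in self.mtry_grid:
                mt = min(int(mtry), Xe.shape[1])
                errs = []
                for f in fold_ids:
                    test = folds == f
                    if not test.any() or test.all():
                        continue
                    rf = RandomForestRegressor(
                        n_estimators=self.n_trees, max_features=mt,
                        random_state=self.seed, n_jobs=1)
                    rf.fit(Xe[~test], yt[~test])
                    pred = rf.predict(Xe[test])
                    errs.append(float(np.mean((pred - yt[test]) ** 2)))
                rows.append(dict(mtry=int(mtry), mse=float(np.mean(errs))))
            self.cv_mse_ = pd.DataFrame(rows)
            best = self.cv_mse_.sort_values(["mse", "mtry"], kind="stable").iloc[0]
            self.mtry_ = int(best.mtry)
        else:
            self.cv_mse_ = None
            self.mtry_ = int(self.mtry_grid[0])
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=min(self.mtry_, Xe.shape[1]),
            random_state=self.seed, n_jobs=1)
        self.model_.fit(Xe, yt)
        self._train_X_, self._train_y_ = Xe, yt
        return self

    def _encode_fit(self, X: pd.DataFrame) -> np.ndarray:
        if hasattr(self, "feature_names_"):
            del self.feature_names_
        Xe = self._encode(X)
        self.feature_names_ = list(Xe.columns)
        return Xe.to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "model_")
        pred = self.model_.predict(self._encode(X).to_numpy())
        if self.response_transform == "log":
            return np.maximum(np.exp(pred) - self.log_offset_, 0.0)
        return pred

    def importance_table(self, n_repeats: int = 5) -> pd.DataFrame:
        """Permutation importance (increase in prediction error after
        permuting each predictor), sorted descending."""
        check_is_fitted(self, "model_")
        res = permutation_importance(self.model_, self._train_X_, self._train_y_,
                                     n_repeats=n_repeats, random_state=self.seed,
                                     n_jobs=1)
        tab = pd.DataFrame(dict(predictor=self.feature_names_,
                                importance=res.importances_mean))
        return tab.sort_values("importance", ascending=False).reset_index(drop=True)


@dataclass
class CounterfactualResult:
    """Paired empirical / high-sampling predictions with center classes."""

    empirical_pred: DiversityRaster
    counterfactual_pred: DiversityRaster
    empirical_centers: CenterMask
    counterfactual_centers: CenterMask
    change_class: np.ndarray = field(repr=False, default=None)


def counterfactual_high_sampling(model: SamplingBiasForest, stack: PredictorStack,
                                 metric: str, fraction: float = 0.10
                                 ) -> CounterfactualResult:
    """Predict with observed vs density:=1 stacks and classify center changes.

    The sampling-density layer is replaced by the constant 1 (the highest
    observed sampling density); diversity centers are recomputed on both
    predictions and every cell gets exactly one class: noncenter (0),
    robust (1, center in both), drop (2, center only empirically), enter
    (3, center only counterfactually).
    """
    if DENSITY_LAYER not in stack.continuous:
        raise ValueError("predictor stack lacks the sampling-density layer")
    if not any(n == DENSITY_LAYER for n in getattr(model, "feature_names_", [DENSITY_LAYER])):
        raise ValueError("model was fit without the sampling-density predictor")
    grid = stack.grid
    mask = grid.analysis_mask
    for arr in stack.continuous.values():
        mask = mask & np.isfinite(arr)
    X = stack.to_frame(mask)
    rows, cols = X.pop("row").to_numpy(), X.pop("col").to_numpy()
    emp = model.predict(X)
    X_cf = X.copy()
    X_cf[DENSITY_LAYER] = 1.0
    cf = model.predict(X_cf)

    def as_raster(v):
        out = np.full(grid.shape, np.nan)
        out[rows, cols] = v
        return DiversityRaster(grid=grid, metric=metric, values=out)

    emp_r, cf_r = as_raster(emp), as_raster(cf)
    emp_c = detect_centers(emp_r, fraction)
    cf_c = detect_centers(cf_r, fraction)
    cls = np.full(grid.shape, CLASS_NONCENTER, dtype=int)
    cls[emp_c.member & cf_c.member] = CLASS_ROBUST
    cls[emp_c.member & ~cf_c.member] = CLASS_DROP
    cls[~emp_c.member & cf_c.member] = CLASS_ENTER
    return CounterfactualResult(empirical_pred=emp_r, counterfactual_pred=cf_r,
                                empirical_centers=emp_c, counterfactual_centers=cf_c,
                                change_class=cls)


def robustness_fraction(result: CounterfactualResult) -> dict[str, float]:
    """Area fractions: robust and drop relative to the empirical centers,
    enter relative to the counterfactual centers."""
    areas = spherical_cell_areas(result.empirical_pred.grid)
    emp = float(areas[result.empirical_centers.member].sum())
    cf = float(areas[result.counterfactual_centers.member].sum())
    a_robust = float(areas[result.change_class == CLASS_ROBUST].sum())
    a_drop = float(areas[result.change_class == CLASS_DROP].sum())
    a_enter = float(areas[result.change_class == CLASS_ENTER].sum())
    return dict(robust=a_robust / emp if emp else np.nan,
                drop=a_drop / emp if emp else np.nan,
                enter=a_enter / cf if cf else np.nan)
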