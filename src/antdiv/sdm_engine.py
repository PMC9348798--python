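"""Penalized presence-background suitability modeling.

The model is a Gibbs (log-linear) density over the study extent,
``p(x) proportional to exp(eta(x))`` with ``eta(x) = beta . f(x)``, fitted by
minimizing the penalized negative log-likelihood of the presence
localities relative to the background sample:

    L(beta) = -mean_presence eta(x_i) + log mean_background e^{eta(x_b)}
              + sum_f m * lambda_f * |beta_f|

This is the classic presence-background maximum-entropy formulation:
the fit is constrained to best match the background environmental
distribution, complexity is governed by feature classes (linear,
quadratic, hinge) and an L1 regularization multiplier ``m``, and
coefficients shrink to exactly zero under strong penalization. The
per-feature penalty scale is ``lambda_f = sd_f(background) / sqrt(n_presence)``,
mirroring the usual sample-size scaling. Optimization is FISTA (proximal
gradient with backtracking) on the convex objective.

Predictions use the complementary log-log transform
``1 - exp(-exp(eta - r))`` with ``r = log mean_background e^{eta}``, a
monotone map of ``eta`` onto (0, 1).

Model tuning fits all combinations of feature classes {L, LQ, H, LQH}
and multipliers {1..5}, evaluates them by cross-validation (leave-one-out
below 25 localities, random 5-fold otherwise), and selects sequentially:
drop all-zero models, drop Continuous Boyce Index <= 0 or NA, then
minimize the 10-percentile omission rate, break ties by validation AUC,
then by coefficient count, then deterministically by (simpler feature
class, smaller multiplier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_array, check_is_fitted

from .grid import GridSpec
from .synthetic_world import BiasField

FEATURE_CLASSES = ("L", "LQ", "H", "LQH")


# ---------------------------------------------------------------------------
# sampling density and background

def build_sampling_density(lon: np.ndarray, lat: np.ndarray, grid: GridSpec,
                           bandwidth_cells: float = 2.0) -> BiasField:
    """Kernel density of all occurrence localities, rescaled to [0, 1].

    Gaussian kernel smoothing of the per-cell locality counts; water cells
    are removed before rescaling so the maximum over land is exactly 1.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    if lon.size == 0:
        raise ValueError("at least one occurrence required")
    counts = np.zeros(grid.shape)
    ok = grid.contains(lon, lat)
    r, c = grid.cell_of(lon[ok], lat[ok])
    np.add.at(counts, (r, c), 1.0)
    dens = ndimage.gaussian_filter(counts, sigma=bandwidth_cells, mode="constant")
    dens = np.where(grid.land_mask, dens, 0.0)
    m = dens.max()
    if m > 0:
        dens = dens / m
    return BiasField(grid=grid, density=dens)


def sample_background(density: BiasField, extent_mask: np.ndarray,
                      n: int = 10000, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Bias-matched background cells within a study extent.

    Extents smaller than ``n`` cells get the full cell set (all cells);
    larger extents are sampled with replacement probability proportional
    to the sampling-density surface (uniform fallback, with a warning, if
    the density is zero everywhere in the extent).
    """
    rows, cols = np.nonzero(extent_mask)
    if rows.size == 0:
        raise ValueError("extent contains no cells")
    if rows.size < n:
        return rows, cols
    w = density.density[rows, cols].astype(float)
    if w.sum() <= 0:
        warnings.warn("all-zero sampling density in extent; uniform background")
        w = np.ones_like(w)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=True, p=w)
    return rows[idx], cols[idx]


# ---------------------------------------------------------------------------
# feature construction

class FeatureBuilder:
    """Maps raw environmental values to model features.

    Standardization (mean/sd) and hinge knots (equal quantiles) are fitted
    on the background sample only. Feature classes: L = standardized
    variables, Q = their squares, H = forward hinges ``max(0, x - k)`` at
    ``hinge_knots`` knots per variable. Constant variables are dropped
    with a warning.
    """

    def __init__(self, classes: str = "LQH", hinge_knots: int = 8):
        if classes not in FEATURE_CLASSES:
            raise ValueError(f"classes must be one of {FEATURE_CLASSES}")
        if hinge_knots < 2:
            raise ValueError("hinge_knots must be >= 2")
        self.classes = classes
        self.hinge_knots = hinge_knots

    def fit(self, background: np.ndarray) -> "FeatureBuilder":
        X = check_array(np.asarray(background, float))
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn("constant variable(s) dropped from features")
        self.keep_ = keep
        self.mean_ = X[:, keep].mean(axis=0)
        self.sd_ = sd[keep]
        if "H" in self.classes:
            Z = (X[:, keep] - self.mean_) / self.sd_
            qs = np.linspace(0, 1, self.hinge_knots + 2)[1:-1]
            self.knots_ = np.quantile(Z, qs, axis=0)  # (K, n_vars)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        Z = (X[:, self.keep_] - self.mean_) / self.sd_
        blocks = []
        if "L" in self.classes:
            blocks.append(Z)
        if "Q" in self.classes:
            blocks.append(Z ** 2)
        if "H" in self.classes:
            hinge = np.maximum(0.0, Z[:, None, :] - self.knots_[None, :, :])
            blocks.append(hinge.reshape(len(Z), -1))
        return np.hstack(blocks)


# ---------------------------------------------------------------------------
# the estimator

class PresenceBackgroundModel(BaseEstimator):
    """L1-penalized log-linear presence-background suitability model.

    scikit-learn estimator: ``fit(X, y)`` with ``y = 1`` for presence rows
    and ``y = 0`` for background rows of the raw environmental matrix
    ``X``; ``predict(X)`` returns cloglog suitability in (0, 1) and
    ``decision_function(X)`` the linear predictor.

    Parameters
    ----------
    feature_classes : {"L", "LQ", "H", "LQH"}
    reg_multiplier : float
        Multiplier m on the per-feature penalty scale (the published
        tool's tuning knob; 1 = default penalization).
    hinge_knots : int
    max_iter, tol : FISTA stopping rule (objective-change tolerance).
    """

    def __init__(self, feature_classes: str = "LQH", reg_multiplier: float = 1.0,
                 hinge_knots: int = 8, max_iter: int = 500, tol: float = 1e-6):
        self.feature_classes = feature_classes
        self.reg_multiplier = reg_multiplier
        self.hinge_knots = hinge_knots
        self.max_iter = max_iter
        self.tol = tol

    # objective pieces -----------------------------------------------------
    @staticmethod
    def _smooth_val_grad(beta, Fp, Fb):
        eta_p = Fp @ beta
        eta_b = Fb @ beta
        mx = eta_b.max()
        w = np.exp(eta_b - mx)
        Zs = w.sum()
        val = -eta_p.mean() + mx + np.log(Zs / len(eta_b))
        grad = -Fp.mean(axis=0) + (w / Zs) @ Fb
        return val, grad

    def fit(self, X, y):
        X = check_array(np.asarray(X, float))
        y = np.asarray(y).ravel()
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary (1 = presence, 0 = background)")
        Xp, Xb = X[y == 1], X[y == 0]
        if len(Xp) < 1:
            raise ValueError("at least one presence required")
        if len(Xb) < len(Xp):
            raise ValueError("background must be at least as large as presences")
        self.builder_ = FeatureBuilder(self.feature_classes, self.hinge_knots).fit(Xb)
        Fp = self.builder_.transform(Xp)
        Fb = self.builder_.transform(Xb)
        lam = Fb.std(axis=0) * np.sqrt(1.0 / len(Fp)) * self.reg_multiplier
        lam = np.maximum(lam, 1e-12)

        beta = np.zeros(Fb.shape[1])
        z_acc = beta.copy()
        t = 1.0
        step = 1.0
        fval, grad = self._smooth_val_grad(beta, Fp, Fb)
        obj_prev = fval + np.abs(beta) @ lam
        self.converged_ = False
        for _ in range(self.max_iter):
            fval, grad = self._smooth_val_grad(z_acc, Fp, Fb)
            while True:  # backtracking on the smooth majorizer
                cand = z_acc - step * grad
                cand = np.sign(cand) * np.maximum(np.abs(cand) - step * lam, 0.0)
                diff = cand - z_acc
                f_cand, _ = self._smooth_val_grad(cand, Fp, Fb)
                if f_cand <= fval + grad @ diff + (diff @ diff) / (2 * step) + 1e-12:
                    break
                step *= 0.5
                if step < 1e-12:
                    break
            t_next = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
            z_acc = cand + ((t - 1) / t_next) * (cand - beta)
            beta, t = cand, t_next
            obj = f_cand + np.abs(beta) @ lam
            if abs(obj_prev - obj) < self.tol * max(1.0, abs(obj_prev)):
                self.converged_ = True
                break
            obj_prev = obj
        self.coef_ = beta
        self.n_nonzero_ = int(np.count_nonzero(np.abs(beta) > 1e-10))
        eta_b = Fb @ beta
        mx = eta_b.max()
        self.offset_r_ = float(mx + np.log(np.mean(np.exp(eta_b - mx))))
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self.builder_.transform(X) @ self.coef_

    def predict(self, X) -> np.ndarray:
        """Cloglog suitability 1 - exp(-exp(eta - r)), r the background
        log-mean of e^eta (entropy-equivalent normalizing offset)."""
        eta = self.decision_function(X)
        return 1.0 - np.exp(-np.exp(np.clip(eta - self.offset_r_, -700.0, 30.0)))


# ---------------------------------------------------------------------------
# cross-validation folds

@dataclass
class FoldScheme:
    """Presence partition: LOO below 25 localities, random 5-fold otherwise."""

    kind: str            # "loo" | "random_k"
    k: int
    assignment: np.ndarray


def partition_folds(n_presences: int, seed: int = 0) -> FoldScheme:
    if n_presences < 5:
        raise ValueError("SDM branch requires >= 5 presences")
    if n_presences < 25:
        return FoldScheme("loo", n_presences, np.arange(n_presences))
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n_presences)
    assignment = np.empty(n_presences, int)
    assignment[idx] = np.arange(n_presences) % 5
    return FoldScheme("random_k", 5, assignment)


# ---------------------------------------------------------------------------
# evaluation metrics

def continuous_boyce_index(suit_presence: np.ndarray, suit_extent: np.ndarray,
                           n_windows: int = 101, width_frac: float = 0.1
                           ) -> float:
    """Spearman correlation of predicted-to-expected ratio vs suitability.

    Moving windows of width = ``width_frac`` of the observed suitability
    range slide across it; in each, P = share of presence suitabilities,
    E = share of extent suitabilities, and the index is the Spearman
    correlation of P/E with the window midpoint. NaN when degenerate.
    """
    sp = np.asarray(suit_presence, float)
    se = np.asarray(suit_extent, float)
    lo, hi = se.min(), se.max()
    if hi - lo <= 0 or sp.size == 0:
        return np.nan
    width = width_frac * (hi - lo)
    starts = np.linspace(lo, hi - width, n_windows)
    mids, ratios = [], []
    for s in starts:
        e = np.mean((se >= s) & (se <= s + width))
        p = np.mean((sp >= s) & (sp <= s + width))
        if e > 0:
            mids.append(s + width / 2)
            ratios.append(p / e)
    if len(mids) < 3 or len(set(ratios)) < 2:
        return np.nan
    rho, _ = spearmanr(ratios, mids)
    return float(rho)


@dataclass
class EvalMetrics:
    or10: float
    auc_val: float
    cbi: float
    n_nonzero: int


def evaluate_candidate(X_pres: np.ndarray, X_bg: np.ndarray,
                       feature_classes: str, reg_multiplier: float,
                       folds: FoldScheme, hinge_knots: int = 8,
                       full_model: PresenceBackgroundModel | None = None
                       ) -> EvalMetrics:
    """Cross-validated OR10/AUC plus full-data CBI for one candidate setting.

    OR10 per fold: fraction of withheld presences whose suitability falls
    below the 10th percentile of the training presences' suitabilities.
    AUC per fold: rank discrimination of withheld presences vs the
    background sample. CBI: computed from the full-data fit over the
    background (extent) sample.
    """
    X_pres = np.asarray(X_pres, float)
    X_bg = np.asarray(X_bg, float)
    y = np.concatenate([np.ones(len(X_pres)), np.zeros(len(X_bg))])
    X_all = np.vstack([X_pres, X_bg])
    if full_model is None:
        full_model = PresenceBackgroundModel(feature_classes, reg_multiplier,
                                             hinge_knots).fit(X_all, y)
    ors, aucs = [], []
    for f in range(folds.k):
        test = folds.assignment == f
        if not test.any() or test.all():
            continue
        Xtr = X_pres[~test]
        m = PresenceBackgroundModel(feature_classes, reg_multiplier, hinge_knots)
        m.fit(np.vstack([Xtr, X_bg]),
              np.concatenate([np.ones(len(Xtr)), np.zeros(len(X_bg))]))
        # rank on the linear predictor: monotone in suitability but immune
        # to cloglog saturation when the fit separates the classes
        s_tr = m.decision_function(Xtr)
        thr = np.percentile(s_tr, 10)
        s_te = m.decision_function(X_pres[test])
        ors.append(float(np.mean(s_te < thr)))
        s_bg = m.decision_function(X_bg)
        labels = np.concatenate([np.ones(len(s_te)), np.zeros(len(s_bg))])
        scores = np.concatenate([s_te, s_bg])
        if len(set(scores.tolist())) > 1:
            aucs.append(float(roc_auc_score(labels, scores)))
        else:
            aucs.append(0.5)
    cbi = continuous_boyce_index(full_model.predict(X_pres), full_model.predict(X_bg))
    return EvalMetrics(
        or10=float(np.mean(ors)) if ors else np.nan,
        auc_val=float(np.mean(aucs)) if aucs else np.nan,
        cbi=cbi, n_nonzero=full_model.n_nonzero_)


# ---------------------------------------------------------------------------
# tuning / sequential selection

@dataclass
class SelectionResult:
    """Outcome of the tuning grid: the chosen model or a polygon fallback."""

    model: PresenceBackgroundModel | None
    settings: tuple[str, float] | None
    table: pd.DataFrame = field(repr=False, default=None)

    @property
    def polygon_fallback(self) -> bool:
        return self.model is None


def tune_and_select(X_pres: np.ndarray, X_bg: np.ndarray,
                    classes: tuple[str, ...] = FEATURE_CLASSES,
                    multipliers: tuple[float, ...] = (1, 2, 3, 4, 5),
                    hinge_knots: int = 8, seed: int = 0) -> SelectionResult:
    """Fit the candidate grid and apply the sequential selection filter.

    (1) drop candidates with no nonzero coefficients; (2) drop CBI <= 0 or
    NA; (3) keep minimum OR10; (4) ties -> maximum validation AUC; (5)
    ties -> minimum coefficient count; (6) residual ties -> simpler
    feature class then smaller multiplier (candidates are enumerated in
    that order, so selection is independent of enumeration order). If no
    candidate survives (1)-(2) the species falls back to its polygon
    (``polygon_fallback``).
    """
    X_pres = np.asarray(X_pres, float)
    folds = partition_folds(len(X_pres), seed=seed)
    rows = []
    models = {}
    y = np.concatenate([np.ones(len(X_pres)), np.zeros(len(X_bg))])
    X_all = np.vstack([X_pres, X_bg])
    for ci, fc in enumerate(c for c in FEATURE_CLASSES if c in classes):
        for m in multipliers:
            full = PresenceBackgroundModel(fc, m, hinge_knots).fit(X_all, y)
            met = evaluate_candidate(X_pres, X_bg, fc, m, folds,
                                     hinge_knots, full_model=full)
            models[(fc, m)] = full
            rows.append(dict(feature_classes=fc, class_order=ci, reg_multiplier=m,
                             or10=met.or10, auc_val=met.auc_val, cbi=met.cbi,
                             n_nonzero=met.n_nonzero))
    table = pd.DataFrame(rows)
    key = select_from_table(table)
    if key is None:
        return SelectionResult(model=None, settings=None, table=table)
    return SelectionResult(model=models[key], settings=key, table=table)


def select_from_table(table: pd.DataFrame) -> tuple[str, float] | None:
    """Apply the sequential selection filter to a candidate metrics table.

    Columns required: feature_classes, class_order, reg_multiplier, or10,
    auc_val, cbi, n_nonzero. Returns the winning (feature_classes,
    reg_multiplier) or None when every candidate is filtered out (the
    polygon-fallback branch).
    """
    surv = table[table.n_nonzero > 0]
    surv = surv[surv.cbi.notna() & (surv.cbi > 0)]
    if surv.empty:
        return None
    surv = surv[surv.or10 == surv.or10.min()]
    surv = surv[surv.auc_val == surv.auc_val.max()]
    surv = surv[surv.n_nonzero == surv.n_nonzero.min()]
    surv = surv.sort_values(["class_order", "reg_multiplier"], kind="stable")
    best = surv.iloc[0]
    return (best.feature_classes, best.reg_multiplier)
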