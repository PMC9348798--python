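"""End-to-end orchestration: synthetic world -> QC -> ranges -> SDMs ->
stacking -> centers -> congruence -> bias model -> counterfactual ->
rarefaction -> protection.

Every stochastic stage consumes a seed derived deterministically from
the master seed and a fixed per-stage code (counter-based splitting), so
adding a stage never perturbs earlier streams and rerunning a config
reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias_model as bm
from . import congruence as cg
from . import diversity_mapping as dm
from . import occurrence_qc as qc
from . import range_geometry as rg
from . import richness_estimators as re_
from . import sdm_engine as sdm
from . import synthetic_world as sw

STAGE_CODES = {name: i for i, name in enumerate(
    ["world", "qc", "density", "ranges", "sdm", "stack", "centers",
     "congruence", "rarefy", "biasmodel", "treasure", "protect"])}


def stage_seed(master_seed: int, stage: str) -> int:
    """Counter-based per-stage seed below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), STAGE_CODES[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """All stage parameters with their canonical defaults.

    Analysis parameters (buffer_km, alpha, thin_km, n_background,
    feature classes and multipliers, rarity constant c, center fraction,
    collinearity threshold, mtry grid) default to the standard protocol
    values; synthetic-world parameters define the desk-scale study
    conditions (2-degree grid over a +-60 degree band, ~10^4 cells).
    """

    # grid / world
    resolution_arcmin: float = 120.0
    lon_min: float = -180.0
    lon_max: float = 180.0
    lat_min: float = -60.0
    lat_max: float = 60.0
    land_fraction: float = 0.35
    n_env_layers: int = 3
    n_species: int = 120
    log_range_mu: float = float(np.log(8e5))
    log_range_sigma: float = 1.2
    effort: float = 5.0
    bias_concentration: float = 1.5
    bias_kind: str = "smooth"          # "smooth" | "regional" (recovery experiment)
    bias_low_density: float = 0.03
    bias_boundary_lon: float = 0.0
    noise: dict = field(default_factory=lambda: dict(
        p_missing_coords=0.10, p_wrong_country=0.02,
        p_coarse_precision=0.10, p_duplicate=0.05))
    companion_rho: float = 0.75
    protected_fraction: float = 0.15
    # qc
    max_precision_km: float = 100.0
    centroid_tol_km: float = 1.0
    # ranges
    buffer_km: float = 30.0
    alpha: float = 15.0
    thin_km: float = 10.0
    # sdm
    n_background: int = 10000
    feature_classes: tuple = ("L", "LQ", "H", "LQH")
    multipliers: tuple = (1, 2, 3, 4, 5)
    hinge_knots: int = 8
    # diversity
    rarity_c: float = 60000.0
    center_fraction: float = 0.10
    # rarefaction: 60-cell windows at 10 arcmin = 10 degrees; scaled to the
    # run's resolution so the geographic window matches
    window_cells: int = 60
    window_reference_arcmin: float = 10.0
    # bias model
    density_predictor: str = "kde"     # "kde" | "true_effort" (recovery experiment)
    collinearity_threshold: float = 0.7
    mtry_grid: tuple = tuple(range(1, 11))
    rf_trees: int = 300
    # master seed
    seed: int = 0

    def effective_window_cells(self) -> int:
        """Window size in cells at this run's resolution covering the same
        geographic span as ``window_cells`` at the reference resolution."""
        span_arcmin = self.window_cells * self.window_reference_arcmin
        return max(2, round(span_arcmin / self.resolution_arcmin))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        problems = validate_config(cfg)
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["feature_classes"] = list(self.feature_classes)
        d["multipliers"] = list(self.multipliers)
        d["mtry_grid"] = list(self.mtry_grid)
        Path(path).write_text(yaml.safe_dump(d))


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Type/range checks; an empty list means the config is valid."""
    p: list[str] = []
    if cfg.resolution_arcmin <= 0:
        p.append("resolution_arcmin must be positive")
    if not 0 < cfg.land_fraction < 1:
        p.append("land_fraction must be in (0,1)")
    if cfg.n_species < 1:
        p.append("n_species must be >= 1")
    if cfg.rarity_c < 0:
        p.append("rarity_c must be non-negative")
    if not 0 < cfg.center_fraction < 1:
        p.append("center_fraction must be in (0,1)")
    if not 0 < cfg.collinearity_threshold <= 1:
        p.append("collinearity_threshold must be in (0,1]")
    if cfg.buffer_km <= 0 or cfg.alpha <= 0 or cfg.thin_km <= 0:
        p.append("buffer_km, alpha and thin_km must be positive")
    if cfg.n_background < 1:
        p.append("n_background must be >= 1")
    if any(m < 1 for m in cfg.mtry_grid):
        p.append("mtry grid values must be >= 1")
    if cfg.density_predictor not in ("kde", "true_effort"):
        p.append("density_predictor must be 'kde' or 'true_effort'")
    if cfg.bias_kind not in ("smooth", "regional"):
        p.append("bias_kind must be 'smooth' or 'regional'")
    if not 0 < cfg.protected_fraction < 1:
        p.append("protected_fraction must be in (0,1)")
    for k, v in cfg.noise.items():
        if not 0 <= v <= 1:
            p.append(f"noise fraction {k} must be in [0,1]")
    return p


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All pipeline artifacts plus the run manifest."""

    config: PipelineConfig
    manifest: dict
    grid: object = None
    env: object = None
    bias: object = None
    gazetteer: object = None
    pool: list = None
    records: pd.DataFrame = None
    qc_records: pd.DataFrame = None
    qc_report: qc.QCReport = None
    density: object = None
    ranges: list = None
    richness: dm.DiversityRaster = None
    rarity: dm.DiversityRaster = None
    richness_centers: dm.CenterMask = None
    rarity_centers: dm.CenterMask = None
    companions: dict = None
    congruence_rho: pd.DataFrame = None
    congruence_overlap: pd.DataFrame = None
    rarefaction: dm.DiversityRaster = None
    counterfactuals: dict = None
    robustness: dict = None
    protected: list = None
    protection_coverage: dict = None

    def manifest_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.manifest, indent=2, default=str)
        if path is not None:
            Path(path).write_text(s)
        return s


def run_pipeline(cfg: PipelineConfig, skip: set[str] = frozenset()
                 ) -> PipelineResult:
    """Execute all stages on the synthetic world defined by ``cfg``.

    ``skip={'sdm'}`` runs a polygon-only analysis (every species weighted
    1 inside its polygon). Stage failures are recorded in the manifest
    and downstream stages that need the failed artifact are skipped.
    """
    manifest: dict[str, dict] = {}
    res = PipelineResult(config=cfg, manifest=manifest)

    def record(stage, t0, **info):
        manifest[stage] = dict(status="ok", seed=stage_seed(cfg.seed, stage),
                               duration_s=round(time.time() - t0, 3), **info)

    # --- world ------------------------------------------------------------
    t0 = time.time()
    s = stage_seed(cfg.seed, "world")
    grid = sw.generate_grid(cfg.resolution_arcmin, cfg.lon_min, cfg.lon_max,
                            cfg.lat_min, cfg.lat_max, cfg.land_fraction, seed=s)
    env = sw.generate_environment(grid, cfg.n_env_layers, seed=s + 1)
    if cfg.bias_kind == "regional":
        bias = sw.regional_bias_field(grid, cfg.bias_low_density,
                                      cfg.bias_boundary_lon)
    else:
        bias = sw.generate_bias_field(grid, seed=s + 2,
                                      concentration=cfg.bias_concentration)
    gaz = sw.build_gazetteer(grid)
    pool = sw.generate_species_pool(env, cfg.n_species, cfg.log_range_mu,
                                    cfg.log_range_sigma, seed=s + 3)
    records = sw.simulate_collection(pool, bias, cfg.effort,
                                     sw.NoiseConfig(**cfg.noise), gaz, seed=s + 4)
    protected = sw.generate_protected_areas(grid, cfg.protected_fraction, seed=s + 5)
    res.grid, res.env, res.bias, res.gazetteer = grid, env, bias, gaz
    res.pool, res.records, res.protected = pool, records, protected
    record("world", t0, n_records=len(records), n_species=len(pool),
           land_cells=int(grid.land_mask.sum()),
           env_hash=_hash_array(env.as_array()))

    # --- qc ---------------------------------------------------------------
    t0 = time.time()
    qdf, report = qc.run_qc(records, gaz, cfg.max_precision_km, cfg.centroid_tol_km)
    res.qc_records, res.qc_report = qdf, report
    retained = qc.retained(qdf)
    record("qc", t0, n_retained=report.n_total_retained,
           n_unresolved=report.n_unresolved)

    # --- sampling density ---------------------------------------------------
    t0 = time.time()
    density = sdm.build_sampling_density(retained["resolved_lon"].to_numpy(float),
                                         retained["resolved_lat"].to_numpy(float),
                                         grid)
    res.density = density
    record("density", t0, max=float(density.density.max()))

    # --- ranges + sdm -------------------------------------------------------
    t0 = time.time()
    ranges: list[rg.RangeEstimate] = []
    sdm_stats = dict(n_sdm=0, n_fallback=0)
    seed_sdm = stage_seed(cfg.seed, "sdm")
    for k, (sp_id, sub) in enumerate(retained.groupby("species_id")):
        pts = np.unique(np.column_stack([
            sub["resolved_lon"].to_numpy(float).round(4),
            sub["resolved_lat"].to_numpy(float).round(4)]), axis=0)
        est = rg.build_polygon_range(sp_id, pts, grid, cfg.alpha, cfg.buffer_km)
        if (est.method.method == rg.METHOD_SDM_IN_HULL and "sdm" not in skip):
            thinned = rg.thin_points(pts, cfg.thin_km, seed=seed_sdm + k)
            if len(thinned) >= 5:
                est = _fit_sdm_range(est, thinned, env, density, cfg,
                                     seed=seed_sdm + k, stats=sdm_stats)
        ranges.append(est)
    res.ranges = ranges
    record("ranges", t0, n_ranges=len(ranges), **sdm_stats)

    # --- stacking + centers -------------------------------------------------
    t0 = time.time()
    res.richness = dm.stack_richness(ranges, grid)
    res.rarity = dm.stack_rarity(ranges, dm.RarityParams(cfg.rarity_c), grid)
    res.richness_centers = dm.detect_centers(res.richness, cfg.center_fraction)
    res.rarity_centers = dm.detect_centers(res.rarity, cfg.center_fraction)
    record("stack", t0, richness_hash=_hash_array(res.richness.values))

    # --- congruence ---------------------------------------------------------
    t0 = time.time()
    s = stage_seed(cfg.seed, "congruence")
    # companion taxa emulate independently compiled (expert-range) maps:
    # they correlate with the *true* diversity surface, not with the
    # sampling-suppressed empirical one
    truth = sw.true_diversity_rasters(res.pool, grid, cfg.rarity_c)
    companions = {
        "companion_a": sw.generate_companion_taxa(truth["richness"], cfg.companion_rho, seed=s),
        "companion_b": sw.generate_companion_taxa(truth["richness"], cfg.companion_rho, seed=s + 1),
    }
    res.companions = companions
    rasters = {"focal": res.richness, **companions}
    res.congruence_rho, res.congruence_overlap = cg.congruence_matrix(
        rasters, cfg.center_fraction)
    record("congruence", t0,
           mean_rho=float(res.congruence_rho.loc["focal", list(companions)].mean()))

    # --- rarefaction --------------------------------------------------------
    t0 = time.time()
    rr, cc = grid.cell_of(retained["resolved_lon"].to_numpy(float),
                          retained["resolved_lat"].to_numpy(float))
    cell_records = pd.DataFrame(dict(species_id=retained["species_id"].to_numpy(),
                                     row=rr, col=cc))
    w = cfg.effective_window_cells()
    res.rarefaction = re_.moving_window_map(
        cell_records, grid, re_.WindowSpec(w, max(1, w // 2)))
    record("rarefy", t0, window_cells=w)

    # --- bias model + counterfactual ---------------------------------------
    t0 = time.time()
    s = stage_seed(cfg.seed, "biasmodel")
    stack = _build_predictor_stack(res, cfg, seed=s)
    names = bm.screen_collinearity(stack, cfg.collinearity_threshold)
    stack = bm.PredictorStack(grid, {n: stack.continuous[n] for n in names},
                              realm=stack.realm)
    folds_grid = bm.checkerboard_folds(grid)
    res.counterfactuals, res.robustness = {}, {}
    for metric, raster in (("richness", res.richness), ("rarity", res.rarity)):
        mask = grid.analysis_mask & np.isfinite(raster.values)
        for arr in stack.continuous.values():
            mask = mask & np.isfinite(arr)
        X = stack.to_frame(mask)
        rows, cols = X.pop("row").to_numpy(), X.pop("col").to_numpy()
        y = raster.values[rows, cols]
        forest = bm.SamplingBiasForest(
            mtry_grid=cfg.mtry_grid, n_trees=cfg.rf_trees,
            response_transform="log" if metric == "rarity" else "identity",
            seed=s)
        forest.fit(X, y, folds=folds_grid[rows, cols])
        cf = bm.counterfactual_high_sampling(forest, stack, metric,
                                             cfg.center_fraction)
        res.counterfactuals[metric] = (forest, cf)
        res.robustness[metric] = bm.robustness_fraction(cf)
    record("treasure", t0,
           mtry={m: res.counterfactuals[m][0].mtry_ for m in res.counterfactuals},
           robustness=res.robustness)

    # --- protection ---------------------------------------------------------
    t0 = time.time()
    res.protection_coverage = {
        "richness": cg.protected_coverage(res.richness_centers, protected),
        "rarity": cg.protected_coverage(res.rarity_centers, protected),
    }
    record("protect", t0, coverage=res.protection_coverage)
    return res


def _fit_sdm_range(est: rg.RangeEstimate, thinned: np.ndarray, env,
                   density, cfg: PipelineConfig, seed: int,
                   stats: dict) -> rg.RangeEstimate:
    """Tune/select a suitability model inside the species' buffered hull;
    on success the range weights become the cloglog prediction, otherwise
    the polygonal estimate is kept (polygon fallback)."""
    grid = env.grid
    extent = (est.weight_raster > 0) & grid.land_mask
    if extent.sum() < 5:
        return est
    br, bc = sdm.sample_background(density, extent, cfg.n_background, seed=seed)
    X_bg = env.values_at(br, bc)
    pr, pc = grid.cell_of(thinned[:, 0], thinned[:, 1])
    X_pres = env.values_at(pr, pc)
    ok_p = np.isfinite(X_pres).all(axis=1)
    ok_b = np.isfinite(X_bg).all(axis=1)
    X_pres, X_bg = X_pres[ok_p], X_bg[ok_b]
    if len(X_pres) < 5 or len(X_bg) < len(X_pres):
        return est
    sel = sdm.tune_and_select(X_pres, X_bg, cfg.feature_classes,
                              cfg.multipliers, cfg.hinge_knots, seed=seed)
    if sel.polygon_fallback:
        stats["n_fallback"] += 1
        return est
    stats["n_sdm"] += 1
    er, ec = np.nonzero(extent)
    X_ext = env.values_at(er, ec)
    ok = np.isfinite(X_ext).all(axis=1)
    w = np.zeros(grid.shape)
    w[er[ok], ec[ok]] = sel.model.predict(X_ext[ok])
    method = rg.RangeMethod(rg.METHOD_SDM_IN_HULL, cfg.alpha, cfg.buffer_km)
    return rg.RangeEstimate(species_id=est.species_id, method=method,
                            polygon=est.polygon, weight_raster=w,
                            area_km2=rg.range_area_km2(w, grid),
                            hull_fallback=est.hull_fallback)


def _build_predictor_stack(res: PipelineResult, cfg: PipelineConfig,
                           seed: int) -> bm.PredictorStack:
    """Environment + terrain analog + sampling density + companion
    diversity, with a realm layer (synthetic country tiles, a few cells
    unlabeled to exercise the nearest-neighbor fill)."""
    grid = res.grid
    cont = {f"env{i + 1:02d}": arr for i, (n, arr) in
            enumerate(res.env.layers.items())}
    cont["terrain"] = np.where(grid.land_mask,
                               sw.smooth_field(grid, seed=seed + 7), np.nan)
    if cfg.density_predictor == "true_effort":
        cont[bm.DENSITY_LAYER] = res.bias.density
    else:
        cont[bm.DENSITY_LAYER] = res.density.density
    cont["companion_diversity"] = res.companions["companion_a"].values
    countries = res.gazetteer.country_grid
    codes = pd.factorize(countries.ravel())[0].reshape(grid.shape).astype(float)
    rng = np.random.default_rng(seed)
    knock = rng.random(grid.shape) < 0.02
    codes[knock] = np.nan
    realm = bm.fill_realms(codes, grid)
    return bm.PredictorStack(grid=grid, continuous=cont, realm=realm)


def recovery_config(seed: int = 0) -> PipelineConfig:
    """Study conditions for the sampling-bias recovery experiment.

    One hemisphere is severely under-collected (regional bias, density
    0.005 vs 1.0), the species pool is larger and less dominated by
    huge-range species (200 species, log-range sigma 0.8), and the
    forest's sampling-density predictor is the generator's known effort
    surface — the experiment probes the counterfactual machinery, not
    the kernel-density effort estimator.
    """
    return PipelineConfig(seed=seed, bias_kind="regional",
                          bias_low_density=0.005,
                          density_predictor="true_effort",
                          n_species=200, log_range_sigma=0.8)


def run_recovery_experiment(seed: int = 0, cfg: PipelineConfig | None = None,
                            skip_sdm: bool = True) -> dict:
    """Biased-sampling recovery: does the high-sampling counterfactual map
    track true diversity better than the empirical map does?

    Returns per-metric Spearman correlations with ground truth for the
    empirical and counterfactual maps, their margin, and the overlap of
    each map's diversity centers with the true centers. Polygon-only
    ranges by default (suitability-model noise is orthogonal to the
    question being asked).
    """
    from . import congruence as _cg
    from . import diversity_mapping as _dm

    cfg = cfg or recovery_config(seed)
    res = run_pipeline(cfg, skip={"sdm"} if skip_sdm else set())
    truth = sw.true_diversity_rasters(res.pool, res.grid, cfg.rarity_c)
    out: dict[str, dict] = {}
    for metric in ("richness", "rarity"):
        _, cf = res.counterfactuals[metric]
        emp = res.richness if metric == "richness" else res.rarity
        true_centers = _dm.detect_centers(truth[metric], cfg.center_fraction)
        emp_centers = _dm.detect_centers(emp, cfg.center_fraction)
        out[metric] = dict(
            rho_empirical=_cg.spearman_between(emp, truth[metric]),
            rho_counterfactual=_cg.spearman_between(cf.counterfactual_pred,
                                                    truth[metric]),
            overlap_empirical=_cg.overlap_fraction(true_centers, emp_centers),
            overlap_counterfactual=_cg.overlap_fraction(
                true_centers, cf.counterfactual_centers),
        )
        out[metric]["margin"] = (out[metric]["rho_counterfactual"]
                                 - out[metric]["rho_empirical"])
    return out
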