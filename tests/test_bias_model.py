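"""Collinearity screening, realm fill, checkerboard CV, forest, counterfactual."""

import numpy as np
import pandas as pd
import pytest

from antdiv import bias_model as bm
from antdiv import diversity_mapping as dm
from antdiv.grid import great_circle_km, spherical_cell_areas
from .conftest import make_flat_grid


def stack_from(grid, **layers):
    realm = layers.pop("realm", None)
    return bm.PredictorStack(grid=grid, continuous=layers, realm=realm)


class TestCollinearityScreen:
    def test_identical_layers_one_dropped(self, flat_grid):
        rng = np.random.default_rng(0)
        a = rng.normal(size=flat_grid.shape)
        st = stack_from(flat_grid, a=a, b=a.copy(), sampling_density=a * 0 + 1)
        kept = bm.screen_collinearity(st)
        assert sorted(kept) == ["a", "sampling_density"]

    def test_uncorrelated_layers_all_kept(self, flat_grid):
        rng = np.random.default_rng(1)
        st = stack_from(flat_grid, a=rng.normal(size=flat_grid.shape),
                        b=rng.normal(size=flat_grid.shape),
                        c=rng.normal(size=flat_grid.shape))
        assert len(bm.screen_collinearity(st, exempt=())) == 3

    def test_planted_structure_deterministic(self, flat_grid):
        rng = np.random.default_rng(2)
        a = rng.normal(size=flat_grid.shape)
        b = a + 0.05 * rng.normal(size=flat_grid.shape)  # r ~ 1
        c = rng.normal(size=flat_grid.shape)
        st = stack_from(flat_grid, a=a, b=b, c=c)
        kept1 = bm.screen_collinearity(st, exempt=())
        kept2 = bm.screen_collinearity(st, exempt=())
        assert kept1 == kept2
        assert "c" in kept1 and len(kept1) == 2

    def test_density_layer_exempt(self, flat_grid):
        rng = np.random.default_rng(3)
        a = rng.normal(size=flat_grid.shape)
        st = stack_from(flat_grid, a=a, sampling_density=a.copy())
        kept = bm.screen_collinearity(st)
        assert "sampling_density" in kept


class TestRealmFill:
    def test_single_label_propagates_everywhere(self, flat_grid):
        realm = np.full(flat_grid.shape, np.nan)
        realm[3, 3] = 2.0
        out = bm.fill_realms(realm, flat_grid)
        assert np.all(out == 2.0)

    def test_no_missing_is_identity(self, flat_grid):
        realm = np.ones(flat_grid.shape)
        assert np.array_equal(bm.fill_realms(realm, flat_grid), realm)

    def test_east_west_split_matches_voronoi_oracle(self):
        grid = make_flat_grid(8, 16)
        realm = np.full(grid.shape, np.nan)
        realm[:, 0] = 0.0
        realm[:, -1] = 1.0
        out = bm.fill_realms(realm, grid)
        lon, lat = np.meshgrid(grid.lon_centers, grid.lat_centers)
        d0 = great_circle_km(lon, lat, grid.lon_centers[0], lat)
        d1 = great_circle_km(lon, lat, grid.lon_centers[-1], lat)
        expect = (d1 < d0).astype(float)
        ties = np.isclose(d0, d1)
        assert np.array_equal(out[~ties], expect[~ties])

    def test_no_labels_rejected(self, flat_grid):
        with pytest.raises(ValueError):
            bm.fill_realms(np.full(flat_grid.shape, np.nan), flat_grid)


class TestCheckerboard:
    def test_140_blocks_28_per_fold(self):
        grid = make_flat_grid(40, 56, resolution_arcmin=30.0)
        folds = bm.checkerboard_folds(grid)
        ri = np.minimum((np.arange(grid.n_rows) * 10) // grid.n_rows, 9)
        ci = np.minimum((np.arange(grid.n_cols) * 14) // grid.n_cols, 13)
        block = ri[:, None] * 14 + ci[None, :]
        assert len(np.unique(block)) == 140
        per_fold = [len(np.unique(block[folds == f])) for f in range(5)]
        assert per_fold == [28] * 5

    def test_horizontally_adjacent_blocks_differ(self):
        grid = make_flat_grid(20, 28)
        folds = bm.checkerboard_folds(grid)
        # sample block-corner cells: consecutive blocks along a row
        row = 1
        cols = np.arange(0, grid.n_cols, 2)
        vals = folds[row, cols]
        assert all(a != b for a, b in zip(vals, vals[1:]))

    def test_every_cell_assigned(self, flat_grid):
        folds = bm.checkerboard_folds(flat_grid)
        assert folds.shape == flat_grid.shape
        assert set(np.unique(folds)) <= set(range(5))


def frame_and_response(grid, kind="linear", seed=0):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=grid.shape)
    x2 = rng.normal(size=grid.shape)
    dens = rng.uniform(0.1, 1.0, size=grid.shape)
    if kind == "linear":
        y = 3.0 * x1
    else:
        y = rng.normal(size=grid.shape)
    st = bm.PredictorStack(grid, dict(x1=x1, x2=x2, sampling_density=dens))
    X = st.to_frame(np.ones(grid.shape, bool))
    rows, cols = X.pop("row"), X.pop("col")
    return st, X, y[rows, cols], bm.checkerboard_folds(grid)[rows, cols]


class TestForestTuning:
    def test_signal_dominant_fixture_beats_variance(self, flat_grid):
        _, X, y, folds = frame_and_response(flat_grid, "linear")
        f = bm.SamplingBiasForest(mtry_grid=(1, 2, 3), n_trees=100, seed=0)
        f.fit(X, y, folds=folds)
        assert f.cv_mse_.mse.min() < 0.2 * y.var()

    def test_noise_response_no_better_than_mean(self, flat_grid):
        _, X, y, folds = frame_and_response(flat_grid, "noise")
        f = bm.SamplingBiasForest(mtry_grid=(1, 3), n_trees=100, seed=0)
        f.fit(X, y, folds=folds)
        assert f.cv_mse_.mse.min() > 0.8 * y.var()

    def test_seed_reproducibility(self, flat_grid):
        _, X, y, folds = frame_and_response(flat_grid, "linear")
        a = bm.SamplingBiasForest(mtry_grid=(1, 2), n_trees=50, seed=3).fit(X, y, folds=folds)
        b = bm.SamplingBiasForest(mtry_grid=(1, 2), n_trees=50, seed=3).fit(X, y, folds=folds)
        assert a.mtry_ == b.mtry_
        pd.testing.assert_frame_equal(a.cv_mse_, b.cv_mse_)

    def test_selected_mtry_minimizes_cv_mse(self, flat_grid):
        _, X, y, folds = frame_and_response(flat_grid, "linear", seed=4)
        f = bm.SamplingBiasForest(mtry_grid=(1, 2, 3), n_trees=80, seed=1)
        f.fit(X, y, folds=folds)
        best = f.cv_mse_.loc[f.cv_mse_.mse.idxmin()]
        assert f.mtry_ == int(best.mtry)

    def test_log_transform_roundtrip(self, flat_grid):
        _, X, y, folds = frame_and_response(flat_grid, "linear", seed=5)
        y = np.exp(y / 3)  # strictly positive response
        f = bm.SamplingBiasForest(mtry_grid=(2,), n_trees=100,
                                  response_transform="log", seed=0)
        f.fit(X, y)
        pred = f.predict(X)
        assert np.all(pred >= 0)
        assert np.corrcoef(pred, y)[0, 1] > 0.9

    def test_permutation_importance_ranks_signal_first(self, flat_grid):
        _, X, y, folds = frame_and_response(flat_grid, "linear", seed=6)
        f = bm.SamplingBiasForest(mtry_grid=(2,), n_trees=100, seed=0).fit(X, y)
        tab = f.importance_table(n_repeats=3)
        assert tab.predictor.iloc[0] == "x1"
        noise_imp = tab.set_index("predictor").importance["x2"]
        assert noise_imp < 0.05 * tab.importance.iloc[0]


class TestCounterfactual:
    def test_uniform_density_gives_identical_predictions(self, flat_grid):
        rng = np.random.default_rng(7)
        x1 = rng.normal(size=flat_grid.shape)
        dens = np.ones(flat_grid.shape)
        st = bm.PredictorStack(flat_grid, dict(x1=x1, sampling_density=dens))
        X = st.to_frame(np.ones(flat_grid.shape, bool))
        rows, cols = X.pop("row"), X.pop("col")
        y = 2 * x1[rows, cols] + rng.normal(0, 0.1, len(rows))
        f = bm.SamplingBiasForest(mtry_grid=(1,), n_trees=60, seed=0).fit(X, y)
        res = bm.counterfactual_high_sampling(f, st, "richness")
        a, b = res.empirical_pred.values, res.counterfactual_pred.values
        assert np.array_equal(a[np.isfinite(a)], b[np.isfinite(b)])
        assert not np.any(res.change_class == bm.CLASS_DROP)
        assert not np.any(res.change_class == bm.CLASS_ENTER)

    def test_every_cell_in_exactly_one_class(self, flat_grid):
        rng = np.random.default_rng(8)
        x1 = rng.normal(size=flat_grid.shape)
        dens = rng.uniform(0.05, 1.0, size=flat_grid.shape)
        st = bm.PredictorStack(flat_grid, dict(x1=x1, sampling_density=dens))
        X = st.to_frame(np.ones(flat_grid.shape, bool))
        rows, cols = X.pop("row"), X.pop("col")
        y = x1[rows, cols] * dens[rows, cols]
        f = bm.SamplingBiasForest(mtry_grid=(1,), n_trees=60, seed=0).fit(X, y)
        res = bm.counterfactual_high_sampling(f, st, "richness")
        assert set(np.unique(res.change_class)) <= {0, 1, 2, 3}

    def test_missing_density_layer_rejected(self, flat_grid):
        rng = np.random.default_rng(9)
        st = bm.PredictorStack(flat_grid, dict(x1=rng.normal(size=flat_grid.shape)))
        f = bm.SamplingBiasForest(mtry_grid=(1,), n_trees=10, seed=0)
        with pytest.raises(ValueError, match="density"):
            bm.counterfactual_high_sampling(f, st, "richness")


class TestRobustnessFractions:
    def make_result(self, grid, emp, cf):
        cls = np.full(grid.shape, bm.CLASS_NONCENTER)
        cls[emp & cf] = bm.CLASS_ROBUST
        cls[emp & ~cf] = bm.CLASS_DROP
        cls[~emp & cf] = bm.CLASS_ENTER
        rast = dm.DiversityRaster(grid, "richness", np.ones(grid.shape))
        return bm.CounterfactualResult(
            empirical_pred=rast, counterfactual_pred=rast,
            empirical_centers=dm.CenterMask(grid=grid, member=emp),
            counterfactual_centers=dm.CenterMask(grid=grid, member=cf),
            change_class=cls)

    def test_identity_counterfactual_fully_robust(self, flat_grid):
        m = np.zeros(flat_grid.shape, bool)
        m[2:5, 2:5] = True
        out = bm.robustness_fraction(self.make_result(flat_grid, m, m.copy()))
        assert out["robust"] == 1.0 and out["drop"] == 0.0

    def test_disjoint_centers_zero_robust(self, flat_grid):
        a = np.zeros(flat_grid.shape, bool)
        b = np.zeros(flat_grid.shape, bool)
        a[0, 0] = True
        b[5, 5] = True
        out = bm.robustness_fraction(self.make_result(flat_grid, a, b))
        assert out["robust"] == 0.0 and out["drop"] == 1.0 and out["enter"] == 1.0

    def test_three_cell_toy_enumeration(self):
        # equal-area cells: 1 robust, 1 drop, 1 enter -> (0.5, 0.5, 0.5)
        grid = make_flat_grid(1, 4)
        emp = np.array([[True, True, False, False]])
        cf = np.array([[True, False, True, False]])
        out = bm.robustness_fraction(self.make_result(grid, emp, cf))
        assert out["robust"] == pytest.approx(0.5)
        assert out["drop"] == pytest.approx(0.5)
        assert out["enter"] == pytest.approx(0.5)
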