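"""Presence-background model: features, fitting, metrics, tuning/selection."""

import numpy as np
import pandas as pd
import pytest

from antdiv import sdm_engine as sdm
from antdiv.synthetic_world import BiasField
from .conftest import make_flat_grid


class TestSamplingDensity:
    def test_single_occurrence_peaks_at_its_cell(self):
        grid = make_flat_grid(10, 10)
        dens = sdm.build_sampling_density(np.array([grid.lon_centers[4]]),
                                          np.array([grid.lat_centers[5]]), grid)
        assert dens.density.max() == 1.0
        assert dens.density[5, 4] == 1.0

    def test_rescaled_max_exactly_one(self):
        grid = make_flat_grid(10, 10)
        rng = np.random.default_rng(0)
        dens = sdm.build_sampling_density(
            rng.uniform(grid.lon_min, grid.lon_max, 500),
            rng.uniform(grid.lat_min, grid.lat_max, 500), grid)
        assert dens.density.max() == 1.0

    def test_uniform_dense_occurrences_flat_interior(self):
        grid = make_flat_grid(20, 20)
        lon, lat = np.meshgrid(grid.lon_centers, grid.lat_centers)
        dens = sdm.build_sampling_density(np.tile(lon.ravel(), 3),
                                          np.tile(lat.ravel(), 3), grid)
        interior = dens.density[6:14, 6:14]
        assert interior.min() > 0.8 * interior.max()


class TestBackgroundSampling:
    def grid_density(self):
        grid = make_flat_grid(100, 200)  # 20,000 cells (> background n)
        d = np.ones(grid.shape)
        d[:, 100:] = 0.2  # right half 5x less collected
        return grid, BiasField(grid, d)

    def test_small_extent_gets_every_cell(self):
        grid, dens = self.grid_density()
        extent = np.zeros(grid.shape, bool)
        extent[:10, :50] = True  # 500 cells < 10,000 -> full assignment
        r, c = sdm.sample_background(dens, extent, n=10000, seed=0)
        assert len(r) == 500

    def test_sampled_mass_follows_density(self):
        grid, dens = self.grid_density()
        extent = np.ones(grid.shape, bool)
        r, c = sdm.sample_background(dens, extent, n=10000, seed=1)
        frac_left = float(np.mean(c < 100))
        expect = 1.0 / (1.0 + 0.2)  # density mass in the left half
        assert frac_left == pytest.approx(expect, abs=0.02)

    def test_seed_reproducibility(self):
        grid, dens = self.grid_density()
        extent = np.ones(grid.shape, bool)
        a = sdm.sample_background(dens, extent, n=10000, seed=7)
        b = sdm.sample_background(dens, extent, n=10000, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestFeatures:
    def test_column_counts_by_class(self):
        rng = np.random.default_rng(0)
        bg = rng.normal(size=(200, 2))
        assert sdm.FeatureBuilder("L").fit(bg).transform(bg).shape[1] == 2
        assert sdm.FeatureBuilder("LQ").fit(bg).transform(bg).shape[1] == 4
        assert sdm.FeatureBuilder("LQH", hinge_knots=8).fit(bg).transform(bg).shape[1] == 4 + 16

    def test_hinge_definition(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(500, 1))
        fb = sdm.FeatureBuilder("H", hinge_knots=4).fit(bg)
        x = np.array([[-1.0], [0.0], [2.0]])
        z = (x[:, 0] - fb.mean_[0]) / fb.sd_[0]
        expect = np.maximum(0.0, z[:, None] - fb.knots_[:, 0][None, :])
        assert np.allclose(fb.transform(x), expect)

    def test_constant_variable_dropped_with_warning(self):
        bg = np.column_stack([np.random.default_rng(0).normal(size=100),
                              np.full(100, 3.0)])
        with pytest.warns(UserWarning, match="constant"):
            fb = sdm.FeatureBuilder("L").fit(bg)
        assert fb.transform(bg).shape[1] == 1


def gradient_data(n_pres=80, n_bg=600, seed=0):
    """1-D world: presences concentrate at high x."""
    rng = np.random.default_rng(seed)
    bg = rng.uniform(-2, 2, size=(n_bg, 1))
    pres = rng.normal(1.2, 0.4, size=(n_pres, 1))
    X = np.vstack([pres, bg])
    y = np.concatenate([np.ones(n_pres), np.zeros(n_bg)])
    return X, y, pres, bg


class TestPresenceBackgroundModel:
    def test_huge_penalty_yields_null_model(self):
        X, y, *_ = gradient_data()
        m = sdm.PresenceBackgroundModel("LQH", reg_multiplier=1e6).fit(X, y)
        assert m.n_nonzero_ == 0
        # null model predicts a constant suitability everywhere
        assert np.ptp(m.predict(X)) == pytest.approx(0.0, abs=1e-12)

    def test_sign_agrees_with_logistic_regression_oracle(self):
        from sklearn.linear_model import LogisticRegression
        X, y, *_ = gradient_data()
        m = sdm.PresenceBackgroundModel("L", reg_multiplier=1.0).fit(X, y)
        lr = LogisticRegression().fit(X, y)
        assert m.coef_[0] > 0
        assert np.sign(m.coef_[0]) == np.sign(lr.coef_[0, 0])

    def test_rank_agreement_with_logistic_oracle(self):
        from scipy.stats import spearmanr
        from sklearn.linear_model import LogisticRegression
        X, y, pres, bg = gradient_data(seed=2)
        m = sdm.PresenceBackgroundModel("L", reg_multiplier=1.0).fit(X, y)
        lr = LogisticRegression().fit(X, y)
        rho, _ = spearmanr(m.predict(X), lr.predict_proba(X)[:, 1])
        assert rho > 0.99

    @pytest.mark.parametrize("classes", ["L", "LQH"])
    def test_stronger_penalty_never_adds_coefficients(self, classes):
        X, y, *_ = gradient_data(seed=3)
        counts = [sdm.PresenceBackgroundModel(classes, m).fit(X, y).n_nonzero_
                  for m in (1, 2, 4, 8, 16)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cloglog_monotone_in_eta_and_bounded(self):
        X, y, *_ = gradient_data()
        m = sdm.PresenceBackgroundModel("L").fit(X, y)
        xs = np.linspace(-3, 3, 50)[:, None]
        s = m.predict(xs)
        assert np.all((s > 0) & (s < 1))
        eta = m.decision_function(xs)
        order = np.argsort(eta)
        assert np.all(np.diff(s[order]) >= -1e-12)

    def test_unbalanced_input_rejected(self):
        X, y, *_ = gradient_data(n_pres=50, n_bg=10)
        with pytest.raises(ValueError, match="background"):
            sdm.PresenceBackgroundModel().fit(X, y)


class TestFolds:
    def test_loo_below_25(self):
        f = sdm.partition_folds(24, seed=0)
        assert f.kind == "loo" and f.k == 24
        assert np.array_equal(np.sort(f.assignment), np.arange(24))

    def test_random_k5_at_25(self):
        f = sdm.partition_folds(25, seed=0)
        assert f.kind == "random_k" and f.k == 5
        assert np.array_equal(np.bincount(f.assignment), np.full(5, 5))

    def test_fold_sizes_within_one(self):
        f = sdm.partition_folds(27, seed=1)
        sizes = np.bincount(f.assignment)
        assert sizes.max() - sizes.min() <= 1

    def test_seed_determinism_and_minimum(self):
        assert np.array_equal(sdm.partition_folds(30, seed=5).assignment,
                              sdm.partition_folds(30, seed=5).assignment)
        with pytest.raises(ValueError):
            sdm.partition_folds(4, seed=0)


class TestEvaluation:
    def test_perfect_separation_gives_auc_one(self):
        # presences fully above the background's support: every withheld
        # presence outranks every background cell under a monotone model
        rng = np.random.default_rng(4)
        bg = rng.uniform(-2, 0, size=(400, 1))
        pres = rng.uniform(1, 2, size=(40, 1))
        folds = sdm.partition_folds(len(pres), seed=0)
        met = sdm.evaluate_candidate(pres, bg, "L", 1.0, folds)
        assert met.auc_val == pytest.approx(1.0)

    def test_null_auc_is_half(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(0)
        labels = np.concatenate([np.ones(500), np.zeros(5000)])
        scores = rng.uniform(size=5500)
        assert roc_auc_score(labels, scores) == pytest.approx(0.5, abs=0.05)

    def test_training_omission_at_threshold_definition(self):
        rng = np.random.default_rng(1)
        s_train = rng.uniform(size=200)
        thr = np.percentile(s_train, 10)
        om = np.mean(s_train < thr)
        assert om == pytest.approx(0.10, abs=1.0 / len(s_train))

    def test_boyce_positive_for_calibrated_model(self):
        rng = np.random.default_rng(2)
        suit_ext = rng.uniform(size=5000)
        keep = rng.uniform(size=5000) < suit_ext  # occurrence prob ~ suitability
        cbi = sdm.continuous_boyce_index(suit_ext[keep], suit_ext)
        assert cbi > 0.5

    def test_boyce_nan_for_degenerate_range(self):
        assert np.isnan(sdm.continuous_boyce_index(np.array([0.5]),
                                                   np.full(100, 0.5)))


def candidate_table(rows):
    cols = ["feature_classes", "class_order", "reg_multiplier",
            "or10", "auc_val", "cbi", "n_nonzero"]
    return pd.DataFrame(rows, columns=cols)


class TestSequentialSelection:
    def test_single_survivor_selected(self):
        t = candidate_table([("L", 0, 1, 0.1, 0.8, 0.5, 2),
                             ("LQ", 1, 1, 0.2, 0.9, np.nan, 4)])
        assert sdm.select_from_table(t) == ("L", 1)

    def test_auc_breaks_or10_ties(self):
        t = candidate_table([("L", 0, 1, 0.1, 0.7, 0.5, 2),
                             ("H", 2, 3, 0.1, 0.8, 0.5, 9)])
        assert sdm.select_from_table(t) == ("H", 3)

    def test_coefficient_count_breaks_remaining_ties(self):
        t = candidate_table([("LQ", 1, 2, 0.1, 0.8, 0.5, 6),
                             ("L", 0, 4, 0.1, 0.8, 0.5, 2)])
        assert sdm.select_from_table(t) == ("L", 4)

    def test_deterministic_final_tiebreak_simpler_first(self):
        t = candidate_table([("LQ", 1, 2, 0.1, 0.8, 0.5, 3),
                             ("L", 0, 3, 0.1, 0.8, 0.5, 3),
                             ("L", 0, 2, 0.1, 0.8, 0.5, 3)])
        assert sdm.select_from_table(t) == ("L", 2)
        assert sdm.select_from_table(t.iloc[::-1]) == ("L", 2)  # order-invariant

    def test_all_filtered_returns_fallback(self):
        t = candidate_table([("L", 0, 1, 0.1, 0.8, -0.2, 2),
                             ("LQ", 1, 1, 0.1, 0.8, np.nan, 0)])
        assert sdm.select_from_table(t) is None

    def test_zero_coefficient_models_dropped_first(self):
        t = candidate_table([("L", 0, 5, 0.0, 0.9, 0.9, 0),
                             ("L", 0, 1, 0.3, 0.6, 0.2, 2)])
        assert sdm.select_from_table(t) == ("L", 1)


class TestTuneAndSelect:
    def test_parameter_recovery_on_gradient_world(self):
        """Selected model's suitability tracks the true occupancy gradient."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(5)
        bg = rng.uniform(-2, 2, size=(800, 2))
        true_prob = 1 / (1 + np.exp(-3 * bg[:, 0]))
        pres_idx = rng.uniform(size=800) < true_prob
        pres = bg[pres_idx][:120]
        sel = sdm.tune_and_select(pres, bg, multipliers=(1, 2), seed=0)
        assert not sel.polygon_fallback
        rho, _ = spearmanr(sel.model.predict(bg), true_prob)
        assert rho >= 0.7

    def test_selection_reproducible(self):
        rng = np.random.default_rng(6)
        bg = rng.uniform(-2, 2, size=(300, 1))
        pres = rng.normal(1.0, 0.5, size=(30, 1))
        a = sdm.tune_and_select(pres, bg, classes=("L", "LQ"),
                                multipliers=(1, 3), seed=2)
        b = sdm.tune_and_select(pres, bg, classes=("L", "LQ"),
                                multipliers=(1, 3), seed=2)
        assert a.settings == b.settings
        pd.testing.assert_frame_equal(a.table, b.table)
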