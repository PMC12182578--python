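"""Training-table construction, filtering, splitting, tuning, evaluation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from dasypop import (
    COVARIATE_NAMES,
    DEPTH_CANDIDATES,
    TREE_CANDIDATES,
    build_training_table,
    evaluate_on_test,
    filter_middle_99,
    importance_and_pdp,
    split_train_test,
    tune_and_fit,
)

REDUCED_TREES = (5, 20, 100)
REDUCED_DEPTHS = (10, 40)


def _synth_table(n, rng, noise=0.0, informative=("builtup_frac",)):
    X = pd.DataFrame(rng.random((n, 8)), columns=list(COVARIATE_NAMES))
    y = sum(X[c] for c in informative) + noise * rng.standard_normal(n)
    X["density_total"] = y
    X["inhabited_area_ha"] = 10.0
    return X


class TestBuildTrainingTable:
    def _inputs(self):
        idx = pd.Index([1, 2, 3], name="zone_id")
        census = pd.DataFrame({"total": [500.0, 0.0, 80.0]}, index=idx)
        cov = pd.DataFrame(np.ones((3, 8)), index=idx,
                           columns=list(COVARIATE_NAMES))
        areas = pd.Series([25.0, 10.0, 0.0], index=idx)
        return census, cov, areas

    def test_density_is_count_over_area(self):
        census, cov, areas = self._inputs()
        tab = build_training_table(census, cov, areas, groups=("total",))
        assert tab.at[1, "density_total"] == 20.0
        assert tab.at[2, "density_total"] == 0.0

    def test_zero_area_with_population_excluded_with_warning(self):
        census, cov, areas = self._inputs()
        with pytest.warns(UserWarning, match="zero inhabited area"):
            tab = build_training_table(census, cov, areas, groups=("total",))
        assert 3 not in tab.index

    def test_null_covariates_excluded(self):
        census, cov, areas = self._inputs()
        cov.at[2, "ntl"] = np.nan
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            tab = build_training_table(census, cov, areas, groups=("total",))
        assert 2 not in tab.index
        assert any("null covariate" in str(w.message) for w in rec)

    def test_densities_match_truth_oracle(self, study):
        tab = study["table"]
        census, mask = study["census"], study["mask"]
        zones = study["zones"]
        labels = zones.labels.values
        for zid in list(tab.index[:10]):
            area = ((labels == zid) & mask.values).sum()  # ha at 100 m
            assert tab.at[zid, "density_total"] == pytest.approx(
                census.at[zid, "total"] / area, rel=1e-12)


class TestFilterMiddle99:
    def test_1000_distinct_keeps_990(self, rng):
        tab = pd.DataFrame({"density_total": rng.permutation(1000).astype(float)})
        out = filter_middle_99(tab, "total")
        assert len(out) == 990

    def test_degenerate_all_equal_keeps_all(self):
        tab = pd.DataFrame({"density_total": np.full(300, 7.0)})
        assert len(filter_middle_99(tab, "total")) == 300

    def test_matches_sort_slice_oracle(self, rng):
        d = rng.normal(size=400)
        tab = pd.DataFrame({"density_total": d})
        out = filter_middle_99(tab, "total")
        lo, hi = np.percentile(d, [0.5, 99.5])
        oracle = set(np.where((d > lo) & (d < hi))[0])
        assert set(out.index) == oracle

    def test_small_table_skipped_with_warning(self, rng):
        tab = pd.DataFrame({"density_total": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="skipped"):
            out = filter_middle_99(tab, "total")
        assert len(out) == 50


class TestSplitTrainTest:
    @pytest.mark.parametrize("n,n_train,n_test", [(100, 85, 15), (7, 5, 2)])
    def test_sizes(self, rng, n, n_train, n_test):
        tab = _synth_table(n, rng)
        train, test = split_train_test(tab, seed=3)
        assert (len(train), len(test)) == (n_train, n_test)

    def test_disjoint_exhaustive_and_seeded(self, rng):
        tab = _synth_table(40, rng)
        tr1, te1 = split_train_test(tab, seed=8)
        tr2, te2 = split_train_test(tab, seed=8)
        pd.testing.assert_frame_equal(tr1, tr2)
        assert set(tr1.index) | set(te1.index) == set(tab.index)
        assert not set(tr1.index) & set(te1.index)

    def test_too_small_raises(self, rng):
        with pytest.raises(ValueError):
            split_train_test(_synth_table(1, rng))


class TestTuneAndFit:
    def test_cv_table_covers_full_candidate_grid(self, rng):
        tab = _synth_table(40, rng)
        model = tune_and_fit(tab, "total", seed=1)
        assert len(model.cv_table) == 117
        assert set(model.cv_table["n_trees"]) == set(TREE_CANDIDATES)
        assert set(model.cv_table["max_depth"]) == set(DEPTH_CANDIDATES)
        assert (model.n_trees, model.max_depth) in set(
            zip(model.cv_table["n_trees"], model.cv_table["max_depth"]))

    def test_winner_minimizes_cv_rmse_with_tie_break(self, rng):
        tab = _synth_table(40, rng)
        model = tune_and_fit(tab, "total", seed=1,
                             tree_candidates=REDUCED_TREES,
                             depth_candidates=REDUCED_DEPTHS)
        cv = model.cv_table
        best = cv[cv.cv_rmse == cv.cv_rmse.min()].sort_values(
            ["n_trees", "max_depth"]).iloc[0]
        assert model.n_trees == best.n_trees
        assert model.max_depth == best.max_depth
        assert model.cv_rmse == best.cv_rmse

    def test_grid_search_matches_naive_per_combo_fits(self, rng):
        """Prefix-average scoring equals refitting each combination fresh."""
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.model_selection import KFold
        tab = _synth_table(30, rng, noise=0.3)
        model = tune_and_fit(tab, "total", seed=2,
                             tree_candidates=(5, 20),
                             depth_candidates=(10, 40))
        X = tab[list(COVARIATE_NAMES)].to_numpy()
        y = tab["density_total"].to_numpy()
        folds = list(KFold(5, shuffle=True, random_state=2).split(X))
        for _, row in model.cv_table.iterrows():
            sq, n = 0.0, 0
            for tr, va in folds:
                rf = RandomForestRegressor(n_estimators=int(row.n_trees),
                                           max_depth=int(row.max_depth),
                                           random_state=2, n_jobs=1)
                rf.fit(X[tr], y[tr])
                resid = rf.predict(X[va]) - y[va]
                sq += resid @ resid
                n += len(va)
            assert row.cv_rmse == pytest.approx(np.sqrt(sq / n), rel=1e-12)

    def test_noise_free_target_learned_tightly(self, rng):
        tab = _synth_table(500, rng, noise=0.0)
        model = tune_and_fit(tab, "total", seed=4)
        assert model.cv_rmse < tab["density_total"].std() / 10

    def test_rerun_reproducibility(self, rng):
        tab = _synth_table(60, rng, noise=0.2)
        m1 = tune_and_fit(tab, "total", seed=9, tree_candidates=REDUCED_TREES,
                          depth_candidates=REDUCED_DEPTHS)
        m2 = tune_and_fit(tab, "total", seed=9, tree_candidates=REDUCED_TREES,
                          depth_candidates=REDUCED_DEPTHS)
        assert (m1.n_trees, m1.max_depth) == (m2.n_trees, m2.max_depth)
        pd.testing.assert_series_equal(m1.feature_importances,
                                       m2.feature_importances)

    def test_non_finite_target_raises(self, rng):
        tab = _synth_table(20, rng)
        tab.loc[tab.index[0], "density_total"] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            tune_and_fit(tab, "total", seed=0,
                         tree_candidates=REDUCED_TREES,
                         depth_candidates=REDUCED_DEPTHS)


class TestEvaluate:
    def _model(self, rng, **kw):
        tab = _synth_table(80, rng, noise=0.1)
        return tune_and_fit(tab, "total", seed=5,
                            tree_candidates=REDUCED_TREES,
                            depth_candidates=REDUCED_DEPTHS), tab

    def test_perfect_predictions(self, rng):
        model, tab = self._model(rng)
        test = tab.iloc[:20].copy()
        test["density_total"] = model.predict(
            test[list(COVARIATE_NAMES)].to_numpy())
        r2, rmse = evaluate_on_test(model, test)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-12)

    def test_r2_matches_formula_oracle(self, rng):
        model, tab = self._model(rng)
        test = _synth_table(50, rng, noise=0.1)
        r2, rmse = evaluate_on_test(model, test)
        y = test["density_total"].to_numpy()
        pred = model.predict(test[list(COVARIATE_NAMES)].to_numpy())
        ss_res = ((y - pred) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
        assert rmse == pytest.approx(np.sqrt(ss_res / len(y)), abs=1e-12)

    def test_constant_prediction_r2_zero(self, rng):
        # predicting the target mean gives R^2 = 0 by definition
        y = rng.normal(size=30)
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - ((y - y.mean()) ** 2).sum() / ss_tot
        assert r2 == pytest.approx(0.0)

    def test_empty_test_raises(self, rng):
        model, tab = self._model(rng)
        with pytest.raises(ValueError, match="empty"):
            evaluate_on_test(model, tab.iloc[:0])


class TestImportanceAndPdp:
    def test_informative_covariate_ranks_first(self, rng):
        tab = _synth_table(300, rng, noise=0.05, informative=("ntl",))
        model = tune_and_fit(tab, "total", seed=6,
                             tree_candidates=REDUCED_TREES,
                             depth_candidates=REDUCED_DEPTHS)
        imp, pdp = importance_and_pdp(model, tab)
        assert imp.idxmax() == "ntl"
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp >= 0).all()

    def test_pdp_flat_for_ignored_covariate(self, rng):
        tab = _synth_table(300, rng, noise=0.05, informative=("ntl",))
        model = tune_and_fit(tab, "total", seed=6,
                             tree_candidates=REDUCED_TREES,
                             depth_candidates=REDUCED_DEPTHS)
        _, pdp = importance_and_pdp(model, tab)
        sd = tab["density_total"].std()
        flat = pdp[pdp.covariate == "elevation"]["mean_prediction"]
        steep = pdp[pdp.covariate == "ntl"]["mean_prediction"]
        assert flat.max() - flat.min() < 0.05 * sd
        assert steep.max() - steep.min() > 0.5 * sd

    def test_pdp_grid_spans_percentiles(self, rng):
        tab = _synth_table(100, rng)
        model = tune_and_fit(tab, "total", seed=7,
                             tree_candidates=REDUCED_TREES,
                             depth_candidates=REDUCED_DEPTHS)
        _, pdp = importance_and_pdp(model, tab, n_grid=20)
        for name in COVARIATE_NAMES:
            sub = pdp[pdp.covariate == name]
            assert len(sub) == 20
            lo, hi = np.percentile(tab[name], [1, 99])
            assert sub["value"].min() == pytest.approx(lo)
            assert sub["value"].max() == pytest.approx(hi)
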