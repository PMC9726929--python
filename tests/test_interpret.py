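"""Exact Shapley attribution and partial-dependence curves."""

import numpy as np
import pandas as pd
import pytest

from cytodose.interpret import (exact_shap, ice_curves, mean_abs_shap,
                                onehot_groups, pd_surface_2d)
from oracles import FunctionModel, permutation_oracle


@pytest.fixture()
def linear_case(rng):
    X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["x1", "x2", "x3"])
    bg = pd.DataFrame(rng.normal(size=(25, 3)), columns=["x1", "x2", "x3"])
    model = FunctionModel(lambda df: 2.0 * df["x1"] + 3.0 * df["x2"])
    return model, X, bg


class TestExactShap:
    def test_local_accuracy(self, linear_case):
        model, X, bg = linear_case
        shap = exact_shap(model, X, bg)
        assert shap.check_local_accuracy(atol=1e-9)

    def test_linear_model_closed_form(self, linear_case):
        # for f = 2 x1 + 3 x2 with an interventional background,
        # SHAP_1 = 2 (x1 - mean background x1)
        model, X, bg = linear_case
        shap = exact_shap(model, X, bg)
        expect = 2.0 * (X["x1"] - bg["x1"].mean())
        assert shap.values["x1"].to_numpy() == pytest.approx(
            expect.to_numpy(), abs=1e-9)

    def test_ignored_feature_gets_exact_zero(self, linear_case):
        model, X, bg = linear_case
        shap = exact_shap(model, X, bg)
        assert (shap.values["x3"] == 0.0).all()

    def test_single_feature_collapses_to_prediction_minus_base(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=10)})
        bg = pd.DataFrame({"x": rng.normal(size=15)})
        model = FunctionModel(lambda df: df["x"] ** 2)
        shap = exact_shap(model, X, bg)
        expect = X["x"] ** 2 - (bg["x"] ** 2).mean()
        assert shap.values["x"].to_numpy() == pytest.approx(
            expect.to_numpy(), abs=1e-12)

    def test_matches_permutation_oracle_exactly(self, rng):
        cols = ["a", "b", "c", "d"]
        X = pd.DataFrame(rng.normal(size=(4, 4)), columns=cols)
        bg = pd.DataFrame(rng.normal(size=(6, 4)), columns=cols)
        model = FunctionModel(
            lambda df: df["a"] * df["b"] + np.exp(df["c"] / 3) - 0.5 * df["d"])
        shap = exact_shap(model, X, bg)
        for i in range(len(X)):
            oracle = permutation_oracle(model, X.iloc[i], bg)
            assert shap.values.iloc[i].to_numpy() == pytest.approx(
                oracle, abs=1e-12)

    def test_symmetry_for_exchangeable_features(self, rng):
        cols = ["u", "v"]
        X = pd.DataFrame({"u": [1.5], "v": [1.5]})
        bg = pd.DataFrame(np.zeros((10, 2)), columns=cols)
        model = FunctionModel(lambda df: df["u"] + df["v"])
        shap = exact_shap(model, X, bg)
        assert shap.values.loc[0, "u"] == pytest.approx(
            shap.values.loc[0, "v"], abs=1e-12)

    def test_efficiency_over_explained_set(self, linear_case):
        model, X, bg = linear_case
        shap = exact_shap(model, X, bg)
        lhs = shap.values.to_numpy().sum(axis=1).mean()
        rhs = shap.predictions.mean() - shap.base_value
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_groups_toggle_onehot_blocks_together(self, rng):
        cols = ["age", "race_0", "race_1"]
        X = pd.DataFrame([[40.0, 1.0, 0.0]], columns=cols)
        bg = pd.DataFrame([[20.0, 0.0, 1.0]] * 8, columns=cols)
        model = FunctionModel(
            lambda df: df["age"] + 5 * df["race_0"] - 5 * df["race_1"])
        groups = onehot_groups(cols)
        assert groups == {"age": ["age"], "race": ["race_0", "race_1"]}
        shap = exact_shap(model, X, bg, feature_groups=groups)
        assert list(shap.values.columns) == ["age", "race"]
        assert shap.check_local_accuracy()
        assert shap.values.loc[0, "race"] == pytest.approx(10.0)

    def test_feature_limit_enforced(self, rng):
        cols = [f"f{i}" for i in range(11)]
        X = pd.DataFrame(rng.normal(size=(2, 11)), columns=cols)
        model = FunctionModel(lambda df: df["f0"])
        with pytest.raises(ValueError, match="sampling"):
            exact_shap(model, X, X)

    def test_empty_background_rejected(self, linear_case):
        model, X, _ = linear_case
        with pytest.raises(ValueError):
            exact_shap(model, X, X.iloc[:0])


class TestMeanAbsShap:
    def test_ranking_descends_and_ties_break_by_name(self, linear_case):
        model, X, bg = linear_case
        ranking = mean_abs_shap(exact_shap(model, X, bg))
        vals = ranking.to_numpy()
        assert (vals[:-1] >= vals[1:]).all()
        assert ranking.index[0] in ("x1", "x2")
        assert ranking.index[-1] == "x3"

    def test_identical_columns_equal_importance(self, rng):
        X = pd.DataFrame({"p": rng.normal(size=20)})
        X["q"] = X["p"]
        bg = X.iloc[:10]
        model = FunctionModel(lambda df: df["p"] + df["q"])
        ranking = mean_abs_shap(exact_shap(model, X, bg))
        assert ranking["p"] == pytest.approx(ranking["q"], abs=1e-12)

    def test_cohort_model_ranks_assay_indices_on_top(self, matrix):
        from cytodose.forest import QuantileForest
        sub = matrix.select_rows(np.arange(len(matrix.X)) < 500)
        model = QuantileForest(n_trees=60, mtry=6, seed=0).fit(sub.X, sub.y)
        rng = np.random.default_rng(0)
        exp = sub.X.iloc[:40]
        bg = sub.X.iloc[rng.choice(len(sub.X), 50, replace=False)].reset_index(drop=True)
        shap = exact_shap(model, exp, bg,
                          feature_groups=onehot_groups(sub.X.columns))
        ranking = mean_abs_shap(shap)
        assert ranking.index[0] == "mi_bn_c"
        assert set(ranking.index[:3]) <= {"mi_bn_c", "mi_bn", "yield", "age"}


class TestPartialDependence:
    def test_constant_model_flat_curves(self, rng):
        X = pd.DataFrame(rng.normal(size=(15, 2)), columns=["a", "b"])
        model = FunctionModel(lambda df: np.full(len(df), 4.2))
        res = ice_curves(model, X, "a", np.linspace(-2, 2, 7))
        assert res.ice == pytest.approx(np.full((15, 7), 4.2))
        assert res.pd == pytest.approx(np.full(7, 4.2))

    def test_pd_is_mean_of_ice(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        model = FunctionModel(lambda df: df["a"] * df["b"])
        res = ice_curves(model, X, "a", [-1.0, 0.0, 1.0])
        assert res.pd == pytest.approx(res.ice.mean(axis=0))

    def test_single_point_grid_equals_predictions(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        model = FunctionModel(lambda df: df["a"] + df["b"])
        res = ice_curves(model, X, "a", [0.5])
        fixed = X.copy()
        fixed["a"] = 0.5
        assert res.ice[:, 0] == pytest.approx(model.predict(fixed))

    def test_unknown_feature_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 1)), columns=["a"])
        model = FunctionModel(lambda df: df["a"])
        with pytest.raises(ValueError):
            ice_curves(model, X, "zzz", [0.0])

    def test_cohort_pd_nondecreasing_in_linearized_index(self, matrix):
        from cytodose.forest import QuantileForest
        sub = matrix.select_rows(np.arange(len(matrix.X)) < 400)
        model = QuantileForest(n_trees=50, mtry=6, seed=2).fit(sub.X, sub.y)
        grid = np.linspace(sub.X["mi_bn_c"].quantile(0.05),
                           sub.X["mi_bn_c"].quantile(0.95), 8)
        res = ice_curves(model, sub.X.iloc[:60], "mi_bn_c", grid)
        # overall trend: higher linearized index -> higher reconstructed dose
        assert res.pd[-1] > res.pd[0]
        assert np.mean(np.diff(res.pd) >= -0.05) > 0.7

    def test_2d_surface_constant_model_flat(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        model = FunctionModel(lambda df: np.full(len(df), 1.0))
        res = pd_surface_2d(model, X, ("a", "b"), ([0, 1], [0, 1, 2]))
        assert res.pd == pytest.approx(np.ones((2, 3)))

    def test_2d_surface_high_high_corner_is_maximal(self, matrix):
        from cytodose.forest import QuantileForest
        sub = matrix.select_rows(np.arange(len(matrix.X)) < 400)
        model = QuantileForest(n_trees=50, mtry=6, seed=3).fit(sub.X, sub.y)
        ga = np.quantile(sub.X["yield"], [0.1, 0.9])
        gb = np.quantile(sub.X["mi_bn_c"], [0.1, 0.9])
        res = pd_surface_2d(model, sub.X.iloc[:50], ("yield", "mi_bn_c"),
                            (ga, gb))
        assert res.pd[1, 1] == res.pd.max()
        assert res.pd[1, 1] > res.pd[0, 0]
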