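import numpy as np
import pandas as pd
import pytest

import synmap as sm
from synmap.second_order import (
    MEASURES,
    correlation_table,
    fit_regression,
    pair_color_measures,
    sort_and_bin,
    vif,
)


@pytest.fixture(scope="module")
def hira_pairs(palette_mod, dataset_mod):
    """Merged pair measures + predictors for one seeded Hiragana cohort."""
    ds = dataset_mod
    inv = ds.inventories["hiragana"]
    measures = pair_color_measures(ds.responses, palette_mod, inv)
    preds = sm.predictor_table(inv, norms=ds.norms["hiragana"])
    return measures.merge(preds, on=["symbol_a", "symbol_b"], validate="1:1")


@pytest.fixture(scope="module")
def palette_mod():
    return sm.load_default_palette()


@pytest.fixture(scope="module")
def dataset_mod(palette_mod):
    return sm.generate_dataset(sm.GeneratorConfig(seed=99), palette=palette_mod)


PREDICTORS = [
    "ordinality_difference",
    "phonological_similarity",
    "visual_similarity",
    "familiarity_difference",
]


class TestPairColorMeasures:
    def test_toy_two_participants_hand_checked(self, palette_mod):
        from synmap.graphemes import Grapheme, GraphemeInventory

        inv = GraphemeInventory(
            "toy",
            [
                Grapheme("x", "toy", 1, ("a",)),
                Grapheme("y", "toy", 2, ("b",)),
                Grapheme("z", "toy", 3, ("c",)),
            ],
        )
        rows = []
        choices = {
            "p1": {"x": "red", "y": "red", "z": "blue"},
            "p2": {"x": "white", "y": "black", "z": "black"},
        }
        for pid, cmap in choices.items():
            for sym, col in cmap.items():
                rows.append((pid, "synesthete", 1, "toy", sym, col))
                rows.append((pid, "synesthete", 2, "toy", sym, col))
        df = pd.DataFrame(
            rows,
            columns=["participant", "group", "session", "script", "symbol", "color_name"],
        )
        out = pair_color_measures(df, palette_mod, inv)
        assert len(out) == 3
        lab = palette_mod.lab_of
        # pair (x, y): p1 identical colours -> 0; p2 white vs black -> 100
        d_p2 = sm.color_distance(lab("white"), lab("black"))
        row_xy = out[(out.symbol_a == "x") & (out.symbol_b == "y")].iloc[0]
        assert row_xy["color_distance"] == pytest.approx((0 + d_p2) / 2)
        # identical choices give all-zero component distances (pair y,z for p2)
        row_yz = out[(out.symbol_a == "y") & (out.symbol_b == "z")].iloc[0]
        d_p1 = sm.color_distance(lab("red"), lab("blue"))
        assert row_yz["color_distance"] == pytest.approx(d_p1 / 2)

    def test_full_design_row_count(self, hira_pairs):
        assert len(hira_pairs) == 1035
        assert all(m in hira_pairs.columns for m in MEASURES)
        assert (hira_pairs[list(MEASURES)] >= 0).all().all()

    def test_hue_distance_bounded_in_circular_mode(self, hira_pairs):
        assert (hira_pairs["hue_distance"] <= 180).all()


class TestSortAndBin:
    def test_hiragana_and_latin_bin_counts(self, hira_pairs):
        binned = sort_and_bin(hira_pairs, 15)
        assert binned.n_bins == 69
        assert (binned.assignment.groupby("bin").size() == 15).all()

    def test_six_pairs_hand_checked(self):
        df = pd.DataFrame(
            {
                "color_distance": [30.0, 10.0, 50.0, 20.0, 60.0, 40.0],
                "pred": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        binned = sort_and_bin(df, 3)
        # sorted dv: 10,20,30 | 40,50,60 -> means 20, 50; preds 2,4,1 | 6,3,5
        assert binned.bins["color_distance"].tolist() == [20.0, 50.0]
        assert binned.bins["pred"].tolist() == [pytest.approx(7 / 3), pytest.approx(14 / 3)]
        assert binned.bins["color_distance"].is_monotonic_increasing

    def test_non_divisible_count_raises_unless_policy(self):
        df = pd.DataFrame({"color_distance": np.arange(7.0)})
        with pytest.raises(ValueError, match="divisible"):
            sort_and_bin(df, 3)
        with pytest.warns(UserWarning, match="dropping"):
            binned = sort_and_bin(df, 3, policy="drop_remainder")
        assert binned.n_bins == 2

    def test_bin_means_nondecreasing_and_conservation(self, hira_pairs):
        binned = sort_and_bin(hira_pairs, 15)
        assert binned.bins["color_distance"].is_monotonic_increasing
        # conservation: every pair appears exactly once across bins
        key = binned.assignment[["symbol_a", "symbol_b"]].apply(tuple, axis=1)
        orig = hira_pairs[["symbol_a", "symbol_b"]].apply(tuple, axis=1)
        assert sorted(key) == sorted(orig)

    def test_ties_broken_by_canonical_order(self):
        df = pd.DataFrame({"color_distance": [5.0, 5.0, 5.0, 5.0], "tag": [0, 1, 2, 3]})
        binned = sort_and_bin(df, 2)
        assert binned.assignment["tag"].tolist() == [0, 1, 2, 3]


class TestCorrelationTable:
    def test_self_and_exact_linear_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = 2 * df["x"] + 1
        r, p = correlation_table(df, ["x", "y"])
        assert r.loc["x", "x"] == 1
        assert r.loc["x", "y"] == pytest.approx(1)

    def test_matches_covariance_formula(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
        r, _ = correlation_table(df, ["u", "v"])
        u, v = df["u"], df["v"]
        brute = ((u - u.mean()) * (v - v.mean())).sum() / np.sqrt(
            ((u - u.mean()) ** 2).sum() * ((v - v.mean()) ** 2).sum()
        )
        assert r.loc["u", "v"] == pytest.approx(brute)

    def test_zero_variance_column_warns_nan(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            r, _ = correlation_table(df, ["x", "c"])
        assert np.isnan(r.loc["x", "c"])


class TestVif:
    def test_orthogonal_predictors_are_one(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 1.0, -1.0, -1.0, 1.0, -1.0, 1.0, -1.0],
                "b": [1.0, -1.0, 1.0, -1.0, 1.0, 1.0, -1.0, -1.0],
            }
        )
        if abs(np.corrcoef(df["a"], df["b"])[0, 1]) > 1e-12:
            df["b"] = [1.0, -1.0, 1.0, -1.0, -1.0, 1.0, -1.0, 1.0]
        out = vif(df, ["a", "b"])
        assert out["a"] == pytest.approx(1.0, abs=1e-8)

    def test_duplicated_predictor_is_infinite(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        df["b"] = df["a"]
        df["c"] = [1.0, -1.0, 2.0, 0.5, 0.0, 3.0]
        out = vif(df, ["a", "b", "c"])
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_equals_inverse_correlation_diagonal(self, rng):
        """Auxiliary-regression VIF == diag of inverse correlation matrix."""
        X = rng.normal(size=(60, 4))
        X[:, 3] = 0.7 * X[:, 0] + 0.5 * rng.normal(size=60)  # induce collinearity
        df = pd.DataFrame(X, columns=list("abcd"))
        out = vif(df, list("abcd"))
        oracle = np.diag(np.linalg.inv(np.corrcoef(X, rowvar=False)))
        np.testing.assert_allclose(out.to_numpy(), oracle, atol=1e-8)


class TestFitRegression:
    def test_dv_duplicating_predictor(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=["x1", "x2", "x3"])
        df["y"] = df["x1"]
        res = fit_regression(df, "y", ["x1", "x2", "x3"])
        assert res.r_squared == pytest.approx(1.0)
        assert res.coefficients.loc["x1", "beta"] == pytest.approx(1.0, abs=1e-8)
        assert abs(res.coefficients.loc["x2", "beta"]) < 1e-8

    def test_single_predictor_beta_is_pearson_r(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 2)), columns=["x", "y"])
        res = fit_regression(df, "y", ["x"])
        r = np.corrcoef(df["x"], df["y"])[0, 1]
        assert res.coefficients.loc["x", "beta"] == pytest.approx(r)

    def test_planted_coefficients_recovered_exactly(self, rng):
        X = rng.normal(size=(10, 4))
        planted = np.array([2.0, -1.5, 0.25, 4.0])
        df = pd.DataFrame(X, columns=list("abcd"))
        df["y"] = 3.0 + X @ planted  # zero noise
        res = fit_regression(df, "y", list("abcd"))
        np.testing.assert_allclose(res.coefficients["B"], planted, atol=1e-8)
        assert res.intercept == pytest.approx(3.0, abs=1e-8)

    def test_beta_identity_and_r2_oracle_on_real_fit(self, hira_pairs):
        binned = sort_and_bin(hira_pairs, 15)
        for dv in MEASURES:
            res = fit_regression(binned, dv, PREDICTORS)
            X = binned.bins[PREDICTORS].to_numpy()
            y = binned.bins[dv].to_numpy()
            # standardized-beta identity
            np.testing.assert_allclose(
                res.coefficients["beta"],
                res.coefficients["B"] * X.std(axis=0, ddof=1) / y.std(ddof=1),
                atol=1e-12,
            )
            # R^2 equals squared correlation of fitted vs observed
            fitted = res.intercept + X @ res.coefficients["B"].to_numpy()
            r = np.corrcoef(fitted, y)[0, 1]
            assert res.r_squared == pytest.approx(r**2, abs=1e-10)
            assert 0 <= res.r_squared <= 1
            assert res.df_model == 4 and res.df_resid == res.n_obs - 5

    def test_f_statistic_matches_r2_formula(self, hira_pairs):
        binned = sort_and_bin(hira_pairs, 15)
        res = fit_regression(binned, "color_distance", PREDICTORS)
        k, n = res.df_model, res.n_obs
        f = (res.r_squared / k) / ((1 - res.r_squared) / (n - k - 1))
        assert res.f_statistic == pytest.approx(f)

    def test_rank_deficiency_names_columns(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 2)), columns=["a", "b"])
        df["dup"] = df["a"]
        df["y"] = rng.normal(size=15)
        with pytest.raises(ValueError, match="dup|a"):
            fit_regression(df, "y", ["a", "b", "dup"])


class TestRunSecondOrderAnalysis:
    def test_report_structure_and_bin_counts(self, palette_mod, dataset_mod):
        report = sm.run_second_order_analysis(
            dataset_mod.responses,
            palette_mod,
            dataset_mod.inventories,
            norms=dataset_mod.norms,
        )
        hira = report["scripts"]["hiragana"]
        lat = report["scripts"]["latin"]
        assert (hira["n_pairs"], hira["n_bins"], hira["bin_size"]) == (1035, 69, 15)
        assert (lat["n_pairs"], lat["n_bins"], lat["bin_size"]) == (325, 65, 5)
        assert set(hira["regressions"]) == set(MEASURES)
        assert hira["correlations"].shape == (8, 8)

    def test_strong_ordinality_data_ranks_ordinality_first(self, palette_mod):
        ds = sm.generate_dataset(
            sm.GeneratorConfig(
                w_ord=1.0, w_phon=0.0, w_shape=0.0, w_fam=0.0,
                sigma_color=5.0, sigma_retest=5.0,
                scripts=("hiragana",), n_controls=0, seed=5,
            ),
            palette=palette_mod,
        )
        report = sm.run_second_order_analysis(
            ds.responses, palette_mod, ds.inventories, norms=ds.norms,
            scripts=("hiragana",),
        )
        coef = report["scripts"]["hiragana"]["regressions"]["color_distance"].coefficients
        assert coef["beta"].abs().idxmax() == "ordinality_difference"
        assert coef.loc["ordinality_difference", "beta"] > 0

    def test_gibson_shape_measure_for_latin(self, palette_mod, dataset_mod):
        report = sm.run_second_order_analysis(
            dataset_mod.responses,
            palette_mod,
            dataset_mod.inventories,
            norms=dataset_mod.norms,
            features=sm.GibsonFeatures.load_default(),
            scripts=("latin",),
            shape_measure="gibson",
        )
        coef = report["scripts"]["latin"]["regressions"]["color_distance"].coefficients
        assert "shape_difference" in coef.index

    def test_text_report_renders(self, palette_mod, dataset_mod):
        report = sm.run_second_order_analysis(
            dataset_mod.responses, palette_mod, dataset_mod.inventories,
            norms=dataset_mod.norms, scripts=("latin",),
        )
        text = sm.format_report(report)
        assert "latin" in text and "COLOR_DISTANCE" in text
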