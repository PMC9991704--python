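"""Tertiles, correlations, group comparisons and the tertile GLM."""

import numpy as np
import pandas as pd
import pytest

from mealscope.association_stats import (age_band, assign_tertiles,
                                         compare_groups, correlate,
                                         describe_scores, tertile_glm,
                                         tertile_table)
from mealscope.diet_quality import score_population
from mealscope.synthetic_data import default_config, generate_population
from mealscope.records_model import records_frame
from mealscope.meal_classifier import classify_records
from mealscope.intake_aggregation import aggregate


def covariate_frame(rng, n):
    return pd.DataFrame({
        "sex": rng.choice(["male", "female"], n),
        "age_band": rng.choice(["<40", "40-59", ">=60"], n),
        "weight_status": rng.choice(["underweight", "normal", "overweight"],
                                    n, p=[0.1, 0.7, 0.2]),
        "reporting_status": rng.choice(["under", "plausible", "over"],
                                       n, p=[0.05, 0.9, 0.05]),
        "survey_year": rng.choice(["2003", "2013"], n),
    }, index=[f"P{i}" for i in range(n)])


class TestTertiles:
    def test_sizes_and_ordering(self, rng):
        scores = pd.Series(rng.normal(50, 8, 100),
                           index=[f"P{i}" for i in range(100)])
        t = assign_tertiles(scores)
        sizes = t["tertile"].value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert (t.loc[t.tertile == "T1", "score"].max()
                <= t.loc[t.tertile == "T2", "score"].min() + 1e-12)
        assert (t.loc[t.tertile == "T2", "score"].max()
                <= t.loc[t.tertile == "T3", "score"].min() + 1e-12)

    def test_permutation_invariance(self, rng):
        scores = pd.Series(rng.normal(50, 8, 90),
                           index=[f"P{i}" for i in range(90)])
        perm = scores.sample(frac=1, random_state=1)
        a = assign_tertiles(scores)["tertile"].sort_index()
        b = assign_tertiles(perm)["tertile"].sort_index()
        pd.testing.assert_series_equal(a, b)

    def test_summary_median_and_range(self):
        scores = pd.Series(np.arange(9, dtype=float),
                           index=[f"P{i}" for i in range(9)])
        t = assign_tertiles(scores)
        t1 = t[t.tertile == "T1"].iloc[0]
        assert (t1["median"], t1["min"], t1["max"]) == (1.0, 0.0, 2.0)


class TestDescribe:
    def test_constant_scores(self):
        idx = pd.MultiIndex.from_product([["P1", "P2", "P3"], ["total"]],
                                         names=["participant_id", "stratum"])
        scores = pd.DataFrame({"hei_total": [50.0, 50.0, 50.0]}, index=idx)
        d = describe_scores(scores).loc[("hei_total", "total")]
        assert d["sd"] == 0.0
        assert d["q25"] == d["median"] == d["q75"] == 50.0

    def test_single_participant_quartiles(self):
        idx = pd.MultiIndex.from_tuples([("P1", "total")],
                                        names=["participant_id", "stratum"])
        scores = pd.DataFrame({"hei_total": [62.0]}, index=idx)
        d = describe_scores(scores).loc[("hei_total", "total")]
        assert d["q25"] == d["median"] == d["q75"] == 62.0


class TestCorrelate:
    def test_self_correlation_is_one(self, rng):
        wide = pd.DataFrame(rng.normal(size=(50, 2)), columns=["total", "dinner"])
        corr = correlate(wide)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_strata_under_null_config(self, table):
        """With person-level variation off, meal-type scores are independent
        across people, so between-meal correlations sit near zero."""
        cfg = default_config(n_participants=150, seed=9)
        cfg.person_level_variation = False
        participants, lines = generate_population(cfg, table)
        records = records_frame(lines)
        _, labels = classify_records(records, table)
        intakes = aggregate(records, labels, table,
                            [p.id for p in participants], cfg.n_days)
        scores = score_population(intakes, participants)
        wide = scores["hei_total"].unstack("stratum")
        corr = correlate(wide[["breakfast", "lunch", "dinner"]])
        off_diag = corr.to_numpy()[np.triu_indices(3, 1)]
        assert np.all(np.abs(off_diag) < 0.2)

    def test_meal_vs_total_positive_by_construction(self, pop600):
        scores = score_population(pop600["intakes"], pop600["participants"])
        wide = scores["hei_total"].unstack("stratum")
        corr = correlate(wide)
        for meal in ("breakfast", "lunch", "dinner", "snacks"):
            assert corr.loc["total", meal] > 0.15

    def test_quality_ordering_dinner_above_snacks(self, pop600):
        scores = score_population(pop600["intakes"], pop600["participants"])
        means = scores["hei_total"].groupby(level="stratum", observed=True).mean()
        assert means["dinner"] > means["snacks"]
        nrf = scores["nrf_total"].groupby(level="stratum", observed=True).mean()
        assert nrf["dinner"] > nrf["snacks"]


class TestCompareGroups:
    def test_identical_groups_t_zero_p_one(self):
        vals = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = pd.Series(["a", "a", "a", "b", "b", "b"])
        res = compare_groups(vals, groups)
        assert res["test"] == "t"
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_anova_with_separated_group_gets_letters(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 1, 50),
                               rng.normal(5, 1, 50)])
        groups = np.repeat(["a", "b", "c"], 50)
        res = compare_groups(pd.Series(vals), pd.Series(groups))
        assert res["test"] == "anova" and res["p_value"] < 0.05
        letters = res["letters"]
        assert letters["a"] == letters["b"]
        assert set(letters["c"]) & set(letters["a"]) == set()

    def test_no_letters_when_overall_p_large(self, rng):
        vals = rng.normal(0, 1, 150)
        groups = np.repeat(["a", "b", "c"], 50)
        res = compare_groups(pd.Series(vals), pd.Series(groups))
        if res["p_value"] >= 0.05:
            assert res["letters"] is None

    def test_small_group_skipped_with_warning(self, caplog):
        vals = pd.Series([1.0, 2.0, 3.0, 9.0])
        groups = pd.Series(["a", "a", "a", "b"])
        with caplog.at_level("WARNING"):
            res = compare_groups(vals, groups)
        assert res["levels"] == ["a"]
        assert "skipped" in caplog.text


class TestTertileGLM:
    def test_no_covariates_reduces_to_raw_means(self, rng):
        n = 90
        df = pd.DataFrame({"y": rng.normal(10, 2, n)})
        df["tertile"] = assign_tertiles(pd.Series(rng.normal(size=n),
                                                  index=df.index))["tertile"]
        res = tertile_glm(df, "y", covariates=())
        raw = df.groupby("tertile")["y"].mean()
        for t in ("T1", "T2", "T3"):
            assert res.adjusted_means[t] == pytest.approx(raw[t], abs=1e-9)

    def test_balanced_design_matches_raw_means(self, rng):
        """With covariates orthogonal to the tertile, adjustment changes
        nothing."""
        n = 240
        df = covariate_frame(rng, n)
        df["tertile"] = np.tile(["T1", "T2", "T3"], n // 3)
        df["sex"] = np.repeat(["male", "female"], n // 2)  # orthogonal by tiling
        df["y"] = rng.normal(10, 2, n)
        res = tertile_glm(df, "y")
        raw = df.groupby("tertile")["y"].mean()
        # orthogonality is approximate for the random covariates; sex is exact
        res0 = tertile_glm(df, "y", covariates=("sex",))
        for t in ("T1", "T2", "T3"):
            assert res0.adjusted_means[t] == pytest.approx(raw[t], abs=1e-9)

    def test_planted_effect_recovered(self, rng):
        n = 300
        df = covariate_frame(rng, n)
        score = pd.Series(rng.normal(size=n), index=df.index)
        df["tertile"] = assign_tertiles(score)["tertile"]
        t_num = df["tertile"].map({"T1": 1, "T2": 2, "T3": 3})
        df["y"] = 2.0 * t_num + rng.normal(0, 1, n)
        res = tertile_glm(df, "y")
        assert res.trend_slope == pytest.approx(2.0, abs=0.3)
        assert res.trend_p < 1e-3
        spacing = (res.adjusted_means["T3"] - res.adjusted_means["T1"]) / 2
        assert spacing == pytest.approx(2.0, abs=0.4)

    def test_type_one_error_of_trend_test(self):
        """Under the null the trend test rejects at ~5 % (2000 simulations)."""
        rng = np.random.default_rng(1234)
        n, reps, hits = 60, 2000, 0
        for _ in range(reps):
            df = covariate_frame(rng, n)
            df["tertile"] = assign_tertiles(
                pd.Series(rng.normal(size=n), index=df.index))["tertile"]
            df["y"] = rng.normal(size=n)
            if tertile_glm(df, "y").trend_p < 0.05:
                hits += 1
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_unobserved_covariate_level_dropped(self, rng):
        n = 90
        df = covariate_frame(rng, n)
        df["reporting_status"] = "plausible"
        full = covariate_frame(rng, n + 1)
        df = pd.concat([df])
        df["tertile"] = np.tile(["T1", "T2", "T3"], n // 3)
        df["y"] = rng.normal(size=n)
        res = tertile_glm(df, "y")
        assert np.isfinite(res.trend_p)

    def test_tertile_table_layout(self, rng):
        n = 120
        df = covariate_frame(rng, n)
        df["tertile"] = np.tile(["T1", "T2", "T3"], n // 3)
        df["a"] = rng.normal(size=n)
        df["b"] = rng.normal(size=n)
        tab = tertile_table(df, ["a", "b"])
        assert list(tab.index) == ["a", "b"]
        assert {"T1", "T2", "T3", "trend_p"} <= set(tab.columns)


def test_age_band_edges():
    assert age_band(39) == "<40"
    assert age_band(40) == "40-59"
    assert age_band(59) == "40-59"
    assert age_band(60) == ">=60"
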