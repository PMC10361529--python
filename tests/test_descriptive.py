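"""Baseline-relative descriptive series and their exact identities."""

import numpy as np
import pandas as pd
import pytest

from odmobility import (
    SimConfig,
    city_covariate_correlation,
    generate_city,
    income_ratio_series,
    relative_mobility,
    simulate_decline_panel,
    stratified_series,
)
from odmobility.io_prep import TripPanel, ValidationError

from conftest import make_weekly_panel

BASELINE = {1, 2, 3, 4}


class TestRelativeMobility:
    def test_simple_arithmetic(self):
        records = [("A", "B", "18-34", w, 100) for w in range(1, 5)]
        records += [("A", "B", "18-34", 7, 74)]
        series = relative_mobility(make_weekly_panel(records), BASELINE)
        assert series[7] == pytest.approx(0.74, abs=1e-15)

    def test_constant_panel_is_identically_one(self):
        records = [("A", "B", "18-34", w, 250) for w in range(1, 10)]
        series = relative_mobility(make_weekly_panel(records), BASELINE)
        np.testing.assert_allclose(series.to_numpy(), 1.0, rtol=1e-14)

    def test_baseline_weeks_average_to_exactly_one(self, city8):
        _, panel, _ = city8
        series = relative_mobility(panel, BASELINE)
        assert abs(series[sorted(BASELINE)].mean() - 1.0) < 1e-12

    def test_invariant_under_count_rescaling(self, city8):
        _, panel, _ = city8
        s1 = relative_mobility(panel, BASELINE)
        df = panel.df.copy()
        df["count"] *= 13.0
        scaled = TripPanel(df=df, resolution="weekly", censor_threshold=0)
        s2 = relative_mobility(scaled, BASELINE)
        # censored cells are imputed at threshold/2 which does not rescale,
        # so compare on an uncensored view
        uncens = TripPanel(
            df=panel.df[~panel.df["censored"]].copy(),
            resolution="weekly", censor_threshold=0,
        )
        u1 = relative_mobility(uncens, BASELINE)
        df2 = uncens.df.copy()
        df2["count"] *= 13.0
        u2 = relative_mobility(
            TripPanel(df=df2, resolution="weekly", censor_threshold=0), BASELINE
        )
        np.testing.assert_allclose(u1.to_numpy(), u2.to_numpy(), rtol=1e-12)

    def test_zero_baseline_raises(self):
        records = [("A", "B", "18-34", w, 0) for w in range(1, 5)]
        with pytest.raises(ValidationError):
            relative_mobility(make_weekly_panel(records), BASELINE)

    def test_mean_mode_series_matches_trip_weighted_decline(self, city8_mean):
        # in mean mode the all-trips series equals the trip-weighted mean of
        # the per-direction decline fractions, recomputed here from truth
        _, panel, truth = city8_mean
        series = relative_mobility(panel, BASELINE)
        mu = truth["expected"]
        df = panel.df
        for week in (5, 7, 9):
            m = df["week"] == week
            mb = df["week"] == 1  # baseline weeks all equal in mean mode
            expected = mu[m.to_numpy()].sum() / mu[mb.to_numpy()].sum()
            assert series[week] == pytest.approx(expected, rel=1e-12)


class TestIncomeRatio:
    def test_identical_declines_give_unit_ratio(self, tiny_ziptable):
        records = []
        for w, f in [(1, 1.0), (2, 1.0), (3, 1.0), (4, 1.0), (5, 0.8)]:
            records += [
                ("A", "B", "18-34", w, 100 * f),  # A, B: low income props
                ("D", "C", "18-34", w, 200 * f),  # D, C: high income props
            ]
        ratio = income_ratio_series(make_weekly_panel(records), tiny_ziptable, BASELINE)
        np.testing.assert_allclose(ratio.to_numpy(), 1.0, rtol=1e-14)

    def test_hand_example(self, tiny_ziptable):
        # above-median group falls to 0.8 of baseline, below-median stays at 1
        records = []
        for w in range(1, 5):
            records += [("A", "B", "18-34", w, 100), ("D", "C", "18-34", w, 200)]
        records += [("A", "B", "18-34", 5, 100), ("D", "C", "18-34", 5, 160)]
        ratio = income_ratio_series(make_weekly_panel(records), tiny_ziptable, BASELINE)
        assert ratio[5] == pytest.approx(0.8, abs=1e-14)

    def test_antisymmetric_under_group_swap(self, city8):
        zt, panel, _ = city8
        prop = zt.df["prop_higher_income"]
        med = float(prop.median())
        above = set(prop.index[prop > med])
        below = set(prop.index[prop <= med])
        r1 = income_ratio_series(panel, zt, BASELINE, groups=(above, below))
        r2 = income_ratio_series(panel, zt, BASELINE, groups=(below, above))
        np.testing.assert_allclose(r1.to_numpy() * r2.to_numpy(), 1.0, rtol=1e-12)

    def test_positive_income_effect_drives_ratio_below_one(self):
        # generative truth: higher-income zips decline faster (beta_inc > 0,
        # all other effects zero so the income signal is isolated)
        cfg = SimConfig(
            n_zips=20, seed=5, censor_threshold=0,
            beta={"prop_higher_income": 0.4}, beta_a=(0.0, 0.0, 0.0),
        )
        zt = generate_city(cfg)
        panel, _ = simulate_decline_panel(zt, cfg, mode="mean")
        ratio = income_ratio_series(panel, zt, BASELINE)
        assert (ratio[[7, 8, 9]] < 1.0).all()


class TestStratifiedSeries:
    def test_proportional_age_panels_give_identical_series(self):
        records = []
        for w, f in [(1, 1.0), (2, 1.0), (3, 1.0), (4, 1.0), (5, 0.6), (6, 0.5)]:
            records += [
                ("A", "B", "18-34", w, 300 * f),
                ("A", "B", "55+", w, 120 * f),
            ]
        out = stratified_series(make_weekly_panel(records), "age", BASELINE)
        np.testing.assert_allclose(
            out["18-34"].to_numpy(), out["55+"].to_numpy(), rtol=1e-14
        )

    def test_strata_aggregate_back_to_total_with_baseline_shares(self, city8):
        _, panel, _ = city8
        total = relative_mobility(panel, BASELINE)
        per_age = stratified_series(panel, "age", BASELINE)
        # baseline share of each stratum, from the same midpoint-imputed totals
        df = panel.df.copy()
        df["count"] = df["count"].fillna(panel.censor_threshold / 2.0)
        base = df[df["week"].isin(BASELINE)]
        shares = base.groupby("age_group")["count"].sum() / base["count"].sum()
        recomposed = sum(per_age[a] * shares[a] for a in per_age)
        np.testing.assert_allclose(recomposed.to_numpy(), total.to_numpy(), rtol=1e-12)

    def test_fully_censored_stratum_week_omitted_under_drop_policy(self):
        records = [("A", "B", "18-34", w, 100) for w in range(1, 6)]
        records += [("A", "B", "55+", w, 100) for w in range(1, 5)]
        records += [("A", "B", "55+", 5, None)]
        out = stratified_series(
            make_weekly_panel(records), "age", BASELINE, censored_policy="drop"
        )
        assert 5 in out["18-34"].index
        assert 5 not in out["55+"].index


class TestCityCorrelation:
    def test_perfect_linear_relationships(self):
        x = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        assert city_covariate_correlation(2 * x, x) == pytest.approx(1.0)
        assert city_covariate_correlation(-x, x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(7)
        cities = [f"c{i}" for i in range(10)]
        x = pd.Series(rng.normal(size=10), index=cities)
        y = pd.Series(rng.normal(size=10), index=cities)
        r = city_covariate_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        manual = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_returns_nan_with_warning(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.warns(UserWarning):
            assert np.isnan(city_covariate_correlation(x, y))

    def test_fewer_than_three_cities_raises(self):
        x = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValidationError):
            city_covariate_correlation(x, x)
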