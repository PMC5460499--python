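"""Interval grid, person-time splitting, Poisson fits and risk curves."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st

from fracture_excess.mortality import (
    aggregate_cells,
    aggregate_curves,
    build_grid,
    crude_risk_curves,
    fit_adjusted,
    fit_crude,
    rates_to_risk,
    split_person_time,
    standardize,
)


def follow_up_frame(durations, events, arm="case", **extra):
    n = len(durations)
    base = dict(
        person_id=[f"s{i}" for i in range(n)],
        arm=arm if isinstance(arm, list) else [arm] * n,
        matched_set_id=[f"m{i}" for i in range(n)],
        sex=["female"] * n,
        birth_year=[1930] * n,
        age_at_index=[78] * n,
        cci_score=[0] * n,
        duration_months=durations,
        event=events,
    )
    base.update(extra)
    return pd.DataFrame(base)


class TestGrid:
    def test_default_grid_enumerates_the_stated_cut_points(self):
        expected = (
            [0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
            + [4, 5, 6, 7, 8, 9, 10, 11, 12]
            + [15, 18, 21, 24]
            + [30, 36, 42, 48]
            + [60, 72, 84, 96, 108, 120]
        )
        grid = build_grid()
        assert grid[0] == 0.5 and grid[-1] == 120
        np.testing.assert_allclose(grid, expected)

    def test_non_monotone_custom_grid_rejected(self):
        with pytest.raises(ValueError):
            build_grid(custom=[12, 6])
        with pytest.raises(ValueError):
            build_grid(custom=[0, 6])


class TestSplit:
    def test_early_death_all_time_in_first_interval(self):
        grid = build_grid()
        rows = split_person_time(follow_up_frame([0.25], ["death"]), grid)
        assert len(rows) == 1
        assert rows.iloc[0]["interval"] == 0
        assert rows.iloc[0]["time"] == pytest.approx(0.25)
        assert bool(rows.iloc[0]["death"])

    def test_full_survivor_time_sums_to_grid_end(self):
        grid = build_grid()
        rows = split_person_time(follow_up_frame([120.0], ["censored"]), grid)
        assert rows["time"].sum() == pytest.approx(120.0)
        assert not rows["death"].any()

    def test_death_at_2_2_months_hand_computed(self):
        grid = build_grid()
        rows = split_person_time(follow_up_frame([2.2], ["death"]), grid)
        np.testing.assert_allclose(rows["time"], [0.5, 0.5, 0.5, 0.5, 0.2])
        assert list(rows["interval"]) == [0, 1, 2, 3, 4]
        assert list(rows["death"]) == [False, False, False, False, True]

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 140.0), min_size=1, max_size=40),
           st.integers(0, 2**31 - 1))
    def test_person_time_conservation(self, durations, seed):
        """Total split person-time equals total (grid-truncated) duration."""
        grid = build_grid()
        rng = np.random.default_rng(seed)
        events = ["death" if rng.random() < 0.5 else "censored"
                  for _ in durations]
        rows = split_person_time(follow_up_frame(durations, events), grid)
        expected = np.minimum(durations, 120.0).sum()
        assert rows["time"].sum() == pytest.approx(expected, abs=1e-9)
        per_subject = rows.groupby("person_id")["time"].sum()
        for pid, dur in zip([f"s{i}" for i in range(len(durations))], durations):
            assert per_subject[pid] == pytest.approx(min(dur, 120.0), abs=1e-9)


class TestCrude:
    def test_closed_form_rates(self):
        grid = np.array([6.0, 12.0])
        cells = pd.DataFrame({
            "arm": ["case", "case", "reference", "reference"],
            "interval": [0, 1, 0, 1],
            "deaths": [2, 0, 5, 1],
            "person_months": [100.0, 50.0, 400.0, 300.0],
        })
        rates = fit_crude(cells, grid)
        lookup = rates.set_index(["arm", "interval"])["rate"]
        assert lookup[("case", 0)] == pytest.approx(0.02)
        assert lookup[("case", 1)] == 0.0
        assert lookup[("reference", 1)] == pytest.approx(1 / 300)

    def test_closed_form_equals_iterative_glm(self):
        """The saturated arm x interval model has the cell-mean solution."""
        grid = np.array([6.0, 12.0])
        cells = pd.DataFrame({
            "arm": ["case", "case", "reference", "reference"],
            "interval": [0, 1, 0, 1],
            "deaths": [7, 3, 11, 6],
            "person_months": [130.0, 55.0, 410.0, 290.0],
        })
        closed = fit_crude(cells, grid).set_index(["arm", "interval"])["rate"]
        glm = smf.glm(
            "deaths ~ C(arm) * C(interval)", data=cells,
            family=sm.families.Poisson(),
            offset=np.log(cells["person_months"]),
        ).fit()
        fitted_rates = glm.predict(cells, offset=np.zeros(len(cells)))
        for (_, row), fitted in zip(cells.iterrows(), fitted_rates):
            assert closed[(row["arm"], row["interval"])] == pytest.approx(
                fitted, abs=1e-8)


class TestRiskChaining:
    def test_constant_rate_telescopes_to_exponential(self):
        grid = build_grid()
        lam = 0.013
        risk = rates_to_risk(np.full(len(grid), lam), grid)
        np.testing.assert_allclose(risk, 1 - np.exp(-lam * grid), atol=1e-12)

    def test_zero_rates_zero_risk(self):
        grid = build_grid()
        assert rates_to_risk(np.zeros(len(grid)), grid).max() == 0.0

    def test_single_interval_probability_value(self):
        # lambda = 0.01/month over a half-month interval
        risk = rates_to_risk(np.array([0.01]), np.array([0.5]))
        assert risk[0] == pytest.approx(1 - np.exp(-0.005), abs=1e-15)
        assert risk[0] == pytest.approx(0.00498752, abs=1e-8)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rates_to_risk(np.array([-0.1]), np.array([1.0]))

    def test_risk_curve_invariant_to_subdividing_constant_rate(self):
        coarse = np.array([6.0, 12.0, 24.0])
        fine = np.array([3.0, 6.0, 9.0, 12.0, 18.0, 24.0])
        lam = 0.02
        r_coarse = rates_to_risk(np.full(3, lam), coarse)
        r_fine = rates_to_risk(np.full(6, lam), fine)
        np.testing.assert_allclose(r_fine[[1, 3, 5]], r_coarse, atol=1e-12)

    def test_curves_non_decreasing_and_bounded(self):
        grid = build_grid()
        rng = np.random.default_rng(7)
        rates = rng.exponential(0.01, len(grid))
        risk = rates_to_risk(rates, grid)
        assert (np.diff(risk) >= 0).all()
        assert risk.min() >= 0 and risk.max() <= 1


class TestAdjusted:
    @staticmethod
    def _simulated_rows(seed=0, n=3000, rr=1.0):
        """Constant-hazard two-arm cohort on a coarse grid."""
        rng = np.random.default_rng(seed)
        lam = 0.02  # per month
        arm = np.where(rng.random(n) < 0.3, "case", "reference")
        lam_i = np.where(arm == "case", lam * rr, lam)
        t = rng.exponential(1 / lam_i)
        cens = 36.0
        dur = np.minimum(t, cens)
        events = np.where(t <= cens, "death", "censored")
        fu = follow_up_frame(list(dur), list(events), arm=list(arm))
        fu["age_at_index"] = rng.integers(70, 90, n)
        fu["cci_score"] = rng.integers(0, 4, n)
        grid = np.array([3.0, 6.0, 12.0, 24.0, 36.0])
        return split_person_time(fu, grid), grid

    def test_constant_rate_ratio_recovered_in_main_effect(self):
        rows, grid = self._simulated_rows(seed=1, rr=2.0)
        model = fit_adjusted(rows, grid=grid)
        est = model.params["fx"]
        se = model.result.bse["fx"]
        assert abs(est - np.log(2.0)) < 3 * se

    def test_null_effect_fracture_terms_near_zero(self):
        rows, grid = self._simulated_rows(seed=2, rr=1.0)
        model = fit_adjusted(rows, grid=grid)
        for term in model.params.index:
            if "fx" in term:
                assert abs(model.params[term]) < 3 * model.result.bse[term], term

    def test_standardized_matches_crude_when_covariates_are_null(self):
        rows, grid = self._simulated_rows(seed=3, rr=1.5)
        model = fit_adjusted(rows, grid=grid)
        std_pop = rows[rows["arm"] == "case"].drop_duplicates("person_id")[
            ["age_at_index", "cci_score"]]
        adj = standardize(model, std_pop, grid)
        crude = crude_risk_curves(aggregate_cells(rows), grid)
        for armname in ("case", "reference"):
            np.testing.assert_allclose(adj[armname], crude[armname], atol=0.02)

    def test_single_pattern_population_returns_that_pattern(self):
        rows, grid = self._simulated_rows(seed=4, rr=1.0)
        model = fit_adjusted(rows, grid=grid)
        pop = pd.DataFrame({"age_at_index": [80], "cci_score": [1]})
        curves = standardize(model, pop, grid)
        rates = model.predict_rates(pop, fx=1)[0]
        width = np.diff(np.concatenate([[0.0], grid]))
        expected = 1 - np.exp(-np.cumsum(rates * width))
        np.testing.assert_allclose(curves["case"], expected, atol=1e-10)


class TestAggregation:
    def test_identical_curves_unchanged(self):
        c = np.array([0.1, 0.2, 0.3])
        np.testing.assert_allclose(aggregate_curves([c, c], [3, 1]), c)

    def test_weighted_mean_arithmetic(self):
        a, b = np.array([0.2]), np.array([0.4])
        assert aggregate_curves([a, b], [3, 1])[0] == pytest.approx(0.25)

    def test_sex_weights_from_case_counts(self):
        # weighting two sex-specific curves by case-group sizes
        men, women = 2383, 5915
        a, b = np.array([0.0]), np.array([1.0])
        agg = aggregate_curves([a, b], [men, women])
        assert agg[0] == pytest.approx(women / (men + women))
        assert agg[0] == pytest.approx(0.7128, abs=5e-5)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            aggregate_curves([np.array([0.1]), np.array([0.1, 0.2])], [1, 1])
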