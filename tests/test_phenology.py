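"""Degree-day accumulation, voltinism mapping and the reduction policy."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ragweed.phenology import (
    CohortRecord,
    DailyTemperatureSeries,
    ReductionPolicy,
    VoltinismParams,
    empirical_reduction_curve,
    estimate_generation_gdd,
    gdd_accumulate,
    generations,
    generations_grid,
    prepost_mean_drop,
    reduction_grid,
)

from conftest import make_grid


def constant_series(site, mean_temp, n_days, start=dt.date(2016, 6, 1), diurnal=0.0):
    dates = [start + dt.timedelta(days=d) for d in range(n_days)]
    t = np.full(n_days, mean_temp)
    return DailyTemperatureSeries(site, dates, t - diurnal / 2, t + diurnal / 2)


class TestGDD:
    def test_at_threshold_accumulates_nothing(self):
        s = constant_series("s", 13.3, 10)
        assert gdd_accumulate(s) == 0.0

    def test_ten_days_ten_degrees_above(self):
        s = constant_series("s", 23.3, 10)
        assert gdd_accumulate(s) == pytest.approx(100.0, abs=1e-9)

    def test_sinusoidal_matches_daily_loop(self):
        start = dt.date(2016, 6, 1)
        dates = [start + dt.timedelta(days=d) for d in range(30)]
        mean = 15.0 + 8.0 * np.sin(np.arange(30) / 5.0)
        s = DailyTemperatureSeries("s", dates, mean - 4, mean + 4)
        expected = sum(max(0.0, m - 13.3) for m in mean)
        assert gdd_accumulate(s) == pytest.approx(expected, rel=1e-12)

    def test_additive_over_adjacent_windows(self):
        s = constant_series("s", 20.0, 20)
        mid = s.dates[9]
        first = gdd_accumulate(s, window=(s.dates[0], mid))
        second = gdd_accumulate(s, window=(s.dates[10], s.dates[-1]))
        assert first + second == pytest.approx(gdd_accumulate(s))

    def test_window_outside_series_rejected(self):
        s = constant_series("s", 20.0, 5)
        with pytest.raises(ValueError, match="outside series"):
            gdd_accumulate(s, window=(s.dates[0] - dt.timedelta(days=1), s.dates[-1]))

    @given(st.floats(min_value=-5, max_value=25), st.floats(min_value=0, max_value=10))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_temperature(self, mean, bump):
        base = gdd_accumulate(constant_series("s", mean, 10))
        warmer = gdd_accumulate(constant_series("s", mean + bump, 10))
        assert warmer >= base


class TestGenerations:
    @pytest.mark.parametrize(
        "gdd,expected", [(288.6, 0), (288.7, 1), (866.1, 3), (0.0, 0), (2000.0, 6)]
    )
    def test_floor_semantics(self, gdd, expected):
        assert generations(gdd) == expected

    def test_matches_repeated_subtraction_oracle(self, rng):
        for g in rng.uniform(0, 3000, size=50):
            n, left = 0, float(g)
            while left >= 288.7:
                left -= 288.7
                n += 1
            assert generations(g) == n

    def test_nondecreasing_and_bounded(self, rng):
        gs = np.sort(rng.uniform(0, 3000, size=20))
        ns = [generations(g) for g in gs]
        assert all(b >= a for a, b in zip(ns, ns[1:]))
        assert all(n * 288.7 <= g for n, g in zip(ns, gs))


class TestGenerationGDD:
    def test_constructed_exact_case(self):
        # 20 days at 14.435 degC above base: 20 * 14.435 = 288.7 exactly
        s = constant_series("s", 13.3 + 14.435, 30)
        cohort = CohortRecord("s", s.dates[0], s.dates[19])
        got = estimate_generation_gdd([cohort], {"s": s})
        assert got == pytest.approx(288.7, abs=1e-9)

    def test_mean_of_identical_cohorts_unchanged(self):
        s = constant_series("s", 20.0, 30)
        c = CohortRecord("s", s.dates[0], s.dates[10])
        one = estimate_generation_gdd([c], {"s": s})
        two = estimate_generation_gdd([c, c], {"s": s})
        assert one == two

    def test_missing_series_names_site(self):
        s = constant_series("s", 20.0, 30)
        c = CohortRecord("elsewhere", s.dates[0], s.dates[10])
        with pytest.raises(ValueError, match="elsewhere"):
            estimate_generation_gdd([c], {"s": s})

    def test_cohort_ladder_recovers_truth_within_2pct(self):
        from ragweed.synthetic import SyntheticConfig, gen_cohorts, gen_daily_temps

        estimates = []
        for seed in range(50):
            cfg = SyntheticConfig(seed=seed)
            temps = gen_daily_temps(cfg)
            cohorts = gen_cohorts(cfg, temps)
            estimates.append(estimate_generation_gdd(cohorts, temps, cfg.voltinism))
        assert abs(np.mean(estimates) / 288.7 - 1.0) < 0.02


def daily_frame(values, year=2008, stations=("a",)):
    rows = []
    start = dt.date(year, 7, 7)
    for s in stations:
        for d, v in enumerate(values):
            rows.append({"station": s, "date": start + dt.timedelta(days=d),
                         "concentration": float(v)})
    return pd.DataFrame(rows)


class TestPrePost:
    def test_identical_series_no_reduction(self):
        pre = daily_frame([5, 10, 20])
        _, _, r = prepost_mean_drop(pre, daily_frame([5, 10, 20], year=2016))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_zero_post_full_reduction(self):
        _, _, r = prepost_mean_drop(daily_frame([5, 10]), daily_frame([0, 0], year=2016))
        assert r == 1.0

    def test_printed_means_give_expected_fraction(self):
        # station means 46.2 and 7.5 reproduce the observed ~83.8% drop
        pre = daily_frame([46.2, 46.2])
        post = daily_frame([7.5, 7.5], year=2016)
        pre_mean, post_mean, r = prepost_mean_drop(pre, post)
        assert (pre_mean, post_mean) == (46.2, 7.5)
        assert r == pytest.approx(1 - 7.5 / 46.2, abs=1e-12)
        assert r == pytest.approx(0.8377, abs=5e-5)

    def test_zero_pre_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            prepost_mean_drop(daily_frame([0, 0]), daily_frame([1, 1], year=2016))


class TestReductionCurve:
    def test_halved_post_gives_flat_half_curve(self):
        pre = daily_frame([10, 20, 30, 40])
        post = daily_frame([5, 10, 15, 20], year=2016)
        curve = empirical_reduction_curve(pre, post)
        np.testing.assert_allclose(curve["reduction"], 0.5, atol=1e-12)

    def test_zero_post_gives_flat_unit_curve(self):
        pre = daily_frame([10, 20, 30])
        post = daily_frame([0, 0, 0], year=2016)
        np.testing.assert_allclose(
            empirical_reduction_curve(pre, post)["reduction"], 1.0
        )

    def test_level_axis_is_cumulative_pre_mean(self):
        pre = daily_frame([10, 20, 30])
        post = daily_frame([1, 2, 3], year=2016)
        curve = empirical_reduction_curve(pre, post)
        np.testing.assert_allclose(curve["level"], [10, 30, 60])

    def test_synthetic_taper_recovered(self):
        from dataclasses import replace
        from ragweed.synthetic import SyntheticConfig, gen_prepost_pollen

        noiseless = SyntheticConfig(seed=1, prepost_noise_sigma_log=1e-9)
        pre, post = gen_prepost_pollen(noiseless)
        curve = empirical_reduction_curve(pre, post)
        diffs = np.diff(curve["reduction"])
        assert np.all(diffs <= 1e-9)  # monotone decreasing without noise
        pre, post = gen_prepost_pollen(SyntheticConfig(seed=1))
        endpoint = empirical_reduction_curve(pre, post)["reduction"].iloc[-1]
        assert abs(endpoint - 0.837) < 0.02


class TestReductionGrid:
    def masks(self, spec3, value=1.0):
        return make_grid(spec3, np.full((3, 3), value))

    def test_three_generations_everywhere(self, spec3):
        gens = make_grid(spec3, np.full((3, 3), 5.0))
        out = reduction_grid(gens, ReductionPolicy(), self.masks(spec3), self.masks(spec3))
        np.testing.assert_array_equal(out.values, 0.86)

    def test_two_generations_inside_masks_only(self, spec3):
        gens = make_grid(spec3, np.full((3, 3), 2.0))
        beetle = make_grid(spec3, [[1, 1, 1], [0, 0, 0], [1, 1, 1]])
        out = reduction_grid(gens, ReductionPolicy(), beetle, self.masks(spec3))
        np.testing.assert_array_equal(out.values[0], 0.30)
        np.testing.assert_array_equal(out.values[1], 0.0)

    def test_mixed_grid_hand_enumerated(self, spec4):
        gens = make_grid(spec4, [[0, 1, 2, 3], [4, 0, 1, 2], [3, 4, 0, 1], [2, 3, 4, 0]])
        beetle = make_grid(spec4, np.ones((4, 4)))
        plant = make_grid(spec4, [[1, 1, 1, 1], [1, 1, 1, 1], [1, 1, 1, 1], [0, 0, 0, 0]])
        out = reduction_grid(gens, ReductionPolicy(), beetle, plant)
        expected = np.array(
            [
                [0.0, 0.30, 0.30, 0.86],
                [0.86, 0.0, 0.30, 0.30],
                [0.86, 0.86, 0.0, 0.30],
                [0.0, 0.0, 0.0, 0.0],
            ]
        )
        np.testing.assert_array_equal(out.values, expected)

    def test_values_restricted_to_policy_levels(self, spec4, rng):
        gens = make_grid(spec4, rng.integers(0, 6, size=(4, 4)).astype(float))
        beetle = make_grid(spec4, rng.integers(0, 2, size=(4, 4)).astype(float))
        plant = make_grid(spec4, rng.integers(0, 2, size=(4, 4)).astype(float))
        out = reduction_grid(gens, ReductionPolicy(), beetle, plant)
        assert set(np.unique(out.values)) <= {0.0, 0.30, 0.86}

    def test_generations_grid_floor(self, spec3):
        gdd = make_grid(spec3, np.full((3, 3), 866.1))
        out = generations_grid(gdd, VoltinismParams())
        np.testing.assert_array_equal(out.values, 3.0)

    def test_policy_must_be_monotone(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            ReductionPolicy(three_plus=0.2, one_or_two=0.5)
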