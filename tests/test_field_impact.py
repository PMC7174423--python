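"""Allometric raceme estimation and the hurdle mixed model."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ragweed.field_impact import (
    AllometryModel,
    AllometryResults,
    AllometrySample,
    HurdleModel,
    PlotRecord,
    Treatment,
    percent_production_reduction,
    plot_raceme_density,
)
from ragweed.glmm import RandomInterceptGLMM


class TestAllometry:
    def test_exact_line_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = AllometryModel(
            AllometrySample("s", Treatment.CONTROL, x, 2 * x + 1)
        ).fit()
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)
        assert fit.beta == pytest.approx(2.0, abs=1e-12)

    def test_constant_response_gives_zero_slope(self):
        x = np.array([1.0, 2.0, 3.0])
        fit = AllometryModel(
            AllometrySample("s", Treatment.CONTROL, x, np.full(3, 4.2))
        ).fit()
        assert fit.beta == pytest.approx(0.0, abs=1e-12)
        assert fit.alpha == pytest.approx(4.2, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        x = rng.normal(6.0, 0.8, size=21)
        y = 1.2 + 0.9 * x + rng.normal(0, 0.25, size=21)
        fit = AllometryModel(AllometrySample("s", Treatment.CONTROL, x, y)).fit()
        # closed-form normal equations
        xc = x - x.mean()
        beta = float((xc * (y - y.mean())).sum() / (xc**2).sum())
        alpha = float(y.mean() - beta * x.mean())
        assert fit.beta == pytest.approx(beta, rel=1e-10)
        assert fit.alpha == pytest.approx(alpha, rel=1e-10)

    def test_degenerate_volumes_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            AllometryModel(
                AllometrySample("s", Treatment.CONTROL, [1.0, 1.0], [2.0, 3.0])
            )


class TestPlotRacemeDensity:
    FIT = AllometryResults(alpha=0.0, beta=1.0, site="s", treatment=Treatment.CONTROL)

    def test_empty_plot_is_zero(self):
        rec = PlotRecord("p", "s", Treatment.CONTROL, 0, 0.5, 1.0)
        assert plot_raceme_density(rec, self.FIT) == 0.0

    def test_unit_exponent_hand_case(self):
        # n=10, m=0.5, v=0, alpha=0, beta=1 -> r=5, density 20 on a 0.25 m^2 plot
        rec = PlotRecord("p", "s", Treatment.CONTROL, 10, 0.5, 0.0)
        assert plot_raceme_density(rec, self.FIT) == pytest.approx(20.0)

    def test_formula_matches_direct_evaluation(self):
        fit = AllometryResults(alpha=1.2, beta=0.9, site="s", treatment=Treatment.CONTROL)
        rec = PlotRecord("p", "s", Treatment.CONTROL, 23, 0.7, 6.1)
        expected = 23 * 0.7 * math.exp(6.1 * 0.9 + 1.2) / 0.25
        assert plot_raceme_density(rec, fit) == pytest.approx(expected, rel=1e-12)

    def test_missing_volume_uses_site_treatment_mean(self):
        rec = PlotRecord("p", "s", Treatment.CONTROL, 10, 0.5, None)
        with_mean = plot_raceme_density(rec, self.FIT, site_treatment_mean_v=0.0)
        assert with_mean == pytest.approx(20.0)
        with pytest.raises(ValueError, match="site-treatment mean"):
            plot_raceme_density(rec, self.FIT)

    def test_linear_in_n_and_m(self):
        r1 = plot_raceme_density(
            PlotRecord("p", "s", Treatment.CONTROL, 10, 0.4, 1.0), self.FIT
        )
        r2 = plot_raceme_density(
            PlotRecord("p", "s", Treatment.CONTROL, 20, 0.4, 1.0), self.FIT
        )
        r3 = plot_raceme_density(
            PlotRecord("p", "s", Treatment.CONTROL, 10, 0.8, 1.0), self.FIT
        )
        assert r2 == pytest.approx(2 * r1) and r3 == pytest.approx(2 * r1)


def hurdle_frame(rows):
    return pd.DataFrame(rows, columns=["site", "treatment", "density"])


class TestHurdleModel:
    def test_all_plots_producing_is_degenerate(self):
        rows = [("A", "control", 10.0), ("A", "beetle_excluded", 20.0),
                ("B", "control", 15.0), ("B", "beetle_excluded", 30.0)]
        fit = HurdleModel(hurdle_frame(rows)).fit()
        assert fit.binomial.degenerate
        assert fit.p_produce[Treatment.CONTROL] == 1.0
        assert fit.p_produce[Treatment.BEETLE_EXCLUDED] == 1.0
        assert math.isnan(fit.binomial.lrt_chi2)

    def test_variance_zero_equals_plain_glm(self, rng):
        from ragweed.synthetic import SyntheticConfig, gen_plot_data

        plots, _ = gen_plot_data(SyntheticConfig(seed=5))
        y = (plots["density"] > 0).to_numpy(float)
        X = np.column_stack(
            [np.ones(len(plots)), (plots["treatment"] == "beetle_excluded").to_numpy(float)]
        )
        mine = RandomInterceptGLMM(y, X, plots["site"], "binomial").fit(random_effect=False)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(mine.params, ref.params, atol=1e-6)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-8)

        pos = plots[plots["density"] > 0]
        counts = np.floor(pos["density"].to_numpy() + 0.5)
        Xp = np.column_stack(
            [np.ones(len(pos)), (pos["treatment"] == "beetle_excluded").to_numpy(float)]
        )
        mine_p = RandomInterceptGLMM(counts, Xp, pos["site"], "poisson").fit(random_effect=False)
        ref_p = sm.GLM(counts, Xp, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(mine_p.params, ref_p.params, atol=1e-6)

    def test_laplace_likelihood_collapses_to_glm_at_tiny_sigma(self):
        from ragweed.synthetic import SyntheticConfig, gen_plot_data

        plots, _ = gen_plot_data(SyntheticConfig(seed=7))
        y = (plots["density"] > 0).to_numpy(float)
        X = np.column_stack(
            [np.ones(len(plots)), (plots["treatment"] == "beetle_excluded").to_numpy(float)]
        )
        model = RandomInterceptGLMM(y, X, plots["site"], "binomial")
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        laplace_ll = model.loglike(np.concatenate([ref.params, [np.log(1e-8)]]))
        assert laplace_ll == pytest.approx(ref.llf, abs=1e-8)

    def test_single_site_reduces_to_fixed_effects(self):
        rows = [("A", "control", 0.0)] * 6 + [("A", "control", 120.0)] * 4 \
             + [("A", "beetle_excluded", 0.0)] * 2 + [("A", "beetle_excluded", 400.0)] * 8
        df = hurdle_frame(rows)
        df2 = df.copy()
        df2.loc[df2.index[-1], "site"] = "B"  # second site to satisfy the design check
        fit = HurdleModel(df2).fit()
        assert fit.n_plots == 20

    def test_complete_separation_flagged_not_crashed(self):
        rows = [("A", "control", 0.0)] * 7 + [("B", "control", 0.0)] * 7 \
             + [("A", "beetle_excluded", 300.0)] * 7 + [("B", "beetle_excluded", 310.0)] * 7
        fit = HurdleModel(hurdle_frame(rows)).fit()
        assert fit.binomial.boundary
        assert fit.p_produce[Treatment.CONTROL] < 0.01
        assert fit.p_produce[Treatment.BEETLE_EXCLUDED] > 0.99

    def test_recovery_of_hurdle_truth(self):
        """Shortened replicate check; the full one runs in the acceptance suite."""
        from ragweed.synthetic import SyntheticConfig, gen_plot_data

        ps, mus = [], []
        for seed in range(15):
            plots, _ = gen_plot_data(SyntheticConfig(seed=seed))
            fit = HurdleModel(plots).fit()
            ps.append([fit.p_produce[t] for t in (Treatment.CONTROL, Treatment.BEETLE_EXCLUDED)])
            mus.append([fit.mean_positive_density[t]
                        for t in (Treatment.CONTROL, Treatment.BEETLE_EXCLUDED)])
        p_mean, mu_mean = np.mean(ps, axis=0), np.mean(mus, axis=0)
        assert abs(p_mean[0] - 0.26) < 0.1 and abs(p_mean[1] - 0.84) < 0.1
        assert abs(mu_mean[0] / 260 - 1) < 0.15 and abs(mu_mean[1] / 905 - 1) < 0.15


class TestExpectedDensityAndReduction:
    def results_with(self, p_c, p_e, mu_c, mu_e):
        from ragweed.field_impact import HurdlePartFit, HurdleResults

        def part(vals):
            return HurdlePartFit(
                glmm=None,
                response_by_treatment={Treatment.CONTROL: vals[0],
                                       Treatment.BEETLE_EXCLUDED: vals[1]},
                ci_by_treatment={},
                sigma_site=0.0, loglik=0.0, lrt_chi2=0.0, lrt_pvalue=1.0,
            )

        return HurdleResults(part((p_c, p_e)), part((mu_c, mu_e)), 70, 30)

    def test_product_rule(self):
        fit = self.results_with(0.84, 0.84, 905.0, 905.0)
        assert fit.expected_density(Treatment.CONTROL) == pytest.approx(0.84 * 905)

    @pytest.mark.parametrize("p,mu,expected", [(0.0, 100.0, 0.0), (1.0, 123.4, 123.4)])
    def test_degenerate_probabilities(self, p, mu, expected):
        fit = self.results_with(p, p, mu, mu)
        assert fit.expected_density(Treatment.CONTROL) == pytest.approx(expected)

    def test_field_scale_example(self):
        # fitted 2015-scale values: p {0.26, 0.84}, positive means {260, 905}
        fit = self.results_with(0.26, 0.84, 260.0, 905.0)
        assert fit.expected_density(Treatment.BEETLE_EXCLUDED) == pytest.approx(760.2)
        assert fit.percent_reduction() == pytest.approx(
            100 * (1 - 0.26 * 260 / (0.84 * 905)), rel=1e-12
        )
        assert fit.percent_reduction() == pytest.approx(91.1, abs=0.05)

    def test_equal_expectations_no_reduction(self):
        fit = self.results_with(0.5, 0.5, 100.0, 100.0)
        assert fit.percent_reduction() == pytest.approx(0.0)

    def test_zero_control_year_contributes_100pct(self):
        # year with no control production at all, positive exclusion production
        assert percent_production_reduction([(0.0, 500.0)]) == 100.0

    def test_multi_year_average(self):
        fit2015 = self.results_with(0.26, 0.84, 260.0, 905.0)
        got = percent_production_reduction([fit2015, (0.0, 500.0)])
        assert got == pytest.approx((fit2015.percent_reduction() + 100.0) / 2)

    def test_zero_exclusion_expectation_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_production_reduction([(0.0, 0.0)])
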