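"""Gamma income model and financial-risk-protection counting."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate, stats

import tobacco_ecea as te
from tobacco_ecea.financial_risk import catastrophic_cases, poverty_cases


def gini_by_numeric_integration(shape, scale):
    """Independent oracle: G = (1/mu) * int F(x)(1-F(x)) dx."""
    d = stats.gamma(shape, scale=scale)
    mu = shape * scale
    val, _ = integrate.quad(lambda x: d.cdf(x) * d.sf(x), 0, np.inf, limit=200)
    return val / mu


@pytest.fixture(scope="module")
def deaths_averted(bundle):
    pop = te.build_population(bundle)
    beh = te.respond(bundle, te.price_shock(0.75), pop)
    curve = te.attenuation_from_params(bundle.mortality, bundle.age_groups)
    return te.deaths_averted(beh, curve, bundle.mortality, bundle.age_groups,
                             pop.smokers, pop.future_initiators).deaths_averted


class TestGammaFromGini:
    def test_gini_half_is_exponential(self):
        model = te.gamma_from_mean_gini(3039, 0.5)
        assert model.shape == pytest.approx(1.0, abs=1e-8)

    def test_round_trip_against_numeric_integration(self):
        model = te.gamma_from_mean_gini(3039, 0.43)
        assert model.mean == pytest.approx(3039, abs=1e-9 * 3039)
        assert gini_by_numeric_integration(model.shape, model.scale) == pytest.approx(
            0.43, abs=1e-6)

    def test_scale_is_mean_over_shape(self):
        model = te.gamma_from_mean_gini(3039, 0.3)
        assert model.scale == pytest.approx(3039 / model.shape)

    def test_unachievable_gini_rejected(self):
        with pytest.raises(ValueError):
            te.gamma_from_mean_gini(3039, 1.5)


class TestQuintileSampling:
    def test_draws_respect_quintile_bounds(self, income_model):
        rng = np.random.default_rng(0)
        q1 = te.sample_quintile_income(income_model, 0, 5000, rng)
        q5 = te.sample_quintile_income(income_model, 4, 5000, rng)
        assert q1.max() < 992
        assert q5.min() > 4718

    def test_middle_quintile_mean_within_support(self, income_model):
        draws = te.sample_quintile_income(income_model, 2, 100_000, 1)
        assert 1870 < draws.mean() < 2973

    def test_seeded_draws_are_reproducible(self, income_model):
        a = te.sample_quintile_income(income_model, 1, 1000, 123)
        b = te.sample_quintile_income(income_model, 1, 1000, 123)
        np.testing.assert_array_equal(a, b)


class TestCaseCounting:
    def test_income_pushed_below_line_is_counted(self):
        # US$1.90/day annualizes to 693.50
        n = poverty_cases(1.0, np.array([800.0]), 7692.88, 1.90)
        assert n == 1.0

    def test_income_already_below_line_not_counted(self):
        assert poverty_cases(1.0, np.array([500.0]), 7692.88, 1.90) == 0.0

    def test_zero_oop_no_poverty_cases(self):
        assert poverty_cases(5.0, np.array([800.0, 900.0]), 0.0, 1.90) == 0.0

    def test_zero_poverty_line_no_cases(self):
        assert poverty_cases(5.0, np.array([100.0, 800.0]), 5000.0, 0.0) == 0.0

    def test_catastrophic_threshold_boundary(self):
        assert catastrophic_cases(1.0, np.array([10_000.0]), 1001.0, 0.10) == 1.0
        assert catastrophic_cases(1.0, np.array([10_000.0]), 999.0, 0.10) == 0.0

    def test_zero_oop_no_catastrophic_cases(self):
        assert catastrophic_cases(5.0, np.array([100.0]), 0.0, 0.10) == 0.0


class TestAnalyticBackend:
    def test_catastrophic_matches_truncated_gamma_tail(self, bundle, income_model):
        # single cause, quintile I: closed-form truncated-gamma CDF oracle
        averted = np.array([1000.0, 0, 0, 0, 0])
        mort = replace(bundle.mortality,
                       cause_shares={"copd": 0.0, "stroke": 1.0,
                                     "heart": 0.0, "neoplasm": 0.0})
        out = te.analytic_frp(income_model, averted, bundle.costs, mort,
                              bundle.income)
        oop = 2197 * 0.52
        at_risk = 1000.0 * min(1.0, 0.80 * 0.79)
        d = income_model.distribution
        p = (d.cdf(min(992.0, oop / 0.10)) - d.cdf(0)) / (d.cdf(992.0) - d.cdf(0))
        assert out.catastrophic_averted[0] == pytest.approx(at_risk * p)

    def test_full_reimbursement_zeroes_both_counts(self, bundle, income_model,
                                                   deaths_averted):
        costs = replace(bundle.costs, reimbursement_fraction=1.0 - 1e-12)
        out = te.analytic_frp(income_model, deaths_averted, costs,
                              bundle.mortality, bundle.income)
        assert out.total_poverty == pytest.approx(0.0, abs=1e-3)
        assert out.total_catastrophic == pytest.approx(0.0, abs=1e-3)

    def test_degenerate_point_mass_behaves_as_indicator(self, bundle):
        # near-degenerate income distribution: everyone at ~mean income
        model = te.IncomeModel(1e6, 2000.0 / 1e6, np.array([1.0, 2.0, 3.0, 1999.0]))
        averted = np.array([0, 0, 0, 0, 1000.0])
        mort = replace(bundle.mortality,
                       cause_shares={"copd": 0.0, "stroke": 1.0,
                                     "heart": 0.0, "neoplasm": 0.0})
        costs = replace(bundle.costs,
                        quintile_utilization_multipliers=np.full(5, 1.25))
        out = te.analytic_frp(model, averted, costs, mort, bundle.income)
        # income ~2000 > 693.5; 2000 - 1142 < 693.5 is false -> no poverty
        assert out.poverty_averted[4] == pytest.approx(0.0, abs=1e-6)
        # OOP 1142 > 10% of 2000 -> every at-risk person is catastrophic
        assert out.catastrophic_averted[4] == pytest.approx(1000.0, rel=1e-6)

    def test_quintile_average_assignment_close_to_mixture(self, bundle,
                                                          income_model,
                                                          deaths_averted):
        mix = te.analytic_frp(income_model, deaths_averted, bundle.costs,
                              bundle.mortality, bundle.income)
        avg = te.analytic_frp(income_model, deaths_averted, bundle.costs,
                              bundle.mortality, bundle.income,
                              oop_assignment="quintile_average")
        assert avg.total_poverty == pytest.approx(mix.total_poverty, rel=0.35)
        assert avg.total_catastrophic == pytest.approx(mix.total_catastrophic,
                                                       rel=0.35)


class TestMonteCarloBackend:
    def test_agrees_with_analytic_within_three_se(self, bundle, income_model,
                                                  deaths_averted):
        exact = te.analytic_frp(income_model, deaths_averted, bundle.costs,
                                bundle.mortality, bundle.income)
        reps = [te.monte_carlo_frp(income_model, deaths_averted, bundle.costs,
                                   bundle.mortality, bundle.income,
                                   seed=seed, thinning=500.0)
                for seed in range(8)]
        for attr in ("total_poverty", "total_catastrophic"):
            vals = np.array([getattr(r, attr) for r in reps])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - getattr(exact, attr)) < 3 * se + 1e-6

    def test_seeded_runs_bit_reproducible(self, bundle, income_model,
                                          deaths_averted):
        kw = dict(seed=11, thinning=1000.0)
        a = te.monte_carlo_frp(income_model, deaths_averted, bundle.costs,
                               bundle.mortality, bundle.income, **kw)
        b = te.monte_carlo_frp(income_model, deaths_averted, bundle.costs,
                               bundle.mortality, bundle.income, **kw)
        np.testing.assert_array_equal(a.poverty_averted, b.poverty_averted)
        np.testing.assert_array_equal(a.catastrophic_averted, b.catastrophic_averted)
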