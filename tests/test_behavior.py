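"""Behavioural response: participation, consumption, brand switching."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tobacco_ecea as te
from tobacco_ecea.synthetic import make_degenerate_bundle


class TestParticipationReduction:
    def test_quintile_one_adult_under_75pct_price_rise(self, bundle):
        # |-0.64| x 0.5 x 0.75
        red = te.participation_reduction(bundle.elasticity, te.price_shock(0.75),
                                         quintile=0, age_class="adult")
        assert red == pytest.approx(0.24)

    def test_zero_elasticity_gives_zero(self):
        b = make_degenerate_bundle(adult_elasticity=0.0)
        red = te.participation_reduction(b.elasticity, te.price_shock(0.75), 2, "adult")
        assert red == 0.0

    def test_ban_returns_nine_percent_for_every_class(self, bundle):
        ban = te.workplace_ban(0.09)
        for age_class in ("adult", "youth", "future"):
            for q in range(5):
                assert te.participation_reduction(
                    bundle.elasticity, ban, q, age_class) == pytest.approx(0.09)

    def test_unknown_age_class_raises(self, bundle):
        with pytest.raises(KeyError):
            te.participation_reduction(bundle.elasticity, te.price_shock(), 0, "elder")

    def test_reduction_clamped_to_one(self):
        b = make_degenerate_bundle(adult_elasticity=-4.0)
        red = te.participation_reduction(b.elasticity, te.price_shock(0.75), 0, "adult")
        assert red == 1.0


class TestBrandSwitching:
    @pytest.mark.parametrize("p,expected", [(0.75, -0.095), (0.33, -0.2546)])
    def test_effective_average_elasticity(self, bundle, p, expected):
        eff = te.apply_brand_switching(
            te.price_shock(switching_proportion=p), bundle.elasticity)
        assert eff.adult.mean() == pytest.approx(expected)

    def test_rounded_equivalents_match_reported_values(self, bundle):
        for p, rounded in ((0.75, -0.10), (0.33, -0.25)):
            eff = te.apply_brand_switching(
                te.price_shock(switching_proportion=p), bundle.elasticity)
            assert round(eff.adult.mean(), 2) == rounded

    def test_zero_switching_is_identity(self, bundle):
        eff = te.apply_brand_switching(te.price_shock(), bundle.elasticity)
        assert eff is bundle.elasticity

    def test_switching_only_valid_for_price_shock(self):
        with pytest.raises(ValueError):
            te.Policy("workplace_ban", switching_proportion=0.5,
                      ban_relative_reduction=np.full(5, 0.09))


class TestRespond:
    def test_quitters_are_smokers_times_reduction(self):
        b = make_degenerate_bundle(n_males=10_000_000, prevalence=0.5,
                                   adult_elasticity=-0.64)
        out = te.respond(b, te.price_shock(0.75))
        # 1,000,000 smokers per quintile, reduction 0.24 in quintile I
        assert out.quitters[0, 0] == pytest.approx(240_000)

    def test_consumption_reduction_independent_mode(self, bundle):
        b = replace(bundle, consumption_response="independent")
        out = te.respond(b, te.price_shock(0.75))
        i = b.age_labels.index("25-29")
        # 15.6 x (1 - 0.64 x 0.5 x 0.75)
        assert out.cigs_after[i, 0] == pytest.approx(11.856)

    def test_consumption_residual_mode_delivers_full_demand_elasticity(self, bundle):
        out = te.respond(bundle, te.price_shock(0.75))
        pop = te.build_population(bundle)
        i = bundle.age_labels.index("25-29")
        demand_after = out.continuing[i, 0] * out.cigs_after[i, 0]
        demand_before = pop.smokers[i, 0] * bundle.consumption[0]
        assert demand_after / demand_before == pytest.approx(1 - 0.64 * 0.75)

    def test_ban_quits_nine_percent_consumption_unchanged(self):
        b = make_degenerate_bundle(n_males=10_000_000, prevalence=0.5)
        out = te.respond(b, te.workplace_ban(0.09))
        assert out.quitters[0, 0] == pytest.approx(90_000)
        np.testing.assert_allclose(out.cigs_after, b.consumption[None, :])

    def test_conservation_quitters_plus_continuing(self, bundle, population):
        for policy in (te.price_shock(0.75), te.workplace_ban(0.09)):
            out = te.respond(bundle, policy, population)
            np.testing.assert_allclose(out.quitters + out.continuing,
                                       population.smokers)

    def test_null_policy_is_identity(self, bundle, population):
        out = te.respond(bundle, te.null_policy(), population)
        assert not out.quitters.any()
        assert not out.averted_initiators.any()
        np.testing.assert_allclose(out.cigs_after,
                                   np.broadcast_to(out.cigs_before, out.cigs_after.shape))

    def test_ban_applies_to_future_initiators(self, bundle, population):
        out = te.respond(bundle, te.workplace_ban(0.09), population)
        np.testing.assert_allclose(out.averted_initiators,
                                   population.future_initiators * 0.09)

    def test_switching_default_leaves_initiation_unaffected(self, bundle, population):
        out = te.respond(bundle, te.price_shock(switching_proportion=0.33), population)
        assert not out.averted_initiators.any()

    def test_switching_scaling_mode_matches_prescaled_elasticities(self, bundle,
                                                                   population):
        p = 0.4
        switched = te.respond(
            bundle, te.price_shock(switching_proportion=p,
                                   switching_scales_initiation=True), population)
        prescaled = replace(bundle, elasticity=bundle.elasticity.scaled(1 - p))
        direct = te.respond(prescaled, te.price_shock(0.75), population)
        np.testing.assert_allclose(switched.quitters, direct.quitters)
        np.testing.assert_allclose(switched.averted_initiators,
                                   direct.averted_initiators)

    def test_ban_absolute_mode_targets_working_ages(self, bundle, population):
        policy = te.workplace_ban(absolute_mode=bundle.ban.absolute_mode)
        out = te.respond(bundle, policy, population)
        labels = bundle.age_labels
        # 2.2 percentage points / 58% prevalence among 50-54 year-olds
        i = labels.index("50-54")
        assert out.quitters[i, 0] == pytest.approx(
            population.smokers[i, 0] * 0.022 / 0.580)
        assert out.cigs_after[i, 0] == pytest.approx(bundle.consumption[0] - 3.1)
        # no effect at or above the age cap, none on initiation
        j = labels.index("60-64")
        assert not out.quitters[j:].any()
        assert not out.averted_initiators.any()

    def test_bottom_quintile_ban_sensitivity_vector(self, bundle, population):
        red = np.array([0.045, 0.09, 0.09, 0.09, 0.09])
        out = te.respond(bundle, te.workplace_ban(red), population)
        np.testing.assert_allclose(out.quitters, population.smokers * red[None, :])

    def test_participation_over_one_is_clamped_and_logged(self):
        b = make_degenerate_bundle(adult_elasticity=-4.0)
        with pytest.warns(RuntimeWarning, match="clamped"):
            out = te.respond(b, te.price_shock(0.75))
        pop = te.build_population(b)
        np.testing.assert_allclose(out.quitters[0], pop.smokers[0])
        assert out.warnings


class TestMonotonicity:
    @given(eps=st.floats(0.01, 1.5), dp=st.floats(0.0, 1.0))
    def test_larger_elasticity_or_price_rise_never_decreases_quitters(self, eps, dp):
        base = make_degenerate_bundle(adult_elasticity=-eps)
        stronger = make_degenerate_bundle(adult_elasticity=-min(eps * 1.5, 2.0))
        q_base = te.respond(base, te.price_shock(dp)).quitters
        q_eps = te.respond(stronger, te.price_shock(dp)).quitters
        q_dp = te.respond(base, te.price_shock(min(dp * 1.5, 1.0))).quitters
        assert np.all(q_eps >= q_base - 1e-9)
        assert np.all(q_dp >= q_base - 1e-9)
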