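"""Adaptive dynamics of the inhibition traits: gradients, singular points, ESS."""

import numpy as np
import pytest

from mindread import (
    CognitiveParams,
    EnvironmentParams,
    IntensityModel,
    PayoffParams,
    coordination_upper_bound,
    equilibrium_profile,
    full_inhibition_condition,
    gradient_field,
    invasion_fitness,
    optimal_S,
    pi_observer_S,
    selection_gradient,
    singular_numeric,
    singular_uD_steplinear,
)
from mindread.invasion import TraitPoint


def brute_force_uD_star(env, cog, pay, n=100_000, hi=1.5):
    """Independent oracle: dense grid maximization of the S observer payoff."""
    us = np.linspace(0.0, hi, n)
    vals = pi_observer_S(env, cog, pay, u_D=us)
    return us[int(np.argmax(vals))], hi / (n - 1)


class TestInvasionFitness:
    def test_neutral_at_resident(self, fig_env, cog_sigmoid, pay):
        tp = TraitPoint(0.4, 0.3)
        assert invasion_fitness(tp, tp, fig_env, cog_sigmoid, pay) == pytest.approx(0.0)

    def test_optimum_invades_any_resident(self, fig_env, cog_sigmoid, pay):
        u_star, _ = optimal_S(fig_env, cog_sigmoid, pay)
        best = TraitPoint(u_star, cog_sigmoid.u_B)
        for u_res in [0.05, 0.2, 0.6, 1.0]:
            w = invasion_fitness(best, TraitPoint(u_res, cog_sigmoid.u_B), fig_env, cog_sigmoid, pay)
            assert w > 0

    def test_below_threshold_sign_follows_recruitment(self, point_env, cog_step, pay):
        m = TraitPoint(0.25, 0.3)
        r = TraitPoint(0.15, 0.3)
        assert invasion_fitness(m, r, point_env, cog_step, pay) > 0
        assert invasion_fitness(r, m, point_env, cog_step, pay) < 0


class TestSelectionGradient:
    def test_step_linear_branch_values_exact(self, point_env, pay):
        """Below u_B the gradient is +gamma_a d-, above the ramp it is -c-."""
        cog = CognitiveParams(activation_kind="step_linear", rho_a=2.0, u_B=0.3, gamma_a=0.8)
        below = selection_gradient(TraitPoint(0.15, 0.3), "u_D", point_env, cog, pay)
        assert below == pytest.approx(0.8 * 5.0, abs=1e-9)
        above = selection_gradient(TraitPoint(0.9, 0.3), "u_D", point_env, cog, pay)
        assert above == pytest.approx(-3.0, abs=1e-9)

    def test_zero_at_closed_form_root(self, point_env, pay):
        cog = CognitiveParams(activation_kind="step_linear", rho_a=2.0, u_B=0.3)
        sp = singular_uD_steplinear(0.3, 2.0, 1.0, 5.0, 3.0)
        g = selection_gradient(TraitPoint(sp.u_D, 0.3), "u_D", point_env, cog, pay)
        assert abs(g) < 1e-6

    def test_threshold_gradient_is_finite_and_signed(self, fig_env, cog_sigmoid, pay):
        g_lo = selection_gradient(TraitPoint(0.4, 0.08), "u_B", fig_env, cog_sigmoid, pay)
        g_hi = selection_gradient(TraitPoint(0.4, 0.9), "u_B", fig_env, cog_sigmoid, pay)
        assert np.isfinite(g_lo) and np.isfinite(g_hi)
        assert g_lo > 0 > g_hi  # too-permissive thresholds rise, too-strict ones fall


class TestStepLinearSingularPoint:
    def test_reference_root(self):
        sp = singular_uD_steplinear(0.3, 1.0, 1.0, 5.0, 3.0)
        assert sp.u_D == pytest.approx(0.4625)
        assert sp.branch == "internal" and sp.is_ESS and sp.is_CS

    def test_steep_ramp_fully_inhibits(self):
        sp = singular_uD_steplinear(0.3, 10.0, 1.0, 5.0, 3.0)
        assert sp.u_D == pytest.approx(0.3)
        assert sp.branch == "boundary_full_inhibition"

    def test_costless_coordination_root(self):
        sp = singular_uD_steplinear(0.3, 2.0, 1.0, 5.0, 0.0)
        assert sp.u_D == pytest.approx(0.3 / 2 + 1.0 / (2 * 2.0))

    def test_matches_brute_force_grid_oracle(self, pay):
        """Closed form vs dense-grid maximization for 20 random parameter draws."""
        rng = np.random.default_rng(42)
        env = EnvironmentParams(lambda_e=1.0, p=0.25, intensity=IntensityModel("point", 1.0))
        for _ in range(20):
            u_B = rng.uniform(0.05, 0.6)
            rho_a = rng.uniform(0.8, 5.0)
            gamma_a = rng.uniform(0.3, 1.0)
            d_minus = rng.uniform(1.0, 8.0)
            c_minus = rng.uniform(0.0, 5.0)
            cog = CognitiveParams(
                activation_kind="step_linear", rho_a=rho_a, u_B=u_B, gamma_a=gamma_a
            )
            pay_i = PayoffParams(d_minus=d_minus, c_minus=c_minus)
            sp = singular_uD_steplinear(u_B, rho_a, gamma_a, d_minus, c_minus)
            u_oracle, du = brute_force_uD_star(env, cog, pay_i)
            assert abs(sp.u_D - u_oracle) <= 2 * du

    def test_comparative_statics(self):
        """u_D* nonincreasing in the coordination cost, nondecreasing in the premium."""
        grid_c = [0.0, 1.0, 3.0, 6.0]
        stars = [singular_uD_steplinear(0.3, 1.0, 1.0, 5.0, c).u_D for c in grid_c]
        assert all(a >= b for a, b in zip(stars, stars[1:]))
        grid_d = [1.0, 3.0, 5.0, 9.0]
        stars = [singular_uD_steplinear(0.3, 1.0, 1.0, d, 3.0).u_D for d in grid_d]
        assert all(a <= b for a, b in zip(stars, stars[1:]))


class TestFullInhibitionCondition:
    def test_consistent_with_closed_form(self):
        # threshold rho_a = 1*5/(0.3*8) ~ 2.083
        assert full_inhibition_condition(0.3, 1.0, 1.0, 5.0, 3.0) is True
        assert full_inhibition_condition(0.3, 10.0, 1.0, 5.0, 3.0) is False

    def test_agrees_with_branch_label(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            u_B = rng.uniform(0.05, 0.8)
            rho_a = rng.uniform(0.5, 8.0)
            gamma_a = rng.uniform(0.2, 1.0)
            d = rng.uniform(0.5, 8.0)
            c = rng.uniform(0.0, 5.0)
            evolves = full_inhibition_condition(u_B, rho_a, gamma_a, d, c)
            sp = singular_uD_steplinear(u_B, rho_a, gamma_a, d, c)
            assert evolves == (sp.u_D > u_B)

    def test_infinitely_costly_coordination_is_inhibited(self):
        assert full_inhibition_condition(0.3, 1.0, 1.0, 5.0, 1e12) is False


class TestNumericSingular:
    def test_sigmoid_internal_point_is_ess_and_cs(self, fig_env, cog_sigmoid, pay):
        pts = singular_numeric(fig_env, cog_sigmoid, pay, which={"u_D"})
        internal = [p for p in pts if p.branch == "internal"]
        assert internal and internal[0].is_ESS and internal[0].is_CS

    def test_cross_validates_closed_form(self, point_env, pay):
        cog = CognitiveParams(activation_kind="step_linear", rho_a=2.0, u_B=0.3)
        pts = singular_numeric(point_env, cog, pay, which={"u_D"})
        sp = singular_uD_steplinear(0.3, 2.0, 1.0, 5.0, 3.0)
        assert min(abs(p.u_D - sp.u_D) for p in pts) < 1e-4

    def test_ess_uninvadable_by_random_mutants(self, fig_env, cog_sigmoid, pay):
        pts = singular_numeric(fig_env, cog_sigmoid, pay, which={"u_D"})
        star = [p for p in pts if p.branch == "internal"][0]
        res = TraitPoint(star.u_D, cog_sigmoid.u_B)
        rng = np.random.default_rng(11)
        for _ in range(100):
            m = TraitPoint(abs(star.u_D + rng.normal(0, 0.05)), cog_sigmoid.u_B)
            assert invasion_fitness(m, res, fig_env, cog_sigmoid, pay) <= 1e-10

    def test_joint_evolution_retains_accidental_coordination(self, fig_env, cog_sigmoid, pay):
        """2-D trait evolution under the sigmoid ends with P_C > 0."""
        from mindread import response_profile

        pts = singular_numeric(fig_env, cog_sigmoid, pay, which={"u_D", "u_B"})
        sp = pts[0]
        assert sp.is_ESS and sp.is_CS
        cog_eq = cog_sigmoid.with_traits(u_D=sp.u_D, u_B=sp.u_B)
        prof = response_profile("S", fig_env, cog_eq, pay)
        assert prof.P_C > 0


class TestGradientField:
    def test_field_signs_and_singular_norm(self, fig_env, cog_sigmoid, pay):
        gf = gradient_field(
            np.linspace(0.05, 1.4, 7), np.linspace(0.1, 0.9, 7), fig_env, cog_sigmoid, pay
        )
        mean_x = fig_env.intensity.mean
        low = gf[gf.u_D * mean_x < 0.3 * gf.u_B]
        assert (low.g_uD > 0).all()
        high = gf[gf.u_D * mean_x > gf.u_B + 0.25]
        assert (high.g_uD < 0).all()
        pts = singular_numeric(fig_env, cog_sigmoid, pay, which={"u_D", "u_B"})
        sp = pts[0]
        tp = TraitPoint(sp.u_D, sp.u_B)
        g = np.hypot(
            selection_gradient(tp, "u_D", fig_env, cog_sigmoid, pay),
            selection_gradient(tp, "u_B", fig_env, cog_sigmoid, pay),
        )
        assert g < 1e-5

    def test_empty_grid_rejected(self, fig_env, cog_sigmoid, pay):
        with pytest.raises(ValueError):
            gradient_field([], [0.3], fig_env, cog_sigmoid, pay)


class TestEquilibriumProfile:
    def test_full_inhibition_point_has_no_coordination(self, point_env, pay):
        cog = CognitiveParams(activation_kind="step_linear", rho_a=10.0, u_B=0.3)
        sp, prof = equilibrium_profile(point_env, cog, pay, check_bound=False)
        assert prof.P_C == pytest.approx(0.0, abs=1e-12)

    def test_sigmoid_equilibrium_small_coordination(self, fig_env, cog_sigmoid, pay):
        """At the reference sigmoid equilibrium, 0 < P_C <= 2% of interactions."""
        sp, prof = equilibrium_profile(fig_env, cog_sigmoid, pay)
        assert 0.0 < prof.P_C <= 0.02
        assert prof.P_C < coordination_upper_bound(fig_env, pay, cog_sigmoid)

    def test_coordination_increases_when_costless(self, fig_env, cog_sigmoid):
        _, prof_costly = equilibrium_profile(
            fig_env, cog_sigmoid, PayoffParams(c_minus=3.0), check_bound=False
        )
        _, prof_free = equilibrium_profile(
            fig_env, cog_sigmoid, PayoffParams(c_minus=0.0), check_bound=False
        )
        assert prof_free.P_C > prof_costly.P_C
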