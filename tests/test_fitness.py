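"""Fitness components: outcome probabilities and payoff rates per strategy."""

import numpy as np
import pytest
from scipy.integrate import quad

from mindread import (
    CognitiveParams,
    EnvironmentParams,
    IntensityModel,
    PayoffParams,
    ResponseProfile,
    coordination_upper_bound,
    effective_psi,
    p_B,
    pi_observer_F,
    pi_observer_P,
    pi_observer_S,
    response_profile,
    total_fitness,
)


class TestActorResponseProbability:
    def test_matches_quadrature_over_residence_times(self):
        """P_B equals the expectation of the learning curve under Exp(lambda_d+lambda_e)."""
        for lam_l, p, lam_d, lam_e in [(1.0, 0.0, 1.0, 0.0), (50.0, 0.05, 1.0, 9.0), (10.0, 0.4, 1.0, 3.0)]:
            env = EnvironmentParams(lambda_e=lam_e, lambda_d=lam_d, p=p)
            cog = CognitiveParams(lambda_l=lam_l)
            lam = lam_d + lam_e
            oracle, _ = quad(
                lambda t: lam * np.exp(-lam * t) * (1 - np.exp(-lam_l * (1 - p) * t)),
                0,
                np.inf,
            )
            assert p_B(env, cog) == pytest.approx(oracle, abs=1e-8)

    def test_limits(self):
        env = EnvironmentParams(lambda_e=1.0, p=0.5)
        assert p_B(env, CognitiveParams(lambda_l=1e12)) == pytest.approx(1.0)
        env_half = EnvironmentParams(lambda_e=0.0, lambda_d=1.0, p=0.0)
        assert p_B(env_half, CognitiveParams(lambda_l=1.0)) == pytest.approx(0.5)


class TestObserverPayoffs:
    def test_fixed_strategy_state_fraction(self, pay):
        cog = CognitiveParams()
        env0 = EnvironmentParams(lambda_e=0.0)
        assert pi_observer_F(env0, cog, pay, 0.7) == pytest.approx(0.7 * 5.0)
        env1 = EnvironmentParams(lambda_e=1.0, lambda_d=1.0)
        assert pi_observer_F(env1, cog, pay, 0.7) == pytest.approx(0.5 * 0.7 * 5.0)

    def test_associative_strategy_social_exposure(self, pay):
        cog = CognitiveParams(lambda_l=50.0)
        env = EnvironmentParams(lambda_e=0.0, lambda_d=1.0, p=0.5)
        assert pi_observer_P(env, cog, pay, 0.7) == pytest.approx(25.0 / 26.0 * 0.7 * 5.0)
        env0 = EnvironmentParams(lambda_e=0.0, p=0.0)
        assert pi_observer_P(env0, cog, pay, 0.7) == 0.0

    def test_simulative_strategy_step_linear_example(self, pay):
        """Direct evaluation on the middle activation branch (alpha = 0.1625)."""
        env = EnvironmentParams(lambda_e=1.0, p=0.25, intensity=IntensityModel("point", 1.0))
        cog = CognitiveParams(activation_kind="step_linear", rho_a=1.0, u_B=0.3)
        val = pi_observer_S(env, cog, pay, p_B_focal=1.0, p_B_partner=1.0, u_D=0.4625)
        assert val == pytest.approx(0.4625 * ((1 - 0.1625) * 5.0 - 0.1625 * 3.0), abs=1e-12)

    def test_simulative_strategy_vanishes_without_recruitment(self, fig_env, cog_sigmoid, pay):
        assert pi_observer_S(fig_env, cog_sigmoid, pay, u_D=0.0) == 0.0

    def test_full_inhibition_branch(self, pay):
        env = EnvironmentParams(lambda_e=1.0, p=0.25, intensity=IntensityModel("point", 1.0))
        cog = CognitiveParams(activation_kind="step_linear", rho_a=2.0, u_B=0.3, gamma_a=0.8)
        u_D = 0.2  # below threshold: alpha = 0 exactly
        val = pi_observer_S(env, cog, pay, p_B_focal=1.0, p_B_partner=1.0, u_D=u_D)
        assert val == pytest.approx(0.2 * 0.8 * 5.0)

    def test_nonnegative_and_monotone_when_coordination_free(self, fig_env, cog_sigmoid):
        pay0 = PayoffParams(c_minus=0.0)
        u = np.linspace(0.0, 2.0, 50)
        vals = pi_observer_S(fig_env, cog_sigmoid, pay0, u_D=u)
        assert np.all(vals >= 0.0)
        for d_lo, d_hi in [(2.0, 5.0)]:
            v_lo = pi_observer_S(fig_env, cog_sigmoid, PayoffParams(c_minus=0.0, d_minus=d_lo), u_D=0.5)
            v_hi = pi_observer_S(fig_env, cog_sigmoid, PayoffParams(c_minus=0.0, d_minus=d_hi), u_D=0.5)
            assert v_hi >= v_lo


def test_distributed_intensities_converge_to_point_mass(cog_sigmoid, pay):
    """As sd -> 0 the truncated-normal expectations approach the point evaluation."""
    point = EnvironmentParams(lambda_e=9.0, p=0.05, intensity=IntensityModel("point", 0.5))
    vals = []
    for sd in [0.1, 0.02, 0.004]:
        env = EnvironmentParams(lambda_e=9.0, p=0.05, intensity=IntensityModel("truncnorm", 0.5, sd))
        vals.append(pi_observer_S(env, cog_sigmoid, pay, u_D=0.45))
    target = pi_observer_S(point, cog_sigmoid, pay, u_D=0.45)
    errs = [abs(v - target) for v in vals]
    assert errs[-1] < 1e-3 * max(abs(target), 1.0)
    assert errs[0] > errs[-1]


class TestTotalFitness:
    def test_unpaired_limit(self, pay):
        env = EnvironmentParams(lambda_e=1.0, p=0.0)
        prof = ResponseProfile(P_B=0.6, P_noact=0.4, P_D=0.3, P_0=0.7, P_C=0.0)
        assert total_fitness(prof, prof, env, pay) == pytest.approx(0.6 * 1.0)

    def test_weighted_sum_arithmetic(self):
        env = EnvironmentParams(lambda_e=1.0, p=0.25)
        pay = PayoffParams(b=1.0, d_minus=5.0, d_plus=5.0)
        focal = ResponseProfile(P_B=1.0, P_noact=0.0, P_D=1.0, P_0=0.0, P_C=0.0)
        partner = ResponseProfile(P_B=1.0, P_noact=0.0, P_D=1.0, P_0=0.0, P_C=0.0)
        # 0.5*1 + 0.25*5 + 0.25*(1-5) = 0.75
        assert total_fitness(focal, partner, env, pay) == pytest.approx(0.75)

    def test_zero_probabilities_zero_fitness(self, pay):
        env = EnvironmentParams(lambda_e=1.0, p=0.3)
        zero = ResponseProfile(P_B=0.0, P_noact=0.0, P_D=0.0, P_0=0.0, P_C=0.0)
        assert total_fitness(zero, zero, env, pay) == 0.0


class TestCoordinationBound:
    def test_reference_value(self):
        env = EnvironmentParams(lambda_e=0.0, lambda_d=1.0, p=0.5)
        cog = CognitiveParams(lambda_l=50.0)
        pay = PayoffParams(d_minus=5.0, c_minus=3.0)
        assert coordination_upper_bound(env, pay, cog) == pytest.approx(2.5 / 26.0)

    def test_costless_coordination_first_factor_unity(self):
        env = EnvironmentParams(lambda_e=2.0, lambda_d=1.0, p=0.3)
        cog = CognitiveParams(lambda_l=10.0)
        pay = PayoffParams(c_minus=0.0)
        assert coordination_upper_bound(env, pay, cog) == pytest.approx(3.0 / (3.0 + 3.0))

    def test_perfect_social_learning_tolerates_nothing(self):
        env = EnvironmentParams(lambda_e=0.0, p=0.5)
        pay = PayoffParams()
        assert coordination_upper_bound(env, pay, CognitiveParams(lambda_l=1e12)) < 1e-9

    def test_undefined_when_coordination_cheaper_than_defection(self):
        env = EnvironmentParams(lambda_e=0.0, p=0.5)
        with pytest.raises(ValueError):
            coordination_upper_bound(env, PayoffParams(d_minus=2.0, c_minus=3.0), CognitiveParams())


class TestEffectivePsi:
    @pytest.mark.parametrize(
        "psi, w, expected", [(0.5, 1.0, 0.5), (0.0, 3.0, 0.0), (0.5, 2.0, 1.0 / 3.0)]
    )
    def test_values(self, psi, w, expected):
        assert effective_psi(psi, w) == pytest.approx(expected)

    def test_assortment_masks_differences(self):
        assert effective_psi(0.7, 4.0) < 0.7


def test_response_profile_consistency(fig_env, cog_sigmoid, pay):
    for strat in ("F", "P", "S"):
        prof = response_profile(strat, fig_env, cog_sigmoid, pay)
        assert prof.P_D + prof.P_0 + prof.P_C == pytest.approx(1.0)
        assert prof.P_B + prof.P_noact == pytest.approx(1.0)
        if strat != "S":
            assert prof.P_C == 0.0
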