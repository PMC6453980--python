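"""Adaptive dynamics of the inhibition traits u_D and u_B.

The simulative strategy carries two continuous traits: the recruitment
intensity ``u_D`` (how strongly the as-actor network is engaged during
observation) and the inhibition threshold ``u_B`` of the activation function.
When ``u_B`` is fixed, every individual shares the same actor-side performance,
so a mutant's growth rate depends only on its own as-observer payoff: the
singular ``u_D*`` is the global maximum of ``pi_minus^S(u_D)`` and is both an
ESS and convergence stable.  In the step-linear model this maximum has a closed
form (:func:`singular_uD_steplinear`); coordination survives at the optimum
whenever the activation ramp is shallow enough
(:func:`full_inhibition_condition`).

When ``u_B`` itself evolves, raising the threshold also suppresses the
individual's own actor responses (false negatives), so invasion fitness must
use the total payoff: the actor-side term enters with weight ``(1-p)`` against
the observer-side ``p``.  All gradients here are central finite differences;
the 2-D singular point is located by a trait-substitution walk followed by a
root polish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root

from .cognitive import CognitiveParams, activation, learning_accuracy
from .fitness import (
    EnvironmentParams,
    PayoffParams,
    ResponseProfile,
    coordination_upper_bound,
    p_B,
    response_profile,
    s_conditional_rates,
)
from .replicator import classify_dominant, optimal_S

__all__ = [
    "TraitPoint",
    "SingularPoint",
    "invasion_fitness",
    "selection_gradient",
    "singular_uD_steplinear",
    "full_inhibition_condition",
    "singular_numeric",
    "gradient_field",
    "equilibrium_profile",
]

_FD_STEP = 1e-5
_CURV_STEP = 1e-4


@dataclass(frozen=True)
class TraitPoint:
    """A point in the (u_D, u_B) trait space."""

    u_D: float
    u_B: float

    def __post_init__(self) -> None:
        if self.u_D < 0:
            raise ValueError("u_D must be nonnegative")
        if not 0.0 <= self.u_B <= 1.0:
            raise ValueError("u_B must lie in [0, 1]")


@dataclass(frozen=True)
class SingularPoint:
    """A singular strategy with its stability classification."""

    u_D: float
    u_B: float | None
    is_ESS: bool
    is_CS: bool
    branch: str  # internal | boundary_full_inhibition | boundary_full_coordination


def _time_factor(env: EnvironmentParams, cog: CognitiveParams) -> float:
    """Expected as-actor learning-time factor (equals P_B in the simplified case)."""
    rate = cog.lambda_l * (1.0 - env.p)
    return rate / (env.lam + rate)


def _actor_exec(env: EnvironmentParams, cog: CognitiveParams) -> float:
    """Actor-side execution probability E_x[l_x(x) alpha(x)] times gamma."""
    return cog.gamma * env.intensity.expect(
        lambda x: learning_accuracy(x, cog) * activation(x, cog)
    )


def _p_B_traits(env: EnvironmentParams, cog: CognitiveParams, tp: TraitPoint) -> float:
    c = cog.with_traits(u_D=tp.u_D, u_B=tp.u_B)
    return _time_factor(env, c) * _actor_exec(env, c)


def _observer_rates(env: EnvironmentParams, cog: CognitiveParams, tp: TraitPoint):
    """Per-(partner B) observer D/C probabilities, including the focal's learning."""
    c = cog.with_traits(u_D=tp.u_D, u_B=tp.u_B)
    q_D, q_C = s_conditional_rates(env, c)
    T = _time_factor(env, c)
    return T * q_D, T * q_C


def _total_payoff(
    focal: TraitPoint,
    resident: TraitPoint,
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
) -> float:
    """Total fitness of a focal S trait point in an S resident population."""
    pb_f = _p_B_traits(env, cog, focal)
    pb_r = _p_B_traits(env, cog, resident)
    qD_f, qC_f = _observer_rates(env, cog, focal)
    qD_r, qC_r = _observer_rates(env, cog, resident)
    pi_plus = pb_f * pay.b
    pi_minus = (qD_f * pay.d_minus - qC_f * pay.c_minus) * pb_r
    pi_obs = pb_f * (pay.b - qD_r * pay.d_plus + qC_r * pay.c_plus)
    return (1.0 - 2.0 * env.p) * pi_plus + env.p * pi_minus + env.p * pi_obs


def invasion_fitness(
    mutant: TraitPoint,
    resident: TraitPoint,
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
) -> float:
    """Payoff advantage of a rare mutant trait in a monomorphic resident.

    Because a rare mutant's partners are residents, the advantage is the
    difference in total payoff against the resident background.  For mutants
    differing only in ``u_D`` this reduces to ``p * (pi_minus^S(u_D^m) -
    pi_minus^S(u_D^res))`` times the resident's actor performance.
    """
    return _total_payoff(mutant, resident, env, cog, pay) - _total_payoff(
        resident, resident, env, cog, pay
    )


def _conditional_payoff(env, cog, pay, u_D):
    """Observer payoff conditional on the focal having learned and partner B.

    ``q_D d_minus - q_C c_minus``: the P_B factors drop out of gradient signs
    and zeros, and on the step-linear branches the derivative takes the exact
    values ``+gamma_a d_minus`` / ``-c_minus``.
    """
    q_D, q_C = s_conditional_rates(env, cog, u_D=u_D)
    return q_D * pay.d_minus - q_C * pay.c_minus


def selection_gradient(
    resident: TraitPoint,
    which: str,
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    step: float = _FD_STEP,
) -> float:
    """Central finite-difference selection gradient at the resident.

    ``which='u_D'`` differentiates the conditional observer payoff (the trait
    only acts through the observer channel); ``which='u_B'`` differentiates
    the total fitness, so the actor-side false-negative cost is included.
    """
    if which == "u_D":
        u = resident.u_D
        h = min(step, u) if u > 0 else step
        c = cog.with_traits(u_B=resident.u_B)
        if u - h >= 0 and h > 0:
            g = (
                _conditional_payoff(env, c, pay, u + h)
                - _conditional_payoff(env, c, pay, u - h)
            ) / (2 * h)
        else:
            g = (
                _conditional_payoff(env, c, pay, u + step)
                - _conditional_payoff(env, c, pay, u)
            ) / step
    elif which == "u_B":
        u = resident.u_B
        h = min(step, u - 1e-9, 1.0 - u - 1e-9)
        if h <= 0:
            raise ValueError("u_B too close to its bounds for a central difference")
        up = TraitPoint(resident.u_D, u + h)
        dn = TraitPoint(resident.u_D, u - h)
        g = (
            invasion_fitness(up, resident, env, cog, pay)
            - invasion_fitness(dn, resident, env, cog, pay)
        ) / (2 * h)
    else:
        raise ValueError("which must be 'u_D' or 'u_B'")
    if not np.isfinite(g):
        raise ValueError("non-finite selection gradient")
    return float(g)


def singular_uD_steplinear(
    u_B: float,
    rho_a: float,
    gamma_a: float,
    d_minus: float,
    c_minus: float,
) -> SingularPoint:
    """Closed-form singular recruitment intensity for the step-linear model.

    On the middle activation branch the observer payoff is quadratic in u_D
    and its stationary point is ``u_B/2 + gamma_a d_minus /
    (2 rho_a (gamma_a d_minus + c_minus))``; the singular strategy is this
    root clipped to the branch (and to the learning cap at x = 1):
    ``u_D* = max(u_B, min(root, u_B + 1/rho_a, 1))``.
    """
    if min(rho_a, gamma_a, d_minus) <= 0 or c_minus < 0:
        raise ValueError("rho_a, gamma_a, d_minus must be positive; c_minus nonnegative")
    gd = gamma_a * d_minus
    root_val = 0.5 * u_B + gd / (2.0 * rho_a * (gd + c_minus))
    top = min(u_B + 1.0 / rho_a, 1.0)
    u_star = max(u_B, min(root_val, top))
    if root_val <= u_B:
        branch = "boundary_full_inhibition"
    elif root_val >= u_B + 1.0 / rho_a and u_star == u_B + 1.0 / rho_a:
        branch = "boundary_full_coordination"
    else:
        branch = "internal"
    # The objective is concave on the middle branch; clipped optima are corner
    # maxima (gradient points inward on both sides when c_minus > 0).
    is_ess = not (branch == "boundary_full_coordination" and c_minus == 0.0)
    return SingularPoint(u_D=float(u_star), u_B=float(u_B), is_ESS=is_ess, is_CS=is_ess, branch=branch)


def full_inhibition_condition(
    u_B: float,
    rho_a: float,
    gamma_a: float,
    d_minus: float,
    c_minus: float,
) -> bool:
    """Whether accidental coordination evolves (u_D* > u_B) in the step-linear model.

    True iff ``rho_a < gamma_a d_minus / (u_B (gamma_a d_minus + c_minus))``:
    a shallow activation ramp cannot separate inference from execution, so the
    optimum overshoots the threshold even though coordination is costly.
    """
    if u_B <= 0:
        return True  # no inhibition range at all
    gd = gamma_a * d_minus
    return rho_a < gd / (u_B * (gd + c_minus))


def _uD_grid_hi(env: EnvironmentParams, cog: CognitiveParams) -> float:
    scale = 1.0 / min(1.0, env.intensity.mean)
    return (cog.u_B + 2.0 / cog.rho_a + 1.0) * scale


def singular_numeric(
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    which: set[str] | frozenset[str] = frozenset({"u_D"}),
    n_scan: int = 201,
    grad_tol: float = 1e-6,
) -> list[SingularPoint]:
    """Locate singular strategies of the selected trait(s) numerically.

    1-D: sign-scan of the selection gradient followed by bisection; 2-D: a
    trait-substitution walk (step 1e-3) followed by a Newton-type root polish
    of the finite-difference gradient.  Each point is classified locally:
    ESS if the second difference of fitness in each trait is negative, CS if
    the gradient slope across residents is negative.  If the scan finds no
    interior sign change, the relevant boundary point is returned.
    """
    which = frozenset(which)
    if which == frozenset({"u_D"}):
        return _singular_uD(env, cog, pay, n_scan)
    if which == frozenset({"u_B"}):
        return _singular_uB(env, cog, pay, n_scan)
    if which == frozenset({"u_D", "u_B"}):
        return _singular_2d(env, cog, pay, grad_tol)
    raise ValueError(f"unsupported trait selection {which}")


def _classify_1d(g, u_star: float, h: float = _CURV_STEP) -> tuple[bool, bool]:
    slope = (g(u_star + h) - g(u_star - h)) / (2 * h)
    # frequency-independent 1-D case: ESS and CS both reduce to a negative
    # gradient slope at the singular point
    return slope < 0, slope < 0


def _singular_uD(env, cog, pay, n_scan) -> list[SingularPoint]:
    u_B = cog.u_B
    hi = _uD_grid_hi(env, cog)
    g = lambda u: selection_gradient(TraitPoint(u, u_B), "u_D", env, cog, pay)  # noqa: E731
    us = np.linspace(1e-6, hi, n_scan)
    gs = np.array([g(u) for u in us])
    points: list[SingularPoint] = []
    for i in range(n_scan - 1):
        if gs[i] == 0.0:
            continue
        if np.sign(gs[i]) != np.sign(gs[i + 1]) and gs[i + 1] != 0.0:
            u_star = brentq(g, us[i], us[i + 1], xtol=1e-12)
            ess, cs = _classify_1d(g, u_star)
            branch = "internal"
            if cog.activation_kind == "step_linear":
                if abs(u_star - u_B) < 1e-9:
                    branch = "boundary_full_inhibition"
                elif abs(u_star - (u_B + 1.0 / cog.rho_a)) < 1e-9:
                    branch = "boundary_full_coordination"
            points.append(SingularPoint(float(u_star), None, ess, cs, branch))
    if not points:
        if gs[-1] > 0:
            points.append(SingularPoint(float(hi), None, False, True, "boundary_full_coordination"))
        else:
            points.append(SingularPoint(0.0, None, False, True, "boundary_full_inhibition"))
    return points


def _singular_uB(env, cog, pay, n_scan) -> list[SingularPoint]:
    u_D = cog.u_D
    g = lambda ub: selection_gradient(TraitPoint(u_D, ub), "u_B", env, cog, pay)  # noqa: E731
    us = np.linspace(5e-3, 0.995, n_scan)
    gs = np.array([g(u) for u in us])
    points: list[SingularPoint] = []
    for i in range(n_scan - 1):
        if np.sign(gs[i]) != np.sign(gs[i + 1]) and gs[i] != 0.0 and gs[i + 1] != 0.0:
            ub_star = brentq(g, us[i], us[i + 1], xtol=1e-12)
            ess, cs = _classify_1d(g, ub_star)
            points.append(SingularPoint(float(u_D), float(ub_star), ess, cs, "internal"))
    if not points:
        if gs[-1] > 0:
            points.append(SingularPoint(float(u_D), float(us[-1]), False, True, "boundary_full_inhibition"))
        else:
            points.append(SingularPoint(float(u_D), float(us[0]), False, True, "boundary_full_coordination"))
    return points


def _singular_2d(env, cog, pay, grad_tol) -> list[SingularPoint]:
    def grad(v: np.ndarray) -> np.ndarray:
        u_d = max(float(v[0]), 1e-9)
        u_b = float(np.clip(v[1], 6e-3, 0.994))
        tp = TraitPoint(u_d, u_b)
        return np.array(
            [
                selection_gradient(tp, "u_D", env, cog, pay),
                selection_gradient(tp, "u_B", env, cog, pay),
            ]
        )

    v = np.array([max(cog.u_D, 1e-3), float(np.clip(cog.u_B, 0.05, 0.95))])
    step = 1e-3
    g = grad(v)
    for _ in range(5000):
        if np.linalg.norm(g) < grad_tol:
            break
        v = v + step * np.sign(g)
        v[0] = max(v[0], 1e-9)
        v[1] = np.clip(v[1], 6e-3, 0.994)
        g_new = grad(v)
        if np.all(np.sign(g_new) != np.sign(g)):  # overshooting on both axes
            step = max(step * 0.5, 1e-6)
        g = g_new
    sol = root(grad, v, method="hybr", options={"xtol": 1e-10})
    if sol.success and np.linalg.norm(grad(sol.x)) < 1e-5:
        v = sol.x
    tp = TraitPoint(max(float(v[0]), 0.0), float(np.clip(v[1], 0.0, 1.0)))

    def fit_along(trait: str, delta: float) -> float:
        if trait == "u_D":
            m = TraitPoint(max(tp.u_D + delta, 0.0), tp.u_B)
        else:
            m = TraitPoint(tp.u_D, float(np.clip(tp.u_B + delta, 0.0, 1.0)))
        return invasion_fitness(m, tp, env, cog, pay)

    h = _CURV_STEP
    ess = all(
        fit_along(t, +h) + fit_along(t, -h) < 0 for t in ("u_D", "u_B")
    )
    cs = all(
        (
            selection_gradient(
                TraitPoint(
                    tp.u_D + (h if t == "u_D" else 0.0),
                    float(np.clip(tp.u_B + (h if t == "u_B" else 0.0), 0.0, 1.0)),
                ),
                t,
                env,
                cog,
                pay,
            )
            - selection_gradient(
                TraitPoint(
                    max(tp.u_D - (h if t == "u_D" else 0.0), 0.0),
                    float(np.clip(tp.u_B - (h if t == "u_B" else 0.0), 0.0, 1.0)),
                ),
                t,
                env,
                cog,
                pay,
            )
        )
        < 0
        for t in ("u_D", "u_B")
    )
    return [SingularPoint(tp.u_D, tp.u_B, bool(ess), bool(cs), "internal")]


def gradient_field(
    u_D_values,
    u_B_values,
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
):
    """Selection-gradient vectors on a (u_D, u_B) grid (long-format DataFrame)."""
    import pandas as pd

    u_D_values = np.asarray(u_D_values, dtype=float)
    u_B_values = np.asarray(u_B_values, dtype=float)
    if u_D_values.size == 0 or u_B_values.size == 0:
        raise ValueError("gradient field grid must be nonempty")
    rows = []
    for ub in u_B_values:
        for ud in u_D_values:
            tp = TraitPoint(float(ud), float(ub))
            rows.append(
                {
                    "u_D": float(ud),
                    "u_B": float(ub),
                    "g_uD": selection_gradient(tp, "u_D", env, cog, pay),
                    "g_uB": selection_gradient(tp, "u_B", env, cog, pay),
                }
            )
    return pd.DataFrame(rows)


def equilibrium_profile(
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    check_bound: bool = True,
) -> tuple[SingularPoint, ResponseProfile]:
    """Singular u_D* (fixed u_B) and the response profile of S evaluated there.

    When S dominates the strategy competition, the equilibrium coordination
    probability must respect the analytic upper bound; a violation signals an
    inconsistency and raises.
    """
    u_star, _ = optimal_S(env, cog, pay)
    pts = _singular_uD(env, cog, pay, n_scan=201)
    best = min(pts, key=lambda sp: abs(sp.u_D - u_star))
    c_eq = cog.with_traits(u_D=best.u_D)
    prof = response_profile("S", env, c_eq, pay)
    if check_bound and classify_dominant(env, cog, pay) == "S":
        bound = coordination_upper_bound(env, pay, cog)
        if not prof.P_C < bound:
            raise RuntimeError(
                f"equilibrium P_C={prof.P_C} violates the coordination bound {bound}"
            )
    return best, prof
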