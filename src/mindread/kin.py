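"""Kin selection: relatedness-transformed payoffs and the empathic gradient.

Indirect benefits are modelled with an abstract assortment coefficient
``r`` in [0, 1] (relatedness or group structure): each party's payoff is mixed
with ``r`` times its partner's and normalized by ``1 + r``.  For the evolution
of the recruitment intensity ``u_D`` the transform collapses to effective
observer payoffs

    d_minus_eff = (d_minus - r d_plus) / (1 + r)
    c_minus_eff = (c_minus - r c_plus) / (1 + r)

(the do-nothing cell ``r b / (1+r)`` is a u_D-independent baseline).  Raising
``r`` steepens or flattens the inferred-response premium depending on the
payoff ratios: the singular ``u_D*`` increases with ``r`` — the *empathic
gradient* of stronger contagion toward kin — exactly when
``c_plus/c_minus > d_plus/d_minus``.  Once ``r c_plus > c_minus`` the
effective coordination cost turns negative and full coordination (no
inhibition of the recruited response) can become evolutionarily stable,
possibly bistably with an internal inhibited equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cognitive import CognitiveParams
from .fitness import (
    EnvironmentParams,
    PayoffParams,
    p_B,
    s_conditional_rates,
)

__all__ = [
    "KinPayoffMatrix",
    "RegimeLabel",
    "transform_payoffs",
    "empathic_gradient_condition",
    "pi_observer_S_kin",
    "singular_uD_kin",
    "duD_dr",
    "classify_regime",
    "regime_map",
]

REGIMES = ("inhibition_only", "full_coordination_only", "bistable")


@dataclass(frozen=True)
class RegimeLabel:
    label: str

    def __post_init__(self) -> None:
        if self.label not in REGIMES:
            raise ValueError(f"label must be one of {REGIMES}, got {self.label!r}")


@dataclass(frozen=True)
class KinPayoffMatrix:
    """Relatedness-transformed payoffs, all normalized by ``1 + r``.

    Entries are (observer payoff, actor payoff) for the cells where the actor
    played B; every cell of the no-act column pays zero to both.
    """

    r: float
    obs_D: float
    obs_0: float
    obs_C: float
    act_D: float
    act_0: float
    act_C: float

    @property
    def d_minus_eff(self) -> float:
        """Effective premium of D over doing nothing for the observer."""
        return self.obs_D - self.obs_0

    @property
    def c_minus_eff(self) -> float:
        """Effective cost of C relative to doing nothing (can go negative)."""
        return self.obs_0 - self.obs_C


def transform_payoffs(pay: PayoffParams, r: float) -> KinPayoffMatrix:
    """Mix partner payoffs into own payoff with weight r, normalized by 1 + r.

    Observer column (actor played B): D -> (d- + r(b - d+))/(1+r),
    0 -> r b/(1+r), C -> (-c- + r(b + c+))/(1+r); actor entries symmetric.
    ``r = 0`` recovers the untransformed matrix exactly.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must lie in [0, 1], got {r}")
    z = 1.0 + r
    return KinPayoffMatrix(
        r=r,
        obs_D=(pay.d_minus + r * (pay.b - pay.d_plus)) / z,
        obs_0=r * pay.b / z,
        obs_C=(-pay.c_minus + r * (pay.b + pay.c_plus)) / z,
        act_D=((pay.b - pay.d_plus) + r * pay.d_minus) / z,
        act_0=pay.b / z,
        act_C=((pay.b + pay.c_plus) - r * pay.c_minus) / z,
    )


def empathic_gradient_condition(pay: PayoffParams) -> bool:
    """Whether stronger contagion toward kin can evolve: c+/c- > d+/d-."""
    if pay.c_minus == 0 or pay.d_minus == 0:
        raise ValueError("empathic-gradient condition needs c_minus, d_minus != 0")
    return pay.c_plus / pay.c_minus > pay.d_plus / pay.d_minus


def pi_observer_S_kin(
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    r: float,
    u_D=None,
    p_B_focal: float | None = None,
    p_B_partner: float | None = None,
):
    """As-observer payoff of S under the relatedness transform.

    Per paired observer interaction with an informative actor the observer
    collects ``obs_D``, ``obs_C`` or ``obs_0`` according to its response;
    u_D may be an array.
    """
    kin = transform_payoffs(pay, r)
    if p_B_focal is None:
        p_B_focal = p_B(env, cog)
    if p_B_partner is None:
        p_B_partner = p_B(env, cog)
    q_D, q_C = s_conditional_rates(env, cog, u_D=u_D)
    cond = kin.obs_0 + q_D * kin.d_minus_eff - q_C * kin.c_minus_eff
    return cond * p_B_focal * p_B_partner


def _kin_cond_payoff(env, cog, pay, r, u_D):
    """Conditional observer payoff under kin (vectorized in u_D, P_B factors dropped)."""
    kin = transform_payoffs(pay, r)
    q_D, q_C = s_conditional_rates(env, cog, u_D=u_D)
    return kin.obs_0 + q_D * kin.d_minus_eff - q_C * kin.c_minus_eff


def _kin_gradient(env, cog, pay, r, u_D, h=1e-6):
    u_D = np.asarray(u_D, dtype=float)
    lo = np.maximum(u_D - h, 0.0)
    out = (
        _kin_cond_payoff(env, cog, pay, r, u_D + h)
        - _kin_cond_payoff(env, cog, pay, r, lo)
    ) / (u_D + h - lo)
    return float(out) if out.ndim == 0 else out


def _uD_bound(env: EnvironmentParams, cog: CognitiveParams) -> float:
    """Recruitment intensity beyond which inhibition is effectively absent.

    Under the sigmoid the activation never reaches 1 exactly; at
    ``u_D x_ref = u_B + 6 u_B / rho_a`` the activation exceeds 0.997, which we
    take as the full-coordination boundary (x_ref is the mean intensity).
    """
    x_ref = env.intensity.mean
    return (cog.u_B + 6.0 * cog.u_B / cog.rho_a) / x_ref


def singular_uD_kin(
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    r: float,
    n_scan: int = 241,
) -> float | None:
    """Interior convergence-stable u_D* under relatedness r, or None.

    Sign-scan of the kin observer-payoff gradient over (0, u_D_bound],
    followed by bisection; only down-crossings (local maxima) qualify.
    """
    hi = _uD_bound(env, cog)
    us = np.linspace(1e-6, hi, n_scan)
    gs = _kin_gradient(env, cog, pay, r, us)
    for i in range(n_scan - 1):
        if gs[i] > 0 and gs[i + 1] < 0:
            return float(
                brentq(lambda u: _kin_gradient(env, cog, pay, r, u), us[i], us[i + 1], xtol=1e-10)
            )
    return None


def duD_dr(
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    r: float,
    method: str = "implicit",
    delta: float = 1e-3,
) -> float:
    """Sensitivity of the singular recruitment intensity to relatedness.

    ``method='implicit'``: ``-(d2 pi / du_D dr) / (d2 pi / du_D^2)`` at
    u_D*(r) by finite differences of the payoff gradient.
    ``method='resolve'``: central difference of u_D*(r +/- delta).
    Raises if no interior singular point exists at r (boundary regime).
    """
    u_star = singular_uD_kin(env, cog, pay, r)
    if u_star is None:
        raise ValueError(f"no interior singular u_D at r={r}: boundary regime")
    if method == "resolve":
        lo = max(r - delta, 0.0)
        hi = min(r + delta, 1.0)
        u_lo = singular_uD_kin(env, cog, pay, lo)
        u_hi = singular_uD_kin(env, cog, pay, hi)
        if u_lo is None or u_hi is None:
            raise ValueError("interior singular point disappears within the r stencil")
        return (u_hi - u_lo) / (hi - lo)
    if method != "implicit":
        raise ValueError("method must be 'implicit' or 'resolve'")
    h_u = 1e-4
    dg_dr = (
        _kin_gradient(env, cog, pay, min(r + delta, 1.0), u_star)
        - _kin_gradient(env, cog, pay, max(r - delta, 0.0), u_star)
    ) / (min(r + delta, 1.0) - max(r - delta, 0.0))
    dg_du = (
        _kin_gradient(env, cog, pay, r, u_star + h_u)
        - _kin_gradient(env, cog, pay, r, u_star - h_u)
    ) / (2 * h_u)
    return -dg_dr / dg_du


def classify_regime(
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    r: float,
) -> RegimeLabel:
    """Stability regime of inhibition vs full coordination at relatedness r.

    Full coordination is stable iff the payoff gradient in u_D is nonnegative
    at the uninhibited boundary; an internal inhibited equilibrium exists iff
    the gradient scan finds an interior maximum; both together -> bistable.
    """
    hi = _uD_bound(env, cog)
    boundary_stable = _kin_gradient(env, cog, pay, r, hi) >= 0.0
    internal = singular_uD_kin(env, cog, pay, r) is not None
    if internal and boundary_stable:
        return RegimeLabel("bistable")
    if boundary_stable:
        return RegimeLabel("full_coordination_only")
    return RegimeLabel("inhibition_only")


def regime_map(
    r_values,
    c_ratio_values,
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
) -> pd.DataFrame:
    """Regime labels over a (r, c+/c-) grid at fixed d+/d-.

    ``c_plus`` is set to ``ratio * c_minus`` per cell.  Returns a long-format
    frame with columns r, c_ratio, label, u_D_star, P_C (NaN where no internal
    equilibrium exists).
    """
    r_values = np.asarray(r_values, dtype=float)
    c_ratio_values = np.asarray(c_ratio_values, dtype=float)
    if r_values.size == 0 or c_ratio_values.size == 0:
        raise ValueError("regime map grids must be nonempty")
    pb = p_B(env, cog)
    rows = []
    for ratio in c_ratio_values:
        pay_cell = replace(pay, c_plus=float(ratio) * pay.c_minus)
        for r in r_values:
            label = classify_regime(env, cog, pay_cell, float(r)).label
            u_star = singular_uD_kin(env, cog, pay_cell, float(r))
            if u_star is None:
                P_C = np.nan
                u_val = np.nan
            else:
                _, q_C = s_conditional_rates(env, cog, u_D=u_star)
                P_C = q_C * pb * pb
                u_val = u_star
            rows.append(
                {
                    "r": float(r),
                    "c_ratio": float(ratio),
                    "label": label,
                    "u_D_star": u_val,
                    "P_C": P_C,
                }
            )
    return pd.DataFrame(rows)
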