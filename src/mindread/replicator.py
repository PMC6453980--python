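"""Replicator dynamics of the three mind-reading strategy types.

With the inhibition threshold ``u_B`` shared by all strategies, P_B is common,
payoffs are frequency independent, and the dynamics on the F/P/S simplex reduce
to ``dy^j/dt = y^j (pi_minus^j - phi_minus)`` with ``phi_minus`` the
frequency-weighted mean as-observer payoff.  The system exhibits transcritical
bifurcations only: the strategy with the highest as-observer payoff dominates,
which is what :func:`classify_dominant` computes analytically (the S strategy
is first optimized over its recruitment intensity ``u_D``, since a single
optimal S exists for fixed ``u_B``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .cognitive import CognitiveParams
from .fitness import (
    EnvironmentParams,
    PayoffParams,
    p_B,
    pi_observer_F,
    pi_observer_P,
    pi_observer_S,
)

__all__ = [
    "PopulationState",
    "SweepGrid",
    "replicator_rhs",
    "integrate_dynamics",
    "optimal_S",
    "observer_payoffs",
    "classify_dominant",
    "phase_diagram",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class PopulationState:
    """Frequencies (y_F, y_P, y_S) on the 2-simplex."""

    y_F: float
    y_P: float
    y_S: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-12) or np.any(arr > 1.0 + 1e-12):
            raise ValueError(f"frequencies must lie in [0, 1]: {arr}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {arr.sum()}")

    def as_array(self) -> np.ndarray:
        return np.array([self.y_F, self.y_P, self.y_S], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "PopulationState":
        y = np.asarray(y, dtype=float)
        return cls(*(y / y.sum()))


@dataclass
class SweepGrid:
    """A (t_bar, p) parameter grid with per-cell payoffs and dominant labels."""

    t_bar: np.ndarray
    p: np.ndarray
    table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.t_bar = np.asarray(self.t_bar, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t_bar.size == 0 or self.p.size == 0:
            raise ValueError("sweep grid must be nonempty")
        if np.any(self.t_bar <= 0):
            raise ValueError("t_bar values must be positive")
        if np.any((self.p < 0) | (self.p > 0.5)):
            raise ValueError("p values must lie in [0, 0.5]")

    def region_count(self, label: str) -> int:
        if self.table is None:
            raise ValueError("sweep has not been evaluated")
        return int((self.table["dominant"] == label).sum())


def replicator_rhs(state: PopulationState | np.ndarray, payoffs) -> np.ndarray:
    """dy^j/dt = y^j (pi^j - phi); components sum to zero exactly."""
    y = state.as_array() if isinstance(state, PopulationState) else np.asarray(state, float)
    if abs(y.sum() - 1.0) > 1e-6:
        raise ValueError(f"state off the simplex: sum={y.sum()}")
    pi = np.asarray(payoffs, dtype=float)
    if not np.all(np.isfinite(pi)):
        raise ValueError("payoffs must be finite")
    phi = float(y @ pi)
    return y * (pi - phi)


def integrate_dynamics(
    state0: PopulationState,
    payoffs,
    horizon: float = 500.0,
    rtol: float = 1e-8,
    n_report: int = 201,
):
    """Integrate the replicator ODE; returns ``(t, Y)`` with Y rows on the simplex.

    ``payoffs`` is either a length-3 sequence (frequency-independent case) or a
    callable ``payoffs(y) -> (pi_F, pi_P, pi_S)``.
    """
    if callable(payoffs):
        fn = payoffs
    else:
        const = np.asarray(payoffs, dtype=float)
        fn = lambda y: const  # noqa: E731

    def rhs(_t, y):
        pi = np.asarray(fn(y), dtype=float)
        if not np.all(np.isfinite(pi)):
            raise ValueError("payoffs must be finite")
        return y * (pi - y @ pi)

    t_eval = np.linspace(0.0, horizon, n_report)
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        state0.as_array(),
        method="LSODA",
        rtol=rtol,
        atol=1e-12,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    Y = sol.y.T
    drift = np.abs(Y.sum(axis=1) - 1.0)
    if drift.max() > _SIMPLEX_TOL:
        Y = Y / Y.sum(axis=1, keepdims=True)
    return sol.t, Y


def optimal_S(
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    xtol: float = 1e-8,
) -> tuple[float, float]:
    """Optimal recruitment intensity u_D* of the S strategy and its payoff.

    Bounded maximization of ``pi_minus^S(u_D)`` over ``[0, u_B + 2/rho_a + 1]``
    (widened by the inverse mean intensity so the activation ramp is reachable
    under distributed stimuli), with an 11-point pre-scan against local optima.
    """
    scale = 1.0 / min(1.0, env.intensity.mean)
    hi = (cog.u_B + 2.0 / cog.rho_a + 1.0) * scale
    grid = np.linspace(0.0, hi, 33)
    vals = pi_observer_S(env, cog, pay, u_D=grid)
    k = int(np.argmax(vals))
    lo_b = grid[max(k - 1, 0)]
    hi_b = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda u: -pi_observer_S(env, cog, pay, u_D=u),
        bounds=(lo_b, hi_b),
        method="bounded",
        options={"xatol": xtol},
    )
    u_star = float(res.x)
    best = float(-res.fun)
    if vals[k] > best:  # degenerate flat objective; keep the scan point
        u_star, best = float(grid[k]), float(vals[k])
    return u_star, best


def observer_payoffs(
    env: EnvironmentParams, cog: CognitiveParams, pay: PayoffParams
) -> dict[str, float]:
    """As-observer payoffs (pi_minus^F, pi_minus^P, pi_minus^S*) and u_D*."""
    pb = p_B(env, cog)
    u_star, pi_S = optimal_S(env, cog, pay)
    return {
        "pi_F": pi_observer_F(env, cog, pay, pb),
        "pi_P": pi_observer_P(env, cog, pay, pb),
        "pi_S": pi_S,
        "u_D_star": u_star,
    }


def classify_dominant(
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    tie_tol: float = 1e-9,
) -> str:
    """Label of the strategy with the highest as-observer payoff (S at its optimum).

    Returns 'tie' when the top two payoffs differ by less than ``tie_tol``
    relative to their magnitude.
    """
    po = observer_payoffs(env, cog, pay)
    pis = np.array([po["pi_F"], po["pi_P"], po["pi_S"]])
    order = np.argsort(pis)[::-1]
    top, second = pis[order[0]], pis[order[1]]
    scale = max(abs(top), 1e-300)
    if (top - second) / scale < tie_tol:
        return "tie"
    return STRAT_LABELS[order[0]]


STRAT_LABELS = ("F", "P", "S")


def phase_diagram(
    grid: SweepGrid,
    env_base: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
) -> SweepGrid:
    """Evaluate dominance over a (t_bar, p) grid.

    ``lambda_e`` is set per cell from ``t_bar = 1/(lambda_e + lambda_d)`` with
    ``lambda_d`` taken from ``env_base`` (cells with ``t_bar > 1/lambda_d`` are
    infeasible and rejected).  Returns the grid with a long-format table
    (t_bar, p, pi_F, pi_P, pi_S, u_D_star, dominant).
    """
    if np.any(grid.t_bar > 1.0 / env_base.lambda_d + 1e-12):
        raise ValueError("t_bar exceeds 1/lambda_d: lambda_e would be negative")
    rows = []
    for tb in grid.t_bar:
        lam_e = 1.0 / tb - env_base.lambda_d
        for p in grid.p:
            env = replace(env_base, lambda_e=max(lam_e, 0.0), p=float(p))
            po = observer_payoffs(env, cog, pay)
            pis = np.array([po["pi_F"], po["pi_P"], po["pi_S"]])
            order = np.argsort(pis)[::-1]
            scale = max(abs(pis[order[0]]), 1e-300)
            label = (
                "tie"
                if (pis[order[0]] - pis[order[1]]) / scale < 1e-9
                else STRAT_LABELS[order[0]]
            )
            rows.append(
                {
                    "t_bar": float(tb),
                    "p": float(p),
                    "pi_F": po["pi_F"],
                    "pi_P": po["pi_P"],
                    "pi_S": po["pi_S"],
                    "u_D_star": po["u_D_star"],
                    "dominant": label,
                }
            )
    return SweepGrid(t_bar=grid.t_bar, p=grid.p, table=pd.DataFrame(rows))
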