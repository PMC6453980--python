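"""Cognitive building blocks of the mind-reading model.

An individual's behaviour is built from symbolic *representations* — pairs of a
referent (a stimulus or action, tagged as-actor ``+i`` or as-observer ``-i``)
and a nonnegative activation *intensity* ``x`` — connected by stochastic
cognitive functions:

perception   s -> s_hat         succeeds with probability ``gamma``
learning     s_hat -> a_hat     succeeds with probability l(x, t_e)
activation   a_hat -> a         executed with probability alpha(x)
simulation   s_hat(-i) -> s_hat(+i)   recruits the as-actor network at
                                      intensity ``u_D * x`` (prob. ``gamma_s``),
             a_hat(+i) -> a_hat(-i)   mapped back to a social response with
                                      probability ``gamma_a``

Two activation models are supported: a steep sigmoid (smooth inhibition
threshold at ``u_B``) and an exactly piecewise step-linear variant that is 0 at
and below ``u_B`` and 1 at and above ``u_B + 1/rho_a``.  In the step-linear
model the intensity-accuracy of learning is the capped identity ``min(x, 1)``;
in the sigmoid model it is the saturating curve ``1 - exp(-rho_l * x)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "CognitiveParams",
    "Representation",
    "perceive_prob",
    "learn_prob",
    "learning_accuracy",
    "activation",
    "rho_a_for_zero_leak",
    "simulate_intensity",
]

ActivationKind = Literal["sigmoid", "step_linear"]


@dataclass(frozen=True)
class Representation:
    """A (referent, intensity) pair; ``role`` is 'as_actor' or 'as_observer'."""

    referent: int
    role: str
    intensity: float

    def __post_init__(self) -> None:
        if self.role not in ("as_actor", "as_observer"):
            raise ValueError(f"role must be 'as_actor' or 'as_observer', got {self.role!r}")
        if self.intensity < 0:
            raise ValueError("intensity must be nonnegative")


@dataclass(frozen=True)
class CognitiveParams:
    """Parameters of the cognitive functions plus the evolvable traits.

    Parameters
    ----------
    gamma :
        Probability a stimulus is perceived as its correct representation.
    gamma_s, gamma_a :
        Efficiencies of the two simulation maps (cue -> as-actor stimulus,
        as-actor action -> social response).  Fixed parameters.
    rho_l :
        Scale of the intensity dependence of learning accuracy.
    rho_a :
        Steepness of the activation function.  For the sigmoid the exponent is
        ``-rho_a * (x - u_B) / u_B``, so ``rho_a = 13.8155`` pins the leak at
        zero intensity to ``alpha(0) = 1e-6`` for every ``u_B > 0``.
    lambda_l :
        Learning rate per unit of experience time.
    u_B :
        Inhibition threshold of the activation function (evolvable trait).
    u_D :
        Simulation intensity — the extent to which the as-actor network is
        recruited during observation (evolvable trait).
    activation_kind :
        ``"sigmoid"`` or ``"step_linear"``.
    """

    gamma: float = 1.0
    gamma_s: float = 1.0
    gamma_a: float = 1.0
    rho_l: float = 5.0
    rho_a: float = 13.8155
    lambda_l: float = 50.0
    u_B: float = 0.3
    u_D: float = 0.5
    activation_kind: ActivationKind = "sigmoid"

    def __post_init__(self) -> None:
        for name in ("gamma", "gamma_s", "gamma_a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("rho_l", "rho_a", "lambda_l"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0.0 <= self.u_B <= 1.0:
            raise ValueError(f"u_B must lie in [0, 1], got {self.u_B}")
        if self.u_D < 0:
            raise ValueError(f"u_D must be nonnegative, got {self.u_D}")
        if self.activation_kind not in ("sigmoid", "step_linear"):
            raise ValueError(f"unknown activation_kind {self.activation_kind!r}")
        if self.activation_kind == "sigmoid" and self.u_B == 0:
            raise ValueError("sigmoid activation requires u_B > 0 (exponent undefined at 0)")

    def with_traits(self, u_D: float | None = None, u_B: float | None = None) -> "CognitiveParams":
        kw = {}
        if u_D is not None:
            kw["u_D"] = float(u_D)
        if u_B is not None:
            kw["u_B"] = float(u_B)
        return replace(self, **kw)


def perceive_prob(params: CognitiveParams) -> float:
    """Probability that a stimulus maps to its correct representation (gamma)."""
    return params.gamma


def learn_prob(x, t_e, params: CognitiveParams):
    """Probability the learning function associates the correct action.

    ``l(x, t_e) = (1 - exp(-rho_l x)) * (1 - exp(-lambda_l t_e))`` —
    increasing both in the representation intensity ``x`` and in the
    experience time ``t_e``.
    """
    x = np.asarray(x, dtype=float)
    t_e = np.asarray(t_e, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensity x must be nonnegative")
    if np.any(t_e < 0):
        raise ValueError("experience time t_e must be nonnegative")
    out = -np.expm1(-params.rho_l * x) * -np.expm1(-params.lambda_l * t_e)
    return float(out) if out.ndim == 0 else out


def learning_accuracy(x, params: CognitiveParams):
    """Asymptotic (experience-saturated) accuracy l_x(x) of the learned map.

    Sigmoid model: ``1 - exp(-rho_l x)``; step-linear model: ``min(x, 1)``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensity x must be nonnegative")
    if params.activation_kind == "step_linear":
        out = np.clip(x, 0.0, 1.0)
    else:
        out = -np.expm1(-params.rho_l * x)
    return float(out) if out.ndim == 0 else out


def activation(x, params: CognitiveParams):
    """Probability alpha(x) that a primed action representation is executed.

    Sigmoid: ``(1 + exp(-rho_a (x - u_B)/u_B))^-1``.
    Step-linear: 0 for ``x <= u_B``, ``rho_a (x - u_B)`` on the middle branch,
    1 for ``x >= u_B + 1/rho_a``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensity x must be nonnegative")
    if params.activation_kind == "step_linear":
        out = np.clip(params.rho_a * (x - params.u_B), 0.0, 1.0)
    else:
        if params.u_B <= 0:
            raise ValueError("sigmoid activation requires u_B > 0")
        z = -params.rho_a * (x - params.u_B) / params.u_B
        # clip the exponent to avoid overflow; alpha saturates anyway
        out = 1.0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))
    return float(out) if out.ndim == 0 else out


def rho_a_for_zero_leak(target: float) -> float:
    """Steepness rho_a such that the sigmoid leak at zero intensity equals ``target``.

    At ``x = 0`` the exponent reduces to ``+rho_a`` independently of ``u_B``,
    so ``alpha(0) = (1 + e^{rho_a})^{-1} = target`` gives
    ``rho_a = ln(1/target - 1)``.  Requires ``0 < target < 0.5``.
    """
    if not 0.0 < target < 0.5:
        raise ValueError(f"target leak must lie in (0, 0.5), got {target}")
    return math.log(1.0 / target - 1.0)


def simulate_intensity(x, params: CognitiveParams):
    """Intensity ``u_D * x`` at which the as-actor network is recruited.

    The referent mapping succeeds with probability ``gamma_s`` and the
    downstream action-to-response map with probability ``gamma_a``; those
    probabilities are applied by the fitness layer, not here.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensity x must be nonnegative")
    out = params.u_D * x
    return float(out) if out.ndim == 0 else out
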