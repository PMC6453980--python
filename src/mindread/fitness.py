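"""Expected outcome probabilities and fitness components of the three strategies.

Pairwise interactions: at each moment an individual is an unpaired actor with
probability ``1 - 2p`` or paired with probability ``2p`` (then actor or
observer with equal chance).  An actor responds to an environmental stimulus;
an observer responds to the actor using its mind-reading strategy:

F  (fixed)        an evolved cue -> response map, correct only while the
                  environment is still in the state it was shaped for;
P  (associative)  a map learned from social experience, accruing at rate
                  ``p * lambda_l``;
S  (simulative)   recruits the observer's own as-actor network at intensity
                  ``u_D * x`` and inhibits the primed as-actor action through
                  the activation function — failed inhibition produces the
                  actor's own action, i.e. accidental coordination C.

Residence times in an environmental state are Exp(lambda_d + lambda_e), which
turns every learning curve into the simple saturating ratios below.  Fitness is
the payoff-weighted expectation of the five outcome classes B, no-act, D, 0, C
(Table-1-style dis-coordination payoffs: D is best for the observer, C is
always worse than doing nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cognitive import CognitiveParams, activation, learning_accuracy

__all__ = [
    "PayoffParams",
    "IntensityModel",
    "EnvironmentParams",
    "ResponseProfile",
    "StrategyType",
    "STRATEGIES",
    "effective_psi",
    "p_B",
    "s_conditional_rates",
    "pi_observer_F",
    "pi_observer_P",
    "pi_observer_S",
    "total_fitness",
    "coordination_upper_bound",
    "response_profile",
]

STRATEGIES = ("F", "P", "S")


@dataclass(frozen=True)
class StrategyType:
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in STRATEGIES:
            raise ValueError(f"strategy kind must be one of {STRATEGIES}, got {self.kind!r}")


@dataclass(frozen=True)
class PayoffParams:
    """Dis-coordination game payoffs.

    ``b``: actor's payoff for its best response B.  ``d_minus``: observer's
    payoff for the informed response D; ``d_plus``: the cost D imposes on the
    actor.  ``c_minus``: observer's cost of coordinating (C); ``c_plus``: the
    benefit C confers on the actor.  The (C, no-act) and all 0/no-act cells pay
    zero.
    """

    b: float = 1.0
    d_minus: float = 5.0
    d_plus: float = 5.0
    c_minus: float = 3.0
    c_plus: float = 3.0

    def assert_dilemma(self) -> None:
        """Check the conservative ordering: D best for the observer, C worse than 0."""
        if not (self.d_minus > 0.0 > -self.c_minus):
            raise ValueError(
                "dis-coordination ordering violated: need d_minus > 0 and c_minus > 0"
            )


_QUAD_CACHE: dict = {}


@dataclass(frozen=True)
class IntensityModel:
    """Distribution of stimulus intensities x.

    ``kind='point'``: all stimuli have intensity ``mean`` (sd ignored).
    ``kind='truncnorm'``: normal(mean, sd) truncated to x > 0 and
    renormalized; expectations use fixed 64-node Gauss-Legendre quadrature on
    [0, mean + 8 sd].
    """

    kind: str = "point"
    mean: float = 1.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("point", "truncnorm"):
            raise ValueError(f"intensity kind must be 'point' or 'truncnorm', got {self.kind!r}")
        if self.mean <= 0:
            raise ValueError("intensity mean must be positive")
        if self.kind == "truncnorm" and self.sd <= 0:
            raise ValueError("truncnorm intensity requires sd > 0")

    def nodes_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Quadrature nodes and probability weights (weights sum to 1)."""
        key = (self.kind, self.mean, self.sd)
        hit = _QUAD_CACHE.get(key)
        if hit is not None:
            return hit
        if self.kind == "point":
            out = np.array([self.mean]), np.array([1.0])
        else:
            lo, hi = 0.0, self.mean + 8.0 * self.sd
            t, w = np.polynomial.legendre.leggauss(64)
            x = 0.5 * (hi - lo) * t + 0.5 * (hi + lo)
            w = 0.5 * (hi - lo) * w
            pdf = np.exp(-0.5 * ((x - self.mean) / self.sd) ** 2)
            out = x, w * pdf / np.sum(w * pdf)
        _QUAD_CACHE[key] = out
        return out

    def expect(self, f) -> float:
        """E[f(x)] under the intensity distribution."""
        x, w = self.nodes_weights()
        return float(np.sum(w * np.asarray(f(x), dtype=float)))


@dataclass(frozen=True)
class EnvironmentParams:
    """Environment, pairing and population-heterogeneity parameters.

    ``lambda_e``: rate of environmental change; ``lambda_d``: death rate
    (time unit; default 1).  ``p``: pairing parameter in [0, 0.5].  ``psi``:
    probability two individuals differ in their response to a given stimulus;
    ``assort_w >= 1``: how much more often same-behaviour individuals interact
    (assortment partially masks psi).  ``intensity``: stimulus intensity model.
    """

    lambda_e: float = 9.0
    lambda_d: float = 1.0
    p: float = 0.05
    psi: float = 0.0
    assort_w: float = 1.0
    intensity: IntensityModel = field(default_factory=IntensityModel)

    def __post_init__(self) -> None:
        if self.lambda_e < 0:
            raise ValueError("lambda_e must be nonnegative")
        if self.lambda_d <= 0:
            raise ValueError("lambda_d must be positive")
        if not 0.0 <= self.p <= 0.5:
            raise ValueError(f"p must lie in [0, 0.5] (1-2p >= 0), got {self.p}")
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must lie in [0, 1]")
        if self.assort_w < 1.0:
            raise ValueError("assort_w must be >= 1")

    @property
    def lam(self) -> float:
        """Total residence-ending rate lambda_d + lambda_e."""
        return self.lambda_d + self.lambda_e

    @property
    def t_bar(self) -> float:
        """Mean time spent in a single environmental state."""
        return 1.0 / self.lam

    @property
    def psi_eff(self) -> float:
        return effective_psi(self.psi, self.assort_w)


@dataclass(frozen=True)
class ResponseProfile:
    """Expected probabilities of the five outcome classes for one strategy.

    ``P_B``/``P_noact`` are per actor interaction; ``P_D``/``P_0``/``P_C`` per
    paired observer interaction.
    """

    P_B: float
    P_noact: float
    P_D: float
    P_0: float
    P_C: float

    def __post_init__(self) -> None:
        for name in ("P_B", "P_noact", "P_D", "P_0", "P_C"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.P_B + self.P_noact > 1.0 + 1e-9:
            raise ValueError("P_B + P_noact exceeds 1")
        if self.P_D + self.P_0 + self.P_C > 1.0 + 1e-9:
            raise ValueError("P_D + P_0 + P_C exceeds 1")


def effective_psi(psi: float, assort_w: float = 1.0) -> float:
    """Post-assortment probability that an interaction partner differs.

    With weight ``w`` toward same-behaviour partners, the encounter odds of a
    differing partner shrink: ``psi_eff = psi / (psi + w (1 - psi))``.
    ``w = 1`` leaves psi unchanged.
    """
    if not 0.0 <= psi <= 1.0:
        raise ValueError("psi must lie in [0, 1]")
    if assort_w < 1.0:
        raise ValueError("assort_w must be >= 1")
    if psi == 0.0:
        return 0.0
    return psi / (psi + assort_w * (1.0 - psi))


def p_B(env: EnvironmentParams, cog: CognitiveParams) -> float:
    """Expected probability of the best actor response B.

    Expectation of the as-actor learning curve ``1 - exp(-lambda_l (1-p) t)``
    over the Exp(lambda_d + lambda_e) residence time:
    ``lambda_l (1-p) / (lambda_d + lambda_e + lambda_l (1-p))``.
    """
    rate = cog.lambda_l * (1.0 - env.p)
    return rate / (env.lam + rate)


def s_conditional_rates(
    env: EnvironmentParams, cog: CognitiveParams, u_D=None
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Per-(learned observer, informative actor) probabilities of D and C for S.

    Returns ``(q_D, q_C)`` where, conditional on the focal observer having
    learned its as-actor map and the observed actor responding informatively,

    ``q_D = gamma_s * gamma_a * (1 - psi_eff) * E_x[l(u_D x) (1 - alpha(u_D x))]``
    ``q_C = gamma_s * E_x[l(u_D x) alpha(u_D x)]``

    A wrong inference (probability psi_eff) forfeits D but still risks C: the
    recruited as-actor representation is executed whenever uninhibited.
    ``u_D`` may be an array (broadcast over the intensity quadrature).
    """
    if u_D is None:
        u_D = cog.u_D
    u_D = np.asarray(u_D, dtype=float)
    x, w = env.intensity.nodes_weights()
    y = u_D[..., None] * x  # (..., nodes)
    l = learning_accuracy(y, cog)
    a = activation(y, cog)
    q_D = cog.gamma_s * cog.gamma_a * (1.0 - env.psi_eff) * np.sum(w * l * (1.0 - a), axis=-1)
    q_C = cog.gamma_s * np.sum(w * l * a, axis=-1)
    if q_D.ndim == 0:
        return float(q_D), float(q_C)
    return q_D, q_C


def pi_observer_F(
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    p_B_partner: float,
) -> float:
    """As-observer payoff rate of the fixed strategy.

    ``(lambda_d / (lambda_d + lambda_e)) * P_B * d_minus`` — the first factor
    is the fraction of time spent in the single (natal) predictable state.
    """
    return env.lambda_d / env.lam * p_B_partner * pay.d_minus


def pi_observer_P(
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    p_B_partner: float,
) -> float:
    """As-observer payoff rate of the associative strategy.

    Social learning accrues at rate ``p * lambda_l``; inter-individual
    differences dilute the usable social exposure by ``1 - psi_eff``.
    """
    rate = env.p * cog.lambda_l * (1.0 - env.psi_eff)
    return rate / (env.lam + rate) * p_B_partner * pay.d_minus


def pi_observer_S(
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    p_B_focal: float | None = None,
    p_B_partner: float | None = None,
    u_D=None,
):
    """As-observer payoff rate of the simulative strategy.

    ``(q_D d_minus - q_C c_minus) * P_B_focal * P_B_partner`` with the
    conditional rates of :func:`s_conditional_rates`: the focal must have
    learned its own as-actor map and the observed actor must be responding
    informatively.  ``u_D`` may be an array for vectorized trait sweeps.
    """
    if p_B_focal is None:
        p_B_focal = p_B(env, cog)
    if p_B_partner is None:
        p_B_partner = p_B(env, cog)
    q_D, q_C = s_conditional_rates(env, cog, u_D=u_D)
    return (q_D * pay.d_minus - q_C * pay.c_minus) * p_B_focal * p_B_partner


def total_fitness(
    profile_focal: ResponseProfile,
    profile_partner: ResponseProfile,
    env: EnvironmentParams,
    pay: PayoffParams,
) -> float:
    """Total payoff rate ``(1-2p) pi_plus + p pi_minus + p pi_obs_actor``.

    ``pi_plus = P_B b`` (solitary actor); ``pi_minus = P_D d_minus - P_C
    c_minus`` (observer); ``pi_obs_actor = P_B b - P_D_partner d_plus +
    P_C_partner c_plus`` (actor being observed).
    """
    pi_plus = profile_focal.P_B * pay.b
    pi_minus = profile_focal.P_D * pay.d_minus - profile_focal.P_C * pay.c_minus
    pi_obs = (
        profile_focal.P_B * pay.b
        - profile_partner.P_D * pay.d_plus
        + profile_partner.P_C * pay.c_plus
    )
    return (1.0 - 2.0 * env.p) * pi_plus + env.p * pi_minus + env.p * pi_obs


def coordination_upper_bound(
    env: EnvironmentParams, pay: PayoffParams, cog: CognitiveParams
) -> float:
    """Upper bound on P_C compatible with S outcompeting the associative strategy.

    ``d_minus/(d_minus - c_minus) * (lambda_d+lambda_e)/(lambda_d+lambda_e +
    p lambda_l)``; requires ``d_minus > c_minus`` to be meaningful.
    """
    if pay.d_minus <= pay.c_minus:
        raise ValueError("coordination bound undefined unless d_minus > c_minus")
    return (
        pay.d_minus
        / (pay.d_minus - pay.c_minus)
        * env.lam
        / (env.lam + env.p * cog.lambda_l)
    )


def response_profile(
    strategy: str | StrategyType,
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    p_B_partner: float | None = None,
) -> ResponseProfile:
    """Expected outcome probabilities for one strategy in a monomorphic setting."""
    kind = strategy.kind if isinstance(strategy, StrategyType) else strategy
    if kind not in STRATEGIES:
        raise ValueError(f"unknown strategy {kind!r}")
    pb = p_B(env, cog)
    if p_B_partner is None:
        p_B_partner = pb
    if kind == "F":
        P_D = env.lambda_d / env.lam * p_B_partner
        P_C = 0.0
    elif kind == "P":
        rate = env.p * cog.lambda_l * (1.0 - env.psi_eff)
        P_D = rate / (env.lam + rate) * p_B_partner
        P_C = 0.0
    else:
        q_D, q_C = s_conditional_rates(env, cog)
        P_D = q_D * pb * p_B_partner
        P_C = q_C * pb * p_B_partner
    return ResponseProfile(
        P_B=pb,
        P_noact=1.0 - pb,
        P_D=P_D,
        P_0=1.0 - P_D - P_C,
        P_C=P_C,
    )
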