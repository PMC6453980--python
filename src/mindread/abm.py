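"""Stochastic agent-based counterpart of the deterministic model.

Finite populations of F/P/S agents interact in discrete time steps of length
``dt``.  Each step every agent is an unpaired actor (probability ``1 - 2p``)
or paired (``2p``, then actor or observer with equal chance); observers are
matched at random with paired actors.  Actors respond to a freshly drawn
stimulus intensity through perception, learning and activation; observers
respond to an informative actor according to their strategy.  Payoffs follow
the dis-coordination matrix (or its relatedness transform), and experience
clocks advance per environmental state.

Two reset processes reproduce the analytic model's exponential residence
times: a *global* environment switch at rate ``lambda_e`` (all per-state
experience is lost, the fixed strategy's natal mapping goes stale) and a
*per-agent* reset at rate ``lambda_d`` (experience cleared, natal state
re-anchored) standing in for individual turnover, so that the stationary
time-in-state is Exp(lambda_d + lambda_e) as in the deterministic model.
Reproduction is Wright-Fisher: at the end of each generation, offspring are
sampled proportionally to accumulated payoff (shifted positive), inherit
strategy and traits subject to mutation, and start with blank experience.

This module is a reconstruction: the update rules, population sizes and
mutation scheme are the package's own choices, designed to converge to the
deterministic expectations, not a transcription of any published simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cognitive import CognitiveParams
from .fitness import EnvironmentParams, PayoffParams
from .invasion import TraitPoint
from .kin import KinPayoffMatrix, transform_payoffs
from .replicator import observer_payoffs

__all__ = [
    "Agent",
    "ABMConfig",
    "ABMResult",
    "Population",
    "init_population",
    "step_interactions",
    "reproduce",
    "run",
    "monomorphic_profile",
    "validate_against_replicator",
]

STRAT_CODE = {"F": 0, "P": 1, "S": 2}
CODE_STRAT = {v: k for k, v in STRAT_CODE.items()}


@dataclass(frozen=True)
class Agent:
    """Read-only record view of one agent (the population itself is columnar)."""

    strategy: str
    traits: TraitPoint
    t_actor: float
    t_observer: float
    natal_ok: bool
    payoff: float


@dataclass(frozen=True)
class ABMConfig:
    """Simulation sizes and inheritance parameters (artifact plumbing)."""

    n_agents: int = 200
    generations: int = 100
    steps_per_generation: int = 400
    dt: float = 0.005
    mutation_rate: float = 0.0
    mutation_sd: float = 0.02
    strategy_mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("mutation_rate", "strategy_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Population:
    """Columnar population state."""

    strategy: np.ndarray  # int8 codes
    u_D: np.ndarray
    u_B: np.ndarray
    t_actor: np.ndarray
    t_obs: np.ndarray
    natal_ok: np.ndarray  # bool
    payoff: np.ndarray

    @property
    def n(self) -> int:
        return self.strategy.size

    def agent(self, i: int) -> Agent:
        return Agent(
            strategy=CODE_STRAT[int(self.strategy[i])],
            traits=TraitPoint(float(self.u_D[i]), float(self.u_B[i])),
            t_actor=float(self.t_actor[i]),
            t_observer=float(self.t_obs[i]),
            natal_ok=bool(self.natal_ok[i]),
            payoff=float(self.payoff[i]),
        )

    def frequencies(self) -> dict[str, float]:
        return {k: float(np.mean(self.strategy == c)) for k, c in STRAT_CODE.items()}


@dataclass
class ABMResult:
    """Per-generation strategy frequencies, mean traits and outcome counts."""

    freq: pd.DataFrame
    counts: pd.DataFrame
    config: ABMConfig = field(repr=False, default=ABMConfig())

    def final_majority(self) -> str:
        last = self.freq.iloc[-1]
        return max("FPS", key=lambda k: last[f"y_{k}"])


def init_population(
    n: int,
    strategy_fractions: dict[str, float],
    u_D: float,
    u_B: float,
    rng: np.random.Generator,
) -> Population:
    """Population with given strategy composition and common traits."""
    total = sum(strategy_fractions.values())
    counts = {k: int(round(n * v / total)) for k, v in strategy_fractions.items()}
    while sum(counts.values()) < n:
        counts[max(strategy_fractions, key=strategy_fractions.get)] += 1
    while sum(counts.values()) > n:
        counts[max(counts, key=counts.get)] -= 1
    codes = np.concatenate(
        [np.full(c, STRAT_CODE[k], dtype=np.int8) for k, c in counts.items()]
    )
    rng.shuffle(codes)
    return Population(
        strategy=codes,
        u_D=np.full(n, float(u_D)),
        u_B=np.full(n, float(u_B)),
        t_actor=np.zeros(n),
        t_obs=np.zeros(n),
        natal_ok=np.ones(n, dtype=bool),
        payoff=np.zeros(n),
    )


def _alpha(x: np.ndarray, u_B: np.ndarray, cog: CognitiveParams) -> np.ndarray:
    if cog.activation_kind == "step_linear":
        return np.clip(cog.rho_a * (x - u_B), 0.0, 1.0)
    z = np.clip(-cog.rho_a * (x - u_B) / u_B, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def _lx(x: np.ndarray, cog: CognitiveParams) -> np.ndarray:
    if cog.activation_kind == "step_linear":
        return np.clip(x, 0.0, 1.0)
    return -np.expm1(-cog.rho_l * x)


def _draw_intensity(model, size: int, rng: np.random.Generator) -> np.ndarray:
    if model.kind == "point":
        return np.full(size, model.mean)
    # truncated normal on x > 0 by resampling
    x = rng.normal(model.mean, model.sd, size)
    bad = x <= 0
    while np.any(bad):
        x[bad] = rng.normal(model.mean, model.sd, int(bad.sum()))
        bad = x <= 0
    return x


def step_interactions(
    pop: Population,
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    rng: np.random.Generator,
    dt: float = 0.005,
    kin: KinPayoffMatrix | None = None,
    counts: dict[str, int] | None = None,
) -> dict[str, int]:
    """Advance one time step: roles, responses, payoffs, learning, resets.

    Returns (and accumulates into ``counts``) the outcome tally with keys
    B / noact / actor_n (actor side) and D / zero / C / obs_n (matched
    observer side).  The population is updated in place.
    """
    if counts is None:
        counts = {k: 0 for k in ("B", "noact", "actor_n", "D", "zero", "C", "obs_n")}
    mat = kin if kin is not None else transform_payoffs(pay, 0.0)
    _step(pop, env, cog, mat, dt, rng, counts)
    return counts


def _step(
    pop: Population,
    env: EnvironmentParams,
    cog: CognitiveParams,
    mat: KinPayoffMatrix,
    dt: float,
    rng: np.random.Generator,
    counts: dict[str, int],
    pay_b_solitary: float | None = None,
) -> None:
    n = pop.n
    p = env.p

    # Per-agent state refresh at rate lambda_e: environmental states are
    # uncorrelated, and what matters per agent is whether its learned mapping
    # is stale.  Independent clocks keep partners' learning states independent,
    # matching the mean-field factorization of the analytic expectations.
    switch = rng.random(n) < -math.expm1(-env.lambda_e * dt)
    pop.t_actor[switch] = 0.0
    pop.t_obs[switch] = 0.0
    pop.natal_ok[switch] = False
    reset = rng.random(n) < -math.expm1(-env.lambda_d * dt)
    pop.t_actor[reset] = 0.0
    pop.t_obs[reset] = 0.0
    pop.natal_ok[reset] = True

    # K actor-observer pairs with K ~ Binomial(N//2, 2p): every agent is
    # paired with probability 2p (actor or observer with equal chance, via the
    # random permutation) and the rest are unpaired actors
    perm = rng.permutation(n)
    m = int(rng.binomial(n // 2, 2.0 * p))
    ai = perm[:m]
    oi = perm[m : 2 * m]
    solitary = perm[2 * m :]
    acting = np.concatenate([solitary, ai])

    x = _draw_intensity(env.intensity, acting.size, rng)
    # midpoint convention: learning evaluated at the middle of the step
    lt = -np.expm1(-cog.lambda_l * (pop.t_actor[acting] + 0.5 * dt))
    p_b = cog.gamma * _lx(x, cog) * _alpha(x, pop.u_B[acting], cog) * lt
    did_b = rng.random(acting.size) < p_b

    # solitary successes earn b outside the (possibly kin-transformed) game;
    # matched actors start from the (0, B) cell and are adjusted below
    b_solo = mat.act_0 * (1.0 + mat.r) if pay_b_solitary is None else pay_b_solitary
    ns = solitary.size
    pop.payoff[solitary[did_b[:ns]]] += b_solo
    pop.payoff[ai[did_b[ns:]]] += mat.act_0
    counts["B"] += int(did_b.sum())
    counts["noact"] += int((~did_b).sum())
    counts["actor_n"] += int(acting.size)

    did_b_full = np.zeros(n, dtype=bool)
    did_b_full[acting] = did_b
    x_full = np.zeros(n)
    x_full[acting] = x

    obs = oi
    part = ai
    counts["obs_n"] += int(m)
    if m:
        informative = did_b_full[part]
        o = obs[informative]
        a = part[informative]
        xo = x_full[a]
        resp_d = np.zeros(o.size, dtype=bool)
        resp_c = np.zeros(o.size, dtype=bool)

        s = pop.strategy[o]
        is_f = s == STRAT_CODE["F"]
        is_p = s == STRAT_CODE["P"]
        is_s = s == STRAT_CODE["S"]

        resp_d[is_f] = pop.natal_ok[o[is_f]]
        if np.any(is_p):
            lp = -np.expm1(-cog.lambda_l * (pop.t_obs[o[is_p]] + 0.5 * dt))
            resp_d[is_p] = rng.random(int(is_p.sum())) < lp
        if np.any(is_s):
            osel = o[is_s]
            y = pop.u_D[osel] * xo[is_s]
            # the as-actor clock is idle while observing: no half-step
            own_learn = -np.expm1(-cog.lambda_l * pop.t_actor[osel])
            recruited = rng.random(osel.size) < cog.gamma_s * _lx(y, cog) * own_learn
            act = recruited & (rng.random(osel.size) < _alpha(y, pop.u_B[osel], cog))
            infer = recruited & ~act
            same = rng.random(osel.size) >= env.psi
            d_ok = infer & same & (rng.random(osel.size) < cog.gamma_a)
            tmp_d = np.zeros(o.size, dtype=bool)
            tmp_c = np.zeros(o.size, dtype=bool)
            tmp_d[is_s] = d_ok
            tmp_c[is_s] = act
            resp_d |= tmp_d
            resp_c |= tmp_c

        zero = ~resp_d & ~resp_c
        counts["D"] += int(resp_d.sum())
        counts["C"] += int(resp_c.sum())
        counts["zero"] += int(zero.sum()) + int((~informative).sum())

        pop.payoff[o[resp_d]] += mat.obs_D
        pop.payoff[o[zero]] += mat.obs_0
        pop.payoff[o[resp_c]] += mat.obs_C
        # matched actors already received act_0; adjust to the realized cell
        pop.payoff[a[resp_d]] += mat.act_D - mat.act_0
        pop.payoff[a[resp_c]] += mat.act_C - mat.act_0

    pop.t_actor[acting] += dt
    pop.t_obs[obs] += dt


def reproduce(
    pop: Population,
    rng: np.random.Generator,
    config: ABMConfig,
) -> Population:
    """Wright-Fisher resampling proportional to shifted accumulated payoff.

    Payoffs are shifted by the generation minimum plus 1e-6 so weights stay
    positive; equal payoffs therefore reduce to uniform resampling.  Offspring
    inherit strategy and traits (with optional Gaussian mutation on u_D,
    clipped at 0) and start with blank experience.
    """
    w = pop.payoff - pop.payoff.min() + 1e-6
    parents = rng.choice(pop.n, size=pop.n, p=w / w.sum())
    strategy = pop.strategy[parents].copy()
    u_D = pop.u_D[parents].copy()
    u_B = pop.u_B[parents].copy()
    if config.strategy_mutation_rate > 0:
        flip = rng.random(pop.n) < config.strategy_mutation_rate
        strategy[flip] = rng.integers(0, 3, int(flip.sum()), dtype=np.int8)
    if config.mutation_rate > 0:
        mut = rng.random(pop.n) < config.mutation_rate
        u_D[mut] = np.maximum(u_D[mut] + rng.normal(0.0, config.mutation_sd, int(mut.sum())), 0.0)
    n = pop.n
    return Population(
        strategy=strategy,
        u_D=u_D,
        u_B=u_B,
        t_actor=np.zeros(n),
        t_obs=np.zeros(n),
        natal_ok=np.ones(n, dtype=bool),
        payoff=np.zeros(n),
    )


def run(
    config: ABMConfig,
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    strategy_fractions: dict[str, float] | None = None,
    u_D: float | None = None,
    u_B: float | None = None,
    r: float = 0.0,
) -> ABMResult:
    """Run a full Wright-Fisher simulation; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    if strategy_fractions is None:
        strategy_fractions = {"F": 1 / 3, "P": 1 / 3, "S": 1 / 3}
    pop = init_population(
        config.n_agents,
        strategy_fractions,
        cog.u_D if u_D is None else u_D,
        cog.u_B if u_B is None else u_B,
        rng,
    )
    mat = transform_payoffs(pay, r)
    freq_rows = []
    count_rows = []
    for g in range(config.generations):
        counts = {k: 0 for k in ("B", "noact", "actor_n", "D", "zero", "C", "obs_n")}
        for _ in range(config.steps_per_generation):
            _step(pop, env, cog, mat, config.dt, rng, counts)
        f = pop.frequencies()
        freq_rows.append(
            {
                "generation": g,
                "y_F": f["F"],
                "y_P": f["P"],
                "y_S": f["S"],
                "mean_u_D": float(pop.u_D.mean()),
                "mean_u_B": float(pop.u_B.mean()),
            }
        )
        count_rows.append({"generation": g, **counts})
        pop = reproduce(pop, rng, config)
    return ABMResult(freq=pd.DataFrame(freq_rows), counts=pd.DataFrame(count_rows), config=config)


def monomorphic_profile(
    strategy: str,
    env: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    n_agents: int = 80,
    total_time: float = 400.0,
    dt: float = 0.005,
    burn_in: float = 10.0,
    n_blocks: int = 20,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Empirical outcome frequencies of one long monomorphic behavioural run.

    No reproduction: a single cohort interacts for ``total_time`` time units.
    Returns ``{quantity: (estimate, standard_error)}`` for P_B, P_D, P_C with
    standard errors from batch means over ``n_blocks`` time blocks (outcomes
    are correlated through the shared environmental state, so binomial errors
    would be optimistic).
    """
    rng = np.random.default_rng(seed)
    pop = init_population(n_agents, {strategy: 1.0}, cog.u_D, cog.u_B, rng)
    mat = transform_payoffs(pay, 0.0)
    steps = int(round(total_time / dt))
    burn_steps = int(round(burn_in / dt))
    block_len = max((steps - burn_steps) // n_blocks, 1)
    blocks: list[dict[str, int]] = []
    counts = {k: 0 for k in ("B", "noact", "actor_n", "D", "zero", "C", "obs_n")}
    taken = 0
    for i in range(steps):
        _step(pop, env, cog, mat, dt, rng, counts)
        if i >= burn_steps:
            taken += 1
            if taken % block_len == 0:
                blocks.append(counts)
                counts = {k: 0 for k in counts}
    if any(v for v in counts.values()):
        blocks.append(counts)

    def ratio(num: str, den: str) -> tuple[float, float]:
        vals = np.array(
            [b[num] / b[den] for b in blocks if b[den] > 0], dtype=float
        )
        return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(vals.size))

    return {
        "P_B": ratio("B", "actor_n"),
        "P_D": ratio("D", "obs_n"),
        "P_C": ratio("C", "obs_n"),
    }


def validate_against_replicator(
    cells,
    env_base: EnvironmentParams,
    cog: CognitiveParams,
    pay: PayoffParams,
    config: ABMConfig,
    n_replicates: int = 20,
    near_tie_rel: float = 0.05,
) -> pd.DataFrame:
    """Compare modal ABM fixation with analytic dominance at (t_bar, p) cells.

    The S strategy's u_D is set to its analytic optimum per cell.  Cells whose
    top-two analytic payoffs differ by less than ``near_tie_rel`` (relative)
    are flagged near ties and carry no agreement expectation.
    """
    from dataclasses import replace as _replace

    rows = []
    for t_bar, p in cells:
        lam_e = 1.0 / t_bar - env_base.lambda_d
        if lam_e < 0:
            raise ValueError("t_bar exceeds 1/lambda_d")
        env = _replace(env_base, lambda_e=lam_e, p=float(p))
        po = observer_payoffs(env, cog, pay)
        pis = sorted([po["pi_F"], po["pi_P"], po["pi_S"]], reverse=True)
        near_tie = (pis[0] - pis[1]) / max(abs(pis[0]), 1e-300) < near_tie_rel
        analytic = max(
            [("F", po["pi_F"]), ("P", po["pi_P"]), ("S", po["pi_S"])], key=lambda kv: kv[1]
        )[0]
        cog_cell = cog.with_traits(u_D=po["u_D_star"])
        wins: dict[str, int] = {"F": 0, "P": 0, "S": 0}
        for rep in range(n_replicates):
            cfg = ABMConfig(
                n_agents=config.n_agents,
                generations=config.generations,
                steps_per_generation=config.steps_per_generation,
                dt=config.dt,
                seed=config.seed + 1000 * rep + hash((round(t_bar, 6), round(p, 6))) % 997,
            )
            res = run(cfg, env, cog_cell, pay)
            wins[res.final_majority()] += 1
        modal = max(wins, key=wins.get)
        rows.append(
            {
                "t_bar": float(t_bar),
                "p": float(p),
                "analytic": analytic,
                "modal": modal,
                "wins_F": wins["F"],
                "wins_P": wins["P"],
                "wins_S": wins["S"],
                "near_tie": bool(near_tie),
                "match": bool(near_tie or modal == analytic),
            }
        )
    return pd.DataFrame(rows)
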