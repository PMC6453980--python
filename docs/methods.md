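# Methods

## Model overview and assumptions

The package studies the evolution of observer ("mind-reading") strategies in
a large population with pairwise interactions. Time is continuous; each
individual is an unpaired actor with probability `1 − 2p`, or paired
(actor/observer with equal chance) with probability `2p`. The environment is
a mapping from stimuli to best responses; it changes at rate `λ_e`,
individuals die at rate `λ_d` (the time unit; default 1), and environmental
states are uncorrelated, so the time available to learn any one state is
exponential with rate `λ = λ_d + λ_e`. Payoffs are additive; fitness is the
expected payoff rate over the three interaction roles (solitary actor,
observer, observed actor):

    π = (1 − 2p) π₊ + p π₋ + p π∓ .

The payoff structure is deliberately conservative against the simulative
strategy: the informed observer response D is strictly best for the observer
(`d⁻ > 0`), coordination C is strictly worse than doing nothing
(`−c⁻ < 0`), while C is the actor's best outcome (`+c⁺`) and D its worst
(`−d⁺`).

Cognition is a chain of stochastic maps with a single scalar intensity `x`
carried along: perception (prob. γ), learning
`l(x, t) = (1 − e^{−ρ_l x})(1 − e^{−λ_l t})`, and activation `α(x)`.
Averaging the learning curve over the exponential residence time gives the
closed-form response probabilities used throughout, e.g.
`P_B = λ_l(1−p) / (λ + λ_l(1−p))` for an actor (unit tests verify this
against direct quadrature). Two activation models are provided:

- **sigmoid** `α(x) = (1 + e^{−ρ_a (x − u_B)/u_B})⁻¹`, calibrated so that
  the leak at zero intensity is `α(0) = 10⁻⁶`, which fixes
  `ρ_a = ln(10⁶ − 1) ≈ 13.8155` independently of `u_B` (the exponent at
  `x = 0` is `+ρ_a` exactly). Note the `1/u_B` in the exponent: quoting the
  steepness of the *un-normalized* exponent `−ρ(x − u_B)` would give
  `ρ = ρ_a/u_B`; the two parametrizations describe the same curve.
- **step-linear** `α = 0` for `x ≤ u_B`, `ρ_a(x − u_B)` on
  `[u_B, u_B + 1/ρ_a]`, `1` above; paired with the capped-identity learning
  accuracy `l(x) = min(x, 1)`. This variant admits closed forms and exact
  gradient branches.

The simulative observer recruits its own as-actor representation at
intensity `u_D·x` (referent correct with prob. `γ_s`, back-mapping to a
social response with prob. `γ_a`; both fixed parameters). The intensity
dependence of the learned as-actor map is evaluated at the recruited
intensity, `l_x(u_D x) = 1 − e^{−ρ_l u_D x}` in the sigmoid model — the
x-dependent saturating form, which is the only reading consistent with the
learning function `l(x, t)` itself. Intensities are not clipped above 1
except where the step-linear learning branch caps them.

## Observer fitness and heterogeneity

Conditional on the focal observer having learned its as-actor map and the
observed actor responding informatively, the simulative outcome rates are

    q_D = γ_s γ_a (1 − ψ_eff) E_x[ l(u_D x) (1 − α(u_D x)) ]
    q_C = γ_s            E_x[ l(u_D x)      α(u_D x)  ]

and `π₋^S = (q_D d⁻ − q_C c⁻) · P_B^focal · P_B^partner`. The squared `P_B`
is read as focal × partner: the observer must have learned as an actor and
the partner must be acting informatively; in a monomorphic population both
equal the resident `P_B`. Inter-individual differences enter through ψ, the
probability that two individuals respond differently to the same stimulus: a
wrong simulative inference forfeits D but *still* risks C (an uninhibited
recruited representation is executed regardless of whether the inference was
right), so only the D term is scaled by `1 − ψ_eff`. For the associative
strategy the usable social exposure is thinned to `p λ_l (1 − ψ_eff)`.
Assortment toward same-behaviour partners with weight `w ≥ 1` masks
differences through the encounter odds, `ψ_eff = ψ / (ψ + w(1 − ψ))`.

Distributed stimulus intensities (truncated normal on `x > 0`, renormalized)
are integrated with fixed 64-node Gauss–Legendre quadrature on
`[0, mean + 8·sd]`; with `sd → 0` all expectations converge to the
point-mass evaluations (tested).

## Replicator layer

With a common threshold `u_B`, `P_B` is shared and the replicator dynamics
`dy^j/dt = y^j (π₋^j − φ₋)` are frequency independent: the strategy with the
largest as-observer payoff fixes (transcritical bifurcations only).
Dominance maps are therefore computed analytically from the payoffs —
`integrate_dynamics` (LSODA, rtol 1e−8, horizon 500) is kept for trajectory
plots and is cross-checked in the tests against the two-strategy logistic
closed form. The S entry is first optimized over `u_D` (bounded scalar
maximization, tolerance 1e−8, with a 33-point pre-scan against local
optima). "Behavioural complexity" is encoded purely as a division of `λ_l`
(learning rate inversely proportional to the number of stimuli); no explicit
stimulus multiplicity is modelled. Sweeps are parametrized by the mean
residence time `t̄ = 1/(λ_e + λ_d)` and `p`.

## Adaptive dynamics of the inhibition traits

For fixed `u_B` a mutant's growth rate depends only on its own `u_D`, so the
singular `u_D*` is the global maximum of `π₋^S(u_D)`, simultaneously ESS and
convergence stable. In the step-linear model the middle-branch stationarity
condition is linear and gives
`u_D* = max(u_B, u_B/2 + γ_a d⁻ / (2 ρ_a (γ_a d⁻ + c⁻)))`, additionally
clipped at `min(u_B + 1/ρ_a, 1)` because the learning accuracy caps at 1;
coordination survives at the optimum exactly when
`ρ_a < γ_a d⁻ / (u_B (γ_a d⁻ + c⁻))`. The published special case of this
root replaces `γ_a d⁻/(γ_a d⁻ + c⁻)` by the shorthand ratio `b/(b+c)`
(i.e. `γ_a = 1`, `b ≡ d⁻`, `c ≡ c⁻`); the general root is canonical here.
A dense-grid maximizer of the true piecewise objective serves as the
independent oracle in the tests (20 random parameter draws, agreement within
two grid steps on a 10⁵-point grid).

The `u_D` selection gradient is reported on the scale of the *conditional*
observer payoff (`q_D d⁻ − q_C c⁻`), i.e. with the positive `P_B` factors
divided out: zeros and signs are unchanged and the step-linear branches take
the exact values `+γ_a d⁻` (below `u_B`) and `−c⁻` (above the ramp). When
`u_B` itself evolves it also gates the individual's own actor responses, so
its gradient uses the total fitness with
`P_B(u_B) = T · γ E_x[l_x(x) α(x; u_B)]` (T the learning-time factor): the
false-negative cost on the actor side enters with weight `(1 − p)` against
the observer side's `p` and emerges rather than being hand-coded. Gradients
are central finite differences (step 1e−5; curvature step 1e−4); 1-D
singular points come from a sign scan plus Brent bisection, the 2-D point
from a trait-substitution walk (step 1e−3) polished by a Newton-type root
solve of the finite-difference gradient. Classification is local only (ESS:
negative second difference per trait; CS: negative gradient slope across
residents); no global uninvadability is claimed. Under the sigmoid the joint
(u_D, u_B) equilibrium retains `P_C > 0` — with the reference parameter set
about 1.6 % of paired observer interactions — and respects the analytic
bound `P_C < d⁻/(d⁻ − c⁻) · λ/(λ + p λ_l)`.

## Kin selection

Indirect benefits use an abstract assortment coefficient `r ∈ [0, 1]`: each
payoff is mixed with `r` times the partner's and normalized by `1 + r`. For
the evolution of `u_D` the transform collapses to effective observer payoffs
`d⁻_eff = (d⁻ − r d⁺)/(1 + r)` and `c⁻_eff = (c⁻ − r c⁺)/(1 + r)` (the
do-nothing cell `r b/(1+r)` is a u_D-independent baseline), which makes the
empathic-gradient condition exact: `d u_D*/dr > 0 ⟺ c⁺/c⁻ > d⁺/d⁻`.
`duD_dr` is nevertheless computed numerically two independent ways
(implicit differentiation of the payoff gradient, and re-solving `u_D*(r±δ)`
with δ = 1e−3), which agree to within 5 % in the tests. The observer's
optimal response D is held fixed as `r` varies (no re-optimization of the
action set). Because the sigmoid never reaches 1 exactly, "full
coordination" is operationalized as the gradient being nonnegative at
`u_D = (u_B + 6 u_B/ρ_a)/x̄` (activation > 0.997 at the mean intensity x̄);
bistability requires a convergence-stable interior point and a nonnegative
boundary gradient simultaneously. Regime maps default to the reference
environment's S-dominant cell (`t̄ = 0.1`, `p = 0.05`), since the kin
question presupposes a resident simulative population.

## Agent-based simulator

The ABM is the package's own reconstruction, designed to converge to the
deterministic expectations rather than to transcribe any published
simulation. Discrete steps of length `dt`; per step: (i) each agent's
per-state experience is refreshed at rate `λ_e` and reset (with natal-state
re-anchoring) at rate `λ_d`, so time-in-state is Exp(λ_d + λ_e) in
stationarity — the refresh clocks are *per agent and independent*, because
the analytic expectations are mean-field products and a single global
environment clock demonstrably correlates partners' learning states and
biases joint outcome frequencies upward; (ii) K ~ Binomial(N/2, 2p)
actor–observer pairs form (every agent paired with probability 2p, rest
unpaired actors); (iii) actors respond through perception × learning ×
activation with a freshly drawn intensity, observers respond per strategy,
and payoffs are credited from the (possibly relatedness-transformed) game
matrix. Learning clocks that are accruing during a step are evaluated at
mid-step (midpoint convention), which removes most of the O(dt)
discretization bias; the residual bias of the discrete chain converges
linearly in `dt` (verified directly against the continuous formulas).
Reproduction is Wright–Fisher on payoffs shifted by the generation minimum
plus 1e−6 (equal payoffs → uniform resampling; note the shift makes
selection strength depend on payoff spread), with Gaussian mutation on `u_D`
clipped at 0 and blank offspring experience (non-cultural inheritance).
Runs are bitwise reproducible for a fixed seed.

Validation sizes (chosen as a balance of statistical resolution and
simulation cost): fixation checks use N = 150, 60 generations of 200 steps
at dt = 0.01, 20 replicates per sweep cell; monomorphic frequency checks use
one cohort of 100 agents for 120 time units at dt = 0.0025, with standard
errors from 20-block batch means (outcomes are serially correlated through
the state clocks, so binomial errors would be optimistic); the
mutation–selection walk of mean `u_D` to its singular value uses N = 300 for
320 generations with mutation rate 0.3 and kernel sd 0.02.

## What the synthetic conditions do and do not show

All inputs are parameter configurations; there is no empirical data. The
reference configuration (u_B = 0.3, ρ_a = 13.8155, ρ_l = 5, λ_d = 1,
λ_l = 50, d⁻ = d⁺ = 5, c⁻ = c⁺ = 3, truncated-normal intensities with mean
0.5 and sd 0.1) and its documented variants (λ_l = 10 for higher behavioural
complexity; ψ = 0.5; assortment w = 2) define the conditions under which the
results are computed. Passing tests show internal consistency of the model
chain (closed forms ↔ numerical optimization ↔ stochastic simulation) under
exponential residence times, additive payoffs, a scalar intensity, and
mean-field pairing; they do not show that real nervous systems implement
these cognitive maps, that real payoffs are additive, or that empirical
contagion rates should match the ~0.5–2 % figure outside this parameter
neighbourhood.

## Numerical choices and degenerate inputs

Dominance ties are declared below 1e−9 relative payoff difference. The
sigmoid exponent is clipped at ±700 before exponentiation. The
`u_D` search interval is `[0, (u_B + 2/ρ_a + 1)/min(1, x̄)]`. Quadrature
nodes are cached per intensity model. `p = 0` disables all observer
channels; `u_D = 0` gives `π₋^S = 0` exactly; sigmoid activation with
`u_B = 0` is rejected at construction (undefined exponent); the coordination
bound is rejected when `d⁻ ≤ c⁻`. Boundary ties in the step-linear singular
point resolve toward the branch with the higher payoff (the closed form's
max/min composition does this implicitly).

## Known limitations

No frequency-dependent analysis of competing `u_B` values among non-S
strategies (with heterogeneous `P_B` the strategy competition can be
bistable; the ABM can exhibit it but no analytic machinery is provided). No
multi-state environment bookkeeping, no correlated environmental states, no
spatial structure, no lifetime strategy switching, no learning of γ_a, and
no explicit genetics behind `r`. The 2-D trait classification is local;
the ABM's update rules are one reasonable discretization among several.
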