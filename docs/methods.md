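# Methods

## The single-gene circuit

The TI circuit couples the target-specific siRNA pool `g` to the
repressive chromatin mark `h`:

    dg = ( I(t) + V·g^n/(k1^n + g^n) · k2/(k2 + h) − γ1·g ) dt + σ1·g·dW1
    dh = ( ψ·g/(k3 + g) − γ2·h ) dt + σ2·h·dW2

Concentrations are in arbitrary units (AU), rates in hr⁻¹. The
amplification term is cooperative (`n > 1`) and saturating, and is
inhibited by `h`; mark deposition saturates in `g`; γ1, γ2 represent
dilution by growth and reproduction, the dominant loss process on the
transgenerational timescale. Multiplicative noise (`σ·state·dW`)
keeps the exact process non-negative; the Euler–Maruyama discretisation
can still cross zero, so states are clipped at 0 after each step — the
clip removes a discretisation artifact, not probability mass of the
exact process.

**Phase-plane structure.** With `I = 0` the g-nullclines are `g = 0`
and `h = k2·(V·g^{n−1}/(γ1·(g^n + k1^n)) − 1)`, a unimodal curve with
extremum at `g = (n−1)^{1/n}·k1`; the h-nullcline
`h = (ψ/γ2)·g/(k3+g)` saturates at `ψ/γ2`. Fixed-point finding is
reduced to one dimension by substituting the explicit h-nullcline into
`dg/dt` and locating roots in `g`; the residual is partitioned into
monotone pieces at its interior extrema before bracketing, so
nearly-tangent root pairs close to the saddle-node are resolved (g
tolerance 1e-10). The bifurcation in `V` is located by bisection on
the fixed-point count (relative tolerance 1e-8); the coalescence
location is the midpoint of the merging pair evaluated just above
`V_crit`, and the per-gene cost there is `c_crit = g_crit`.

At the coalescence point the Jacobian has one eigenvalue numerically
indistinguishable from 0 (the slow direction). The fast eigenvalue
equals the full trace `∂g(dg/dt) − γ2`; for the shipped defaults it is
−γ2/2 rather than −γ2 because the g-direction diagonal term is not
negligible there. Tests assert the exact zero mode and check the fast
mode against −γ2 only to within a factor of about two.

**Default parameters.** The regime structure of the circuit is what
matters — monostable / critical / bistable relative to `V_crit` — not
absolute rate values. The package ships a dimensionless default set

    n = 2, k1 = k2 = k3 = 1 AU, ψ = 1, γ1 = γ2 = 0.1 hr⁻¹,
    σ1 = σ2 = 0.05 hr^{-1/2}

for which `V_crit = 1.0762`, `(g_crit, h_crit) = (0.579, 3.668)`, and a
helper `calibrate_to_critical(params, offset)` that places `V` at a
chosen relative distance from the bifurcation. γ ≈ 0.1 hr⁻¹ makes
dilution act on the scale of days, fast within a 72-hour generation;
`σ = 0.05` is an exploratory single-gene default (see the competition
section for the smaller value used there).

**Integration.** Forward Euler (deterministic) or Euler–Maruyama
(stochastic) with `dt = 0.1` hr throughout; generations are 72 hr, and
the generation index is `floor(t/72)`. A gene or worm counts as
silenced while `s = √(g² + h²) > s_silenced`, with `s_silenced = 1` AU
by default (the threshold value is a package choice, configurable; the
`s > s_select = 3` threshold marks *strong* silencing for directed
selection). De-silencing is the first time `s` drops below the
threshold after having been above it. Non-finite states abort with the
offending step reported.

## Normal form and timing theory

Near the bifurcation the dynamics reduce to `dx = (x² − μ)dt + σdW`,
`μ ∝ V − V_crit`. Implemented closed forms:

* deterministic ghost delay `T = ∫dx/(x²−μ) = π/√|μ|` (μ < 0, full
  line); finite integration bounds use the arctan antiderivative;
* Kramers escape `T = (π/√μ)·exp(8μ^{3/2}/(3σ²))` (μ > 0), from the
  cubic potential `Φ = −x³/3 + μx`;
* the Airy interpolation
  `T = 2^{1/3}π²σ^{−2/3}(Ai²[2^{2/3}ξ] + Bi²[2^{2/3}ξ])`,
  `ξ = μσ^{−4/3}`, valid for either sign of μ. For `2^{2/3}ξ > 4` the
  `Bi²` term is evaluated in log space via the scaled Airy functions to
  avoid overflow (`log_airy_time` is exact up to the negligible `Ai²`
  correction, which is included via `log1p`);
* OU statistics around the silenced state `x = −√μ`:
  `var = σ²/(4√μ)`, autocorrelation `exp(−2√μ·lag)`.

**Absorbed simulation.** De-silencing is modelled as an absorbing
boundary at `x_max` with capped drift and tapered noise:

    dx = min(x² − μ, γ(x_max − x)) dt + σ(1 − x/x_max) dW.

Both the capped drift and the tapered noise vanish exactly at `x_max`,
so the boundary is approached only asymptotically; absorption is
declared at `0.99·x_max`, which adds a bounded `O(1/γ)·log` relaxation
tail to each passage time. "x0 → −∞" is operationalised as a finite
start far below the ghost (the far-tail contribution to the delay is
`O(1/|x0|)`). The default censoring horizon is 50× the Airy
prediction; non-absorbed paths are flagged right-censored, never
dropped. When comparing simulated mean passage times against the Airy
law, use `γ` large enough that the boundary tail is small relative to
the critical-region passage.

**Duration distributions under parameter variation.** With
`μ ~ Gaussian(mean, b)` restricted to the monostable side and
`T = a|μ|^{−1/2}`, the change of variables gives
`Pr(T) = F(−a²/T²)·2a²/T³`, integrating to the monostable mass of F
and scaling as `T^{−3}` at large T. On the bistable side with
`T = A·exp(Bμ^{3/2})` the survival function is
`S(T) = G(T)/G(T_min)` with
`G ∝ u·E_{1/2}(u²/2b²)`, `u = (ln(T/A)/B)^{2/3}`; the generalized
exponential integral of order 1/2 is evaluated through
`E_{1/2}(x) = √(π/x)·erfc(√x)`, under which `S` reduces exactly to an
erfc ratio — identical to the direct Monte-Carlo survival of the delay
law, which confirms the reading of the order-1/2 integral. The
survival law requires `T_min ≥ A`.

## Population and selection

Each generation, `n_worms` (default 250) worms evolve independently for
72 hr; every offspring inherits its mother's end-of-generation (g, h)
unchanged. The next generation samples mothers with replacement from
all worms (random selection) or from worms with `s > s_select`
(directed selection). Directed selection with no eligible mothers is
recorded as an extinction event, not an exception. The population
silencing duration is the first generation at which the silenced
fraction falls below 50% (threshold exposed as configuration);
per-lineage durations are first de-silencing events along
mother–daughter chains silenced in every prior generation. Sister
experiments start all sisters from one mother state; the uniformity
statistic is the across-sister standard deviation of the de-silencing
generation. `duration_ensemble` runs selection-free independent
lineages with optional per-lineage `V` (Gaussian variation around
`V_crit` produces the heavy-tailed duration distribution).

Randomness is organised as one `SeedSequence([master_seed, generation,
stream])` per generation, with worm *i* consuming column *i* of the
vectorised draws — replay is bit-exact and independent of execution
order.

## Competition (TIC)

Active genes share capacity through `V_eff = V_tot / max(C, C_min)`,
`C = Σgᵢ`, recomputed every Euler–Maruyama step. Arrivals occur at
generation boundaries — `Binomial(N − M, q)` in finite-N mode (only
unsilenced genes are eligible) or `Poisson(λ)` in the large-N limit —
and are injected at `(g, h) = (3, 0)`. Genes retire at the step where
`s < s_silenced`; the log keeps both the integer generation count
(arrival and retirement generations) and the continuous residence in
hours. Steady-state summaries use the continuous residence: Little's
law `M = λT` holds for time-in-system, and rounding durations up to
whole generations would bias `T` by about half a generation, which is
material when `T` is ~10 generations. The cost floor
`C_min = c_crit/10` keeps the empty pool bistable without dividing by
zero. Burn-in (default the first 20% of generations, raised for
slow-filling configurations) is discarded; a Kendall-τ trend screen on
M over the analysis window warns about non-stationarity.

**Noise level.** The competition simulations use
`σ1 = σ2 = 0.005` (exposed as `TIC_SIGMA`), smaller than the
single-gene exploratory default: de-silencing should be dominated by
the slow saddle-node ghost passage, not by noise-driven escape from a
deep well. At this level the stationary `V_eff` parks within ~1–2% of
`V_crit` and the closed forms `T = V_tot/(λ·c_crit·V_crit)`,
`M = V_tot/(c_crit·V_crit)` hold to ~10–15%; the residual offset comes
from the stable-state cost exceeding `c_crit` by
`O(√(V_eff − V_crit))` plus the transit cost of newly injected genes.

**Feedback variants.** The cost-normalised rule is the algebraic
baseline. `proportional-ODE` integrates `dV = γ_V(V_tot − C·V)dt` and
matches the baseline when `γ_V·C·dt ≪ 1` with `1/(γ_V·C)` much shorter
than a generation (Euler stability bounds `γ_V` above).
`integral-ODE` integrates `dV = γ_V(V_tot − C)dt`; its stationarity
requires `⟨C⟩ = V_tot`. The integrator plus the queue's lag form an
oscillatory loop, so the capacity is initialised at `V_crit` (avoiding
an enormous cold-start load) and small gains with long averaging
windows are needed; with the shipped test configuration
(`V_tot = 150, λ = 10, γ_V = 0.001`) the time-averaged cost balances
the budget to within ~10% and `V` hovers within ~5% of `V_crit`.
`feedforward` slaves the budget to the arrival rate, `V_tot = ηλ`,
which cancels λ from the duration: `T = η/(c_crit·V_crit)`.

**Perturbation response.** After a step in `V_tot`, relaxation of M is
measured as the first generation at which the step response has covered
90% of the gap to the new closed-form level (one-sided: transient
under/overshoot past the target counts as arrived, because down-steps
overshoot by design). Down-steps shed the excess within ~1 generation
— the transiently monostable genes lose `g` at the dilution rate, with
retirement lagging one generation while `h` decays — while up-steps
refill at the arrival rate, taking of order `ΔM/λ` generations; the
asymmetry between the two is the fast-loss / slow-recovery signature.

**Per-gene variation.** Per-gene budgets `V_tot,i ~ Gaussian(V_tot, b)`
are drawn at arrival; each gene is driven by `V_tot,i / C`. Summaries
report the arrival-averaged effective capacity, the residence-weighted
capacity of silenced genes, and the fraction of arrivals retired within
one generation (the monostable-excluded subgroup). As `b` grows the
silenced subgroup stays near `V_crit` while the overall average drifts
below it.

## pUGylation extension

The four-variable per-gene circuit adds template mRNA `u` and
pUG-tagged templates `y`:

    dg = ( I + V_eff·y − γ1 g ) dt + σ1 g dW
    dh = ( ψ·g/(g + k3) − γ2 h ) dt + σ2 h dW      (ψ = 1 by default, as printed)
    du = ( k2/(h + k2) − γ3 u ) dt + σ3 u dW
    dy = ( (gu)^n/(k1^n + (gu)^n) − γ4 y ) dt + σ4 y dW

with the same shared-capacity normalisation `V_eff = V_tot/Σgᵢ` and
arrival/retirement protocol. The amplification term is read as
`V_eff · yᵢ` (capacity normalised by total siRNA load, applied to the
tagged-template drive). Its single-gene bifurcation is located
numerically by bisection on the steady-state count of the chained
1-D reduction; the structure differs from the two-variable circuit —
the saddle hugs the origin (`g ~ k1²γ1γ3γ4/V` for small g) and the
monostable regime exists only below a small `V_crit(4D) ≈ 4.6·10⁻³` at
the default rates, with `g_crit ≈ 0.080`. Because the circuit lives on
this much smaller concentration scale, the competition defaults are
scale-matched: injection at `g = 0.3` (~3.7× `g_crit`, the same ratio
class as the two-variable protocol), `s_silenced = 0.25` (~1/3 of the
critical-state amplitude, as in the two-variable setup), and
`V_tot = 0.074` (a ~200-gene stationary pool). Arrivals carry their
tagged-template pool at quasi-steady state (`u* = 1/γ3`, `y*` the QSS
of `y` given the injected `g` and `u*`): an arriving silencing event
tags templates as it seeds siRNAs, and injecting `y = 0` would kill
every arrival during the tagging lag. Under these conditions the
model self-tunes to within ~7% of its own bifurcation. With fast
template dynamics (γ3, γ4 large) the circuit collapses onto an
effective two-variable model obtained by quasi-steady-state elimination
of `u` and `y`, which the tests verify against the full integration.

Capacity fluctuations are modelled by an OU process
`dV = γ_V(V0 − V)dt + σ_V dW` (stationary mean `V0`, variance
`σ_V²/2γ_V`), clipped at 0, substituted for `V` each step; the
super-exponential growth of silencing duration with `V0` across the
bifurcation survives the fluctuations.

## Estimators

Survival curves use the Kaplan–Meier product-limit estimator
(censoring-aware; equal to 1 − ECDF on uncensored data). The tail
exponent is an ordinary-least-squares fit of log density against log
duration on 20 logarithmic bins spanning the top decade of durations
(window ending at the 0.999 quantile — the extreme-order quantile
rather than the maximum, to keep the top bins populated); a second fit
on a half-decade-shifted window is reported, and a large
window-to-window slope change flags non-power-law tails. The fit is
invariant under duration rescaling. Lineage autocorrelation is the
across-trajectory Pearson correlation between states at `t` and
`t + lag`, averaged over time origins; the correlation time is the lag
at which it first drops below 1/e. The regime discriminator packages
four statistics — duration scale (with censored fraction), tail slope,
correlation time, sister dispersion — that separate monostable
(sub-generation durations), strongly bistable (censored durations,
short-lived fluctuations, dispersed sister de-silencing) and critical
(multi-generation durations, flat tails, long correlation times,
uniform sisters) configurations.

## What the synthetic experiments do and do not show

All experiments run on simulator-generated data; there is no external
input. The generator's study conditions are: `dt = 0.1` hr, 72-hr
generations, 250-worm populations with `s_select = 3`, arrival rate
λ = 10 per generation (the `N = 1000, q = 0.01` worked example), and
the parameter defaults above. Passing tests show the implementation
reproduces the mathematical structure of the models — the bifurcation
geometry, the passage-time laws, the queuing steady state and its
linear tuning — under those conditions. They do not calibrate the
circuit to measured siRNA/ChIP time courses, do not model egg-by-egg
partitioning (dilution is a continuous rate), piRNA species (their
removal is represented as a change in `V_tot` or `N`), or spatial/
tissue structure, and say nothing about absolute rate constants in the
worm.

## Problem sizes

The shipped test suite and the acceptance script size their simulations
for a desktop CPU: competition runs of 100–900 generations with pools
of 40–1600 genes, populations of 20–800 worms over 3–50 generations,
first-passage ensembles of a few hundred paths, and 10⁶-draw
Monte-Carlo experiments for distribution checks. The long-duration
budget comparison (`V_tot = 1000` vs `100`) uses 900 vs 500 generations
with half the run discarded as burn-in, enough for the ~1400-gene pool
to fill and its residence times to equilibrate.
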