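# ticsim

Simulation and analysis of **transgenerational epigenetic silencing in
*C. elegans*** as a stochastic dynamical system: the Toggle-Inhibitor
(TI) circuit for a single gene, the timing theory of the saddle-node
bifurcation it sits near, and the Toggle-Inhibitor-Competition (TIC)
model in which many genes share limited silencing machinery and the
system *self-tunes* to the bifurcation.

Intended for quantitative biologists and modellers studying RNAi
inheritance, epigenetic memory duration, and self-organized criticality
in biochemical networks.

## The models

**TI circuit.** A target-specific pool of secondary (22G) siRNAs `g`
amplifies itself cooperatively, deposits repressive chromatin marks
(H3K9me3) `h`, and is inhibited by them; both are diluted by growth and
reproduction:

    dg = ( I(t) + V g^n/(k1^n + g^n) · k2/(k2 + h) − γ1 g ) dt + σ1 g dW1
    dh = ( ψ g/(k3 + g) − γ2 h ) dt + σ2 h dW2

`I(t)` is the dsRNA trigger. For small amplification capacity `V` the
only attractor is the unsilenced origin (*monostable*); above a critical
capacity `V_crit` a silenced high-(g, h) state appears through a
saddle-node bifurcation (*bistable*). Near `V_crit` the dynamics reduce
to the normal form `dx = (x² − μ)dt + σ dW` with `μ ∝ V − V_crit`, whose
passage times interpolate between the deterministic ghost delay
`T ≈ π/√|μ|` (monostable) and the Kramers escape time
`T ≈ (π/√μ)·exp(8μ^{3/2}/3σ²)` (bistable) via the Airy-function law
`T = 2^{1/3} π² σ^{−2/3} (Ai²[2^{2/3}ξ] + Bi²[2^{2/3}ξ])`, with
`ξ = μσ^{−4/3}`.

**TIC model.** `N` silenceable genes compete for shared synthesis
capacity: each gene sees `V_eff = V_tot / C` with cost `C = Σᵢ gᵢ`.
Silencing events arrive stochastically (Poisson rate λ, injected at
`g = 3, h = 0`) and genes retire when their silencing degree
`s = √(g² + h²)` drops below threshold. At stationarity the queue obeys
Little's law `M = λT` and the capacity self-tunes to `V_eff ≈ V_crit`,
which pins the mean silencing duration to

    T = V_tot / (λ · c_crit · V_crit)        (large-N limit)

— linear in `V_tot`, in contrast to the super-exponential sensitivity of
the single-gene circuit. This reproduces multi-generation but finite
silencing, heavy-tailed duration distributions, heritable variation that
responds to selection, and uniform de-silencing among sister worms.

## Worked example

```python
import ticsim as ts

params = ts.TIParams()                      # n=2, k=1 AU, gamma=0.1/hr, psi=1
crit = ts.find_v_crit(params)
print(f"V_crit = {crit.V_crit:.4f}  critical point (g, h) = ({crit.g_crit:.3f}, {crit.h_crit:.3f})")

for offset, label in [(-0.3, "monostable"), (0.5, "bistable")]:
    p = ts.calibrate_to_critical(params, offset)
    fps = ts.find_fixed_points(p)
    print(f"V = {p.V:.3f} ({label}): {len(fps)} fixed points "
          f"[{', '.join(f.stability for f in fps)}]")

cfg = ts.TICConfig(V_tot=100.0, lam=10.0)   # shared budget, 10 arrivals/generation
res = ts.run_tic(cfg, n_generations=300, seed=1, crit=crit)
s = res.summary
print(f"TIC: M = {s.M:.0f} silenced genes, T = {s.T:.1f} generations, "
      f"V_eff/V_crit = {s.V_eff/s.V_crit:.3f}, Little residual = {s.littles_residual:.3f}")
```

prints

```
V_crit = 1.0762  critical point (g, h) = (0.579, 3.668)
V = 0.753 (monostable): 1 fixed points [stable]
V = 1.614 (bistable): 3 fixed points [stable, unstable, stable]
TIC: M = 139 silenced genes, T = 14.2 generations, V_eff/V_crit = 1.013, Little residual = 0.035
```

Read: the default circuit bifurcates at `V_crit ≈ 1.076`; below it only
the unsilenced origin exists, above it a silenced state appears. The
competition run holds ≈139 genes silenced for ≈14 generations each,
with the effective per-gene capacity parked 1.3% above the bifurcation
— the self-tuned critical state (the closed forms give M = 160,
T = 16.0 at exact criticality).

A command-line interface wraps the same library:

```sh
ticsim bifurcation --v-min 0.3 --v-max 4 --out runs/bif     # locates V_crit
ticsim simulate-ti --seed 1 --out runs/traj                 # one trajectory
ticsim tic run --seed 1 --out runs/tic                      # competition run
ticsim population run --mode directed --out runs/sel        # selection experiment
```

Each command writes TSV tables plus a `manifest.json` with config echo,
seed and checksums; a config + seed reproduces every byte.

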