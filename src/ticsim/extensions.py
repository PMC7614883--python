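"""Model variants probing the robustness of self-tuned criticality.

Two extensions of the core circuits:

* a four-variable per-gene model adding the poly(UG)-tailed template
  mRNAs from which siRNAs are transcribed (g: siRNAs, h: chromatin
  marks, u: template mRNA, y: pUG-tagged mRNA), competing for the
  shared capacity exactly as in the two-variable competition model;
* the single-gene TI circuit with a fluctuating amplification capacity
  V(t) following an Ornstein-Uhlenbeck process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .ti import (
    DEFAULT_DT,
    DEFAULT_GENERATION_HOURS,
    DEFAULT_S_SILENCED,
    TIParams,
    TIState,
    Trajectory,
    TriggerSchedule,
)
from .tic import GenePool, SteadyStateSummary, TICConfig, _trend_ok

__all__ = [
    "PUGParams",
    "PUGConfig",
    "PUGResult",
    "CapacityFluctuation",
    "pug_fixed_point_count",
    "pug_v_crit",
    "run_pug",
    "simulate_ti_fluctuating_V",
]


@dataclass(frozen=True)
class PUGParams:
    """Rates of the pUGylation circuit.

    siRNAs are amplified from pUG-tagged templates (rate V*y per gene);
    tagging is autocatalytic in (g*u) with Hill cooperativity n;
    template production is repressed by chromatin marks.  The chromatin
    synthesis rate is 1 as printed in the source model; ``psi`` restores
    an explicit maximal rate if desired.
    """

    k1: float = 1.0
    k2: float = 1.0
    k3: float = 1.0
    n: float = 2.0
    psi: float = 1.0
    gamma1: float = 0.1
    gamma2: float = 0.1
    gamma3: float = 0.1
    gamma4: float = 0.1
    sigma1: float = 0.005
    sigma2: float = 0.005
    sigma3: float = 0.005
    sigma4: float = 0.005

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "psi", "gamma1", "gamma2", "gamma3", "gamma4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PUGParams.{name} must be positive")
        for name in ("sigma1", "sigma2", "sigma3", "sigma4"):
            if getattr(self, name) < 0:
                raise ValueError(f"PUGParams.{name} must be >= 0")
        if self.n <= 1:
            raise ValueError("PUGParams.n must exceed 1")


def pug_drift(g, h, u, y, V: float, p: PUGParams, I: float = 0.0):
    """Deterministic drift of the single-gene pUGylation circuit at
    amplification V (scalars or arrays)."""
    gu = g * u
    gun = gu**p.n
    dg = I + V * y - p.gamma1 * g
    dh = p.psi * g / (g + p.k3) - p.gamma2 * h
    du = p.k2 / (h + p.k2) - p.gamma3 * u
    dy = gun / (p.k1**p.n + gun) - p.gamma4 * y
    return dg, dh, du, dy


def _pug_steady_residual(g: np.ndarray, V: float, p: PUGParams) -> np.ndarray:
    """Steady-state residual of the single-gene deterministic circuit,
    reduced to one dimension by chaining the h, u, y steady states."""
    h = p.psi * g / (g + p.k3) / p.gamma2
    u = p.k2 / (h + p.k2) / p.gamma3
    gu = g * u
    y = gu**p.n / (p.k1**p.n + gu**p.n) / p.gamma4
    return V * y - p.gamma1 * g


def _pug_positive_roots(V: float, params: PUGParams, n_grid: int = 40001) -> list[float]:
    """Positive steady states of the reduced residual, on a log grid
    partitioned at the residual's interior extrema so that shallow or
    nearly-tangent crossings are not missed."""
    g_hi = max(10.0, 4.0 * V / params.gamma1)
    grid = np.logspace(-8, math.log10(g_hi), n_grid)
    res = _pug_steady_residual(grid, V, params)
    d = np.diff(res)
    turning = np.nonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)[0] + 1
    knots = [grid[0]]
    f = lambda x: float(_pug_steady_residual(np.asarray(x), V, params))
    for i in turning:
        lo, hi = grid[i - 1], grid[i + 1]
        sgn = -1.0 if d[i - 1] > 0 else 1.0  # maximise or minimise
        r = optimize.minimize_scalar(
            lambda x: sgn * f(x), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        knots.append(float(r.x))
    knots.append(grid[-1])
    roots = []
    for a, b in zip(knots[:-1], knots[1:]):
        fa, fb = f(a), f(b)
        if fa * fb < 0:
            roots.append(float(optimize.brentq(f, a, b, xtol=1e-12)))
    return sorted(r for r in set(roots) if r > 1e-7)


def pug_fixed_point_count(V: float, params: PUGParams, n_grid: int = 40001) -> int:
    """Number of non-negative steady states of the single-gene
    four-variable circuit at amplification V (origin included)."""
    return 1 + len(_pug_positive_roots(V, params, n_grid))


def pug_v_crit(
    params: PUGParams, bracket: tuple[float, float] = (1e-4, 0.05), rel_tol: float = 1e-6
) -> float:
    """Saddle-node location of the four-variable circuit by bisection on
    the steady-state count (no closed form is attempted)."""
    lo, hi = bracket
    c_lo, c_hi = pug_fixed_point_count(lo, params), pug_fixed_point_count(hi, params)
    if c_lo >= 3 or c_hi < 3:
        raise ValueError(
            f"bracket does not straddle the bifurcation (counts {c_lo}, {c_hi})"
        )
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if pug_fixed_point_count(mid, params) >= 3:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PUGConfig:
    """Competition configuration for the pUGylation model (mirrors
    :class:`ticsim.tic.TICConfig`; cost is still C = sum_i g_i).

    The pUGylation circuit lives on a much smaller concentration scale
    than the two-variable one (critical state g_crit ~ 0.08 AU at the
    default rates), so the injection state, silencing threshold and
    shared budget are scaled accordingly: defaults hold a stationary
    pool of roughly 200 silenced genes."""

    V_tot: float = 0.074
    lam: float = 10.0
    injection_g: float = 0.3
    injection_h: float = 0.0
    c_min: float | None = None
    s_silenced: float = 0.25
    pug: PUGParams = field(default_factory=PUGParams)
    dt: float = DEFAULT_DT
    generation_hours: float = DEFAULT_GENERATION_HOURS

    def __post_init__(self) -> None:
        if self.V_tot <= 0 or self.lam < 0:
            raise ValueError("V_tot must be positive and lam >= 0")


@dataclass
class PUGResult:
    per_generation: pd.DataFrame
    durations: pd.DataFrame
    summary: SteadyStateSummary
    stationary: bool


def run_pug(
    config: PUGConfig,
    n_generations: int = 200,
    seed: int | None = 0,
    burn_in_frac: float = 0.3,
    v_crit: float | None = None,
) -> PUGResult:
    """Competition run of the four-variable pUGylation model.

    Arrivals are Poisson(lam) at generation boundaries, injected at
    (g, h, u, y) = (injection_g, injection_h, u*, y*) where u* is the
    unsilenced template steady state 1/gamma3 and y* the pUG-tagged
    pool at quasi-steady state given the arriving siRNA burst (the
    silencing event tags templates as it seeds siRNAs); the cost
    C = sum g_i normalises the shared capacity, and genes retire when
    sqrt(g^2 + h^2) drops below the silencing threshold.
    """
    p = config.pug
    vc = v_crit if v_crit is not None else pug_v_crit(p)
    # cost at the critical point of the reduced single-gene system
    g_crit = _pug_g_crit(p, vc)
    c_min = config.c_min if config.c_min is not None else g_crit / 10.0
    rng = np.random.default_rng(seed)
    steps_per_gen = int(round(config.generation_hours / config.dt))
    sqdt = math.sqrt(config.dt)

    g = np.empty(0)
    h = np.empty(0)
    u = np.empty(0)
    y = np.empty(0)
    birth = np.empty(0, dtype=int)
    u_star = 1.0 / p.gamma3
    gu0 = config.injection_g * u_star
    y_star = gu0**p.n / (p.k1**p.n + gu0**p.n) / p.gamma4
    durations: list[dict] = []
    rows = []
    for gen in range(n_generations):
        k = int(rng.poisson(config.lam))
        if k:
            g = np.concatenate([g, np.full(k, config.injection_g)])
            h = np.concatenate([h, np.full(k, config.injection_h)])
            u = np.concatenate([u, np.full(k, u_star)])
            y = np.concatenate([y, np.full(k, y_star)])
            birth = np.concatenate([birth, np.full(k, gen, dtype=int)])
        retired = 0
        C = max(g.sum(), c_min)
        for _ in range(steps_per_gen):
            if g.size:
                C = max(g.sum(), c_min)
                Veff = config.V_tot / C
                gu = g * u
                gun = gu**p.n
                dg = (Veff * y - p.gamma1 * g) * config.dt
                dh = (p.psi * g / (g + p.k3) - p.gamma2 * h) * config.dt
                du = (p.k2 / (h + p.k2) - p.gamma3 * u) * config.dt
                dy = (gun / (p.k1**p.n + gun) - p.gamma4 * y) * config.dt
                w = rng.standard_normal((4, g.size)) * sqdt
                g = np.maximum(g + dg + p.sigma1 * g * w[0], 0.0)
                h = np.maximum(h + dh + p.sigma2 * h * w[1], 0.0)
                u = np.maximum(u + du + p.sigma3 * u * w[2], 0.0)
                y = np.maximum(y + dy + p.sigma4 * y * w[3], 0.0)
                if not np.all(np.isfinite(g)):
                    raise FloatingPointError(f"blow-up in generation {gen}")
                dead = g * g + h * h < config.s_silenced**2
                if dead.any():
                    for b in birth[dead]:
                        durations.append(
                            {"birth": int(b), "retired_at": gen, "duration": int(gen - b + 1)}
                        )
                    retired += int(dead.sum())
                    keep = ~dead
                    g, h, u, y, birth = g[keep], h[keep], u[keep], y[keep], birth[keep]
        rows.append(
            {
                "generation": gen,
                "M": g.size,
                "C": C,
                "V_eff": config.V_tot / C,
                "arrivals": k,
                "retirements": retired,
            }
        )
    per_gen = pd.DataFrame(rows)
    dur = pd.DataFrame(durations, columns=["birth", "retired_at", "duration"])
    burn = int(burn_in_frac * n_generations)
    window = per_gen.iloc[burn:]
    in_window = dur[dur.retired_at >= burn] if len(dur) else dur
    M_bar = float(window["M"].mean())
    lam_bar = float(window["arrivals"].mean())
    T_bar = float(in_window["duration"].mean()) if len(in_window) else float("nan")
    resid = abs(M_bar - lam_bar * T_bar) / M_bar if M_bar > 0 and np.isfinite(T_bar) else float("nan")
    summary = SteadyStateSummary(
        M=M_bar,
        lam=lam_bar,
        T=T_bar,
        V_eff=float(window["V_eff"].mean()),
        V_crit=vc,
        c_crit=g_crit,
        littles_residual=resid,
        n_durations=int(len(in_window)),
        window=(burn, n_generations),
    )
    return PUGResult(
        per_generation=per_gen,
        durations=dur,
        summary=summary,
        stationary=_trend_ok(window["M"].to_numpy()),
    )


def _pug_g_crit(p: PUGParams, v_crit: float, rel: float = 1.001) -> float:
    """Location (in g) of the merging steady-state pair just above the
    bifurcation of the reduced single-gene system."""
    roots = _pug_positive_roots(v_crit * rel, p)
    if len(roots) < 2:
        raise RuntimeError("merging pair not resolved above the pUG bifurcation")
    return 0.5 * (roots[0] + roots[1])


@dataclass(frozen=True)
class CapacityFluctuation:
    """Ornstein-Uhlenbeck capacity: dV = gamma_V*(V0 - V)dt + sigma_V dW.

    Stationary mean V0 and variance sigma_V^2/(2*gamma_V)."""

    V0: float
    gamma_V: float = 0.05
    sigma_V: float = 0.0

    def __post_init__(self) -> None:
        if self.V0 <= 0 or self.gamma_V <= 0 or self.sigma_V < 0:
            raise ValueError("need V0 > 0, gamma_V > 0, sigma_V >= 0")

    @property
    def stationary_variance(self) -> float:
        return self.sigma_V**2 / (2.0 * self.gamma_V)


def simulate_ti_fluctuating_V(
    params: TIParams,
    fluct: CapacityFluctuation,
    init: TIState | tuple[float, float] = (0.0, 0.0),
    trigger: TriggerSchedule | None = None,
    t_end: float = 10 * DEFAULT_GENERATION_HOURS,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    generation_hours: float = DEFAULT_GENERATION_HOURS,
    s_silenced: float = DEFAULT_S_SILENCED,
) -> tuple[Trajectory, np.ndarray]:
    """TI trajectory with the amplification capacity V(t) following an
    OU process (clipped at 0); returns (trajectory, V(t) array).

    With sigma_V = 0 and V0 = params.V this reproduces
    :func:`ticsim.ti.simulate_ti` exactly (same seed, same draws).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if isinstance(init, tuple):
        init = TIState(*init)
    trigger = trigger or TriggerSchedule.none()
    p = params
    n_steps = int(round(t_end / dt))
    t = np.arange(n_steps + 1) * dt
    g = np.empty(n_steps + 1)
    h = np.empty(n_steps + 1)
    V = np.empty(n_steps + 1)
    g[0], h[0] = init.g, init.h
    V[0] = fluct.V0
    rng = np.random.default_rng(seed)
    dW = rng.standard_normal((2, n_steps)) * math.sqrt(dt)
    dWv = (
        rng.standard_normal(n_steps) * math.sqrt(dt)
        if fluct.sigma_V > 0
        else np.zeros(n_steps)
    )
    I_grid = trigger.rates_on_grid(t[:-1])
    was_sil = math.hypot(g[0], h[0]) > s_silenced
    desil: float | None = None
    for i in range(n_steps):
        gn = g[i] ** p.n
        dg = (
            I_grid[i]
            + V[i] * gn / (p.k1**p.n + gn) * p.k2 / (p.k2 + h[i])
            - p.gamma1 * g[i]
        ) * dt
        dh = (p.psi * g[i] / (p.k3 + g[i]) - p.gamma2 * h[i]) * dt
        g[i + 1] = max(g[i] + dg + p.sigma1 * g[i] * dW[0, i], 0.0)
        h[i + 1] = max(h[i] + dh + p.sigma2 * h[i] * dW[1, i], 0.0)
        V[i + 1] = max(
            V[i] + fluct.gamma_V * (fluct.V0 - V[i]) * dt + fluct.sigma_V * dWv[i], 0.0
        )
        if not (np.isfinite(g[i + 1]) and np.isfinite(h[i + 1])):
            raise FloatingPointError(f"state blew up at step {i + 1}")
        s = math.hypot(g[i + 1], h[i + 1])
        if s > s_silenced:
            was_sil = True
        elif was_sil and desil is None:
            desil = t[i + 1]
    traj = Trajectory(
        t=t,
        g=g,
        h=h,
        dt=dt,
        seed=seed,
        generation_hours=generation_hours,
        events={"desilencing_time": desil, "s_silenced": s_silenced},
    )
    return traj, V
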