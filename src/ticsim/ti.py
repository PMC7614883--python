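"""Single-gene Toggle-Inhibitor (TI) dynamics.

The TI circuit couples an effector ``g`` (the pool of target-specific
22G siRNAs) to an inhibitor ``h`` (H3K9me3 silencing marks on the
target locus)::

    dg/dt = I(t) + V * g^n/(k1^n + g^n) * k2/(k2 + h) - gamma1 * g
    dh/dt = psi * g/(k3 + g) - gamma2 * h

siRNAs are amplified autocatalytically (Hill cooperativity ``n > 1``,
capacity ``V``), the amplification is inhibited by chromatin marks,
marks are deposited in a saturating fashion driven by siRNAs, and both
species are diluted by growth and reproduction at rates ``gamma1``,
``gamma2``.  Depending on ``V`` the deterministic system is monostable
(only the unsilenced origin) or bistable (origin plus a silenced
high-(g, h) state), with the two regimes separated by a saddle-node
bifurcation at ``V = V_crit``.

Stochastic trajectories use Euler-Maruyama with multiplicative noise
``sigma1*g*dW1``, ``sigma2*h*dW2``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "TIParams",
    "TIState",
    "TriggerSchedule",
    "Trajectory",
    "FixedPoint",
    "CriticalPoint",
    "ti_drift",
    "nullcline_g",
    "nullcline_h",
    "jacobian",
    "find_fixed_points",
    "find_v_crit",
    "calibrate_to_critical",
    "simulate_ti",
    "silencing_degree",
]

#: Integration step used throughout (hours).
DEFAULT_DT = 0.1
#: Generation time used throughout (hours).
DEFAULT_GENERATION_HOURS = 72.0
#: A gene/worm counts as silenced while s = sqrt(g^2 + h^2) exceeds this.
DEFAULT_S_SILENCED = 1.0


@dataclass(frozen=True)
class TIParams:
    """Rate constants and noise amplitudes of the TI circuit.

    All concentrations are in arbitrary units (AU), rates in 1/hour.
    """

    V: float = 1.5
    k1: float = 1.0
    k2: float = 1.0
    k3: float = 1.0
    n: float = 2.0
    psi: float = 1.0
    gamma1: float = 0.1
    gamma2: float = 0.1
    sigma1: float = 0.05
    sigma2: float = 0.05

    def __post_init__(self) -> None:
        for name in ("V", "k1", "k2", "k3", "psi", "gamma1", "gamma2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"TIParams.{name} must be strictly positive, got {v!r}")
        for name in ("sigma1", "sigma2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"TIParams.{name} must be non-negative, got {v!r}")
        if self.n <= 1:
            raise ValueError(f"TIParams.n must exceed 1 (cooperative amplification), got {self.n!r}")

    def with_V(self, V: float) -> "TIParams":
        return dataclasses.replace(self, V=float(V))

    def without_noise(self) -> "TIParams":
        return dataclasses.replace(self, sigma1=0.0, sigma2=0.0)


@dataclass(frozen=True)
class TIState:
    """A point (g, h) in the silencing phase plane, both >= 0 AU."""

    g: float
    h: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g) and np.isfinite(self.h)):
            raise ValueError(f"non-finite state ({self.g}, {self.h})")
        if self.g < 0 or self.h < 0:
            raise ValueError(f"negative concentrations in state ({self.g}, {self.h})")

    @property
    def s(self) -> float:
        return silencing_degree(self.g, self.h)


class TriggerSchedule:
    """Piecewise-constant induction rate I(t) >= 0 (AU/hour).

    ``breakpoints`` are the left edges of constant segments; ``rates``
    has the same length and holds the rate on each segment.  Times
    before the first breakpoint have rate 0.
    """

    def __init__(self, breakpoints: Sequence[float], rates: Sequence[float]):
        bp = np.asarray(breakpoints, dtype=float)
        r = np.asarray(rates, dtype=float)
        if bp.ndim != 1 or bp.shape != r.shape:
            raise ValueError("breakpoints and rates must be 1-D and equally long")
        if bp.size and np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(~np.isfinite(r)) or np.any(r < 0):
            raise ValueError("trigger rates must be finite and >= 0")
        self.breakpoints = bp
        self.rates = r

    @classmethod
    def none(cls) -> "TriggerSchedule":
        return cls([], [])

    @classmethod
    def constant(cls, rate: float) -> "TriggerSchedule":
        return cls([0.0], [rate])

    @classmethod
    def pulse(cls, amplitude: float, t_on: float = 0.0, duration: float = DEFAULT_GENERATION_HOURS) -> "TriggerSchedule":
        """A single dsRNA-exposure pulse of the given amplitude (AU/hr)."""
        return cls([t_on, t_on + duration], [amplitude, 0.0])

    @classmethod
    def stochastic(
        cls,
        amplitude: float,
        probability: float,
        t_end: float,
        rng: np.random.Generator,
        generation_hours: float = DEFAULT_GENERATION_HOURS,
    ) -> "TriggerSchedule":
        """Per-generation Bernoulli trigger: each generation carries
        I = ``amplitude`` with probability ``probability``, else 0."""
        if not 0.0 <= probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        n_gen = int(math.ceil(t_end / generation_hours))
        on = rng.random(n_gen) < probability
        bp = np.arange(n_gen) * generation_hours
        return cls(bp, np.where(on, amplitude, 0.0))

    def rate(self, t: float) -> float:
        if self.breakpoints.size == 0:
            return 0.0
        i = np.searchsorted(self.breakpoints, t, side="right") - 1
        return 0.0 if i < 0 else float(self.rates[i])

    def rates_on_grid(self, t: np.ndarray) -> np.ndarray:
        """Vectorised lookup of I(t) on a time grid."""
        if self.breakpoints.size == 0:
            return np.zeros_like(t)
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        out = np.where(idx >= 0, self.rates[np.clip(idx, 0, None)], 0.0)
        return out


@dataclass
class Trajectory:
    """A seeded (g(t), h(t)) time series on a uniform grid."""

    t: np.ndarray
    g: np.ndarray
    h: np.ndarray
    dt: float
    seed: int | None
    generation_hours: float = DEFAULT_GENERATION_HOURS
    events: dict = field(default_factory=dict)

    @property
    def s(self) -> np.ndarray:
        return np.hypot(self.g, self.h)

    @property
    def generation(self) -> np.ndarray:
        return np.floor(self.t / self.generation_hours).astype(int)

    @property
    def desilencing_time(self) -> float | None:
        return self.events.get("desilencing_time")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hr": self.t,
                "generation": self.generation,
                "g": self.g,
                "h": self.h,
                "s": self.s,
            }
        )


@dataclass(frozen=True)
class FixedPoint:
    g: float
    h: float
    eigenvalues: tuple[complex, complex]
    stability: str  # "stable" | "unstable" | "marginal"

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass(frozen=True)
class CriticalPoint:
    """Saddle-node bifurcation of the TI circuit in ``V``."""

    V_crit: float
    g_crit: float
    h_crit: float

    @property
    def c_crit(self) -> float:
        """Per-gene resource cost at the critical point (the cost is the
        siRNA abundance, so c_crit = g_crit)."""
        return self.g_crit


def silencing_degree(g, h):
    """Degree of silencing s = sqrt(g^2 + h^2) (Euclidean norm)."""
    return np.hypot(g, h)


def _check_finite(*vals) -> None:
    for v in vals:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite input {v!r}")


def ti_drift(g, h, params: TIParams, I: float = 0.0):
    """Deterministic time-derivatives (dg/dt, dh/dt) of the TI circuit.

    Accepts scalars or arrays for ``g``, ``h``.
    """
    _check_finite(g, h, I)
    if np.any(np.asarray(I) < 0):
        raise ValueError("trigger rate I must be >= 0")
    p = params
    gn = np.power(g, p.n)
    dg = I + p.V * gn / (p.k1**p.n + gn) * p.k2 / (p.k2 + h) - p.gamma1 * g
    dh = p.psi * g / (p.k3 + g) - p.gamma2 * h
    return dg, dh


def nullcline_g(g, params: TIParams):
    """Nontrivial g-nullcline h(g) (the trivial branch is g = 0).

    May return negative h; a negative value means the nontrivial branch
    has no physical (h >= 0) point at this g.
    """
    g = np.asarray(g, dtype=float)
    _check_finite(g)
    if np.any(g <= 0):
        raise ValueError("nontrivial g-nullcline requires g > 0")
    p = params
    return p.k2 * (p.V / p.gamma1 * np.power(g, p.n - 1) / (np.power(g, p.n) + p.k1**p.n) - 1.0)


def nullcline_h(g, params: TIParams):
    """h-nullcline h(g) = (psi/gamma2) * g/(k3+g); saturates at psi/gamma2."""
    g = np.asarray(g, dtype=float)
    _check_finite(g)
    if np.any(g < 0):
        raise ValueError("g must be >= 0")
    p = params
    return p.psi / p.gamma2 * g / (p.k3 + g)


def jacobian(g: float, h: float, params: TIParams) -> np.ndarray:
    """Jacobian of the deterministic TI drift at (g, h)."""
    _check_finite(g, h)
    p = params
    gn = g**p.n
    k1n = p.k1**p.n
    amp = gn / (k1n + gn) if g > 0 or p.n <= 1 else 0.0
    d_amp = p.n * g ** (p.n - 1) * k1n / (k1n + gn) ** 2 if g > 0 else 0.0
    inh = p.k2 / (p.k2 + h)
    j11 = p.V * d_amp * inh - p.gamma1
    j12 = -p.V * amp * p.k2 / (p.k2 + h) ** 2
    j21 = p.psi * p.k3 / (p.k3 + g) ** 2
    j22 = -p.gamma2
    return np.array([[j11, j12], [j21, j22]])


def _classify(eigs: np.ndarray, tol: float = 1e-9) -> str:
    re = np.real(eigs)
    if np.any(np.abs(re) <= tol):
        return "marginal"
    return "stable" if np.all(re < 0) else "unstable"


def _fixed_point_at(g: float, params: TIParams, I: float) -> FixedPoint:
    h = float(nullcline_h(max(g, 0.0), params))
    eigs = np.linalg.eigvals(jacobian(g, h, params))
    return FixedPoint(float(g), float(h), (complex(eigs[0]), complex(eigs[1])), _classify(eigs))


def _g_residual(g: np.ndarray, params: TIParams, I: float) -> np.ndarray:
    """dg/dt evaluated on the h-nullcline; fixed points are its roots."""
    h = nullcline_h(g, params)
    p = params
    gn = np.power(g, p.n)
    return I + p.V * gn / (p.k1**p.n + gn) * p.k2 / (p.k2 + h) - p.gamma1 * g


def find_fixed_points(
    params: TIParams,
    I: float = 0.0,
    g_tol: float = 1e-10,
    n_grid: int = 4096,
) -> list[FixedPoint]:
    """All fixed points of the deterministic TI circuit, classified.

    Solving is reduced to one dimension: substitute the explicit
    h-nullcline into dg/dt and find roots in g.  The residual is
    partitioned into monotone pieces at its interior extrema so that
    nearly-tangent root pairs close to the saddle-node are not missed.
    With I = 0 the origin is always a fixed point and is returned first.
    """
    if I < 0 or not np.isfinite(I):
        raise ValueError("I must be finite and >= 0")
    out: list[FixedPoint] = []
    g_upper = max(10.0 * params.k1, 2.0 * (params.V + I) / params.gamma1)
    eps = 1e-9 * params.k1
    if I == 0.0:
        out.append(_fixed_point_at(0.0, params, I))

    grid = np.linspace(eps, g_upper, n_grid)
    res = _g_residual(grid, params, I)

    # Partition [eps, g_upper] into monotone intervals of the residual.
    d = np.diff(res)
    turning = np.nonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)[0] + 1
    knots = [grid[0]]
    for i in turning:
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
        r = optimize.minimize_scalar(
            lambda x: _g_residual(np.asarray(x), params, I) * np.sign(d[i - 1]) * -1.0,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": g_tol / 10},
        )
        knots.append(float(r.x))
    knots.append(grid[-1])

    roots: list[float] = []
    for a, b in zip(knots[:-1], knots[1:]):
        fa = float(_g_residual(np.asarray(a), params, I))
        fb = float(_g_residual(np.asarray(b), params, I))
        if fa == 0.0 and a > eps:
            roots.append(a)
            continue
        if fa * fb < 0:
            try:
                r = optimize.brentq(
                    lambda x: float(_g_residual(np.asarray(x), params, I)), a, b, xtol=g_tol
                )
            except ValueError as exc:  # pragma: no cover - diagnostic path
                raise RuntimeError(
                    f"root bracketing failed on [{a}, {b}] (f={fa}, {fb})"
                ) from exc
            roots.append(float(r))

    for r in sorted(set(roots)):
        if r <= 2 * eps and I == 0.0:
            continue  # numerical duplicate of the origin
        if nullcline_h(r, params) >= 0:
            out.append(_fixed_point_at(r, params, I))
    return out


def find_v_crit(
    params: TIParams,
    bracket: tuple[float, float] = (0.05, 50.0),
    rel_tol: float = 1e-8,
    I: float = 0.0,
) -> CriticalPoint:
    """Locate the saddle-node bifurcation in V by bisection on the
    fixed-point count (1 below V_crit, 3 above, counting the origin).

    The coalescence location is the midpoint of the merging nontrivial
    pair evaluated just above V_crit.
    """
    v_lo, v_hi = bracket
    if not (0 < v_lo < v_hi):
        raise ValueError("bracket must satisfy 0 < V_low < V_high")

    def count(V: float) -> int:
        return len(find_fixed_points(params.with_V(V), I=I))

    c_lo, c_hi = count(v_lo), count(v_hi)
    if c_lo == c_hi:
        raise ValueError(
            f"invalid bracket: {c_lo} fixed points at V={v_lo} and {c_hi} at V={v_hi}; "
            "the bracket must straddle the bifurcation (counts 1 vs 3)"
        )
    if c_lo > c_hi:
        raise ValueError("fixed-point count must increase with V across the bracket")

    while (v_hi - v_lo) > rel_tol * v_hi:
        mid = 0.5 * (v_lo + v_hi)
        if count(mid) >= 3:
            v_hi = mid
        else:
            v_lo = mid

    fps = [fp for fp in find_fixed_points(params.with_V(v_hi), I=I) if fp.g > 0]
    fps.sort(key=lambda fp: fp.g)
    if len(fps) < 2:  # pragma: no cover - defensive
        raise RuntimeError("merging pair not resolved at the upper bracket end")
    g_crit = 0.5 * (fps[0].g + fps[1].g)
    h_crit = float(nullcline_h(g_crit, params))
    return CriticalPoint(V_crit=0.5 * (v_lo + v_hi), g_crit=g_crit, h_crit=h_crit)


def calibrate_to_critical(params: TIParams, offset: float = 0.0, **kwargs) -> TIParams:
    """Return a copy of ``params`` with V = (1 + offset) * V_crit.

    Regime-relative placement: offset < 0 puts the circuit in the
    monostable regime, 0 at criticality, > 0 in the bistable regime.
    """
    crit = find_v_crit(params, **kwargs)
    return params.with_V(crit.V_crit * (1.0 + offset))


def _em_step(g, h, params: TIParams, I, dt: float, dW1, dW2, V=None):
    """One Euler-Maruyama step (vectorised); states are clipped at 0 to
    remove the discretisation artifact of multiplicative noise."""
    p = params
    Vamp = p.V if V is None else V
    gn = np.power(g, p.n)
    dg = (I + Vamp * gn / (p.k1**p.n + gn) * p.k2 / (p.k2 + h) - p.gamma1 * g) * dt
    dh = (p.psi * g / (p.k3 + g) - p.gamma2 * h) * dt
    g_new = np.maximum(g + dg + p.sigma1 * g * dW1, 0.0)
    h_new = np.maximum(h + dh + p.sigma2 * h * dW2, 0.0)
    return g_new, h_new


def simulate_ti(
    params: TIParams,
    init: TIState | tuple[float, float] = (0.0, 0.0),
    trigger: TriggerSchedule | None = None,
    t_end: float = 10 * DEFAULT_GENERATION_HOURS,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    generation_hours: float = DEFAULT_GENERATION_HOURS,
    s_silenced: float = DEFAULT_S_SILENCED,
) -> Trajectory:
    """Integrate the TI circuit (Euler for sigma = 0, Euler-Maruyama
    otherwise) from ``init`` with an optional trigger schedule.

    The trajectory records the de-silencing time: the first time the
    silencing degree s drops below ``s_silenced`` after having exceeded
    it.  Identical seeds replay bit-identically.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if isinstance(init, TIState):
        g0, h0 = init.g, init.h
    else:
        g0, h0 = init
        TIState(g0, h0)  # validate
    trigger = trigger or TriggerSchedule.none()
    n_steps = int(round(t_end / dt))
    t = np.arange(n_steps + 1) * dt
    g = np.empty(n_steps + 1)
    h = np.empty(n_steps + 1)
    g[0], h[0] = g0, h0

    noisy = params.sigma1 > 0 or params.sigma2 > 0
    rng = np.random.default_rng(seed)
    if noisy:
        dW = rng.standard_normal((2, n_steps)) * math.sqrt(dt)
    else:
        dW = np.zeros((2, n_steps))
    I_grid = trigger.rates_on_grid(t[:-1])

    was_silenced = math.hypot(g0, h0) > s_silenced
    desil_time: float | None = None
    for i in range(n_steps):
        g[i + 1], h[i + 1] = _em_step(g[i], h[i], params, I_grid[i], dt, dW[0, i], dW[1, i])
        if not (np.isfinite(g[i + 1]) and np.isfinite(h[i + 1])):
            raise FloatingPointError(
                f"state blew up at step {i + 1} (t={t[i + 1]:.2f} hr): "
                f"g={g[i + 1]!r} h={h[i + 1]!r}; reduce dt"
            )
        s = math.hypot(g[i + 1], h[i + 1])
        if s > s_silenced:
            was_silenced = True
        elif was_silenced and desil_time is None:
            desil_time = t[i + 1]

    events = {"desilencing_time": desil_time, "s_silenced": s_silenced}
    return Trajectory(
        t=t, g=g, h=h, dt=dt, seed=seed, generation_hours=generation_hours, events=events
    )
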