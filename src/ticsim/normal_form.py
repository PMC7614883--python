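"""Saddle-node normal form and first-passage timing theory.

Close to the saddle-node bifurcation the TI circuit reduces to the
one-dimensional normal form

    dx = (x^2 - mu) dt + sigma dW,

where ``mu`` is the scaled distance from the bifurcation
(``mu ∝ V - V_crit``): ``mu > 0`` is the bistable regime with fixed
points at ±sqrt(mu), ``mu < 0`` the monostable regime in which every
trajectory escapes to +infinity after a slow "ghost" passage near
x = 0.  This module collects the closed-form passage-time laws
(deterministic ghost delay, Kramers escape, the Airy-function
interpolation valid for either sign of mu), the Ornstein-Uhlenbeck
fluctuation statistics around the silenced state, the induced
silencing-duration distributions when mu itself varies between genes
or lineages, and a stochastic simulator of the absorbed normal form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "NormalFormParams",
    "MuDistribution",
    "DelayLawConstants",
    "FirstPassageEnsemble",
    "ghost_delay_deterministic",
    "kramers_time",
    "airy_time",
    "log_airy_time",
    "simulate_normal_form",
    "ou_variance",
    "ou_autocorr",
    "delay_density_monostable",
    "sample_monostable_delays",
    "survival_bistable",
]


@dataclass(frozen=True)
class NormalFormParams:
    """Parameters of the absorbed stochastic normal form.

    The de-silenced state is an absorbing boundary at ``xmax``; the
    drift is capped at ``gamma * (xmax - x)`` so that trajectories
    relax onto the boundary instead of diverging, and the noise
    amplitude tapers as ``sigma * (1 - x/xmax)``.
    """

    mu: float
    sigma: float
    x0: float
    xmax: float = 10.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.xmax > self.x0:
            raise ValueError("xmax must exceed x0")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def xi(self) -> float:
        """Dimensionless bifurcation distance xi = mu * sigma^(-4/3).

        Recomputed on access; silencing is effectively permanent for
        large positive xi."""
        if self.sigma == 0:
            raise ValueError("xi is undefined for sigma = 0")
        return self.mu * self.sigma ** (-4.0 / 3.0)


@dataclass(frozen=True)
class MuDistribution:
    """Gaussian variation of the bifurcation parameter across genes or
    lineages (width ``b``, optionally restricted to one side of 0)."""

    mean: float = 0.0
    b: float = 1.0
    truncation: str | None = None  # None | "monostable" (mu<0) | "bistable" (mu>0)

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("width b must be positive")
        if self.truncation not in (None, "monostable", "bistable"):
            raise ValueError(f"unknown truncation {self.truncation!r}")

    def pdf(self, mu):
        return stats.norm.pdf(mu, loc=self.mean, scale=self.b)

    def monostable_mass(self) -> float:
        return float(stats.norm.cdf(0.0, loc=self.mean, scale=self.b))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        mu = rng.normal(self.mean, self.b, size=n)
        if self.truncation == "monostable":
            while True:
                bad = mu >= 0
                if not bad.any():
                    break
                mu[bad] = rng.normal(self.mean, self.b, size=int(bad.sum()))
        elif self.truncation == "bistable":
            while True:
                bad = mu <= 0
                if not bad.any():
                    break
                mu[bad] = rng.normal(self.mean, self.b, size=int(bad.sum()))
        return mu


@dataclass(frozen=True)
class DelayLawConstants:
    """Constants of the asymptotic delay laws: monostable
    T = a*|mu|^(-1/2); bistable T = A*exp(B*mu^(3/2)); survival curves
    are reported for T >= Tmin."""

    a: float = 1.0
    A: float = 1.0
    B: float = 1.0
    Tmin: float = 1.0

    def __post_init__(self) -> None:
        if min(self.a, self.A, self.B, self.Tmin) <= 0:
            raise ValueError("all delay-law constants must be positive")


def ghost_delay_deterministic(
    mu: float, x0: float = -math.inf, x1: float = math.inf
) -> float:
    """Deterministic passage time through the saddle-node ghost,
    T = ∫ dx/(x^2 - mu) from x0 to x1 for mu < 0.

    With infinite limits this is pi/sqrt(|mu|): the slow-passage delay
    diverging as the bifurcation is approached from the monostable side.
    """
    if not mu < 0:
        raise ValueError("ghost delay requires mu < 0 (monostable regime)")
    if not x0 < x1:
        raise ValueError("x0 must be below x1")
    s = math.sqrt(-mu)
    a0 = math.atan(x0 / s) if math.isfinite(x0) else -math.pi / 2
    a1 = math.atan(x1 / s) if math.isfinite(x1) else math.pi / 2
    return (a1 - a0) / s


def kramers_time(mu: float, sigma: float) -> float:
    """Kramers mean escape time from the silenced well in the bistable
    regime: T = (pi/sqrt(mu)) * exp(8*mu^(3/2)/(3*sigma^2)).

    Derived from the cubic potential Phi = -x^3/3 + mu*x whose barrier
    height is (4/3)*mu^(3/2).  May overflow to inf for deep wells.
    """
    if not mu > 0:
        raise ValueError("Kramers escape requires mu > 0 (bistable regime)")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    exponent = 8.0 * mu**1.5 / (3.0 * sigma**2)
    try:
        return math.pi / math.sqrt(mu) * math.exp(exponent)
    except OverflowError:
        return math.inf


def log_airy_time(mu: float, sigma: float) -> float:
    """log of :func:`airy_time`, safe for large positive xi."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    xi = mu * sigma ** (-4.0 / 3.0)
    z = 2.0 ** (2.0 / 3.0) * xi
    pref = (1.0 / 3.0) * math.log(2.0) + 2.0 * math.log(math.pi) - (2.0 / 3.0) * math.log(sigma)
    if z < 4.0:
        ai, _, bi, _ = special.airy(z)
        return pref + math.log(ai * ai + bi * bi)
    # log-space: Bi dominates; airye returns Bi*exp(-(2/3)z^(3/2))
    _, _, bie, _ = special.airye(z)
    w = (2.0 / 3.0) * z**1.5
    log_bi = math.log(bie) + w
    aie = special.airye(z)[0]  # Ai*exp(+(2/3)z^(3/2))
    ratio2 = (aie * math.exp(-2.0 * w) / bie) ** 2
    return pref + 2.0 * log_bi + math.log1p(ratio2)


def airy_time(mu: float, sigma: float) -> float:
    """Mean first-passage time through the critical region for any sign
    of mu (Airy-function interpolation):

        T = 2^(1/3) * pi^2 * sigma^(-2/3) * (Ai^2[2^(2/3) xi] + Bi^2[2^(2/3) xi])

    with xi = mu * sigma^(-4/3).  Matches the Kramers time as
    xi -> +inf and the deterministic ghost delay pi/sqrt(|mu|) as
    xi -> -inf.
    """
    lt = log_airy_time(mu, sigma)
    try:
        return math.exp(lt)
    except OverflowError:
        return math.inf


@dataclass
class FirstPassageEnsemble:
    """Absorption times at xmax; non-absorbed paths are right-censored
    at ``t_end``, never silently dropped."""

    times: np.ndarray
    censored: np.ndarray
    t_end: float
    paths: np.ndarray | None = None
    t_grid: np.ndarray | None = None

    @property
    def censored_fraction(self) -> float:
        return float(self.censored.mean())

    def observed(self) -> np.ndarray:
        return self.times[~self.censored]


def simulate_normal_form(
    params: NormalFormParams,
    dt: float = 0.01,
    seed: int | None = None,
    n_paths: int = 1,
    t_end: float | None = None,
    return_paths: bool = False,
    absorb_frac: float = 0.99,
) -> FirstPassageEnsemble:
    """Euler-Maruyama first-passage ensemble of the absorbed normal form

        dx = min(x^2 - mu, gamma*(xmax - x)) dt + sigma*(1 - x/xmax) dW.

    Paths start at ``x0``.  Because both the capped drift and the
    tapered noise vanish exactly at ``xmax``, the boundary is only
    reached asymptotically; absorption is therefore declared at
    ``absorb_frac * xmax``, which adds a bounded O(1/gamma) relaxation
    tail to each passage time.  The default horizon is 50x the Airy
    passage-time prediction.
    """
    p = params
    if dt <= 0:
        raise ValueError("dt must be positive")
    drift_scale = max(abs(p.x0), abs(p.mu) ** 0.5 if p.mu > 0 else 0.0, abs(p.xmax)) ** 2 + abs(p.mu)
    if drift_scale * dt > 0.5 * (p.xmax - p.x0):
        raise ValueError(f"dt={dt} too large for drift scale {drift_scale:.3g}")
    if t_end is None:
        if p.sigma == 0:
            if p.mu >= 0 and p.x0 < math.sqrt(max(p.mu, 0.0)):
                raise ValueError(
                    "deterministic path cannot be absorbed (x0 below the stable "
                    "fixed point); provide t_end explicitly"
                )
            base = ghost_delay_deterministic(p.mu) if p.mu < 0 else 10.0
            t_end = 50.0 * base
        else:
            ref = airy_time(p.mu, p.sigma)
            if not math.isfinite(ref):
                raise ValueError(
                    "Airy prediction overflows (deeply bistable); provide t_end explicitly"
                )
            t_end = 50.0 * ref

    x_abs = absorb_frac * p.xmax
    if not p.x0 < x_abs:
        raise ValueError("x0 must lie below the absorption threshold")
    n_steps = int(math.ceil(t_end / dt))
    rng = np.random.default_rng(seed)
    x = np.full(n_paths, float(p.x0))
    alive = np.ones(n_paths, dtype=bool)
    times = np.full(n_paths, float(t_end))
    sqdt = math.sqrt(dt)
    store = np.full((n_steps + 1, n_paths), np.nan) if return_paths else None
    if store is not None:
        store[0] = x
    for i in range(n_steps):
        if not alive.any():
            break
        xa = x[alive]
        drift = np.minimum(xa * xa - p.mu, p.gamma * (p.xmax - xa))
        if p.sigma > 0:
            noise = p.sigma * (1.0 - xa / p.xmax) * rng.standard_normal(xa.size) * sqdt
        else:
            noise = 0.0
        xa = xa + drift * dt + noise
        x[alive] = xa
        hit = np.zeros_like(alive)
        hit[alive] = xa >= x_abs
        times[hit] = (i + 1) * dt
        alive &= ~hit
        if store is not None:
            store[i + 1] = x
            store[i + 1, ~alive & (times < t_end)] = np.nan
    return FirstPassageEnsemble(
        times=times,
        censored=alive.copy(),
        t_end=float(t_end),
        paths=store,
        t_grid=np.arange(n_steps + 1) * dt if return_paths else None,
    )


def ou_variance(mu: float, sigma: float) -> float:
    """Stationary variance of fluctuations around the silenced fixed
    point x = -sqrt(mu): var = sigma^2 / (4*sqrt(mu)).  Diverges at the
    critical point (critical slowing down)."""
    if not mu > 0:
        raise ValueError("OU statistics require mu > 0")
    return sigma**2 / (4.0 * math.sqrt(mu))


def ou_autocorr(mu: float, lag) -> float | np.ndarray:
    """Stationary autocorrelation exp(-2*sqrt(mu)*|lag|) of fluctuations
    around the silenced fixed point."""
    if not mu > 0:
        raise ValueError("OU statistics require mu > 0")
    return np.exp(-2.0 * math.sqrt(mu) * np.abs(lag))


def delay_density_monostable(
    T, constants: DelayLawConstants = DelayLawConstants(), F: MuDistribution = MuDistribution()
):
    """Probability density of the silencing duration T = a*|mu|^(-1/2)
    induced by the monostable side (mu < 0) of the mu-distribution:

        Pr(T) = F(-a^2/T^2) * 2 a^2 / T^3.

    Integrates to the monostable probability mass of F; the large-T
    tail scales as T^(-3).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("durations must be positive")
    a2 = constants.a**2
    return F.pdf(-a2 / T**2) * 2.0 * a2 / T**3


def sample_monostable_delays(
    n: int,
    rng: np.random.Generator,
    constants: DelayLawConstants = DelayLawConstants(),
    F: MuDistribution = MuDistribution(),
) -> np.ndarray:
    """Monte-Carlo durations T = a*|mu|^(-1/2) with mu drawn from the
    monostable (mu < 0) restriction of F."""
    mu = MuDistribution(F.mean, F.b, truncation="monostable").sample(n, rng)
    return constants.a / np.sqrt(-mu)


def _exp_integral_half(x):
    """Generalized exponential integral E_s(x) of order s = 1/2 via the
    identity E_{1/2}(x) = sqrt(pi/x) * erfc(sqrt(x))."""
    x = np.asarray(x, dtype=float)
    return np.sqrt(np.pi / x) * special.erfc(np.sqrt(x))


def survival_bistable(T, A: float, B: float, b: float, Tmin: float):
    """Survival function S(T) = G(T)/G(Tmin) of silencing durations on
    the bistable side when mu ~ Gaussian(0, b) and T = A*exp(B*mu^(3/2)):

        G(T) ∝ u * E_{1/2}(u^2 / (2 b^2)),   u = (ln(T/A)/B)^(2/3).

    S(Tmin) = 1, S is non-increasing, and the tail flattens as b grows.
    """
    if min(A, B, b) <= 0:
        raise ValueError("A, B, b must be positive")
    if Tmin < A:
        raise ValueError("Tmin must be >= A (durations below A have no bistable preimage)")
    T = np.asarray(T, dtype=float)
    if np.any(T < Tmin):
        raise ValueError("survival defined for T >= Tmin only")

    def G(t):
        t = np.asarray(t, dtype=float)
        u = (np.log(t / A) / B) ** (2.0 / 3.0)
        out = np.ones_like(u)
        pos = u > 0
        out[pos] = u[pos] * _exp_integral_half(u[pos] ** 2 / (2.0 * b**2)) / (
            math.sqrt(2.0 * math.pi) * b * 2.0
        )
        # u -> 0 limit: u * E_{1/2}(u^2/(2b^2)) -> sqrt(2 pi) * b * erfc(0)
        out[~pos] = 0.5
        return out

    s = G(T) / G(np.asarray(Tmin, dtype=float))
    return s if s.shape else float(s)
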