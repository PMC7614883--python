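"""Worm-population simulation over generations with selection.

Each generation, ``n_worms`` individuals evolve independently under the
stochastic TI dynamics for one generation time; each worm inherits its
mother's end-of-generation (g, h) state unchanged.  The next generation
is founded by sampling mothers with replacement, either from the whole
population (*random selection*) or only from strongly silenced worms
with s > s_select (*directed selection*), mimicking the experimental
protocol of propagating the most silenced individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ti import (
    DEFAULT_DT,
    DEFAULT_GENERATION_HOURS,
    DEFAULT_S_SILENCED,
    TIParams,
    TIState,
    _em_step,
)

__all__ = [
    "PopulationConfig",
    "PopulationResult",
    "SisterResult",
    "run_population",
    "sister_desilencing",
    "population_duration",
    "duration_ensemble",
    "dilution_factor",
    "arrival_rate",
]


@dataclass(frozen=True)
class PopulationConfig:
    n_worms: int = 250
    selection_mode: str = "random"  # "random" | "directed"
    s_select: float = 3.0
    s_silenced: float = DEFAULT_S_SILENCED
    generation_hours: float = DEFAULT_GENERATION_HOURS
    n_generations: int = 20
    dt: float = DEFAULT_DT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_worms < 1:
            raise ValueError("n_worms must be >= 1")
        if self.selection_mode not in ("random", "directed"):
            raise ValueError(f"unknown selection mode {self.selection_mode!r}")
        if not self.s_select > self.s_silenced > 0:
            raise ValueError("need s_select > s_silenced > 0")
        if self.dt <= 0 or self.generation_hours <= 0:
            raise ValueError("dt and generation_hours must be positive")


@dataclass
class PopulationResult:
    """Generation-by-generation table plus run-level flags.

    ``table`` columns: generation, worm, mother, g, h, s, silenced
    (state at the end of the generation; mother indexes the previous
    generation, -1 for founders).
    """

    table: pd.DataFrame
    config: PopulationConfig
    extinct_at: int | None = None  # generation with no eligible mothers

    @property
    def extinct(self) -> bool:
        return self.extinct_at is not None

    def fraction_silenced(self) -> pd.Series:
        return self.table.groupby("generation")["silenced"].mean()


def _gen_rng(seed: int, generation: int, stream: int = 0) -> np.random.Generator:
    """Deterministic per-generation RNG stream; worm i always consumes
    column i of the draws, so replay is independent of execution order."""
    return np.random.default_rng(np.random.SeedSequence([seed, generation, stream]))


def _evolve_generation(
    g: np.ndarray,
    h: np.ndarray,
    params: TIParams,
    hours: float,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve an ensemble for one generation (vectorised over worms)."""
    n_steps = int(round(hours / dt))
    sqdt = math.sqrt(dt)
    noisy = params.sigma1 > 0 or params.sigma2 > 0
    for _ in range(n_steps):
        if noisy:
            dW = rng.standard_normal((2, g.size)) * sqdt
        else:
            dW = (0.0, 0.0)
        g, h = _em_step(g, h, params, 0.0, dt, dW[0], dW[1])
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(h))):
        raise FloatingPointError("population state blew up; reduce dt")
    return g, h


def run_population(
    ti_params: TIParams,
    config: PopulationConfig,
    init: TIState | tuple[float, float],
) -> PopulationResult:
    """Simulate selection over generations from a shared initial state
    (typically the post-trigger silenced state).

    Directed selection with zero eligible mothers ends the run and the
    extinction generation is flagged on the result.
    """
    if isinstance(init, tuple):
        init = TIState(*init)
    cfg = config
    n = cfg.n_worms
    g = np.full(n, init.g)
    h = np.full(n, init.h)
    mothers = np.full(n, -1, dtype=int)
    rows: list[pd.DataFrame] = []
    extinct_at: int | None = None

    for gen in range(cfg.n_generations):
        rng = _gen_rng(cfg.seed, gen)
        g, h = _evolve_generation(g, h, ti_params, cfg.generation_hours, cfg.dt, rng)
        s = np.hypot(g, h)
        rows.append(
            pd.DataFrame(
                {
                    "generation": gen,
                    "worm": np.arange(n),
                    "mother": mothers,
                    "g": g,
                    "h": h,
                    "s": s,
                    "silenced": s > cfg.s_silenced,
                }
            )
        )
        if gen == cfg.n_generations - 1:
            break
        if cfg.selection_mode == "directed":
            eligible = np.nonzero(s > cfg.s_select)[0]
            if eligible.size == 0:
                extinct_at = gen
                break
        else:
            eligible = np.arange(n)
        sel_rng = _gen_rng(cfg.seed, gen, stream=1)
        mothers = eligible[sel_rng.integers(0, eligible.size, size=n)]
        g = g[mothers].copy()
        h = h[mothers].copy()

    table = pd.concat(rows, ignore_index=True)
    return PopulationResult(table=table, config=cfg, extinct_at=extinct_at)


@dataclass
class DurationSummary:
    """Population silencing duration and per-lineage duration samples."""

    population_T: float | None  # generations until <50% silenced; None if censored
    censored: bool
    lineage_durations: np.ndarray  # completed first-passage durations (generations)
    lineage_censored: int  # still-silenced worms at the horizon
    horizon: int


def population_duration(
    result: PopulationResult, fraction_threshold: float = 0.5
) -> DurationSummary:
    """Summarise silencing persistence of a population run.

    The population duration T is the first generation (1-based) at
    which the silenced fraction drops below ``fraction_threshold``.
    Per-lineage samples are first de-silencing events along
    mother-daughter chains that were silenced in every prior generation.
    """
    tab = result.table
    frac = tab.groupby("generation")["silenced"].mean()
    below = frac[frac < fraction_threshold]
    population_T: float | None = float(below.index[0]) + 1.0 if len(below) else None

    gens = sorted(tab["generation"].unique())
    sil = {
        gen: tab.loc[tab.generation == gen].set_index("worm")["silenced"]
        for gen in gens
    }
    moms = {
        gen: tab.loc[tab.generation == gen].set_index("worm")["mother"] for gen in gens
    }
    # unbroken[w] = worm w's chain was silenced through the previous generation
    durations: list[int] = []
    unbroken = None
    for gen in gens:
        s = sil[gen].to_numpy()
        if unbroken is None:
            unbroken = np.ones(s.size, dtype=bool)
        else:
            m = moms[gen].to_numpy()
            unbroken = prev_unbroken[m] & prev_sil[m]
        newly_lost = unbroken & ~s
        durations.extend([gen + 1] * int(newly_lost.sum()))
        prev_unbroken, prev_sil = unbroken, s
    lineage_censored = int((prev_unbroken & prev_sil).sum())
    return DurationSummary(
        population_T=population_T,
        censored=population_T is None,
        lineage_durations=np.asarray(durations, dtype=float),
        lineage_censored=lineage_censored,
        horizon=len(gens),
    )


@dataclass
class SisterResult:
    desilencing_generation: np.ndarray  # per sister; horizon+1 when censored
    censored: np.ndarray
    dispersion: float  # across-sister std of observed de-silencing generations


def sister_desilencing(
    ti_params: TIParams,
    config: PopulationConfig,
    mother_state: TIState | tuple[float, float],
    n_sisters: int | None = None,
) -> SisterResult:
    """De-silencing generation of sisters sharing one mother's end state.

    All sisters start from the identical inherited state and evolve
    independently (shared parameters, independent noise).  The
    across-sister standard deviation of the de-silencing generation is
    the uniformity statistic: near-zero dispersion means the sisters
    de-silence together, as observed experimentally.
    """
    if isinstance(mother_state, tuple):
        mother_state = TIState(*mother_state)
    n = n_sisters if n_sisters is not None else config.n_worms
    g = np.full(n, mother_state.g)
    h = np.full(n, mother_state.h)
    desil = np.full(n, config.n_generations + 1, dtype=float)
    alive = np.ones(n, dtype=bool)
    for gen in range(config.n_generations):
        rng = _gen_rng(config.seed, gen, stream=2)
        g, h = _evolve_generation(g, h, ti_params, config.generation_hours, config.dt, rng)
        s = np.hypot(g, h)
        lost = alive & (s <= config.s_silenced)
        desil[lost] = gen + 1
        alive &= ~lost
    observed = desil[~alive]
    dispersion = float(observed.std()) if observed.size else float("nan")
    return SisterResult(desilencing_generation=desil, censored=alive, dispersion=dispersion)


def duration_ensemble(
    ti_params: TIParams,
    config: PopulationConfig,
    init: TIState | tuple[float, float],
    V: np.ndarray | None = None,
    n_lineages: int | None = None,
) -> SisterResult:
    """De-silencing generation of independent worm lineages, optionally
    with per-lineage amplification capacity ``V`` (e.g. Gaussian
    variation around V_crit, which produces the heavy-tailed duration
    distribution: lineages on the monostable side de-silence after the
    ghost delay, bistable ones persist).

    No selection is applied; each lineage inherits its own end state.
    Returns per-lineage de-silencing generations with censoring flags.
    """
    if isinstance(init, tuple):
        init = TIState(*init)
    n = n_lineages if n_lineages is not None else (V.size if V is not None else config.n_worms)
    if V is not None and V.size != n:
        raise ValueError("V must have one entry per lineage")
    g = np.full(n, init.g)
    h = np.full(n, init.h)
    desil = np.full(n, config.n_generations + 1, dtype=float)
    alive = np.ones(n, dtype=bool)
    n_steps = int(round(config.generation_hours / config.dt))
    sqdt = math.sqrt(config.dt)
    noisy = ti_params.sigma1 > 0 or ti_params.sigma2 > 0
    for gen in range(config.n_generations):
        rng = _gen_rng(config.seed, gen, stream=3)
        for _ in range(n_steps):
            dW = rng.standard_normal((2, n)) * sqdt if noisy else (0.0, 0.0)
            g, h = _em_step(g, h, ti_params, 0.0, config.dt, dW[0], dW[1], V=V)
        s = np.hypot(g, h)
        lost = alive & (s <= config.s_silenced)
        desil[lost] = gen + 1
        alive &= ~lost
    observed = desil[~alive]
    dispersion = float(observed.std()) if observed.size else float("nan")
    return SisterResult(desilencing_generation=desil, censored=alive, dispersion=dispersion)


def dilution_factor(n_eggs: float = 250, n_generations: int = 4) -> float:
    """Passive dilution of silencing factors over generations in the
    absence of amplification: each animal partitions its pool between
    ~``n_eggs`` offspring, giving n_eggs**n_generations overall
    (~4e9 over a typical 4-generation memory)."""
    if n_eggs <= 0 or n_generations < 0:
        raise ValueError("need n_eggs > 0 and n_generations >= 0")
    return float(n_eggs) ** n_generations


def arrival_rate(N: int, q: float, M: int = 0) -> float:
    """Mean arrival rate of new silencing events per generation,
    lambda = q * (N - M), for N silenceable genes of which M are
    currently silenced."""
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    if M < 0 or M > N:
        raise ValueError("need 0 <= M <= N")
    return q * (N - M)
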