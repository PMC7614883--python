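"""Estimators shared across experiments: survival curves, power-law
tail fits, lineage autocorrelation, and the four regime-discrimination
statistics (duration scale, tail flatness, correlation time, sister
de-silencing uniformity) used to compare monostable, critical, bistable
and mixed configurations against the observed phenomenology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats as sp_stats

__all__ = [
    "DurationSample",
    "SurvivalCurve",
    "TailFit",
    "RegimeScores",
    "empirical_survival",
    "tail_exponent",
    "lineage_autocorrelation",
    "autocorrelation_time",
    "regime_discriminator",
]


@dataclass
class DurationSample:
    """Silencing durations (generations, > 0) with censoring flags;
    censored entries carry the last observed time."""

    durations: np.ndarray
    censored: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if self.durations.size == 0:
            raise ValueError("empty duration sample")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")
        if self.censored is None:
            self.censored = np.zeros(self.durations.size, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)
            if self.censored.shape != self.durations.shape:
                raise ValueError("censoring flags must match durations")

    @property
    def observed(self) -> np.ndarray:
        return self.durations[~self.censored]


@dataclass
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


def empirical_survival(sample: DurationSample) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) survival estimate honouring
    censoring; on fully uncensored data this equals 1 - ECDF."""
    if sample.censored.all():
        raise ValueError("all durations censored: survival curve undefined")
    km = KaplanMeierFitter()
    km.fit(sample.durations, event_observed=~sample.censored)
    times = km.survival_function_.index.to_numpy(dtype=float)
    surv = km.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array(
        [int((sample.durations >= t).sum()) for t in times], dtype=int
    )
    keep = times > 0
    return SurvivalCurve(times=times[keep], survival=surv[keep], at_risk=at_risk[keep])


@dataclass
class TailFit:
    slope: float
    stderr: float
    window: tuple[float, float]
    n_tail: int
    slope_alt: float  # same fit on a half-decade-shifted window

    @property
    def window_sensitivity(self) -> float:
        """|slope - slope_alt|; large values flag non-power-law tails."""
        return abs(self.slope - self.slope_alt)


def _logbin_slope(
    x: np.ndarray, lo: float, hi: float, n_bins: int
) -> tuple[float, float, int]:
    edges = np.logspace(math.log10(lo), math.log10(hi), n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / (widths * x.size)
    keep = counts > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 occupied bins in the tail window")
    fit = sp_stats.linregress(np.log(centers[keep]), np.log(dens[keep]))
    return float(fit.slope), float(fit.stderr), int(counts.sum())


def tail_exponent(
    durations: np.ndarray | DurationSample,
    upper_quantile: float = 0.999,
    decades: float = 1.0,
    n_bins: int = 20,
    min_tail: int = 100,
) -> TailFit:
    """Power-law exponent of the large-T tail of a duration sample.

    The density is estimated on logarithmic bins over the top
    ``decades`` of durations (window ending at the ``upper_quantile``
    duration) and its log-log slope fitted by ordinary least squares.
    A second fit on a half-decade-shifted window is reported so that
    window-dependence (the signature of a non-power-law tail, e.g.
    exponential) is visible.  Invariant under rescaling of durations.
    """
    if isinstance(durations, DurationSample):
        durations = durations.observed
    x = np.asarray(durations, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < min_tail:
        raise ValueError(f"need at least {min_tail} observations, got {x.size}")
    hi = float(np.quantile(x, upper_quantile))
    lo = hi / 10.0**decades
    n_tail = int(((x >= lo) & (x <= hi)).sum())
    if n_tail < min_tail:
        raise ValueError(
            f"insufficient tail mass: {n_tail} observations in [{lo:.3g}, {hi:.3g}]"
        )
    slope, se, _ = _logbin_slope(x, lo, hi, n_bins)
    shift = 10.0 ** (decades / 2.0)
    slope_alt, _, _ = _logbin_slope(x, lo / shift, hi / shift, n_bins)
    return TailFit(slope=slope, stderr=se, window=(lo, hi), n_tail=n_tail, slope_alt=slope_alt)


def lineage_autocorrelation(trajectories: np.ndarray, lag: int) -> float:
    """Across-trajectory Pearson correlation between states at t and
    t + lag, averaged over time origins.

    ``trajectories`` has shape (n_lineages, n_times); ``lag`` is in
    index units.  Raises on degenerate (zero-variance) ensembles.
    """
    X = np.asarray(trajectories, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D ensemble with >= 2 time points")
    if not 0 <= lag < X.shape[1]:
        raise ValueError("lag out of range")
    if lag == 0:
        if np.all(X.std(axis=0) == 0):
            raise ValueError("degenerate ensemble: zero variance at every time")
        return 1.0
    cors = []
    for t0 in range(X.shape[1] - lag):
        a, b = X[:, t0], X[:, t0 + lag]
        if a.std() == 0 or b.std() == 0:
            continue
        cors.append(np.corrcoef(a, b)[0, 1])
    if not cors:
        raise ValueError("degenerate ensemble: zero variance at every time")
    return float(np.mean(cors))


def autocorrelation_time(trajectories: np.ndarray, dt: float = 1.0, max_lag: int | None = None) -> float:
    """Lag (in units of dt) at which the lineage autocorrelation first
    drops below 1/e; returns the maximal probed lag if it never does."""
    X = np.asarray(trajectories, dtype=float)
    n = X.shape[1]
    max_lag = max_lag or n - 1
    for lag in range(1, max_lag + 1):
        try:
            c = lineage_autocorrelation(X, lag)
        except ValueError:
            return float(lag * dt)
        if c < 1.0 / math.e:
            return float(lag * dt)
    return float(max_lag * dt)


@dataclass
class RegimeScores:
    """The four discrimination statistics: can the configuration give
    multi-generation (finite) durations, a heavy tail, persistent
    heritable variation, and uniform sister de-silencing?"""

    duration_scale: float  # mean observed duration (generations)
    censored_fraction: float
    tail_slope: float | None  # None when the tail carries too little mass
    autocorr_time: float  # generations
    sister_dispersion: float  # std of sister de-silencing generation


def regime_discriminator(
    sample: DurationSample,
    state_ensemble: np.ndarray,
    sister_generations: np.ndarray,
    ensemble_dt_generations: float = 1.0,
) -> RegimeScores:
    """Package the four criterion statistics from simulated data of one
    configuration (durations, an (n_lineages, n_times) silencing-state
    ensemble, and per-sister de-silencing generations)."""
    obs = sample.observed
    duration_scale = float(obs.mean()) if obs.size else float("inf")
    censored_fraction = float(sample.censored.mean())
    try:
        tail = tail_exponent(sample, min_tail=50).slope
    except ValueError:
        tail = None
    act = autocorrelation_time(state_ensemble, dt=ensemble_dt_generations)
    sisters = np.asarray(sister_generations, dtype=float)
    sisters = sisters[np.isfinite(sisters)]
    dispersion = float(sisters.std()) if sisters.size else float("nan")
    return RegimeScores(
        duration_scale=duration_scale,
        censored_fraction=censored_fraction,
        tail_slope=tail,
        autocorr_time=act,
        sister_dispersion=dispersion,
    )
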