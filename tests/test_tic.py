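"""Resource-competition simulator: arrivals, queuing steady state,
self-tuning to criticality, closed forms, feedback variants."""

import dataclasses

import numpy as np
import pytest

from ticsim import (
    TICConfig,
    FeedbackSpec,
    closed_form_M,
    closed_form_T,
    littles_law_residual,
    per_gene_variation,
    perturbation_response,
    run_tic,
    run_tic_with_feedback,
)
from ticsim.tic import GenePool, arrivals, step_tic


@pytest.fixture(scope="module")
def stationary_run(crit):
    """A stationary competition run shared by several checks
    (V_tot=100, lam=10, started empty)."""
    cfg = TICConfig(V_tot=100.0, lam=10.0)
    return run_tic(cfg, n_generations=300, seed=1, burn_in_frac=0.4, crit=crit)


class TestArrivals:
    def test_zero_probability_means_no_arrivals(self, rng):
        cfg = TICConfig(V_tot=10.0, N=100, q=0.0, lam=None)
        assert all(arrivals(cfg, 0, rng) == 0 for _ in range(50))

    def test_mean_rate_matches_worked_example(self, rng):
        # N=1000, q=0.01, M=0: ten new silencing events per generation
        cfg = TICConfig(V_tot=10.0, N=1000, q=0.01, lam=None)
        draws = np.array([arrivals(cfg, 0, rng) for _ in range(3000)])
        assert draws.mean() == pytest.approx(10.0, rel=0.05)

    @pytest.mark.parametrize(
        "mode,expected_ratio",
        [("poisson", 1.0), ("binomial", 0.99)],  # var/mean; binomial: 1-q
    )
    def test_dispersion(self, rng, mode, expected_ratio):
        if mode == "poisson":
            cfg = TICConfig(V_tot=10.0, lam=10.0)
        else:
            cfg = TICConfig(V_tot=10.0, N=1000, q=0.01, lam=None)
        draws = np.array([arrivals(cfg, 0, rng) for _ in range(5000)])
        assert draws.var() / draws.mean() == pytest.approx(expected_ratio, abs=0.06)

    def test_finite_n_saturates(self, rng):
        cfg = TICConfig(V_tot=10.0, N=50, q=0.5, lam=None)
        assert arrivals(cfg, 50, rng) == 0

    def test_config_requires_exactly_one_mode(self):
        with pytest.raises(ValueError):
            TICConfig(V_tot=10.0, N=10, q=0.1, lam=5.0)
        with pytest.raises(ValueError):
            TICConfig(V_tot=10.0, lam=None)


class TestStepTic:
    def test_empty_pool_is_static_with_floor_cost(self, rng):
        cfg = TICConfig(V_tot=50.0, lam=10.0)
        pool = GenePool()
        C = step_tic(pool, cfg, 0.1, rng, 0, c_min=0.05)
        assert C == 0.05
        assert pool.M == 0

    def test_single_gene_self_normalizes(self, rng):
        # with one active gene the drive is V_tot/g * Hill(g): evaluate one
        # deterministic step by hand
        p = dataclasses.replace(TICConfig().ti, sigma1=0.0, sigma2=0.0)
        cfg = TICConfig(V_tot=10.0, lam=10.0, ti=p)
        pool = GenePool()
        pool.inject(1, 2.0, 1.0, 0)
        step_tic(pool, cfg, 0.1, rng, 0, c_min=0.01)
        Veff = 10.0 / 2.0
        dg = (Veff * 4.0 / 5.0 * 1.0 / 2.0 - 0.1 * 2.0) * 0.1
        dh = (1.0 * 2.0 / 3.0 - 0.1 * 1.0) * 0.1
        assert pool.g[0] == pytest.approx(2.0 + dg, rel=1e-12)
        assert pool.h[0] == pytest.approx(1.0 + dh, rel=1e-12)

    def test_identical_genes_stay_identical_without_noise(self, rng):
        p = dataclasses.replace(TICConfig().ti, sigma1=0.0, sigma2=0.0)
        cfg = TICConfig(V_tot=10.0, lam=10.0, ti=p)
        pool = GenePool()
        pool.inject(2, 3.0, 0.0, 0)
        for i in range(500):
            step_tic(pool, cfg, 0.1, rng, 0, c_min=0.01)
        assert pool.g[0] == pool.g[1] and pool.h[0] == pool.h[1]


class TestClosedForms:
    def test_worked_example_coefficient(self):
        # N=1000, q=0.01, c_crit=V_crit=1: T = 100*V_tot/(1000 - V_tot)
        for v in [50.0, 200.0, 500.0, 900.0]:
            assert closed_form_T(v, 1.0, 1.0, q=0.01, N=1000) == pytest.approx(
                100.0 * v / (1000.0 - v), rel=1e-12
            )
        assert closed_form_T(500.0, 1.0, 1.0, q=0.01, N=1000) == pytest.approx(100.0)

    def test_large_n_limit(self):
        assert closed_form_T(500.0, 1.0, 1.0, lam=10.0) == pytest.approx(50.0)
        assert closed_form_M(500.0, 1.0, 1.0) == pytest.approx(500.0)

    def test_saturated_queue_raises(self):
        with pytest.raises(ValueError, match="infinite"):
            closed_form_T(1000.0, 1.0, 1.0, q=0.01, N=1000)


class TestSelfTuning:
    def test_from_empty_pool_veff_settles_at_v_crit(self, stationary_run):
        s = stationary_run.summary
        assert stationary_run.stationary
        assert abs(s.v_eff_distance) < 0.05

    def test_from_loaded_pool_veff_settles_at_v_crit(self, crit):
        # start well past the stationary load: monostable shedding, then
        # convergence to the same critical state from below
        cfg = TICConfig(V_tot=100.0, lam=10.0)
        res = run_tic(
            cfg, n_generations=300, seed=2, burn_in_frac=0.4, initial_pool=400, crit=crit
        )
        # the overloaded start is sub-critical and most of the excess is
        # shed within the first generations (fast dilution; the chromatin
        # mark h outlives g by ~1/gamma2, so retirement lags one generation)
        assert res.per_generation["M"].iloc[1] < 200
        assert abs(res.summary.v_eff_distance) < 0.05

    def test_littles_law_residual_small(self, stationary_run):
        assert littles_law_residual(stationary_run.summary) < 0.1

    def test_closed_form_m_within_15_percent(self, stationary_run, crit):
        expected = closed_form_M(100.0, crit.c_crit, crit.V_crit)
        assert stationary_run.summary.M == pytest.approx(expected, rel=0.15)

    def test_closed_form_t_within_20_percent(self, stationary_run, crit):
        expected = closed_form_T(100.0, crit.c_crit, crit.V_crit, lam=10.0)
        assert stationary_run.summary.T == pytest.approx(expected, rel=0.20)

    def test_gene_accounting_conserved(self, stationary_run):
        pool = stationary_run.pool
        assert pool.n_arrived == pool.M + pool.n_retired
        assert stationary_run.per_generation["arrivals"].sum() == pool.n_arrived
        assert np.all(stationary_run.durations["duration"] >= 1)

    def test_seed_reproducibility(self, crit):
        cfg = TICConfig(V_tot=40.0, lam=10.0)
        a = run_tic(cfg, n_generations=30, seed=9, crit=crit)
        b = run_tic(cfg, n_generations=30, seed=9, crit=crit)
        assert a.per_generation.equals(b.per_generation)
        assert a.durations.equals(b.durations)


class TestFeedback:
    def test_fast_proportional_gain_matches_cost_normalized(self, crit):
        cfg = TICConfig(V_tot=40.0, lam=10.0)
        prop = run_tic_with_feedback(
            cfg,
            FeedbackSpec(mode="proportional-ODE", gamma_V=0.1),
            n_generations=120,
            seed=1,
            burn_in_frac=0.5,
            crit=crit,
        )
        base = run_tic(cfg, n_generations=120, seed=1, burn_in_frac=0.5, crit=crit)
        assert prop.summary.M == pytest.approx(base.summary.M, rel=0.1)
        assert prop.summary.T == pytest.approx(base.summary.T, rel=0.15)

    def test_integral_feedback_balances_cost_against_budget(self, crit):
        # stationarity of dV/dt = gamma_V (V_tot - C) requires <C> = V_tot
        cfg = TICConfig(V_tot=150.0, lam=10.0)
        res = run_tic_with_feedback(
            cfg,
            FeedbackSpec(mode="integral-ODE", gamma_V=0.001),
            n_generations=300,
            seed=3,
            burn_in_frac=0.5,
            crit=crit,
        )
        burn = res.summary.window[0]
        C_bar = res.per_generation["C"].iloc[burn:].mean()
        assert C_bar == pytest.approx(150.0, rel=0.15)
        # and the capacity self-tunes near the critical scale
        assert res.V_trace[burn:].mean() == pytest.approx(crit.V_crit, rel=0.15)

    def test_feedforward_makes_duration_independent_of_arrival_rate(self, crit):
        # V_tot = eta*lam cancels lam: T = eta/(c_crit*V_crit)
        eta = 10.0
        Ts = {}
        for lam in (5.0, 10.0):
            cfg = TICConfig(V_tot=1.0, lam=lam)  # V_tot replaced by eta*lam
            res = run_tic_with_feedback(
                cfg,
                FeedbackSpec(mode="feedforward", eta=eta),
                n_generations=200,
                seed=4,
                burn_in_frac=0.4,
                crit=crit,
            )
            Ts[lam] = res.summary.T
        assert Ts[10.0] == pytest.approx(Ts[5.0], rel=0.25)
        expected = eta / (crit.c_crit * crit.V_crit)
        assert Ts[10.0] == pytest.approx(expected, rel=0.30)

    def test_bad_specs_rejected(self):
        with pytest.raises(ValueError):
            FeedbackSpec(mode="banana")
        with pytest.raises(ValueError):
            FeedbackSpec(mode="feedforward")  # eta missing


class TestPerturbation:
    def test_up_down_asymmetry(self, crit):
        # down-steps shed genes at the dilution rate (fast); up-steps refill
        # at the arrival rate (slow, ~ M/lambda generations)
        cfg = TICConfig(V_tot=40.0, lam=10.0)
        res = perturbation_response(
            cfg, factor=2.0, n_stationary=80, n_after=80, seed=5, crit=crit
        )
        assert res.relaxation_down <= 3.0  # ~1/gamma1 = 10 hr << 1 generation
        assert res.relaxation_up >= 3.0 * res.relaxation_down
        assert res.asymmetry > 1.0


class TestPerGeneVariation:
    def test_silenced_subgroup_stays_critical_as_spread_grows(self, crit):
        cfg = TICConfig(V_tot=100.0, lam=10.0)
        out = per_gene_variation(cfg, spread=30.0, n_generations=250, seed=6, crit=crit)
        # genes that persist see an effective capacity near V_crit ...
        assert out.V_eff_silenced == pytest.approx(crit.V_crit, rel=0.15)
        # ... while the across-arrivals average drifts below it
        assert out.V_eff_overall < out.V_eff_silenced
        # low-capacity arrivals are shed quickly
        assert out.excluded_fraction > 0.05

    def test_zero_spread_reduces_to_plain_run(self, crit):
        cfg = TICConfig(V_tot=40.0, lam=10.0)
        out = per_gene_variation(cfg, spread=0.0, n_generations=60, seed=7, crit=crit)
        base = run_tic(cfg, n_generations=60, seed=7, crit=crit)
        assert out.summary.M == pytest.approx(base.summary.M)
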