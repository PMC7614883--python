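"""Single-gene TI circuit: drift, nullclines, fixed points, bifurcation,
and trajectory simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ticsim import (
    TIParams,
    TIState,
    TriggerSchedule,
    find_fixed_points,
    find_v_crit,
    jacobian,
    nullcline_g,
    nullcline_h,
    silencing_degree,
    simulate_ti,
    ti_drift,
)


class TestDrift:
    def test_origin_is_a_fixed_point(self, default_params):
        dg, dh = ti_drift(0.0, 0.0, default_params, I=0.0)
        assert dg == 0.0 and dh == 0.0

    def test_g_nullcline_zeroes_dg(self, default_params):
        # any point on the nontrivial g-nullcline must satisfy dg/dt = 0
        for g in [0.3, 0.6, 1.0, 2.5, 7.0]:
            h = float(nullcline_g(g, default_params))
            dg, _ = ti_drift(g, h, default_params, I=0.0)
            assert abs(dg) < 1e-12

    def test_rational_point_hand_evaluation(self):
        # V=2, k=1, n=2, psi=1, gamma=0.1 at (g,h)=(1,0):
        # dg = 2 * 1/2 * 1 - 0.1 = 0.9 ; dh = 1 * 1/2 - 0 = 0.5
        p = TIParams(V=2.0)
        dg, dh = ti_drift(1.0, 0.0, p)
        assert dg == pytest.approx(0.9, abs=1e-15)
        assert dh == pytest.approx(0.5, abs=1e-15)

    def test_rejects_nonfinite_and_negative_trigger(self, default_params):
        with pytest.raises(ValueError):
            ti_drift(float("nan"), 0.0, default_params)
        with pytest.raises(ValueError):
            ti_drift(1.0, 1.0, default_params, I=-1.0)


class TestNullclines:
    def test_extremum_location_and_height_n2(self):
        # for n=2 the extremum sits exactly at g = k1 with
        # h_max = k2*(V/(2*gamma1*k1) - 1)
        p = TIParams(V=2.0, k1=1.3)
        g_max = (p.n - 1) ** (1 / p.n) * p.k1
        expected = p.k2 * (p.V / (2 * p.gamma1 * p.k1) - 1)
        assert nullcline_g(g_max, p) == pytest.approx(expected, rel=1e-12)
        # numerical maximisation agrees
        g = np.linspace(0.01, 10, 20001)
        assert abs(g[np.argmax(nullcline_g(g, p))] - g_max) < 2e-3

    def test_entirely_negative_when_v_below_threshold(self):
        # V/gamma1 < 2*k1 leaves no physical branch
        p = TIParams(V=0.15, gamma1=0.1, k1=1.0)
        g = np.linspace(1e-3, 50, 5000)
        assert np.all(nullcline_g(g, p) < 0)

    def test_linear_decay_at_large_g(self, default_params):
        p = default_params
        for g in [50.0, 200.0]:
            approx = p.k2 * (p.V / (p.gamma1 * g) - 1)
            assert nullcline_g(g, p) == pytest.approx(approx, rel=1e-3)

    def test_h_nullcline_saturates(self, default_params):
        p = default_params
        assert nullcline_h(0.0, p) == 0.0
        assert nullcline_h(p.k3, p) == pytest.approx(p.psi / (2 * p.gamma2))
        assert nullcline_h(1e7, p) == pytest.approx(p.psi / p.gamma2, rel=1e-6)
        h = nullcline_h(np.linspace(0, 20, 100), p)
        assert np.all(np.diff(h) > 0)

    def test_rejects_nonpositive_g(self, default_params):
        with pytest.raises(ValueError):
            nullcline_g(0.0, default_params)


class TestJacobian:
    def test_origin_closed_form(self, default_params):
        p = default_params
        J = jacobian(0.0, 0.0, p)
        assert np.allclose(J, [[-p.gamma1, 0.0], [p.psi / p.k3, -p.gamma2]])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        g=st.floats(0.01, 8.0),
        h=st.floats(0.0, 8.0),
        V=st.floats(0.3, 4.0),
    )
    def test_matches_finite_differences(self, g, h, V):
        p = TIParams(V=V)
        J = jacobian(g, h, p)
        eps = 1e-6
        fd = np.empty((2, 2))
        for j, (dg_, dh_) in enumerate([(eps, 0.0), (0.0, eps)]):
            up = ti_drift(g + dg_, h + dh_, p)
            dn = ti_drift(g - dg_, max(h - dh_, 0.0), p)
            denom = 2 * eps if (j == 0 or h >= eps) else eps
            for i in range(2):
                fd[i, j] = (up[i] - dn[i]) / denom
        assert np.allclose(J, fd, rtol=1e-4, atol=1e-5)


def _grid_count(params, n_grid=100_000):
    """Brute-force fixed-point count: sign changes of the nullcline
    difference on a dense grid, plus the origin."""
    g = np.linspace(1e-7, max(10.0, 2 * params.V / params.gamma1), n_grid)
    d = nullcline_g(g, params) - nullcline_h(g, params)
    return 1 + int((np.diff(np.sign(d)) != 0).sum())


class TestFixedPoints:
    def test_monostable_single_stable_origin(self, default_params):
        fps = find_fixed_points(default_params.with_V(0.5))
        assert len(fps) == 1
        assert fps[0].g == 0.0 and fps[0].stability == "stable"
        assert sorted(e.real for e in fps[0].eigenvalues) == pytest.approx(
            sorted([-default_params.gamma1, -default_params.gamma2])
        )

    def test_bistable_three_points(self, default_params):
        fps = find_fixed_points(default_params.with_V(2.0))
        assert len(fps) == 3
        fps.sort(key=lambda f: f.g)
        assert fps[0].stability == "stable"  # origin
        assert fps[1].stability == "unstable"  # low-g saddle
        assert fps[2].stability == "stable"  # high-g silenced state
        for fp in fps:
            dg, dh = ti_drift(fp.g, fp.h, default_params.with_V(2.0))
            assert abs(dg) < 1e-8 and abs(dh) < 1e-8

    @pytest.mark.parametrize("V", [0.3, 0.9, 1.05, 1.1, 1.5, 3.0, 10.0])
    def test_count_matches_grid_scan(self, default_params, V):
        p = default_params.with_V(V)
        assert len(find_fixed_points(p)) == _grid_count(p)

    def test_locations_match_grid_scan_roots(self, default_params):
        p = default_params.with_V(2.0)
        g = np.linspace(1e-7, 40, 100_000)
        d = nullcline_g(g, p) - nullcline_h(g, p)
        idx = np.nonzero(np.diff(np.sign(d)))[0]
        brute = [(g[i] + g[i + 1]) / 2 for i in idx]
        ours = sorted(fp.g for fp in find_fixed_points(p) if fp.g > 0)
        assert len(brute) == len(ours)
        for b, o in zip(sorted(brute), ours):
            assert abs(b - o) < 1e-3

    def test_positive_trigger_shifts_origin(self, default_params):
        # small I and weak amplification so the g ~ I/gamma1 shift dominates
        I = 0.002
        fps = find_fixed_points(default_params.with_V(0.2), I=I)
        low = min(fps, key=lambda f: f.g)
        assert low.g == pytest.approx(I / default_params.gamma1, rel=0.05)
        assert low.stability == "stable"


class TestVCrit:
    def test_count_flips_across_v_crit(self, default_params, crit):
        eps = 10 * 1e-8 * crit.V_crit
        assert len(find_fixed_points(default_params.with_V(crit.V_crit - eps))) == 1
        assert len(find_fixed_points(default_params.with_V(crit.V_crit + eps))) == 3

    def test_count_is_a_single_step_in_v(self, default_params, crit):
        vs = np.linspace(0.3, 4.0, 40)
        counts = np.array(
            [len(find_fixed_points(default_params.with_V(v))) for v in vs]
        )
        assert set(counts) == {1, 3}
        jumps = np.nonzero(np.diff(counts))[0]
        assert len(jumps) == 1
        assert vs[jumps[0]] < crit.V_crit < vs[jumps[0] + 1]

    def test_marginal_eigenvalue_at_coalescence(self, default_params, crit):
        J = jacobian(crit.g_crit, crit.h_crit, default_params.with_V(crit.V_crit))
        eigs = np.sort(np.real(np.linalg.eigvals(J)))
        assert abs(eigs[1]) < 1e-6  # the slow direction loses stability
        # the fast direction is the h-relaxation, -gamma2 up to g-coupling
        assert eigs[0] < 0
        assert 0.3 * default_params.gamma2 < -eigs[0] < 1.5 * default_params.gamma2

    def test_c_crit_is_g_crit(self, crit):
        assert crit.c_crit == crit.g_crit

    def test_invalid_bracket_raises(self, default_params):
        with pytest.raises(ValueError, match="bracket"):
            find_v_crit(default_params, bracket=(2.0, 10.0))


class TestSimulateTI:
    def test_origin_stays_at_origin(self, default_params):
        traj = simulate_ti(
            default_params.without_noise(), init=(0.0, 0.0), t_end=72.0, seed=1
        )
        assert np.all(traj.g == 0.0) and np.all(traj.h == 0.0)

    def test_small_perturbation_decays_at_dilution_rate(self, default_params):
        p = default_params.without_noise()
        traj = simulate_ti(p, init=(1e-4, 0.0), t_end=40.0, dt=0.01, seed=0)
        rate = -(np.log(traj.g[-1]) - np.log(traj.g[0])) / traj.t[-1]
        assert rate == pytest.approx(p.gamma1, rel=2e-3)

    def test_pulse_reaches_high_fixed_point_in_bistable_regime(self, default_params):
        p = default_params.with_V(2.0).without_noise()
        high = max(find_fixed_points(p), key=lambda f: f.g)
        traj = simulate_ti(
            p,
            init=(0.0, 0.0),
            trigger=TriggerSchedule.pulse(amplitude=1.0, duration=72.0),
            t_end=4000.0,
            seed=0,
        )
        assert traj.g[-1] == pytest.approx(high.g, rel=1e-3)
        assert traj.h[-1] == pytest.approx(high.h, rel=1e-3)

    def test_seed_replay_is_bit_identical(self, default_params):
        kw = dict(init=(2.0, 1.0), t_end=144.0, seed=42)
        a = simulate_ti(default_params, **kw)
        b = simulate_ti(default_params, **kw)
        assert np.array_equal(a.g, b.g) and np.array_equal(a.h, b.h)
        c = simulate_ti(default_params, init=(2.0, 1.0), t_end=144.0, seed=43)
        assert not np.array_equal(a.g, c.g)

    def test_deterministic_bounds(self, default_params):
        p = default_params.with_V(2.0).without_noise()
        traj = simulate_ti(p, init=(4.0, 9.0), t_end=2000.0, seed=0)
        assert np.all(traj.g >= 0) and np.all(traj.h >= 0)
        assert np.all(traj.g <= max(4.0, p.V / p.gamma1) + 1e-9)
        assert np.all(traj.h <= max(9.0, p.psi / p.gamma2) + 1e-9)

    def test_small_noise_ensemble_tracks_deterministic(self, default_params):
        import dataclasses

        p = dataclasses.replace(default_params.with_V(2.0), sigma1=0.01, sigma2=0.01)
        det = simulate_ti(p.without_noise(), init=(3.0, 0.0), t_end=300.0, seed=0)
        ends = [
            simulate_ti(p, init=(3.0, 0.0), t_end=300.0, seed=s).g[-1]
            for s in range(25)
        ]
        assert np.mean(ends) == pytest.approx(det.g[-1], rel=0.05)

    def test_generation_markers_and_desilencing_event(self, default_params):
        p = default_params.without_noise()  # monostable: V=1.5? default is above crit
        p = p.with_V(0.8)
        traj = simulate_ti(p, init=(3.0, 0.0), t_end=720.0, seed=0)
        assert traj.generation[0] == 0 and traj.generation[-2] == 9
        # monostable decay from a silenced state must cross s_silenced
        assert traj.desilencing_time is not None
        s = traj.s
        i = np.searchsorted(traj.t, traj.desilencing_time)
        assert s[i] <= 1.0 < s[: max(i, 1)].max()


class TestSilencingDegree:
    def test_euclidean_norm(self):
        assert silencing_degree(0.0, 0.0) == 0.0
        assert silencing_degree(3.0, 4.0) == 5.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(g=st.floats(0, 100), h=st.floats(0, 100))
    def test_definition(self, g, h):
        assert silencing_degree(g, h) ** 2 == pytest.approx(g * g + h * h, rel=1e-12)

    def test_state_validation(self):
        with pytest.raises(ValueError):
            TIState(-1.0, 0.0)
        with pytest.raises(ValueError):
            TIState(float("inf"), 0.0)
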