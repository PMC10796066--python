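"""Steady-state, regime, nullcline, trajectory and dispersion tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erythema_rd.model_core import Params, jacobian, reaction_rates
from erythema_rd.phase_plane import (StimPulse, classify_regime,
                                     dispersion_relation, find_steady_states,
                                     nullclines, regime_report, trajectory)

BASELINE = Params(p_a=0.05, q_a=3.0, r_a=0.8, p_i=0.12, q_i=6.0)
SHRINKAGE = Params(p_a=0.03, q_a=2.0, r_a=0.99, p_i=0.02, q_i=6.0)


def sign_scan_roots(params, n_grid=2000):
    """Brute-force oracle: nullcline intersections via dense sign scan.

    On an (a, i) lattice over the invariant box, cells where both
    rates change sign across the cell are flagged; flagged clusters
    are refined by bisection-like subdivision.  Independent of the
    production root finder.
    """
    a = np.linspace(1e-9, params.a_max * 1.001, n_grid)
    i = np.linspace(0.0, params.i_max * 1.001, n_grid)
    A, I = np.meshgrid(a, i, indexing="ij")
    ra, ri = reaction_rates(A, I, params)
    sa = np.sign(ra)
    si = np.sign(ri)
    # sign change of rate_a along a (rows) and of rate_i along i (cols)
    ca = (sa[:-1, :-1] * sa[1:, :-1] <= 0) | (sa[:-1, :-1] * sa[:-1, 1:] <= 0)
    ci = (si[:-1, :-1] * si[1:, :-1] <= 0) | (si[:-1, :-1] * si[:-1, 1:] <= 0)
    hits = np.argwhere(ca & ci)
    pts = np.column_stack([a[hits[:, 0]], i[hits[:, 1]]])
    # cluster adjacent hits
    roots = []
    da = a[1] - a[0]
    di = i[1] - i[0]
    for p in pts:
        for r in roots:
            if abs(p[0] - r[0]) < 2 * da and abs(p[1] - r[1]) < 2 * di:
                break
        else:
            roots.append(p)
    # polish each cluster with Newton on the analytic system
    out = []
    for a0, i0 in roots:
        x = np.array([a0, i0])
        for _ in range(60):
            f = np.array(reaction_rates(max(x[0], 0), max(x[1], 0), params))
            J = jacobian(max(x[0], 0), max(x[1], 0), params)
            try:
                step = np.linalg.solve(J, f)
            except np.linalg.LinAlgError:
                break
            x = x - step
            if np.linalg.norm(step) < 1e-13:
                break
        if np.linalg.norm(reaction_rates(max(x[0], 0), max(x[1], 0), params)) < 1e-9:
            if all(np.hypot(x[0] - u[0], x[1] - u[1]) > 1e-5 for u in out):
                out.append((float(x[0]), float(x[1])))
    return sorted(out)


class TestFindSteadyStates:
    def test_linear_system_single_stable_state(self):
        p = Params(p_a=0.05, q_a=0.0, r_a=0.8, p_i=0.12, q_i=0.0)
        states = find_steady_states(p)
        assert len(states) == 1
        s = states[0]
        assert s.a_star == pytest.approx(0.05 / 0.8, abs=1e-8)
        assert s.i_star == pytest.approx(0.12, abs=1e-8)
        assert s.stability == "stable"

    def test_baseline_census_one_stable_two_unstable(self):
        """The healthy-skin parameter point is excitable: a single
        attractor plus two unstable states."""
        states = find_steady_states(BASELINE)
        assert len(states) == 3
        assert sum(s.stability == "stable" for s in states) == 1
        assert sum(s.stability == "unstable" for s in states) == 2

    def test_baseline_locations_match_oracle(self):
        states = find_steady_states(BASELINE)
        oracle = sign_scan_roots(BASELINE)
        assert len(states) == len(oracle)
        for s, (a, i) in zip(states, oracle):
            assert s.a_star == pytest.approx(a, abs=1e-4)
            assert s.i_star == pytest.approx(i, abs=1e-4)

    def test_shrinkage_set_is_bistable(self):
        rep = classify_regime(find_steady_states(SHRINKAGE))
        assert rep.regime == "bistable"
        assert rep.S_H.a_star < rep.S_T.a_star < rep.S_I.a_star

    def test_roots_within_invariant_box(self):
        for p in (BASELINE, SHRINKAGE):
            for s in find_steady_states(p):
                assert 0 <= s.a_star <= p.a_max + 1e-9
                assert 0 <= s.i_star <= p.i_max + 1e-9

    def test_residual_small_at_roots(self):
        for s in find_steady_states(BASELINE):
            ra, ri = reaction_rates(s.a_star, s.i_star, BASELINE)
            assert abs(ra) < 1e-9 and abs(ri) < 1e-9

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence_random_params(self, data):
        """Root count and locations match the dense sign-scan oracle
        across the parameter ranges the simulations span."""
        p = Params(
            p_a=data.draw(st.floats(0.02, 0.06)),
            q_a=data.draw(st.floats(1.5, 6.0)),
            r_a=data.draw(st.floats(0.7, 1.1)),
            p_i=data.draw(st.floats(0.02, 0.3)),
            q_i=data.draw(st.floats(4.0, 7.0)),
        )
        states = find_steady_states(p)
        oracle = sign_scan_roots(p, n_grid=1200)
        assert len(states) == len(oracle)
        for s, (a, i) in zip(states, oracle):
            assert s.a_star == pytest.approx(a, abs=1e-4)
            assert s.i_star == pytest.approx(i, abs=1e-4)
        # positive basal production forces at least one attractor; rich
        # censuses (5 roots) can carry up to 3
        n_stable = sum(s.stability == "stable" for s in states)
        assert 1 <= n_stable <= 3


class TestClassifyRegime:
    def test_single_stable_is_monostable(self):
        p = Params(p_a=0.05, q_a=0.0, r_a=0.8, p_i=0.12, q_i=0.0)
        assert regime_report(p).regime == "monostable_plain"

    def test_bistable_roles_ordered(self):
        rep = regime_report(SHRINKAGE)
        assert rep.regime == "bistable"
        assert rep.S_H.stability == "stable"
        assert rep.S_I.stability == "stable"
        assert rep.S_T.stability == "unstable"
        assert rep.d_HT > 0 and rep.d_TI > 0

    def test_excitable_threshold_is_nearest_unstable(self):
        rep = regime_report(BASELINE)
        assert rep.regime == "excitable"
        unstable = [s for s in rep.states if s.stability == "unstable"]
        dists = [s.distance_to(rep.S_H) for s in unstable]
        assert rep.d_HT == pytest.approx(min(dists))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            classify_regime([])

    def test_regime_changes_along_baseline_to_shrinkage_segment(self):
        """A bifurcation (census change) separates the excitable
        healthy-skin point from the bistable shrinkage point."""
        regimes = []
        for lam in np.linspace(0.0, 1.0, 21):
            p = Params(
                p_a=(1 - lam) * BASELINE.p_a + lam * SHRINKAGE.p_a,
                q_a=(1 - lam) * BASELINE.q_a + lam * SHRINKAGE.q_a,
                r_a=(1 - lam) * BASELINE.r_a + lam * SHRINKAGE.r_a,
                p_i=(1 - lam) * BASELINE.p_i + lam * SHRINKAGE.p_i,
                q_i=(1 - lam) * BASELINE.q_i + lam * SHRINKAGE.q_i,
            )
            regimes.append(regime_report(p).regime)
        assert regimes[0] == "excitable"
        assert regimes[-1] == "bistable"
        assert len(set(regimes)) >= 2


class TestNullclines:
    def test_linear_system_lines(self):
        p = Params(p_a=0.05, q_a=0.0, r_a=0.8, p_i=0.12, q_i=0.0)
        a_br, i_br = nullclines(p, np.linspace(0.01, 0.2, 200))
        # a-nullcline collapses onto the vertical line a = p_a / r_a:
        # i values explode away from it, so check the i-nullcline is
        # the horizontal line i = p_i
        assert len(i_br) >= 1
        assert np.allclose(i_br[0][:, 1], 0.12, atol=1e-6)

    def test_closed_form_point(self):
        # a-nullcline at a=1: i = 3/(2*(0.8-0.05)) - 1 = 1.0
        a_br, _ = nullclines(BASELINE, np.array([1.0]))
        assert len(a_br) == 1
        assert a_br[0][0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_steady_states_lie_on_both_families(self):
        states = find_steady_states(BASELINE)
        grid = np.linspace(1e-3, BASELINE.a_max, 6000)
        a_br, i_br = nullclines(BASELINE, grid)
        for s in states:
            d_a = min(np.min(np.hypot(b[:, 0] - s.a_star, b[:, 1] - s.i_star))
                      for b in a_br)
            d_i = min(np.min(np.hypot(b[:, 0] - s.a_star, b[:, 1] - s.i_star))
                      for b in i_br)
            assert d_a < 5e-3 and d_i < 5e-3


class TestTrajectory:
    def test_linear_system_closed_form(self):
        p = Params(p_a=0.05, q_a=0.0, r_a=0.8, p_i=0.12, q_i=0.0)
        ts = trajectory(p, a0=1.0, i0=0.5, t_end=5.0)
        t = ts[:, 0]
        a_exact = 0.05 / 0.8 + (1.0 - 0.05 / 0.8) * np.exp(-0.8 * t)
        i_exact = 0.12 + (0.5 - 0.12) * np.exp(-t)
        assert np.allclose(ts[:, 1], a_exact, atol=1e-6)
        assert np.allclose(ts[:, 2], i_exact, atol=1e-6)

    def test_excitable_excursion_returns_to_healthy(self):
        """Supra-threshold stimulation at the excitable fading
        condition: a large transient excursion, then return to the
        healthy state.  (The census-baseline point is excluded here:
        its upper focus is surrounded by a stable limit cycle, so
        trajectories there oscillate instead of returning.)"""
        from erythema_rd.presets import FADING
        p = FADING.with_(D_a=0.0, D_i=0.0)
        rep = regime_report(p)
        ts = trajectory(p, a0=1.0, i0=0.01, t_end=120.0)
        assert ts[:, 1].max() > 1.0  # transient rise
        assert ts[-1, 1] == pytest.approx(rep.S_H.a_star, abs=1e-4)
        assert ts[-1, 2] == pytest.approx(rep.S_H.i_star, abs=1e-4)

    def test_baseline_supra_threshold_sustained_oscillation(self):
        """At the census-baseline point the same stimulation settles
        into sustained oscillations (stable limit cycle around the
        upper focus) — the pacemaker behind the wood-grain pattern."""
        ts = trajectory(BASELINE, a0=1.0, i0=0.01, t_end=400.0)
        late = ts[ts[:, 0] > 200.0, 1]
        assert late.max() - late.min() > 0.5

    def test_bistable_suprathreshold_reaches_inflamed(self):
        rep = regime_report(SHRINKAGE)
        ts = trajectory(SHRINKAGE, a0=1.0, i0=0.01, t_end=80.0)
        assert ts[-1, 1] == pytest.approx(rep.S_I.a_star, abs=1e-4)

    def test_pulse_applied_only_in_window(self):
        p = Params(p_a=0.05, q_a=0.0, r_a=0.8, p_i=0.12, q_i=0.0)
        pulse = StimPulse(t_on=10.0, t_off=11.0, amplitude=2.0)
        ts = trajectory(p, a0=0.0625, i0=0.12, t_end=30.0, pulse=pulse)
        before = ts[ts[:, 0] < 10.0]
        assert np.allclose(before[:, 1], 0.0625, atol=1e-9)
        peak_t = ts[np.argmax(ts[:, 1]), 0]
        assert 10.0 < peak_t < 12.0
        assert ts[-1, 1] == pytest.approx(0.0625, abs=1e-4)

    def test_matches_adaptive_integrator(self):
        from scipy.integrate import solve_ivp
        sol = solve_ivp(
            lambda t, y: reaction_rates(max(y[0], 0), max(y[1], 0), BASELINE),
            (0, 20.0), [1.0, 0.01], rtol=1e-10, atol=1e-12,
            dense_output=True)
        ts = trajectory(BASELINE, 1.0, 0.01, 20.0)
        ref = sol.sol(ts[:, 0])
        assert np.allclose(ts[:, 1], ref[0], atol=1e-5)
        assert np.allclose(ts[:, 2], ref[1], atol=1e-5)


class TestCsvWriters:
    def test_trajectory_roundtrip(self, tmp_path):
        from erythema_rd.phase_plane import save_trajectory_csv
        ts = trajectory(BASELINE, 0.5, 0.1, t_end=1.0)
        path = tmp_path / "traj.csv"
        save_trajectory_csv(path, ts)
        back = np.loadtxt(path, delimiter=",", skiprows=1)
        assert np.allclose(back, ts, atol=1e-9)

    def test_nullclines_csv_contains_both_families(self, tmp_path):
        from erythema_rd.phase_plane import save_nullclines_csv
        path = tmp_path / "null.csv"
        save_nullclines_csv(path, BASELINE, np.linspace(0.05, 1.5, 100))
        body = path.read_text()
        assert "a_nullcline" in body and "i_nullcline" in body


class TestDispersionRelation:
    def test_k_zero_matches_jacobian(self):
        rep = regime_report(BASELINE)
        lam = dispersion_relation(BASELINE, rep.S_H, [0.0])
        eig = np.linalg.eigvals(jacobian(rep.S_H.a_star, rep.S_H.i_star,
                                         BASELINE))
        assert lam[0] == pytest.approx(float(np.max(np.real(eig))))

    def test_equal_diffusion_shift_identity(self):
        rep = regime_report(BASELINE)
        ks = np.linspace(0.0, 10.0, 33)
        lam = dispersion_relation(BASELINE, rep.S_H, ks)
        assert np.allclose(lam, lam[0] - 0.3 * ks ** 2, atol=1e-10)

    def test_no_turing_instability_at_equal_diffusion(self):
        """Equal diffusion: no wavenumber can destabilize the stable
        healthy state."""
        rep = regime_report(BASELINE)
        ks = np.linspace(0.01, 10.0, 100)
        lam = dispersion_relation(BASELINE, rep.S_H, ks)
        lam0 = dispersion_relation(BASELINE, rep.S_H, [0.0])[0]
        assert np.all(lam < lam0)
        assert np.all(lam < 0)
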