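"""Whole-cell model: flux formulas, conservation, reproducibility."""

import numpy as np
import pytest
from scipy.optimize import brentq

from crucell import control_params, initial_state, make_pacing, run, step
from crucell.metrics import apd
from crucell.model import (SimulationError, k_currents, lcc_current,
                           lcc_single_channel_flux, ncx_current,
                           ncx_reversal_voltage, release_flux, serca_flux,
                           total_calcium)


class TestReleaseFlux:
    def test_closed_cluster_and_no_gradient(self, small_params):
        assert release_flux(1000.0, 10.0, 0, small_params) == 0.0
        assert release_flux(500.0, 500.0, 12, small_params) == 0.0

    def test_linearity_in_open_count(self, small_params):
        j1 = release_flux(1000.0, 0.0, 1, small_params)
        j7 = release_flux(1000.0, 0.0, 7, small_params)
        assert j7 == pytest.approx(7 * j1)

    def test_bounds_checked(self, small_params):
        with pytest.raises(ValueError):
            release_flux(1000.0, 0.0, 50, small_params)


class TestSercaFlux:
    def test_hill_midpoint_is_half_maximum(self, small_params):
        p = small_params
        j_mid = serca_flux(p.serca_Km, p)
        j_max = p.serca_vp * p.Ap_serca
        assert j_mid == pytest.approx(0.5 * j_max)

    def test_halving_pump_concentration_halves_flux(self, small_params):
        p = small_params
        p_half = p.replace(Ap_serca=75.0)
        for ca in (0.05, 0.2, 1.0, 10.0):
            assert serca_flux(ca, p_half) == pytest.approx(
                0.5 * serca_flux(ca, p), rel=1e-12)

    def test_monotone_in_calcium(self, small_params):
        js = [serca_flux(c, small_params) for c in np.linspace(0, 5, 100)]
        assert all(b >= a for a, b in zip(js, js[1:]))


class TestNCX:
    def test_zero_at_reversal(self, small_params):
        v_rev = ncx_reversal_voltage(0.2, small_params)
        assert ncx_current(v_rev, 0.2, small_params) == pytest.approx(0.0,
                                                                      abs=1e-9)

    def test_doubling_conductance_doubles_current(self, small_params):
        p2 = small_params.replace(G_NCX=2000.0)
        for v, ca in ((-80.0, 0.1), (0.0, 1.0), (40.0, 0.5)):
            assert ncx_current(v, ca, p2) == pytest.approx(
                2.0 * ncx_current(v, ca, small_params), rel=1e-12)

    def test_forward_mode_at_rest_extrudes(self, small_params):
        # inward (negative) current at resting potential = Ca2+ extrusion
        assert ncx_current(-80.0, 0.1, small_params) < 0.0


class TestKCurrents:
    def test_all_zero_at_reversal(self, small_params):
        e_k = small_params.E_K
        currents = k_currents(e_k, (0.5, 0.5, 0.5, 0.5), small_params)
        assert np.allclose(currents, 0.0, atol=1e-12)

    def test_ito_scales_with_conductance(self, small_params):
        p_red = small_params.replace(G_to=small_params.G_to * 0.33)
        gates = (0.8, 0.9, 0.3, 0.2)
        i_full = k_currents(20.0, gates, small_params)[1]
        i_red = k_currents(20.0, gates, p_red)[1]
        assert i_red == pytest.approx(0.33 * i_full, rel=1e-12)

    def test_inward_rectifier_bound(self, small_params):
        """IK1 at E_K + 60 mV is smaller than the ohmic value G*60."""
        v = small_params.E_K + 60.0
        i_k1 = k_currents(v, (0, 0, 0, 0), small_params)[0]
        assert 0 < i_k1 < small_params.G_K1 * 60.0

    def test_gate_range_validated(self, small_params):
        with pytest.raises(ValueError):
            k_currents(0.0, (1.5, 0.5, 0.5, 0.5), small_params)


class TestLCCCurrent:
    def test_zero_when_closed(self, small_params):
        i, _ = lcc_current(0.0, 1.0, 0, small_params)
        assert i == 0.0

    def test_zero_at_ghk_reversal(self, small_params):
        f = lambda v: lcc_single_channel_flux(v, 10.0, small_params)
        v_rev = brentq(f, 0.0, 120.0)
        i, _ = lcc_current(v_rev, 10.0, 1000, small_params)
        assert i == pytest.approx(0.0, abs=1e-9)

    def test_whole_cell_peak_iv_is_bell_shaped(self, small_params):
        """Peak I_CaL over the voltage-clamp step family has an interior
        maximum in magnitude, small at both ends of the sweep."""
        from crucell import make_vclamp, run_vclamp_series
        prot = make_vclamp(conditioning_beats=2)
        traces = run_vclamp_series(prot, small_params, seed=6)
        vs = sorted(traces)
        peaks = []
        for v in vs:
            tr = traces[v]
            t0, t1 = tr.meta["step_window"]
            sel = (tr.t >= t0) & (tr.t <= t1)
            peaks.append(-tr["I_CaL"][sel].min())
        i_max = int(np.argmax(peaks))
        assert 0 < i_max < len(vs) - 1
        assert peaks[0] < 0.6 * peaks[i_max]
        assert peaks[-1] < 0.8 * peaks[i_max]


class TestStepAndRun:
    def test_null_dynamics_leaves_state_unchanged(self, small_params):
        """With every conductance and flux off, only time advances."""
        import dataclasses
        p = small_params.replace(
            G_K1=0.0, G_to=0.0, G_Kr=0.0, G_Ks=0.0, G_NCX=0.0, G_Na=0.0,
            G_bCa=0.0, G_NaK=0.0, G_bNa=0.0, v_leak=0.0, v_ryr=0.0,
            serca_vp=0.0,
            ryr=dataclasses.replace(small_params.ryr, base_rate=0.0,
                                    k_close=0.0, k_inact=0.0, k_recover=0.0),
            lcc=dataclasses.replace(small_params.lcc, alpha0=0.0, beta0=0.0,
                                    gamma0=0.0, omega=0.0, g_single=0.0))
        s0 = initial_state(p, seed=1)
        s1 = step(s0, p, dt=0.025, mode="current_clamp", drive=0.0)
        assert s1.time == pytest.approx(0.025)
        assert s1.v == pytest.approx(s0.v)
        assert s1.ca_myo == pytest.approx(s0.ca_myo)
        assert np.array_equal(s1.ryr, s0.ryr)

    def test_closed_membrane_calcium_conserved(self, small_params):
        """With sarcolemmal Ca2+ fluxes disabled, total cell Ca2+ drifts by
        less than 0.1% over 1 s."""
        prot = make_pacing([(1.0, 1.0, 0.0, 1.0)])   # zero-amplitude stimulus
        s0 = initial_state(small_params, seed=2)
        before = total_calcium(s0, small_params)
        tr = run(prot, small_params, seed=2, init=s0, sl_enabled=False)
        after = total_calcium(tr.meta["final_state"], small_params)
        assert abs(after - before) / before < 1e-3

    def test_channel_counts_conserved_in_full_run(self, short_control_trace,
                                                  small_params):
        state = short_control_trace.meta["final_state"]
        assert np.all(state.ryr.sum(axis=1) == small_params.n_ryr_per_cru)
        assert np.all(state.lcc.sum(axis=1) == small_params.n_lcc_per_cru)
        assert (state.ryr >= 0).all() and (state.lcc >= 0).all()

    def test_concentrations_stay_nonnegative(self, short_control_trace):
        for field in ("ca_myo", "ca_nsr", "ca_jsr"):
            assert (short_control_trace[field] >= 0).all()

    def test_same_seed_bitwise_identical(self, small_params):
        prot = make_pacing([(1.0, 1.0)])
        tr1 = run(prot, small_params, seed=42)
        tr2 = run(prot, small_params, seed=42)
        for k in tr1.data:
            assert np.array_equal(tr1[k], tr2[k])

    def test_different_seeds_differ(self, small_params):
        prot = make_pacing([(1.0, 1.0)])
        tr1 = run(prot, small_params, seed=1)
        tr2 = run(prot, small_params, seed=2)
        assert not np.array_equal(tr1["po_ryr"], tr2["po_ryr"])

    def test_quiescent_cell_stays_at_rest(self, small_params):
        prot = make_pacing([(2.0, 0.5, 0.0, 1.0)])  # zero-amplitude stimulus
        tr = run(prot, small_params, seed=3)
        v = tr["v"]
        assert np.abs(v - v[0]).max() < 2.0

    def test_step_halving_converges_in_mean_field(self, small_params):
        """Halving dt changes deterministic fields by < 1% at t = 100 ms
        (expected-occupancy gating isolates integrator error)."""
        prot = make_pacing([(0.1, 10.0)])
        tr_a = run(prot, small_params, seed=5, dt=0.05, stochastic=False)
        tr_b = run(prot, small_params, seed=5, dt=0.025, stochastic=False)
        for field, scale in (("v", 130.0), ("ca_myo", 1.0), ("ca_nsr", 900.0)):
            a, b = tr_a[field][-1], tr_b[field][-1]
            assert abs(a - b) / scale < 0.01

    def test_paced_run_produces_expected_ap_count(self, small_params):
        tr = run(make_pacing([(3.0, 1.0)]), small_params, seed=4)
        n_aps = 0
        for t_on in tr.stim_times:
            sel = (tr.t >= t_on) & (tr.t < t_on + 990.0)
            if apd(tr.t[sel], tr["v"][sel]) is not None:
                n_aps += 1
        assert n_aps == 3

    def test_window_slicing(self, short_control_trace):
        w = short_control_trace.window(500.0, 1500.0)
        assert w.t[0] >= 500.0 and w.t[-1] < 1500.0
        assert len(w.stim_times) == 1


def test_control_reaches_periodic_steady_state():
    """Beat-to-beat peak Ca2+ varies by < 5% (relative SD) late in a 1 Hz
    train, sampling noise aside."""
    from crucell import beat_metrics
    p = control_params(n_cru=512)
    tr = run(make_pacing([(7.0, 1.0)]), p, seed=1)
    tail = beat_metrics(tr).peak_ca_myo.iloc[-4:]
    assert tail.std() / tail.mean() < 0.05
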