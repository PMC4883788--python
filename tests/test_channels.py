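"""Membrane voltage, gating kinetics, currents, and stimulus waveforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinecam.channels import (ChannelParams, MembraneState, StimulusCommand,
                               bap_waveform, calibrate_bap_gain,
                               channel_currents, current_to_flux,
                               glutamate_pulse, mg_unblock, receptor_gating,
                               simulate_voltage_only, sk_steady_state,
                               sk_update, update_voltage, vgcc_gates)

P = ChannelParams()


class TestStimuli:
    def test_glutamate_step_pulse(self):
        assert glutamate_pulse(5.5, onset=5.0) == 1.0
        assert glutamate_pulse(6.5, onset=5.0) == 0.0
        assert glutamate_pulse(4.9, onset=5.0) == 0.0

    def test_bap_instantaneous_rise_and_decay(self):
        p = ChannelParams(bap_gain=1.0)
        assert bap_waveform(2.0, onset=2.0, params=p) == pytest.approx(67.0)
        assert bap_waveform(1.99, onset=2.0, params=p) == 0.0
        assert bap_waveform(200.0, onset=2.0, params=p) == pytest.approx(
            0.0, abs=1e-6)

    def test_bad_decay_constants(self):
        with pytest.raises(ValueError):
            bap_waveform(0.0, 0.0, ChannelParams(bap_tau1=-1.0))


class TestReceptorGating:
    def test_zero_glutamate_fixed_point(self):
        assert receptor_gating(0.0, 0.0, P.alpha_A, P.beta_A, 1.0) == 0.0

    def test_steady_state(self):
        glu, a, b = 1.0, 1.1, 0.19
        r = 0.0
        for _ in range(5000):
            r = receptor_gating(r, glu, a, b, 0.1)
        assert r == pytest.approx(a * glu / (a * glu + b), rel=1e-6)

    def test_matches_closed_form_relaxation(self):
        glu, a, b, dt = 1.0, 1.1, 0.19, 0.013
        r_num, t = 0.2, 0.0
        for _ in range(200):
            r_num = receptor_gating(r_num, glu, a, b, dt)
            t += dt
        k = a * glu + b
        r_exact = a * glu / k + (0.2 - a * glu / k) * np.exp(-k * t)
        assert r_num == pytest.approx(r_exact, abs=1e-6)


class TestMgUnblock:
    def test_asymptotic_unblock(self):
        assert mg_unblock(100.0) > 0.95

    def test_no_mg_no_block(self):
        assert mg_unblock(-70.0, Mg=0.0) == 1.0

    def test_jahr_stevens_value_at_zero(self):
        assert mg_unblock(0.0, Mg=1.0) == pytest.approx(1 / (1 + 1 / 3.57),
                                                        rel=1e-9)

    @given(st.floats(-100, 60), st.floats(-100, 60))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_voltage(self, v1, v2):
        lo, hi = sorted([v1, v2])
        assert mg_unblock(lo) <= mg_unblock(hi) + 1e-12


class TestVgccGates:
    def test_boltzmann_midpoint(self):
        m, _, _ = vgcc_gates(P.vh_mT, 0.5, 0.5, 0.5, P, dt=1e6)
        assert m == pytest.approx(0.5, abs=1e-6)

    def test_lva_vs_hva_separation_at_epsp_voltage(self):
        v = P.V_rest + 25.0
        m_T, _, m_L = vgcc_gates(v, 0.0, 1.0, 0.0, P, dt=1e6)
        assert m_T > 5 * m_L  # T-type activates at EPSP level, L barely

    def test_activation_monotone(self):
        ms = [vgcc_gates(v, 0.0, 1.0, 0.0, P, dt=1e6)[0]
              for v in np.linspace(-90, 30, 25)]
        assert np.all(np.diff(ms) > 0)


class TestSK:
    def test_half_activation_exact(self):
        assert sk_steady_state(P.K_s, P) == pytest.approx(0.5, rel=1e-12)

    def test_decay_to_zero_without_calcium(self):
        s = 0.8
        for _ in range(10000):
            s = sk_update(s, 0.0, P, 0.01)
        assert s < 1e-6

    def test_hill_value_at_twice_ks(self):
        assert sk_steady_state(2 * P.K_s, P) == pytest.approx(16 / 17,
                                                              rel=1e-12)

    def test_step_response_time_constant_fit(self):
        """Step to 2*K_s: single-exponential rise with tau = 6 ms +- 2 %."""
        dt, n = 0.01, 3000
        t = np.arange(1, n + 1) * dt
        s = np.empty(n)
        cur = 0.0
        for k in range(n):
            cur = sk_update(cur, 2 * P.K_s, P, dt)
            s[k] = cur
        s_inf = 16 / 17
        y = np.log(s_inf - s[: int(12 / dt)])
        A = np.vstack([t[: len(y)], np.ones(len(y))]).T
        slope, _ = np.linalg.lstsq(A, y, rcond=None)[0]
        tau = -1.0 / slope
        assert tau == pytest.approx(6.0, rel=0.02)
        # single exponential: R^2 of the log-linear fit
        resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        r2 = 1 - resid.var() / y.var()
        assert r2 > 0.999

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            sk_update(0.1, -1.0, P, 0.01)


class TestCurrents:
    def test_all_gates_zero_all_currents_zero(self):
        state = MembraneState(V=P.V_rest, r_A=0, r_N=0, m_T=0, h_T=0,
                              m_L=0, s=0)
        cur = channel_currents(state, P)
        for k, v in cur.items():
            assert v == pytest.approx(0.0, abs=1e-12), k

    def test_sk_blockade_contract(self):
        state = MembraneState(V=0.0, s=0.9)
        assert channel_currents(state, P, sk_blocked=True)["I_SK"] == 0.0
        assert channel_currents(state, P, sk_blocked=False)["I_SK"] > 0.0

    @pytest.mark.parametrize("driving", ["ohmic", "ghk"])
    def test_calcium_currents_inward_at_rest(self, driving):
        p = ChannelParams(ca_driving=driving)
        state = MembraneState(V=p.V_rest, r_A=0.5, r_N=0.5, m_T=0.5, h_T=0.5,
                              m_L=0.5, s=0.0)
        cur = channel_currents(state, p)
        assert cur["I_N_Ca"] < 0 and cur["I_CaT"] < 0 and cur["I_CaL"] < 0

    def test_current_to_flux(self):
        assert current_to_flux(0.0, 1.0) == 0.0
        # 1 pA over area A: total molar rate = 1e-12/(2 F) mol/s
        area = 7.85e-5
        total = current_to_flux(-1.0, area) * area      # µM·µm³/ms
        mol_per_s = total * 1e-21 * 1e3
        assert mol_per_s == pytest.approx(1e-12 / (2 * 96485.33212), rel=1e-6)
        # halving the area doubles the density, total conserved
        assert current_to_flux(-1.0, area / 2) == pytest.approx(
            2 * current_to_flux(-1.0, area))
        with pytest.raises(ValueError):
            current_to_flux(1.0, 0.0)


class TestVoltage:
    def test_relaxes_to_rest(self):
        state = MembraneState(V=-30.0)
        stim = StimulusCommand()
        for _ in range(5000):
            state = update_voltage(state, P, stim, 0.01)
        # small offset from the T-type window current is expected
        assert state.V == pytest.approx(P.V_rest, abs=0.05)

    def test_epsp_peak_near_25mv(self):
        t, V = simulate_voltage_only(P, [("EPSP", 1.0)], 20.0)
        assert V.max() - P.V_rest == pytest.approx(25.0, rel=0.2)

    def test_calibrated_bap_peak_67mv(self):
        p = calibrate_bap_gain(ChannelParams(bap_gain=1.0))
        t, V = simulate_voltage_only(p, [("bAP", 1.0)], 10.0)
        assert V.max() - p.V_rest == pytest.approx(67.0, abs=0.1)

    def test_voltage_step_halving_convergence(self):
        peaks = {}
        for dt in (0.01, 0.005):
            _, V = simulate_voltage_only(P, [("EPSP", 1.0), ("bAP", 11.0)],
                                         20.0, dt=dt)
            peaks[dt] = V.max()
        assert abs(peaks[0.01] - peaks[0.005]) < 0.1

    @given(st.lists(st.tuples(st.floats(0, 2), st.floats(-10, 80)),
                    min_size=1, max_size=30))
    @settings(max_examples=20, deadline=None)
    def test_gates_stay_in_unit_interval(self, stim_seq):
        """No clipping: the exponential updates keep every gate in [0,1]
        for arbitrary bounded stimuli."""
        state = MembraneState.resting(P)
        for glu, bap in stim_seq:
            stim = StimulusCommand(glutamate=glu, bap_command=bap)
            state = update_voltage(state, P, stim, 0.05)
            for g in state.gates():
                assert -1e-12 <= g <= 1 + 1e-12
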