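"""Unit tests for the reduced relay-cell model."""

import math

import numpy as np
import pytest

import thalatrack.model as tc


def hand_currents(v, h, w, p):
    """Independent scalar re-evaluation of the four current products."""
    m_inf = 1.0 / (1.0 + math.exp(-(v + 37.0) / 7.0))
    p_inf = 1.0 / (1.0 + math.exp(-(v + 60.0) / 6.2))
    i_l = p.g_l * (v - p.e_l)
    i_na = p.g_na * m_inf**3 * h * (v - p.e_na)
    i_k = p.g_k * (0.75 * (1.0 - h))**4 * (v - p.e_k)
    i_t = p.g_t * p_inf**2 * w * (v - p.e_t)
    return i_l, i_na, i_k, i_t


class TestIonicCurrents:
    def test_zero_at_leak_reversal_with_channels_off(self, params):
        import dataclasses

        p = dataclasses.replace(params, g_na=0.0, g_k=0.0, g_t=0.0)
        out = tc.ionic_currents(tc.NeuronState(v=p.e_l, h=0.3, w=0.3), p)
        assert all(abs(i) < 1e-12 for i in out)

    def test_potassium_vanishes_when_h_is_one(self, params):
        _, _, i_k, _ = tc.ionic_currents(tc.NeuronState(v=-30.0, h=1.0, w=0.1), params)
        assert i_k == 0.0

    def test_matches_independent_hand_computation(self, params):
        v = -65.0
        g = params.gating
        h, w = float(g.h_inf(v)), float(g.w_inf(v))
        got = tc.ionic_currents(tc.NeuronState(v=v, h=h, w=w), params)
        expected = hand_currents(v, h, w, params)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_state_raises(self, params):
        with pytest.raises(tc.DivergenceError):
            tc.ionic_currents(tc.NeuronState(v=float("nan"), h=0.5, w=0.5), params)


class TestDerivatives:
    def test_gate_equilibria_are_stationary(self, params):
        v = -55.0
        g = params.gating
        h_eq = float(g.a_h(v) / (g.a_h(v) + g.b_h(v)))
        st = tc.NeuronState(v=v, h=h_eq, w=float(g.w_inf(v)))
        _, dh, dw = tc.derivatives(st, 0.0, 0.0, params)
        assert dh == pytest.approx(0.0, abs=1e-14)
        assert dw == pytest.approx(0.0, abs=1e-14)

    def test_matches_closed_form_at_fixed_state(self, params):
        v, h, w = -58.0, 0.7, 0.12
        g = params.gating
        dv, dh, dw = tc.derivatives(tc.NeuronState(v=v, h=h, w=w), 0.0, 0.0, params)
        i_l, i_na, i_k, i_t = hand_currents(v, h, w, params)
        assert dv == pytest.approx((-i_l - i_na - i_k - i_t) / params.c_m, rel=1e-12)
        a = 0.128 * math.exp(-(v + 46.0) / 18.0)
        b = 4.0 / (1.0 + math.exp(-(v + 23.0) / 5.0))
        assert dh == pytest.approx(a * (1 - h) - b * h, rel=1e-12)
        w_inf = 1.0 / (1.0 + math.exp((v + 84.0) / 4.0))
        tau = 28.0 + math.exp(-(v + 25.0) / 10.5)
        assert dw == pytest.approx((w_inf - w) / tau, rel=1e-12)


class TestEulerStep:
    def test_definition(self, params):
        st = tc.NeuronState(v=-60.0, h=0.6, w=0.2)
        d = tc.derivatives(st, 0.5, 1.0, params)
        new = tc.euler_step(st, 0.5, 1.0, 0.01, params)
        assert new.v == pytest.approx(st.v + 0.01 * d[0])
        assert new.h == pytest.approx(st.h + 0.01 * d[1])
        assert new.w == pytest.approx(st.w + 0.01 * d[2])

    def test_rest_state_is_fixed_point(self, params, rest):
        new = tc.euler_step(rest, 0.0, 0.0, 0.01, params)
        assert new.v == pytest.approx(rest.v, abs=1e-6)

    def test_two_half_steps_match_reference_loop(self, params):
        st = tc.NeuronState(v=-70.0, h=0.9, w=0.05)
        a = tc.euler_step(tc.euler_step(st, 0.0, 2.0, 0.01, params), 0.0, 2.0, 0.01, params)
        ref = st
        for _ in range(2):
            d = tc.derivatives(ref, 0.0, 2.0, params)
            ref = tc.NeuronState(v=ref.v + 0.01 * d[0],
                                 h=min(1.0, max(0.0, ref.h + 0.01 * d[1])),
                                 w=min(1.0, max(0.0, ref.w + 0.01 * d[2])))
        assert a.v == pytest.approx(ref.v, rel=1e-12)

    def test_rejects_nonpositive_dt(self, params, rest):
        with pytest.raises(ValueError):
            tc.euler_step(rest, 0.0, 0.0, 0.0, params)


class TestStimuli:
    def test_square_wave_duty_cycle(self):
        spec = tc.StimulusSpec(kind="square_wave", rho_sm=25.0, delta_sm=5.0, i_sm=5.0)
        assert tc.sm_square_wave(2.0, spec) == 5.0
        assert tc.sm_square_wave(10.0, spec) == 0.0
        assert tc.sm_square_wave(27.0, spec) == 5.0

    def test_square_wave_validation(self):
        with pytest.raises(ValueError):
            tc.StimulusSpec(kind="square_wave", rho_sm=5.0, delta_sm=5.0)

    def test_gamma_train_interval_statistics(self):
        spec = tc.StimulusSpec(kind="gamma_pulse_train", rate=30.0, cv=0.2,
                               i_sm=5.0, delta_sm=5.0, seed=42)
        series = tc.sm_gamma_pulse_train(spec, duration=100_000.0, dt=0.1)
        onsets = 0.1 * np.flatnonzero((series[1:] > 0) & (series[:-1] == 0))
        iv = np.diff(onsets)
        assert np.mean(iv) == pytest.approx(1000.0 / 30.0, rel=0.05)
        assert np.std(iv) / np.mean(iv) == pytest.approx(0.2, rel=0.15)

    def test_gamma_train_determinism_and_zero_amplitude(self):
        spec = tc.StimulusSpec(kind="gamma_pulse_train", seed=7)
        a = tc.sm_gamma_pulse_train(spec, 1000.0, 0.1)
        b = tc.sm_gamma_pulse_train(spec, 1000.0, 0.1)
        np.testing.assert_array_equal(a, b)
        zero = tc.StimulusSpec(kind="gamma_pulse_train", i_sm=0.0, seed=7)
        assert not np.any(tc.sm_gamma_pulse_train(zero, 1000.0, 0.1))

    def test_parkinsonian_gpi_is_hyperpolarizing(self):
        t = np.arange(0.0, 100.0, 0.1)
        normal = tc.gpi_series(tc.GpiInputSpec(mode="normal"), t)
        pd = tc.gpi_series(tc.GpiInputSpec(mode="parkinsonian"), t)
        assert np.mean(pd) < np.mean(normal)


class TestSimulation:
    def test_rest_is_quiescent(self, params, rest):
        traj = tc.simulate(params, tc.GpiInputSpec(), tc.StimulusSpec(kind="none"),
                           1000.0, initial=rest)
        assert len(tc.detect_spikes(traj)) == 0
        assert abs(traj.v[-1] - rest.v) < 0.5

    def test_rest_state_derivatives_vanish(self, params, rest):
        d = tc.derivatives(rest, 0.0, 0.0, params)
        assert np.linalg.norm(d) < 1e-6

    def test_depolarizing_steps_spike_with_decreasing_latency(self, params, rest):
        latencies = []
        for amp in (1.0, 2.0, 5.0):
            traj = tc.simulate(params, tc.GpiInputSpec(),
                               tc.StimulusSpec(kind="constant", level=amp),
                               300.0, initial=rest)
            spikes = tc.detect_spikes(traj)
            assert len(spikes) >= 3, f"no tonic spiking at {amp}"
            latencies.append(spikes[0])
        assert latencies[0] > latencies[1] > latencies[2]

    def test_rebound_burst_after_hyperpolarizing_release(self, params, rest):
        hold = tc.simulate(params, tc.GpiInputSpec(),
                           tc.StimulusSpec(kind="constant", level=-0.6),
                           150.0, initial=rest)
        release_state = hold.state_at(len(hold) - 1)
        assert release_state.w > 2.0 * rest.w  # T-current de-inactivated
        post = tc.simulate(params, tc.GpiInputSpec(), tc.StimulusSpec(kind="none"),
                           120.0, initial=release_state)
        spikes = tc.detect_spikes(post)
        assert np.sum(spikes < 50.0) >= 2

    def test_gates_stay_bounded(self, params, rest):
        for level in (-2.0, 0.0, 8.0):
            traj = tc.simulate(params, tc.GpiInputSpec(mode="parkinsonian"),
                               tc.StimulusSpec(kind="constant", level=level),
                               300.0, initial=rest)
            assert np.all((traj.h >= 0) & (traj.h <= 1))
            assert np.all((traj.w >= 0) & (traj.w <= 1))

    def test_forward_euler_first_order_convergence(self, params, rest):
        sims = {dt: tc.simulate(params, tc.GpiInputSpec(),
                                tc.StimulusSpec(kind="constant", level=0.3),
                                50.0, dt=dt, initial=rest)
                for dt in (0.02, 0.01, 0.005)}
        d1 = np.max(np.abs(sims[0.02].v - sims[0.01].v[::2]))
        d2 = np.max(np.abs(sims[0.01].v - sims[0.005].v[::2]))
        assert 1.4 < d1 / d2 < 2.8  # halving dt roughly halves the error

    def test_normal_relays_parkinsonian_bursts(self, params, normal_trajectory):
        spikes = tc.detect_spikes(normal_trajectory)
        per_pulse = [np.sum((spikes >= 25 * k) & (spikes < 25 * (k + 1)))
                     for k in range(40)]
        assert np.mean([c == 1 for c in per_pulse]) >= 0.9
        pd = tc.simulate(params, tc.GpiInputSpec(mode="parkinsonian"),
                         tc.StimulusSpec(kind="square_wave"), 1000.0)
        sp = tc.detect_spikes(pd)
        sp = sp[sp > 200.0]
        bursts = 0
        i = 0
        while i < len(sp):
            j = i
            while j + 1 < len(sp) and sp[j + 1] - sp[i] <= 25.0:
                j += 1
            bursts += j > i
            i = j + 1
        assert bursts >= 5

    def test_trajectory_shape_and_decimation(self, normal_trajectory):
        traj = normal_trajectory
        assert len(traj.times) == len(traj.v) == len(traj.w) == 100_001
        steps = np.diff(traj.times)
        assert np.allclose(steps, steps[0])
        dec = traj.decimate(5)
        assert dec.dt == pytest.approx(0.05)
        np.testing.assert_array_equal(dec.v, traj.v[::5])


class TestSteadyStateCurrents:
    def test_matches_scalar_loop(self, params):
        grid = np.linspace(-100.0, 0.0, 101)
        table = tc.steady_state_currents(grid, params)
        g = params.gating
        for name, idx in (("I_L", 0), ("I_Na", 1), ("I_K", 2), ("I_T", 3)):
            loop = np.array([
                tc.ionic_currents(tc.NeuronState(v=v, h=float(g.h_inf(v)),
                                                 w=float(g.w_inf(v))), params)[idx]
                for v in grid])
            np.testing.assert_allclose(table[name], loop, rtol=1e-12)

    def test_potassium_negligible_where_h_saturates(self, params):
        table = tc.steady_state_currents([-100.0], params)
        assert abs(table["I_K"][0]) < 1e-4


class TestSpikeDetection:
    def test_flat_and_single_pulse(self):
        dt = 0.1
        flat = np.full(1000, -65.0)
        assert len(tc.detect_spikes(flat, dt=dt)) == 0
        tri = np.concatenate([np.linspace(-65, 0, 50), np.linspace(0, -65, 50)])
        assert len(tc.detect_spikes(tri, dt=dt)) == 1

    def test_three_programmed_crossings(self):
        dt = 1.0
        v = np.full(300, -65.0)
        for t0 in (50, 150, 250):
            v[t0:t0 + 5] = 10.0
        assert len(tc.detect_spikes(v, dt=dt)) == 3

    def test_merge_window_collapses_chatter(self):
        dt = 0.1
        v = np.full(100, -65.0)
        v[10] = 0.0
        v[12] = 0.0  # re-crossing 0.2 ms later merges into one spike
        assert len(tc.detect_spikes(v, dt=dt, merge_window=2.0)) == 1


def test_steady_state_maps_are_monotone_sigmoids(params):
    """Activation curves rise with voltage, inactivation curves fall."""
    g = params.gating
    v = np.linspace(-120.0, 20.0, 500)
    assert np.all(np.diff(g.m_inf(v)) > 0)
    assert np.all(np.diff(g.p_inf(v)) > 0)
    assert np.all(np.diff(g.h_inf(v)) < 0)
    assert np.all(np.diff(g.w_inf(v)) < 0)
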