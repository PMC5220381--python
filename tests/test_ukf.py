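"""Unit tests for the 2N-sigma-point unscented Kalman filter."""

import numpy as np
import pytest

import thalatrack.model as tc
from thalatrack import ukf
from thalatrack.experiments import filter_parameters


def random_spd(rng, n=4, scale=1.0):
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T) + 0.1 * np.eye(n)


class TestCholesky:
    def test_identity(self):
        np.testing.assert_array_equal(ukf.cholesky_factor(np.eye(3)), np.eye(3))

    def test_small_example(self):
        ell = ukf.cholesky_factor(np.array([[4.0, 2.0], [2.0, 5.0]]))
        np.testing.assert_allclose(ell, [[2.0, 0.0], [1.0, 2.0]])

    def test_random_spd_reconstruction(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = random_spd(rng)
            ell = ukf.cholesky_factor(p)
            assert np.max(np.abs(ell @ ell.T - p)) < 1e-10

    def test_jitter_rescues_semidefinite(self):
        p = np.diag([1.0, 0.0, 2.0, 3.0])  # rank deficient
        ell = ukf.cholesky_factor(p)
        assert np.max(np.abs(ell @ ell.T - p)) < 1e-3

    def test_indefinite_matrix_raises(self):
        with pytest.raises(ukf.FilterDivergenceError):
            ukf.cholesky_factor(np.diag([1.0, -1.0, 1.0, 1.0]))


class TestSigmaPoints:
    def test_scalar_case_plus_minus_one(self):
        s = ukf.generate_sigma_points(np.array([0.0]), np.array([[1.0]]))
        assert sorted(s.points[:, 0]) == [-1.0, 1.0]
        np.testing.assert_allclose(s.weights, [0.5, 0.5])

    def test_eight_points_equal_weights_for_augmented_state(self):
        rng = np.random.default_rng(1)
        s = ukf.generate_sigma_points(rng.standard_normal(4), random_spd(rng))
        assert s.points.shape == (8, 4)
        np.testing.assert_allclose(s.weights, np.full(8, 0.125))

    def test_moment_reconstruction_is_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            mean = rng.standard_normal(4)
            cov = random_spd(rng)
            s = ukf.generate_sigma_points(mean, cov)
            assert np.max(np.abs(s.mean() - mean)) < 1e-10
            assert np.max(np.abs(s.scatter() - cov)) < 1e-8

    def test_diagonal_covariance_gives_axis_offsets(self):
        d = np.array([1.0, 4.0, 9.0, 16.0])
        s = ukf.generate_sigma_points(np.zeros(4), np.diag(d))
        offsets = s.points[:4]  # the "+" half
        np.testing.assert_allclose(offsets, np.diag(np.sqrt(4.0 * d)), atol=1e-12)


class TestPropagate:
    def test_zero_dt_is_identity(self, params):
        f = ukf.neuron_transition(params, dt=0.0)
        rng = np.random.default_rng(3)
        s = ukf.generate_sigma_points(np.array([0.0, -65.0, 0.8, 0.1]),
                                      0.01 * np.eye(4))
        out, y = ukf.propagate(s, f)
        np.testing.assert_allclose(out.points, s.points)
        np.testing.assert_allclose(y, s.points[:, 1])

    def test_rest_point_is_fixed(self, params, rest):
        f = ukf.neuron_transition(params, dt=0.01)
        x = np.array([[0.0, rest.v, rest.h, rest.w]])
        out = f(x, 0)
        assert out[0, 1] == pytest.approx(rest.v, abs=1e-6)

    def test_each_point_matches_euler_step(self, params):
        f = ukf.neuron_transition(params, dt=0.05)
        rng = np.random.default_rng(4)
        s = ukf.generate_sigma_points(np.array([1.0, -60.0, 0.7, 0.2]),
                                      0.05 * np.eye(4))
        out, _ = ukf.propagate(s, f)
        for point, new in zip(s.points, out.points):
            st = tc.euler_step(tc.NeuronState(v=point[1], h=point[2], w=point[3]),
                               point[0], 0.0, 0.05, params)
            assert new[0] == point[0]
            assert new[1] == pytest.approx(st.v, rel=1e-12)
            # euler_step clamps gates; the filter transition leaves them free,
            # so compare only when the point stayed inside [0, 1]
            if 0.0 <= new[2] <= 1.0 and 0.0 <= new[3] <= 1.0:
                assert new[2] == pytest.approx(st.h, rel=1e-12)
                assert new[3] == pytest.approx(st.w, rel=1e-12)

    def test_known_control_input_adds_current(self, params):
        x = np.array([[0.0, -65.0, 0.9, 0.05]])
        blind = ukf.neuron_transition(params, dt=0.01)(x, 0)
        driven = ukf.neuron_transition(params, dt=0.01,
                                       control=np.array([5.0]))(x, 0)
        assert driven[0, 1] == pytest.approx(blind[0, 1] + 0.01 * 5.0)


class TestPredictUpdate:
    def test_identical_points_zero_scatter_plus_q(self):
        pts = np.tile(np.array([1.0, -60.0, 0.5, 0.1]), (8, 1))
        s = ukf.SigmaPointSet(points=pts, weights=np.full(8, 0.125))
        _, cov0, _ = ukf.predict(s, 0.0)
        np.testing.assert_allclose(cov0, np.zeros((4, 4)), atol=1e-30)
        _, covq, _ = ukf.predict(s, 0.3)
        np.testing.assert_allclose(covq, 0.3 * np.eye(4), atol=1e-30)

    def test_moments_match_loop_oracle(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((8, 4))
        s = ukf.SigmaPointSet(points=pts, weights=np.full(8, 0.125))
        mean, cov, yhat = ukf.predict(s, 0.0)
        m = sum(p for p in pts) / 8
        c = sum(np.outer(p - m, p - m) for p in pts) / 8
        np.testing.assert_allclose(mean, m)
        np.testing.assert_allclose(cov, c, atol=1e-12)
        assert yhat == pytest.approx(m[1])

    def test_zero_innovation_keeps_prior(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((8, 4))
        s = ukf.SigmaPointSet(points=pts, weights=np.full(8, 0.125))
        mean, cov, yhat = ukf.predict(s, 1e-6)
        post, _, _, innov = ukf.update(mean, cov, yhat, 1.0)
        assert innov == pytest.approx(0.0)
        np.testing.assert_allclose(post, mean)

    def test_infinite_noise_ignores_measurement(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((8, 4))
        s = ukf.SigmaPointSet(points=pts, weights=np.full(8, 0.125))
        mean, cov, _ = ukf.predict(s, 0.0)
        post, pcov, gain, _ = ukf.update(mean, cov, 100.0, 1e12)
        assert np.max(np.abs(gain)) < 1e-9
        np.testing.assert_allclose(post, mean, atol=1e-8)
        np.testing.assert_allclose(pcov, cov, atol=1e-8)

    def test_observed_component_gain_matches_scalar_closed_form(self):
        # points spread only along V: gain on V must equal p/(p+R)
        pts = np.zeros((8, 4))
        pts[:, 1] = [2.0, 0, 0, 0, -2.0, 0, 0, 0]
        s = ukf.SigmaPointSet(points=pts, weights=np.full(8, 0.125))
        mean, cov, _ = ukf.predict(s, 0.0)
        p = cov[1, 1]
        r = 3.0
        _, _, gain, _ = ukf.update(mean, cov, 1.0, r)
        assert gain[1] == pytest.approx(p / (p + r))


class TestExpandQ:
    def test_scalar_diag_full_and_batch(self):
        np.testing.assert_allclose(ukf.expand_q(0.5), 0.5 * np.eye(4))
        np.testing.assert_allclose(ukf.expand_q([1.0, 2.0, 3.0, 4.0]),
                                   np.diag([1.0, 2.0, 3.0, 4.0]))
        full = np.arange(16.0).reshape(4, 4)
        np.testing.assert_allclose(ukf.expand_q(full), full)
        per_filter = ukf.expand_q(np.array([0.1, 0.2]), batch=2)
        assert per_filter.shape == (2, 4, 4)
        np.testing.assert_allclose(per_filter[1], 0.2 * np.eye(4))


class TestEstimate:
    def test_self_consistency_with_matched_plant(self, params, rest):
        # plant integrated at the filter step, zero noise, truth initialization
        dt = 0.05
        traj = tc.simulate(params, tc.GpiInputSpec(),
                           tc.StimulusSpec(kind="constant", level=1.5),
                           200.0, dt=dt, initial=rest)
        truth = np.stack([np.full(len(traj), 1.5), traj.v, traj.h, traj.w], axis=-1)
        config = ukf.UKFConfig(q=0.0, r=1e-6, dt=dt, burn_in_ms=10.0,
                               x0=truth[0], p0=1e-12 * np.eye(4),
                               transition=ukf.neuron_transition(params, dt))
        trace = ukf.estimate(traj.v, config, truth=truth)
        for name in ("v", "h", "w"):
            assert trace.cf_rmse[name] < 1e-3
        # posterior covariances stay symmetric PSD along the whole trace
        sym_gap = np.abs(trace.covariances
                         - np.swapaxes(trace.covariances, -1, -2)).max()
        assert sym_gap == 0.0
        assert np.linalg.eigvalsh(trace.covariances).min() >= -1e-8

    def test_piecewise_constant_current_plateau_recovery(self, params, rest):
        # the estimated parameter should settle on each plateau of a stepped
        # input current, blind
        segments = [(0.0, 400.0), (1.5, 400.0), (3.0, 400.0)]
        parts, state = [], rest
        for level, dur in segments:
            t = tc.simulate(params, tc.GpiInputSpec(mode="custom", level=level),
                            tc.StimulusSpec(kind="none"), dur, initial=state)
            parts.append(t)
            state = t.state_at(len(t) - 1)
        step = 5
        v = np.concatenate([t.v[:-1] for t in parts])[::step]
        obs = v + np.random.default_rng(3).standard_normal(len(v))
        config = ukf.UKFConfig(q=np.array([0.005, 5e-5, 1e-8, 1e-8]), r=5.0,
                               dt=0.05,
                               transition=ukf.neuron_transition(
                                   filter_parameters("cetc"), 0.05))
        trace = ukf.estimate(obs, config)
        for i, (level, _) in enumerate(segments):
            lo = int((i * 400.0 + 200.0) / 0.05)
            hi = int((i + 1) * 400.0 / 0.05)
            assert np.mean(trace.means[lo:hi, 0]) == pytest.approx(level, abs=0.3)

    def test_batch_matches_single_run(self, params, rest):
        dt = 0.05
        traj = tc.simulate(params, tc.GpiInputSpec(),
                           tc.StimulusSpec(kind="constant", level=1.0),
                           100.0, dt=dt, initial=rest)
        rng = np.random.default_rng(12)
        obs = traj.v + rng.standard_normal((3, len(traj)))
        config = ukf.UKFConfig(q=5e-5, r=5.0, dt=dt,
                               transition=ukf.neuron_transition(params, dt))
        batch = ukf.estimate(obs, config)
        solo = ukf.estimate(obs[1], config)
        np.testing.assert_allclose(batch.means[1], solo.means, rtol=1e-10)

    def test_missing_transition_raises(self):
        with pytest.raises(ValueError, match="transition"):
            ukf.estimate(np.zeros(10), ukf.UKFConfig())


class TestCfRmse:
    def test_identical_and_offset(self):
        a = np.linspace(0, 1, 50)
        assert ukf.cf_rmse(a, a) == 0.0
        assert ukf.cf_rmse(a + 0.3, a) == pytest.approx(0.3)

    def test_matches_loop_oracle_with_burn_in(self):
        rng = np.random.default_rng(13)
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        expected = np.sqrt(sum((x - y)**2 for x, y in zip(a[20:], b[20:])) / 80)
        assert ukf.cf_rmse(a, b, burn_in=20) == pytest.approx(expected)

    def test_empty_after_burn_in_raises(self):
        with pytest.raises(ValueError):
            ukf.cf_rmse(np.zeros(5), np.zeros(5), burn_in=5)
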