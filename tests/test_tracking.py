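"""Boundary measurement, velocity by cross-correlation, Kalman fusion,
proportional control."""

import numpy as np
import pytest

from octrack import (
    AScan,
    ControlLaw,
    KalmanModel,
    KalmanState,
    LabelMask,
    control_step,
    kalman_predict_correct,
    kalman_step,
    measure_boundary,
    measure_velocity,
    xcorr_shift,
)


def _mask(labels):
    return LabelMask(np.asarray(labels, dtype=int))


class TestMeasureBoundary:
    def test_contiguous_layers(self):
        m = _mask([0] * 10 + [1] * 10)
        assert measure_boundary(m, 0, 1) == pytest.approx(9.5)

    def test_absent_class_invalid_not_exception(self):
        m = _mask([0] * 20)
        assert np.isnan(measure_boundary(m, 0, 1))

    def test_noisy_overlap_rule_applied_literally(self):
        # upper's bottommost at 14, lower's topmost at 11 -> (14+11)/2
        labels = np.zeros(20, dtype=int)
        labels[10:15] = 0
        labels[11] = 1
        labels[15:] = 1
        m = _mask(labels)
        assert measure_boundary(m, 0, 1) == pytest.approx(12.5)

    def test_non_adjacent_pair_rejected(self):
        m = _mask([0] * 5 + [2] * 5)
        with pytest.raises(ValueError, match="adjacent"):
            measure_boundary(m, 0, 2)


class TestMeasureVelocity:
    def test_identical_scans_zero(self, rng):
        v = rng.random(320)
        vel, ok = measure_velocity(AScan(v), AScan(v), 0.0, 0.002)
        assert ok and vel == 0.0

    def test_rolled_scan_brute_force_lag(self, rng):
        v = rng.random(320)
        rolled = np.roll(v, 4)
        # brute-force circular correlation over all lags agrees
        lags = [(np.roll(v, s) * rolled).sum() for s in range(320)]
        assert int(np.argmax(lags)) == 4
        vel, ok = measure_velocity(AScan(rolled), AScan(v), 0.0, 0.002)
        assert ok and vel == pytest.approx(4 / 0.002)

    def test_motor_motion_cancels(self, rng):
        v = rng.random(320)
        vel, ok = measure_velocity(AScan(np.roll(v, 4)), AScan(v), 4.0, 0.002)
        assert ok and vel == pytest.approx(0.0)

    def test_zero_energy_flagged(self):
        vel, ok = measure_velocity(AScan(np.zeros(64)), AScan(np.zeros(64)), 0.0, 0.01)
        assert vel == 0.0 and not ok

    def test_negative_shift_signed(self, rng):
        v = rng.random(320)
        vel, _ = measure_velocity(AScan(np.roll(v, -6)), AScan(v), 0.0, 0.003)
        assert vel == pytest.approx(-6 / 0.003)

    def test_bad_inputs_rejected(self, rng):
        a = AScan(rng.random(320))
        with pytest.raises(ValueError):
            measure_velocity(a, AScan(rng.random(100)), 0.0, 0.01)
        with pytest.raises(ValueError):
            measure_velocity(a, a, 0.0, 0.0)


class TestXcorrShift:
    def test_tie_breaks_toward_smallest_displacement(self):
        # a two-spike signal where lags 0 and 8 correlate equally
        v = np.zeros(16)
        v[[0, 8]] = 1.0
        assert xcorr_shift(v, v) == 0


class TestKalmanStep:
    def _model(self, **kw):
        return KalmanModel(dt=0.01, sigma_a=50.0, **kw)

    def test_near_zero_r_posterior_equals_measurement(self):
        m = KalmanModel(dt=0.01, sigma_a=50.0, r_pos=1e-12, r_vel=1e-12)
        st = KalmanState(0.0, 0.0, np.eye(2))
        out = kalman_step(st, m, (7.3, -2.0), 0.0)
        assert out.x == pytest.approx(7.3, abs=1e-6)
        assert out.v == pytest.approx(-2.0, abs=1e-6)

    def test_constant_velocity_track_converges(self):
        m = self._model(r_pos=1e-6, r_vel=1e-6)
        st = KalmanState(0.0, 0.0, np.eye(2) * 10)
        for k in range(100):
            truth = 2.0 * (k + 1) * m.dt
            st = kalman_step(st, m, (truth, 2.0), 0.0)
        assert abs(st.x - truth) < 0.1

    def test_scalar_riccati_steady_state_gain(self):
        """Position-only scalar filter matches the closed-form algebraic
        Riccati solution: P = (-Q + sqrt(Q^2 + 4 Q R)) / 2, K = M/(M+R)."""
        Q, R = 0.3, 2.0
        F = H = np.eye(1)
        mean, P = np.zeros(1), np.eye(1) * 50.0
        K_last = None
        for _ in range(1000):
            M = P[0, 0] + Q
            K_last = M / (M + R)
            mean, P = kalman_predict_correct(
                mean, P, F, np.eye(1) * Q, H, np.eye(1) * R, np.zeros(1)
            )
        P_inf = (-Q + np.sqrt(Q**2 + 4 * Q * R)) / 2.0
        K_inf = (P_inf + Q) / (P_inf + Q + R)
        assert P[0, 0] == pytest.approx(P_inf, abs=1e-6)
        assert K_last == pytest.approx(K_inf, abs=1e-6)

    def test_control_input_enters_prediction(self):
        m = self._model()
        st = KalmanState(10.0, 0.0, np.eye(2) * 1e-9)
        # perfect prior, no-information measurement -> estimate follows B*u
        big_r = KalmanModel(dt=m.dt, sigma_a=m.sigma_a, r_pos=1e9, r_vel=1e9)
        out = kalman_step(st, big_r, (0.0, 0.0), u_prev=3.0)
        assert out.x == pytest.approx(13.0, abs=1e-3)

    def test_missing_position_coasts_on_velocity_row(self):
        m = self._model(r_pos=0.5, r_vel=0.1)
        st = KalmanState(5.0, 1.0, np.eye(2))
        out = kalman_step(st, m, (float("nan"), 1.0), 0.0)
        assert np.isfinite(out.x)
        assert out.v == pytest.approx(1.0, abs=0.2)

    def test_posterior_covariance_never_exceeds_prior(self, rng):
        m = self._model()
        st = KalmanState(0.0, 0.0, np.eye(2) * 10)
        for _ in range(50):
            prior_P = m.F @ st.P @ m.F.T + m.Q
            st = kalman_step(st, m, tuple(rng.normal(size=2)), 0.0)
            assert np.trace(st.P) <= np.trace(prior_P) + 1e-9

    def test_shift_equivariance(self, rng):
        """Adding a constant to all position measurements adds the same
        constant to all position estimates."""
        m = self._model()
        z = rng.normal(size=(50, 2))
        c = 123.0
        a = KalmanState(0.0, 0.0, np.eye(2) * 10)
        b = KalmanState(c, 0.0, np.eye(2) * 10)
        for k in range(50):
            a = kalman_step(a, m, (z[k, 0], z[k, 1]), 0.0)
            b = kalman_step(b, m, (z[k, 0] + c, z[k, 1]), 0.0)
        assert b.x - a.x == pytest.approx(c, abs=1e-9)
        assert b.v == pytest.approx(a.v, abs=1e-9)

    def test_filter_reduces_mue_on_noisy_track(self, rng):
        """With 1 px measurement noise over a 1000-step smooth track, the
        filtered position MUE beats the raw measurement MUE."""
        dt = 0.003
        m = KalmanModel(dt=dt, sigma_a=4000.0, r_pos=1.0, r_vel=40000.0)
        t = np.arange(1000) * dt
        truth = 30.0 * np.sin(2 * np.pi * 1.5 * t)
        truth_v = np.gradient(truth, dt)
        z_pos = truth + rng.normal(0, 1.0, size=t.size)
        z_vel = truth_v + rng.normal(0, 200.0, size=t.size)
        st = KalmanState(z_pos[0], 0.0, np.diag([1.0, 1e4]))
        est = [st.x]
        for k in range(1, t.size):
            st = kalman_step(st, m, (z_pos[k], z_vel[k]), 0.0)
            est.append(st.x)
        est = np.array(est)
        mue_raw = np.abs(z_pos - truth).mean()
        mue_kf = np.abs(est - truth).mean()
        assert mue_kf < mue_raw

    def test_invalid_covariances_rejected(self):
        with pytest.raises(ValueError):
            KalmanModel(dt=0.01, r_pos=0.0)
        with pytest.raises(ValueError):
            KalmanState(0.0, 0.0, np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestControlStep:
    def test_at_target_zero(self):
        law = ControlLaw(gain=0.5, x_target=100.0, u_max=10.0)
        assert control_step(law, 100.0) == 0.0

    def test_proportional_arithmetic(self):
        law = ControlLaw(gain=0.5, x_target=110.0, u_max=50.0)
        assert control_step(law, 100.0) == pytest.approx(5.0)

    def test_saturation(self):
        law = ControlLaw(gain=1.0, x_target=100.0, u_max=6.0)
        assert control_step(law, 0.0) == pytest.approx(6.0)
        assert control_step(law, 200.0) == pytest.approx(-6.0)

    def test_nonfinite_estimate_rejected(self):
        law = ControlLaw()
        with pytest.raises(ValueError):
            control_step(law, float("nan"))
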