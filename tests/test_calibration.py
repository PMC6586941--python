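"""Simulated neural user, velocity-KF calibration, recalibration drift."""

import numpy as np
import pytest

from plmsim.calibration import (CalibratedDecoder, SimulatedNeuralUser,
                                calibrate_velocity_kf, generate_features,
                                recalibration_loop, refit_intention)
from plmsim.task import CenterOutLayout, TaskSpec


@pytest.fixture(scope="module")
def neural_user():
    return SimulatedNeuralUser.create(n_features=50, noise_sd=3.0)


def _task(radius=0.08):
    return TaskSpec(target_generator=CenterOutLayout(distance=1.0,
                                                     target_radius=radius),
                    dwell_s=0.5, max_trial_s=10.0)


class TestFeatures:
    def test_zero_noise_on_target_gives_zero(self):
        u = SimulatedNeuralUser.create(noise_sd=0.0)
        rng = np.random.default_rng(0)
        f = generate_features(u, np.array([0.3, 0.3]), np.array([0.3, 0.3]), rng)
        assert np.allclose(f, 0.0)

    def test_regression_recovers_tuning(self, neural_user):
        rng = np.random.default_rng(1)
        err = rng.normal(size=(10_000, 2))
        F = generate_features(neural_user, err, np.zeros((10_000, 2)), rng)
        E_hat = np.linalg.lstsq(err, F, rcond=None)[0].T
        scale = np.abs(neural_user.tuning).max()
        assert np.max(np.abs(E_hat - neural_user.tuning)) < 0.1 * scale

    def test_seeded_draws_identical(self, neural_user):
        g, p = np.array([1.0, 0.0]), np.zeros(2)
        a = generate_features(neural_user, g, p, np.random.default_rng(3))
        b = generate_features(neural_user, g, p, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_preferred_directions_uniform(self, neural_user):
        angles = np.arctan2(neural_user.tuning[:, 1], neural_user.tuning[:, 0])
        spacing = np.diff(np.sort(angles))
        assert np.allclose(spacing, spacing[0], atol=1e-9)


class TestKalmanCalibration:
    def _calib_data(self, user, noise_sd=None, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n, 2))
        # smooth the intended velocities a little so the prior fit is sane
        for t in range(1, n):
            v[t] = 0.8 * v[t - 1] + 0.2 * v[t]
        F = v @ user.tuning.T
        sd = user.noise_sd if noise_sd is None else noise_sd
        F = F + sd * rng.standard_normal(F.shape)
        return F, v

    def test_noiseless_decodes_intended_direction(self):
        user = SimulatedNeuralUser.create(noise_sd=0.0)
        F, v = self._calib_data(user, noise_sd=1e-9)
        dec = calibrate_velocity_kf(F, v, user.tuning)
        # held-out samples decode to the intended direction (< 1 degree)
        rng = np.random.default_rng(9)
        v_new = rng.normal(size=(200, 2))
        y = (v_new @ user.tuning.T) @ dec.D.T
        cos = np.sum(y * v_new, axis=1) / (
            np.linalg.norm(y, axis=1) * np.linalg.norm(v_new, axis=1))
        assert np.all(cos > np.cos(np.radians(1.0)))

    def test_more_noise_means_smaller_kalman_gain(self):
        user = SimulatedNeuralUser.create(noise_sd=1.0)
        ks = []
        for sd in (0.5, 1.5, 4.0, 8.0):
            F, v = self._calib_data(user, noise_sd=sd, seed=1)
            ks.append(calibrate_velocity_kf(F, v, user.tuning).kalman_k)
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_reparameterization_equivalence(self, neural_user):
        # the (D, alpha, beta) form reproduces the steady-state filter
        F, v = self._calib_data(neural_user, seed=2)
        dec = calibrate_velocity_kf(F, v, neural_user.tuning)
        rng = np.random.default_rng(4)
        feats = rng.normal(size=(300, neural_user.n_features))
        a, k = dec.prior_a, dec.kalman_k
        D0_scaled = (1 - dec.alpha_eff) * dec.beta_eff * dec.D  # = k * D0
        v1 = np.zeros(2)
        v2 = np.zeros(2)
        for t in range(300):
            y = (D0_scaled / k) @ feats[t]
            v1 = a * (1 - k) * v1 + k * y                      # raw SSKF
            v2 = dec.alpha_eff * v2 + (1 - dec.alpha_eff) * dec.beta_eff * (dec.D @ feats[t])
            assert np.allclose(v1, v2, atol=1e-8)

    def test_terminal_speed_is_beta_eff(self, neural_user):
        F, v = self._calib_data(neural_user, seed=3)
        dec = calibrate_velocity_kf(F, v, neural_user.tuning)
        # sustained unit command: asymptotic speed ~ beta_eff (+-1%, averaged
        # over directions by construction; check the mean over 8 directions)
        speeds = []
        for th in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            s = np.array([np.cos(th), np.sin(th)])
            f = neural_user.tuning @ s  # noiseless sustained features
            vv = np.zeros(2)
            for _ in range(2000):
                vv = dec.alpha_eff * vv + (1 - dec.alpha_eff) * dec.beta_eff * (dec.D @ f)
            speeds.append(np.linalg.norm(vv))
        assert abs(np.mean(speeds) - dec.beta_eff) < 0.01 * dec.beta_eff


class TestRefitIntention:
    def test_zeroed_on_target(self):
        v = np.array([[1.0, 1.0]])
        out = refit_intention(v, np.array([[0.0, 0.0]]), np.array([[0.05, 0.0]]),
                              np.array([0.1]))
        assert np.allclose(out, 0.0)

    def test_magnitude_preserved_off_target(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(100, 2))
        p = rng.normal(size=(100, 2))
        g = p + rng.normal(size=(100, 2)) * 5 + 10  # far from targets
        out = refit_intention(v, p, g, np.full(100, 0.1))
        assert np.allclose(np.linalg.norm(out, axis=1),
                           np.linalg.norm(v, axis=1))

    def test_already_aligned_vectors_unchanged(self):
        p = np.zeros((1, 2))
        g = np.array([[3.0, 4.0]])
        v = np.array([[0.6, 0.8]])  # pointing at the target
        out = refit_intention(v, p, g, np.array([0.1]))
        assert np.allclose(out, v)

    def test_position_error_mode(self):
        p = np.array([[1.0, 0.0]])
        g = np.array([[3.0, 1.0]])
        out = refit_intention(np.ones((1, 2)), p, g, np.array([0.1]),
                              mode="position_error")
        assert np.allclose(out, [[2.0, 1.0]])


class TestRecalibrationDrift:
    def test_gain_down_smoothing_up(self, neural_user):
        df = recalibration_loop(neural_user, _task(), n_rounds=5, seed=2)
        beta = df["beta_eff"].to_numpy()
        alpha = df["alpha_eff"].to_numpy()
        assert np.all(np.diff(beta) < 0)            # rounds 0..5 strictly down
        assert np.all(np.diff(alpha[1:]) > 0)       # rounds 1..5 strictly up

    def test_position_error_mode_is_stable(self, neural_user):
        # with intention = the encoded position error, the calibration
        # regression is well-specified for this simulated user, so repeated
        # recalibration stays bounded instead of drifting without bound
        df = recalibration_loop(neural_user, _task(), n_rounds=3, seed=2,
                                mode="position_error")
        assert np.isfinite(df[["alpha_eff", "beta_eff"]].to_numpy()).all()
        assert df["beta_eff"].iloc[-1] > 0.5 * df["beta_eff"].iloc[0]
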