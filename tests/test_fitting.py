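"""Model fitting: policy regression, noise fitting, delay recovery."""

import numpy as np
import pytest

from plmsim import presets
from plmsim.decoder import build_state_space
from plmsim.engine import simulate_session_chain
from plmsim.io import make_synthetic_session
from plmsim.model import (FitConfig, PiecewiseLinearControlModel,
                          fit_control_policy, fit_noise_model, fit_user_model)
from plmsim.piecewise import PiecewiseLinearFn


class TestPolicyFit:
    def test_noiseless_tau_zero_exact_recovery(self):
        # zero noise + no delay: plain linear regression is exact
        user = presets.default_user(innovation_sd=0.0, ar_coeff=0.0,
                                    f_vel_slope=-0.8, delay_tau=0)
        dec = presets.default_decoder()
        task = presets.default_task()
        out, _ = simulate_session_chain(user, dec, task, 120.0, seed=3)
        cfg = FitConfig(f_targ_knots=tuple(user.policy.f_targ.knots),
                        f_vel_knots=(0.0, 3.0))
        policy, _, diag = fit_control_policy(out["position"], out["velocity"],
                                             out["u"], out["target"], 0,
                                             build_state_space(dec), cfg)
        # knots with support recover the true ordinates near-exactly
        xs = np.array([0.12, 0.3, 0.5, 0.9])
        assert np.allclose(policy.f_targ(xs), user.policy.f_targ(xs), atol=1e-6)
        assert np.isclose(policy.f_vel.slope_through_origin(), -0.8, atol=1e-6)
        assert diag["r2"][-1] > 1 - 1e-10

    def test_noisy_recovery_within_tolerance(self, fitted_results):
        res = fitted_results  # canonical noisy session, fit at true tau
        user = presets.default_user()
        # f_vel slope within +/- 0.2 of truth (-1.0)
        assert abs(res.f_vel_slope - (-1.0)) < 0.2
        # f_targ RMSE < 10% of max over the observed range
        xs = np.linspace(0.05, 1.0, 30)
        rmse = np.sqrt(np.mean((res.user.policy.f_targ(xs)
                                - user.policy.f_targ(xs)) ** 2))
        assert rmse < 0.1 * user.policy.f_targ.values.max()

    def test_training_objective_non_increasing(self, fitted_results):
        sse = fitted_results.report.policy_sse
        assert all(b <= a + 1e-6 * abs(a) for a, b in zip(sse, sse[1:]))


class TestNoiseFit:
    def test_white_noise_selects_order_zero(self):
        rng = np.random.default_rng(0)
        e = rng.multivariate_normal([0, 0], 0.04 * np.eye(2), size=10_000)
        noise, diag = fit_noise_model(e, None, FitConfig())
        assert diag["n_lags"] == 0
        assert np.all(np.abs(np.diag(noise.innovation_cov) - 0.04) < 0.004)

    def test_ar2_order_and_prediction_power(self):
        # stationary AR(2): e_t = 0.5 e_{t-1} + 0.2 e_{t-2} + eps
        rng = np.random.default_rng(1)
        n, s = 10_000, 0.2
        e = np.zeros((n, 2))
        for t in range(2, n):
            e[t] = 0.5 * e[t - 1] + 0.2 * e[t - 2] + s * rng.standard_normal(2)
        noise, diag = fit_noise_model(e, None, FitConfig())
        assert diag["n_lags"] in (1, 2, 3)
        # theoretical one-step R^2 = 1 - sigma^2/Var(e)
        theo = 1 - s**2 / np.var(e)
        assert abs(max(diag["cv_curve"]) - theo) < 0.05

    def test_constant_scale_recovered_when_signal_independent(self):
        rng = np.random.default_rng(2)
        e = rng.normal(scale=0.2, size=(10_000, 2))
        c_norms = rng.uniform(0, 1.4, size=10_000)
        noise, diag = fit_noise_model(e, c_norms,
                                      FitConfig(fit_sdn=True))
        pop = diag["sdn_scales"][np.isfinite(diag["sdn_scales"])]
        assert np.all((pop > 0.8) & (pop < 1.2))

    def test_order_never_exceeds_max_and_curve_reproducible(self):
        rng = np.random.default_rng(3)
        e = rng.normal(size=(3000, 2))
        cfg = FitConfig(max_lags=4)
        _, d1 = fit_noise_model(e, None, cfg)
        _, d2 = fit_noise_model(e, None, cfg)
        assert d1["n_lags"] <= 4
        assert d1["cv_curve"] == d2["cv_curve"]


class TestFullPipeline:
    def test_delay_and_variance_recovery(self, synthetic_session):
        model = PiecewiseLinearControlModel.from_session(synthetic_session)
        res = model.fit(delay_tau="grid")
        assert abs(res.delay_tau - 10) <= 3
        true_var = 0.25**2
        est_var = float(np.mean(np.diag(res.report.innovation_cov)))
        assert abs(est_var - true_var) / true_var < 0.15
        assert res.report.n_lags in (1, 2)

    def test_noiseless_session_zero_innovation(self):
        user = presets.default_user(innovation_sd=0.0, ar_coeff=0.0,
                                    f_vel_slope=-0.5)
        dec = presets.default_decoder()
        sess = make_synthetic_session(user, dec, presets.default_task(),
                                      120.0, seed=5)
        # knots nesting the true weightings so the policy is representable;
        # extra iterations let the estimate/policy fixed point converge to
        # machine precision
        cfg = FitConfig(f_targ_knots=tuple(user.policy.f_targ.knots),
                        f_vel_knots=(0.0, 3.0), delay_tau=10,
                        n_policy_iterations=14)
        model = PiecewiseLinearControlModel.from_session(sess, config=cfg)
        res = model.fit()
        assert np.all(np.abs(res.report.innovation_cov) < 1e-10)

    def test_self_consistency_refit(self, fitted_results):
        # simulate from the fitted model, refit, recover the same parameters
        fitted = fitted_results.user
        dec = presets.default_decoder()
        sess2 = make_synthetic_session(fitted, dec, presets.default_task(),
                                       300.0, seed=23)
        res2 = PiecewiseLinearControlModel.from_session(sess2).fit(delay_tau=10)
        assert abs(res2.f_vel_slope - fitted_results.f_vel_slope) < 0.2
        v1 = np.mean(np.diag(fitted_results.report.innovation_cov))
        v2 = np.mean(np.diag(res2.report.innovation_cov))
        assert abs(v2 - v1) / v1 < 0.15

    def test_summary_renders(self, fitted_results):
        text = fitted_results.summary()
        assert "feedback delay" in text and "f_vel slope" in text

    def test_policy_plot_smoke(self, fitted_results):
        import matplotlib
        matplotlib.use("Agg")
        axes = fitted_results.plot_policy()
        assert len(axes) == 2


class TestPrediction:
    def test_in_sample_prediction_matches_training(self, synthetic_session,
                                                   fitted_results):
        # simulate the training condition from the fit: means should agree
        # with the training session's observed means within 2 bootstrap CIs
        from plmsim.cli import _per_trial_metrics
        from plmsim.metrics import summarize_frame

        task = presets.default_task()
        preds = fitted_results.predict_conditions(
            [(presets.default_decoder(), task)], n_sims=400, seed=3,
            adapt=False)
        obs_frame = _per_trial_metrics(
            synthetic_session.block_frame("b0"), synthetic_session, task)
        obs = summarize_frame(obs_frame, seed=0)
        pred = preds[0]["summary"]
        for m in ("movement_time", "translation_time"):
            lo, hi = obs.ci(m)
            half = (hi - lo) / 2
            assert abs(pred.mean(m) - obs.mean(m)) < 2 * max(half, 0.05)

    def test_monte_carlo_stability(self, fitted_results):
        task = presets.default_task()
        cond = [(presets.default_decoder(gain_beta=2.0), task)]
        a = fitted_results.predict_conditions(cond, n_sims=400, seed=5, adapt=False)
        b = fitted_results.predict_conditions(cond, n_sims=800, seed=6, adapt=False)
        se = a[0]["summary"].se("movement_time")
        assert abs(a[0]["summary"].mean("movement_time")
                   - b[0]["summary"].mean("movement_time")) < 3 * se


class TestBootstrap:
    def test_zero_noise_training_gives_degenerate_ci(self):
        user = presets.default_user(innovation_sd=0.0, ar_coeff=0.0,
                                    f_vel_slope=-0.5)
        dec = presets.default_decoder()
        sess = make_synthetic_session(user, dec, presets.default_task(),
                                      90.0, seed=8)
        model = PiecewiseLinearControlModel.from_session(
            sess, config=FitConfig(delay_tau=10))
        res = model.fit()
        cis = res.bootstrap_prediction_ci(
            [(dec, presets.default_task())], n_boot=5, n_sims=50, seed=1,
            adapt=False)
        width = cis[0].loc["movement_time", "ci_hi"] - cis[0].loc["movement_time", "ci_lo"]
        assert width < 0.15

    def test_ci_contains_point_prediction(self, synthetic_session, fitted_results):
        dec = presets.default_decoder()
        task = presets.default_task()
        cis = fitted_results.bootstrap_prediction_ci([(dec, task)], n_boot=8,
                                                     n_sims=120, seed=2,
                                                     adapt=False)
        point = fitted_results.predict_conditions([(dec, task)], n_sims=400,
                                                  seed=9, adapt=False)
        m = point[0]["summary"].mean("movement_time")
        lo = cis[0].loc["movement_time", "ci_lo"]
        hi = cis[0].loc["movement_time", "ci_hi"]
        pad = 0.2 * (hi - lo) + 0.05
        assert lo - pad <= m <= hi + pad
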