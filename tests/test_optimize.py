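"""Parameter sweeps, keyboard optimization, speed-transform search."""

import numpy as np
import pandas as pd
import pytest

from plmsim import presets
from plmsim.adaptation import AdaptationConfig
from plmsim.decoder import DecoderParams
from plmsim.optimize import (KeyboardSpec, SweepSpec, TransformSearchSpec,
                             optimize_speed_transform, select_params,
                             simulate_keyboard, sweep_surface)


@pytest.fixture(scope="module")
def small_sweep():
    spec = SweepSpec(gain_grid=(0.6, 1.2, 2.4), smoothing_grid=(0.85, 0.93),
                     n_trials_per_cell=60, seed=2,
                     adapt_cfg=AdaptationConfig(n_sims_per_slope=20))
    return sweep_surface(presets.default_user(), presets.default_task(), spec,
                         base_decoder=presets.default_decoder())


class TestSweep:
    def test_complete_surface(self, small_sweep):
        t = small_sweep.table
        assert len(t) == 6
        assert t["movement_time"].notna().all()
        assert small_sweep.surface("movement_time").shape == (3, 2)

    def test_reproducible(self):
        spec = SweepSpec(gain_grid=(1.2,), smoothing_grid=(0.9,),
                         n_trials_per_cell=40, seed=7,
                         adapt_cfg=AdaptationConfig(n_sims_per_slope=15))
        a = sweep_surface(presets.default_user(), presets.default_task(), spec)
        b = sweep_surface(presets.default_user(), presets.default_task(), spec)
        assert a.table.equals(b.table)

    def test_select_matches_brute_force(self, small_sweep):
        beta, alpha = select_params(small_sweep, "movement_time")
        t = small_sweep.table
        assert t.loc[(t.gain_beta == beta) & (t.smoothing_alpha == alpha),
                     "movement_time"].iloc[0] == t["movement_time"].min()

    def test_tie_break_toward_low_gain_high_smoothing(self):
        t = pd.DataFrame({
            "gain_beta": [1.0, 1.0, 2.0, 2.0],
            "smoothing_alpha": [0.8, 0.9, 0.8, 0.9],
            "movement_time": [1.0, 1.0, 1.0, 1.0],
        })
        assert select_params(t, "movement_time") == (1.0, 0.9)

    def test_maximized_metrics(self):
        t = pd.DataFrame({
            "gain_beta": [1.0, 2.0], "smoothing_alpha": [0.9, 0.9],
            "path_efficiency": [0.7, 0.9],
        })
        assert select_params(t, "path_efficiency") == (2.0, 0.9)


class TestKeyboard:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            KeyboardSpec(n_keys=35)

    def test_key_geometry_round_trip(self):
        kb = KeyboardSpec()
        idx = np.arange(kb.n_keys)
        centers = kb.key_center(idx)
        assert np.array_equal(kb.key_at(centers), idx)
        # keys tile the workspace: centers span it without overlap
        assert np.isclose(centers.min(), -kb.halfwidth + 0.5 * kb.key_size)
        assert np.isclose(centers.max(), kb.halfwidth - 0.5 * kb.key_size)

    def test_noiseless_user_always_correct(self):
        user = presets.default_user(innovation_sd=0.0, ar_coeff=0.0,
                                    f_vel_slope=-0.3)
        kb = KeyboardSpec()
        # quick acceleration so pass-through keys are crossed well within
        # the shortest dwell tested
        dec = DecoderParams(gain_beta=2.0, smoothing_alpha=0.85)
        frames = {d: simulate_keyboard(user, dec, kb, d, 60, seed=1)
                  for d in (0.5, 1.0, 1.5)}
        for f in frames.values():
            assert f["correct"].all()
        # with no errors the mean selection time grows with dwell, so the
        # achieved bit rate strictly decreases in dwell
        from plmsim.optimize import _keyboard_eval
        rates = [_keyboard_eval(frames[d], kb.n_keys)[0] for d in (0.5, 1.0, 1.5)]
        assert rates[0] > rates[1] > rates[2]

    def test_noisy_user_dwell_tradeoff(self):
        # short dwell -> fast but error-prone; long dwell -> slow but safe
        user = presets.default_user()
        kb = KeyboardSpec(max_select_s=8.0)
        dec = DecoderParams(gain_beta=2.4, smoothing_alpha=0.92)
        short = simulate_keyboard(user, dec, kb, 0.3, 200, seed=2)
        long = simulate_keyboard(user, dec, kb, 1.5, 200, seed=2)
        assert short["correct"].mean() < long["correct"].mean()
        assert short["time_s"].mean() < long["time_s"].mean()

    def test_deterministic(self):
        user = presets.default_user()
        kb = KeyboardSpec()
        dec = DecoderParams(gain_beta=2.0, smoothing_alpha=0.9)
        a = simulate_keyboard(user, dec, kb, 0.8, 50, seed=5)
        b = simulate_keyboard(user, dec, kb, 0.8, 50, seed=5)
        assert a.equals(b)


class TestTransformSearch:
    def test_exponent_search_prefers_p1_without_noise_floor(self):
        # purely signal-dependent noise: no benefit from a nonlinearity
        from plmsim.piecewise import PiecewiseLinearFn
        user = presets.default_user(
            sdn_fn=PiecewiseLinearFn([0.0, 1.5], [0.0, 1.5]))
        spec = TransformSearchSpec(
            variant="exponent", exponent_grid=(1.0, 1.5, 2.0, 3.0),
            gain_grid=(0.9, 1.35), smoothing_grid=(0.9,), sims_per_eval=60,
            adapt_cfg=AdaptationConfig(n_sims_per_slope=15))
        dec, info = optimize_speed_transform(user, presets.default_decoder(),
                                             presets.precision_task(), spec,
                                             seed=4)
        assert info["exponent_p"] <= 1.5

    def test_piecewise_search_shape_properties(self):
        user = presets.default_user()
        spec = TransformSearchSpec(
            variant="piecewise", n_breakpoints=6, n_restarts=3,
            sims_per_eval=30, max_pattern_iters=4, init_step=0.3,
            min_step=0.1, adapt=False)
        dec, info = optimize_speed_transform(
            user, presets.default_decoder(gain_beta=1.6, smoothing_alpha=0.9),
            presets.precision_task(), spec, seed=6)
        ord = info["ordinates"]
        assert len(ord) == 6
        assert np.all(np.diff(ord) >= -1e-12)      # isotonic projection
        assert ord[0] < 0.15                       # maps ~0 to ~0
        assert dec.speed_transform.variant == "piecewise"

    def test_pattern_search_descends_on_quadratic(self):
        from plmsim.optimize import _pattern_search
        calls = []

        def f(x):
            calls.append(1)
            return float(np.sum((x - np.array([0.3, 0.7])) ** 2))

        x, fx = _pattern_search(f, np.zeros(2), 0.4, 0.01, 50)
        assert fx < 1e-2
        assert np.allclose(x, [0.3, 0.7], atol=0.05)
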