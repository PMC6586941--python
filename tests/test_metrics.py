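"""Performance metrics and model-evaluation statistics."""

import numpy as np
import pandas as pd
import pytest

from plmsim.engine import TrialRecord
from plmsim.metrics import (achieved_bit_rate, evaluate_predictions,
                            frame_from_summary, index_of_difficulty,
                            summarize_frame, trial_metrics)
from plmsim.task import TaskSpec, CenterOutLayout


def _record_from_path(positions, dt, target, radius, dwell_s, outcome,
                      t_first, t_acq):
    T = len(positions)
    d = positions.shape[1]
    return TrialRecord(
        time=dt * np.arange(1, T + 1),
        position=positions, velocity=np.zeros((T, d)), u=np.zeros((T, d)),
        c=np.zeros((T, d)), e=np.zeros((T, d)),
        target=np.repeat(target[None, :], T, axis=0),
        target_radius=np.full(T, radius),
        contact=np.zeros(T, bool), outcome=outcome,
        t_first_contact=t_first, t_acquire=t_acq,
        start=positions[0] * 0.0 + positions[0], dwell_s=dwell_s)


def _task(dwell=1.0):
    return TaskSpec(target_generator=CenterOutLayout(), dwell_s=dwell,
                    max_trial_s=10.0)


class TestTrialMetrics:
    def test_definition_arithmetic(self):
        # contact at 1.0 s, acquired at 3.5 s, dwell 1.0 s
        path = np.linspace([0, 0], [1, 0], 50)
        rec = _record_from_path(path, 0.07, np.array([1.0, 0.0]), 0.1, 1.0,
                                "success", 1.0, 3.5)
        rec.start = np.zeros(2)
        m = trial_metrics(rec, _task(dwell=1.0))
        assert np.isclose(m.movement_time, 3.5)
        assert np.isclose(m.translation_time, 1.0)
        assert np.isclose(m.dial_in_time, 1.5)

    def test_semicircle_path_efficiency(self):
        # semicircular arc from (0,0) to (1,0): PE = diameter/arc = 2/pi
        theta = np.linspace(np.pi, 0, 2001)
        path = np.stack([0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta)], axis=1)
        rec = _record_from_path(path, 0.01, np.array([1.0, 0.0]), 0.05, 1.0,
                                "success", 10.0, 12.0)
        rec.start = np.zeros(2)
        m = trial_metrics(rec, _task())
        assert np.isclose(m.path_efficiency, 2 / np.pi, atol=1e-5)

    def test_failed_trial_has_no_times(self):
        path = np.linspace([0, 0], [0.5, 0], 10)
        rec = _record_from_path(path, 0.1, np.array([1.0, 0.0]), 0.1, 1.0,
                                "timeout", None, None)
        rec.start = np.zeros(2)
        m = trial_metrics(rec, _task())
        assert not m.success and m.movement_time is None

    def test_zero_path_warns(self):
        path = np.zeros((5, 2))
        rec = _record_from_path(path, 0.1, np.array([1.0, 0.0]), 0.1, 1.0,
                                "timeout", None, None)
        rec.start = np.zeros(2)
        with pytest.warns(UserWarning, match="zero path"):
            m = trial_metrics(rec, _task())
        assert m.path_efficiency is None


class TestIndexOfDifficulty:
    def test_values(self):
        assert np.isclose(index_of_difficulty(2.0, 1.0), 1.0)
        assert np.isclose(index_of_difficulty(14.0, 1.0), 3.0)

    def test_monotone_in_distance(self):
        ids = [index_of_difficulty(d, 0.5) for d in np.linspace(0.5, 20, 40)]
        assert np.all(np.diff(ids) > 0)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            index_of_difficulty(0.0, 1.0)


class TestBitRate:
    def test_floor_at_zero(self):
        assert achieved_bit_rate(36, 5, 5, 10.0) == 0.0

    def test_direct_formula(self):
        assert np.isclose(achieved_bit_rate(36, 10, 0, 20.0),
                          np.log2(35) * 10 / 20)

    def test_time_proportionality(self):
        assert np.isclose(achieved_bit_rate(36, 10, 2, 40.0),
                          achieved_bit_rate(36, 10, 2, 20.0) / 2)


def _frame(movement_times, successes=None):
    n = len(movement_times)
    mt = np.asarray(movement_times, float)
    return pd.DataFrame({
        "success": np.ones(n, bool) if successes is None else successes,
        "movement_time": mt, "translation_time": mt * 0.7,
        "dial_in_time": mt * 0.3 - 0.5, "path_efficiency": np.full(n, 0.9),
    })


class TestSummarize:
    def test_identical_trials_zero_width_ci(self):
        s = summarize_frame(_frame([2.0] * 30), seed=0)
        lo, hi = s.ci("movement_time")
        assert lo == hi == 2.0

    def test_ci_contains_mean_and_is_reproducible(self):
        rng = np.random.default_rng(0)
        f = _frame(rng.gamma(4, 0.5, size=100))
        a = summarize_frame(f, seed=3)
        b = summarize_frame(f, seed=3)
        assert a.table.equals(b.table)
        lo, hi = a.ci("movement_time")
        assert lo <= a.mean("movement_time") <= hi

    def test_ci_width_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(1)
        widths = []
        for n in (50, 200, 800):
            f = _frame(rng.gamma(4, 0.5, size=n))
            s = summarize_frame(f, seed=0)
            lo, hi = s.ci("movement_time")
            widths.append(hi - lo)
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.5)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.5)


class TestComparisonUtilities:
    def test_t_test_detects_shift_and_fisher_detects_rate_change(self):
        from plmsim.metrics import compare_success_rates, compare_times
        rng = np.random.default_rng(0)
        a = rng.normal(2.0, 0.3, 200)
        b = rng.normal(2.4, 0.3, 200)
        t, p = compare_times(a, b)
        assert p < 1e-6 and t < 0
        _, p_same = compare_times(a, a)
        assert p_same > 0.99
        _, p_fisher = compare_success_rates(190, 10, 150, 50)
        assert p_fisher < 1e-6


class TestEvaluatePredictions:
    def test_identity_prediction(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        fvaf, mae, slope, intercept, p = evaluate_predictions(obs, obs)
        assert fvaf == 1.0 and mae == 0.0
        assert np.isclose(slope, 1.0) and np.isclose(intercept, 0.0)

    def test_mean_prediction_gives_zero_fvaf(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.full(3, obs.mean())
        fvaf, *_ = evaluate_predictions(obs, pred)
        assert np.isclose(fvaf, 0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        obs = rng.normal(size=12)
        pred = 0.8 * obs + 0.3 + 0.1 * rng.normal(size=12)
        _, _, slope, intercept, _ = evaluate_predictions(obs, pred)
        X = np.column_stack([obs, np.ones_like(obs)])
        beta = np.linalg.solve(X.T @ X, X.T @ pred)
        assert np.isclose(slope, beta[0], atol=1e-10)
        assert np.isclose(intercept, beta[1], atol=1e-10)

    def test_adversarial_predictor_negative_fvaf(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([3.0, 1.0, -2.0])
        fvaf, *_ = evaluate_predictions(obs, pred)
        assert fvaf < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            evaluate_predictions([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
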