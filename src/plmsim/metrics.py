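"""Trial- and condition-level performance metrics and evaluation statistics.

Metric conventions (all times in seconds from target onset):

* movement time   -- onset to acquisition (includes the obligatory dwell)
* translation time -- onset to first cursor-target contact
* dial-in time    -- first contact to acquisition, minus the dwell time
* path efficiency -- straight-line distance / actual path length, in (0, 1]

Failed (timed-out) trials have no movement or dial-in time; they are
excluded from time and path means but counted in the success rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SimulatedSession, TrialRecord
from .task import TaskSpec

__all__ = [
    "TrialMetrics",
    "ConditionSummary",
    "trial_metrics",
    "index_of_difficulty",
    "achieved_bit_rate",
    "summarize_condition",
    "summarize_frame",
    "evaluate_predictions",
    "compare_times",
    "compare_success_rates",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("movement_time", "translation_time", "dial_in_time", "path_efficiency")


@dataclass(frozen=True)
class TrialMetrics:
    movement_time: float | None
    translation_time: float | None
    dial_in_time: float | None
    path_efficiency: float | None
    success: bool
    index_of_difficulty: float


def index_of_difficulty(distance: float, effective_radius: float) -> float:
    """Shannon index of difficulty, ID = log2(D / (2 r_eff) + 1) bits."""
    if not (distance > 0 and effective_radius > 0):
        raise ValueError("distance and effective_radius must be > 0")
    return math.log2(distance / (2.0 * effective_radius) + 1.0)


def achieved_bit_rate(n_targets: int, n_correct: int, n_wrong: int,
                      elapsed_s: float) -> float:
    """Conservative throughput: log2(N-1) * max(S_c - S_w, 0) / T bits/s."""
    if n_targets < 2:
        raise ValueError("n_targets must be >= 2")
    if not elapsed_s > 0:
        raise ValueError("elapsed_s must be > 0")
    return math.log2(n_targets - 1) * max(n_correct - n_wrong, 0) / elapsed_s


def trial_metrics(trial: TrialRecord, task: TaskSpec) -> TrialMetrics:
    """Compute the four movement metrics for one trial."""
    dist = float(np.linalg.norm(trial.target[0] - trial.start))
    r_eff = task.effective_radius(float(trial.target_radius[0]))
    iod = index_of_difficulty(dist, r_eff)
    path = trial.path_length()
    if path <= 0:
        warnings.warn("trial with zero path length: path efficiency undefined",
                      stacklevel=2)
        pe = None
    else:
        # capped at 1: a success trial can travel marginally less than the
        # center-to-center distance because contact occurs at the boundary
        pe = min(1.0, dist / path)
    if trial.outcome != "success":
        tt = trial.t_first_contact
        return TrialMetrics(None, tt, None, pe, False, iod)
    mt = trial.t_acquire
    tt = trial.t_first_contact
    di = mt - tt - task.dwell_s
    return TrialMetrics(mt, tt, di, pe, True, iod)


def metrics_frame(session: SimulatedSession) -> pd.DataFrame:
    """Per-trial metric table from a simulated session's summary rows."""
    return frame_from_summary(session.trials, session.task.dwell_s)


def frame_from_summary(trials: pd.DataFrame, dwell_s: float) -> pd.DataFrame:
    f = pd.DataFrame(index=trials.index)
    f["success"] = trials["success"]
    f["movement_time"] = trials["t_acquire"]
    f["translation_time"] = trials["t_first_contact"]
    f["dial_in_time"] = trials["t_acquire"] - trials["t_first_contact"] - dwell_s
    with np.errstate(divide="ignore", invalid="ignore"):
        pe = (trials["distance"] / trials["path_length"]).clip(upper=1.0)
    f["path_efficiency"] = pe.where(trials["path_length"] > 0)
    # failed trials carry no movement/dial-in times
    f.loc[~trials["success"], ["movement_time", "dial_in_time"]] = np.nan
    f["index_of_difficulty"] = [
        index_of_difficulty(d, r) if d > 0 else np.nan
        for d, r in zip(trials["distance"], trials["effective_radius"])
    ]
    f["distance"] = trials["distance"]
    f["target_radius"] = trials["target_radius"]
    return f


@dataclass
class ConditionSummary:
    """Per-metric mean, SE, and percentile-bootstrap 95% CI for a condition."""

    table: pd.DataFrame  # rows: metric; cols: mean, se, ci_lo, ci_hi
    n_trials: int
    success_rate: float

    def mean(self, metric: str) -> float:
        return float(self.table.loc[metric, "mean"])

    def se(self, metric: str) -> float:
        return float(self.table.loc[metric, "se"])

    def ci(self, metric: str):
        return (float(self.table.loc[metric, "ci_lo"]),
                float(self.table.loc[metric, "ci_hi"]))


def summarize_frame(frame: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0) -> ConditionSummary:
    """Bootstrap condition summary over a per-trial metric frame."""
    if len(frame) < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    rows = {}
    n = len(frame)
    idx = rng.integers(0, n, size=(n_boot, n))
    for m in METRIC_COLUMNS:
        x = frame[m].to_numpy(dtype=float)
        finite = np.isfinite(x)
        if finite.sum() == 0:
            rows[m] = dict(mean=np.nan, se=np.nan, ci_lo=np.nan, ci_hi=np.nan)
            continue
        mean = float(np.nanmean(x))
        se = float(np.nanstd(x[finite], ddof=1) / math.sqrt(finite.sum())) if finite.sum() > 1 else 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            boot = np.nanmean(x[idx], axis=1)
        ok = np.isfinite(boot)
        if ok.sum() == 0:
            lo = hi = mean
        else:
            lo, hi = np.percentile(boot[ok], [2.5, 97.5])
        rows[m] = dict(mean=mean, se=se, ci_lo=min(lo, mean), ci_hi=max(hi, mean))
    table = pd.DataFrame(rows).T
    return ConditionSummary(table=table, n_trials=n,
                            success_rate=float(frame["success"].mean()))


def summarize_condition(trials, n_boot: int = 1000, seed: int = 0) -> ConditionSummary:
    """Summarize a SimulatedSession, metric frame, or list of TrialRecords."""
    if isinstance(trials, SimulatedSession):
        frame = metrics_frame(trials)
    elif isinstance(trials, pd.DataFrame):
        frame = trials
    else:  # sequence of (TrialRecord, TaskSpec-less) -> needs task; unsupported here
        raise TypeError("pass a SimulatedSession or per-trial metric DataFrame")
    return summarize_frame(frame, n_boot=n_boot, seed=seed)


def compare_times(times_a, times_b):
    """Welch t-test between two per-trial time samples -> (t, p)."""
    a = np.asarray(times_a, float)
    b = np.asarray(times_b, float)
    res = stats.ttest_ind(a[np.isfinite(a)], b[np.isfinite(b)], equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_success_rates(n_success_a, n_fail_a, n_success_b, n_fail_b):
    """Fisher's exact test on two success/failure counts -> (odds ratio, p)."""
    odds, p = stats.fisher_exact([[n_success_a, n_fail_a],
                                  [n_success_b, n_fail_b]])
    return float(odds), float(p)


def evaluate_predictions(observed, predicted):
    """Compare predicted condition means against observed ones.

    Returns ``(fvaf, mae, slope, intercept, slope_p)`` where FVAF is the
    fraction of variance accounted for, 1 - SSE/SST (<= 1, can be negative),
    and (slope, intercept, p) come from the OLS regression of predictions on
    observations with a two-sided test of slope = 0.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 3:
        raise ValueError("observed and predicted must be equal-length 1-D, n >= 3")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values have zero variance; FVAF undefined")
    fvaf = 1.0 - float(np.sum((obs - pred) ** 2)) / sst
    mae = float(np.mean(np.abs(obs - pred)))
    res = stats.linregress(obs, pred)
    return fvaf, mae, float(res.slope), float(res.intercept), float(res.pvalue)
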