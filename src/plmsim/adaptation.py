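"""User adaptation across decoder conditions.

When predicting performance under gain/smoothing settings different from the
fitted condition, the user is assumed to rapidly re-tune their velocity
damping: the damping weighting is replaced by a linear function through the
origin whose slope is chosen, by brute-force search over a grid, to minimize
the mean simulated movement time at the new condition.  No held-out data is
used -- only simulation from the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoder import DecoderParams
from .piecewise import PiecewiseLinearFn
from .task import TaskSpec
from .user import UserModel

__all__ = ["AdaptationConfig", "adapt_damping"]


@dataclass(frozen=True)
class AdaptationConfig:
    """Brute-force damping-slope search settings.

    The grid spans 0 to -3 in steps of -0.1 (31 candidates).  Common random
    numbers are used across candidates (the same per-trial noise streams),
    which removes most Monte-Carlo noise from the comparison; ties are broken
    toward the slope closest to zero (least intervention).
    """

    slope_grid: tuple = field(default_factory=lambda: tuple(np.round(np.arange(0.0, -3.05, -0.1), 10)))
    n_sims_per_slope: int = 100
    objective: str = "movement_time"

    def __post_init__(self):
        g = np.asarray(self.slope_grid, float)
        if g.max() < 0.0 or g.min() > -3.0:
            raise ValueError("slope grid must cover [-3, 0]")


def _objective_value(frame, objective: str) -> float:
    col = frame[objective]
    if np.isfinite(col).sum() == 0:
        return np.inf
    val = float(np.nanmean(col))
    # penalize failures so all-timeout conditions don't look good
    fail = 1.0 - float(frame["success"].mean())
    return val + 1e3 * fail if objective.endswith("time") else val


def _slope_fn(slope: float, speed_cap: float) -> PiecewiseLinearFn:
    if slope == 0.0:
        return PiecewiseLinearFn.constant(0.0, 0.0, speed_cap)
    return PiecewiseLinearFn.linear(slope, hi=speed_cap)


def adapt_damping(user: UserModel, decoder: DecoderParams, task: TaskSpec,
                  cfg: AdaptationConfig | None = None, seed: int = 0) -> UserModel:
    """Return a copy of ``user`` with a re-optimized linear damping slope.

    The push weighting and noise model are unchanged.  The returned user's
    damping function is linear through the origin over [0, 2.5 * gain] with
    a slope drawn from the search grid.

    All slope candidates are evaluated in one vectorized batch that reuses
    the same per-trial targets and noise streams (common random numbers).
    """
    from .engine import _child_seeds, _run_batch
    from .metrics import frame_from_summary

    cfg = cfg or AdaptationConfig()
    speed_cap = 2.5 * decoder.gain_beta
    slopes = np.asarray(sorted(cfg.slope_grid, key=abs), float)
    m = cfg.n_sims_per_slope
    geom_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    starts, targets, radii = task.target_generator.generate(m, geom_rng)
    seqs = _child_seeds(seed, m)

    n = len(slopes) * m
    tile = lambda a: np.concatenate([a] * len(slopes), axis=0)
    summary, _ = _run_batch(
        user, decoder, task, tile(starts), tile(targets), tile(radii),
        seqs * len(slopes), vel_slope=np.repeat(slopes, m), vel_slope_cap=speed_cap)

    best = None
    for i, slope in enumerate(slopes):  # |slope| order: ties -> least damping
        frame = frame_from_summary(summary.iloc[i * m:(i + 1) * m], task.dwell_s)
        val = _objective_value(frame, cfg.objective)
        if best is None or val < best[0] - 1e-12:
            best = (val, float(slope))
    return user.with_f_vel(_slope_fn(best[1], speed_cap))
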