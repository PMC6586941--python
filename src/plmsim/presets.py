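"""Canonical synthetic ground-truth configurations.

These define the study conditions used throughout the test suite and the
acceptance analyses: a 2-D center-out task on a workspace normalized so one
target distance = 1 unit, a decoder at 20 ms steps, and a simulated user with
a 200 ms visual feedback delay, a saturating distance-to-target push, linear
velocity damping, and AR(1) decoding noise whose magnitude is a substantial
fraction of the command scale (as is typical of intracortical decoders).
"""

from __future__ import annotations

import numpy as np

from .decoder import DecoderParams
from .piecewise import PiecewiseLinearFn
from .task import CenterOutLayout, TaskSpec
from .user import ControlPolicy, NoiseModel, UserModel

__all__ = ["default_decoder", "default_task", "default_user", "precision_task"]


def default_decoder(gain_beta: float = 1.2, smoothing_alpha: float = 0.92,
                    dt: float = 0.02, dims: int = 2) -> DecoderParams:
    """Baseline linear velocity decoder: terminal speed 1.2 TD/s, alpha 0.92."""
    return DecoderParams(gain_beta=gain_beta, smoothing_alpha=smoothing_alpha,
                         dt=dt, dims=dims)


def default_task(distance: float = 1.0, target_radius: float = 0.1,
                 dwell_s: float = 0.5, max_trial_s: float = 10.0) -> TaskSpec:
    """Center-out-and-back task, 8 outer targets at one target-distance."""
    return TaskSpec(
        target_generator=CenterOutLayout(distance=distance, target_radius=target_radius),
        dwell_s=dwell_s, max_trial_s=max_trial_s,
    )


def precision_task(distance: float = 1.0, ratio: float = 8.0,
                   dwell_s: float = 4.0, max_trial_s: float = 12.0) -> TaskSpec:
    """High-precision task: effective radius = distance / ratio, long dwell."""
    return TaskSpec(
        target_generator=CenterOutLayout(distance=distance,
                                         target_radius=distance / ratio),
        dwell_s=dwell_s, max_trial_s=max_trial_s,
    )


def default_user(delay_tau: int = 10, f_vel_slope: float = -1.0,
                 innovation_sd: float = 0.25, ar_coeff: float = 0.5,
                 sdn_fn: PiecewiseLinearFn | None = None,
                 dims: int = 2) -> UserModel:
    """Ground-truth simulated user.

    The push weighting saturates at 1 (full effort on the normalized command
    scale) beyond 0.4 target-distances and ramps down near the target; the
    damping weighting is linear with the given slope.  Decoding noise is
    AR(1) with matrix coefficient ``ar_coeff * I`` and isotropic innovation
    variance ``innovation_sd ** 2`` (signal-independent by default).
    """
    f_targ = PiecewiseLinearFn([0.0, 0.15, 0.4, 1.0], [0.0, 0.6, 1.0, 1.0])
    f_vel = PiecewiseLinearFn.linear(f_vel_slope, hi=3.0)
    policy = ControlPolicy(f_targ=f_targ, f_vel=f_vel)
    noise = NoiseModel(
        ar_coeffs=(ar_coeff * np.eye(dims),) if ar_coeff != 0.0 else (),
        innovation_cov=innovation_sd**2 * np.eye(dims),
        sdn_fn=sdn_fn,
    )
    return UserModel(policy=policy, noise=noise, delay_tau=delay_tau)
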