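"""Linear velocity decoder dynamics: gain, exponential smoothing, state space.

The decoder receives a d-dimensional control vector ``u_t`` per time step
(in closed-loop use this is the output of the linear dimensionality-reduction
step applied to neural features; here it is supplied by the simulated user)
and produces a cursor velocity through first-order exponential smoothing::

    v_{t+1} = alpha * v_t + (1 - alpha) * beta * T(u_t)

where ``alpha`` in [0, 1) sets the smoothing, ``beta`` > 0 the gain, and ``T``
an optional static nonlinear speed transform.  Because the decode matrix is
assumed normalized so that a sustained unit-magnitude command saturates the
speed at ``beta``, the gain is the cursor's terminal velocity in workspace
units per second.  Position integrates the updated velocity:
``p_{t+1} = p_t + dt * v_{t+1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpeedTransform",
    "DecoderParams",
    "CursorState",
    "StateSpace",
    "step",
    "build_state_space",
    "apply_speed_transform",
    "transform_magnitude",
    "gain_in_td_per_s",
]


@dataclass(frozen=True)
class SpeedTransform:
    """Static nonlinear transform of the decoded speed.

    Variants
    --------
    identity
        ``s_out = s_in``.
    exponent
        ``s_out = s_in ** p`` with ``p > 0``.  ``p > 1`` contracts speeds
        below 1 (on the normalized command scale) and expands speeds above 1.
    piecewise
        Linear interpolation between ``(s_in, s_out)`` breakpoints; the last
        segment's slope is extrapolated beyond the final breakpoint so there
        is no hard speed ceiling.
    """

    variant: str = "identity"
    exponent_p: float = 1.0
    breakpoints: tuple = ()

    def __post_init__(self):
        if self.variant not in ("identity", "exponent", "piecewise"):
            raise ValueError(f"unknown speed-transform variant {self.variant!r}")
        if self.variant == "exponent" and not self.exponent_p > 0:
            raise ValueError("exponent_p must be > 0")
        if self.variant == "piecewise":
            bp = np.asarray(self.breakpoints, dtype=float)
            if bp.ndim != 2 or bp.shape[1] != 2 or bp.shape[0] < 2:
                raise ValueError("piecewise transform needs >= 2 (s_in, s_out) pairs")
            if bp[0, 0] != 0.0:
                raise ValueError("first breakpoint s_in must be 0")
            if not np.all(np.diff(bp[:, 0]) > 0):
                raise ValueError("breakpoint s_in values must be strictly increasing")
            if np.any(bp < 0):
                raise ValueError("breakpoints must be non-negative")
            object.__setattr__(self, "breakpoints", tuple(map(tuple, bp)))

    @property
    def is_identity(self) -> bool:
        return self.variant == "identity" or (
            self.variant == "exponent" and self.exponent_p == 1.0
        )

    @classmethod
    def identity(cls) -> "SpeedTransform":
        return cls("identity")

    @classmethod
    def exponent(cls, p: float) -> "SpeedTransform":
        return cls("exponent", exponent_p=p)

    @classmethod
    def piecewise(cls, s_in, s_out) -> "SpeedTransform":
        pts = tuple(zip(np.asarray(s_in, float), np.asarray(s_out, float)))
        return cls("piecewise", breakpoints=pts)


def transform_magnitude(s, transform: SpeedTransform):
    """Map speed magnitudes through the transform (vectorized, s >= 0)."""
    s = np.asarray(s, dtype=float)
    if transform.variant == "identity":
        return s
    if transform.variant == "exponent":
        return s**transform.exponent_p
    bp = np.asarray(transform.breakpoints, dtype=float)
    s_in, s_out = bp[:, 0], bp[:, 1]
    out = np.interp(s, s_in, s_out)
    # extrapolate the last segment's slope beyond the final breakpoint
    last_slope = (s_out[-1] - s_out[-2]) / (s_in[-1] - s_in[-2])
    beyond = s > s_in[-1]
    if np.any(beyond):
        out = np.where(beyond, s_out[-1] + last_slope * (s - s_in[-1]), out)
    return out


def apply_speed_transform(u: np.ndarray, transform: SpeedTransform) -> np.ndarray:
    """Apply the transform to a control vector, preserving its direction.

    Accepts a single d-vector or an (n, d) batch; zero vectors stay zero.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("control vector must be finite")
    if transform.is_identity:
        return u
    single = u.ndim == 1
    ub = np.atleast_2d(u)
    s = np.linalg.norm(ub, axis=1)
    s_out = transform_magnitude(s, transform)
    scale = np.where(s > 0, s_out / np.where(s > 0, s, 1.0), 0.0)
    out = ub * scale[:, None]
    return out[0] if single else out


@dataclass(frozen=True)
class DecoderParams:
    """Gain, smoothing, time step, dimensionality, and speed transform."""

    gain_beta: float
    smoothing_alpha: float
    dt: float = 0.02
    dims: int = 2
    speed_transform: SpeedTransform = field(default_factory=SpeedTransform.identity)

    def __post_init__(self):
        if not self.gain_beta > 0:
            raise ValueError("gain_beta must be > 0")
        if not (0.0 <= self.smoothing_alpha < 1.0):
            raise ValueError("smoothing_alpha must be in [0, 1)")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not (isinstance(self.dims, (int, np.integer)) and self.dims >= 1):
            raise ValueError("dims must be an integer >= 1")

    def with_(self, **kw) -> "DecoderParams":
        return replace(self, **kw)


@dataclass
class CursorState:
    """Cursor position and velocity (workspace units, units/s)."""

    position: np.ndarray
    velocity: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.position.shape != self.velocity.shape:
            raise ValueError("position and velocity must have the same shape")
        if not (np.all(np.isfinite(self.position)) and np.all(np.isfinite(self.velocity))):
            raise ValueError("cursor state must be finite")

    @classmethod
    def zero(cls, dims: int) -> "CursorState":
        return cls(np.zeros(dims), np.zeros(dims))

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.position, self.velocity])


@dataclass(frozen=True)
class StateSpace:
    """Block matrices (A, B) with x_t = A x_{t-1} + B u_t.

    The stacked state is ``x = [position; velocity]``.  One application of
    (A, B) equals one decoder :func:`step` with the identity transform.
    """

    A: np.ndarray
    B: np.ndarray


def build_state_space(params: DecoderParams) -> StateSpace:
    d = params.dims
    a, b, dt = params.smoothing_alpha, params.gain_beta, params.dt
    I = np.eye(d)
    # v' = a v + (1-a) b u ;  p' = p + dt v'  =>  lower-block-triangular A
    A = np.block([[I, dt * a * I], [np.zeros((d, d)), a * I]])
    B = np.vstack([dt * (1 - a) * b * I, (1 - a) * b * I])
    return StateSpace(A=A, B=B)


def step(state: CursorState, u: np.ndarray, params: DecoderParams) -> CursorState:
    """Advance the cursor one decoder time step."""
    u = np.asarray(u, dtype=float)
    if u.shape != (params.dims,):
        raise ValueError(f"control vector must have shape ({params.dims},)")
    if not np.all(np.isfinite(u)):
        raise ValueError("control vector must be finite")
    tu = apply_speed_transform(u, params.speed_transform)
    v = params.smoothing_alpha * state.velocity + (1 - params.smoothing_alpha) * params.gain_beta * tu
    p = state.position + params.dt * v
    return CursorState(position=p, velocity=v)


def gain_in_td_per_s(params: DecoderParams, target_distance: float) -> float:
    """Express the gain in target distances per second."""
    if not target_distance > 0:
        raise ValueError("target_distance must be > 0")
    return params.gain_beta / target_distance
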