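"""Knot-parameterized one-dimensional piecewise-linear functions.

These are the basic building block of the user model: the target-distance
weighting ``f_targ``, the speed-damping weighting ``f_vel``, and the
signal-dependent-noise scale ``f_SDN`` are all instances.  Evaluation between
knots is linear interpolation; outside the knot range the boundary ordinate is
returned (clamped).  The decoder's piecewise speed transform deliberately does
*not* use this class because it extrapolates beyond its last breakpoint (see
:mod:`plmsim.decoder`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PiecewiseLinearFn:
    """A clamped piecewise-linear function defined by knots and values.

    Parameters
    ----------
    knots : array-like
        Strictly increasing abscissae, at least 2.
    values : array-like
        Ordinates, same length as ``knots``.
    """

    knots: np.ndarray
    values: np.ndarray

    def __init__(self, knots, values):
        knots = np.asarray(knots, dtype=float)
        values = np.asarray(values, dtype=float)
        if knots.ndim != 1 or knots.size < 2:
            raise ValueError("need at least 2 knots")
        if values.shape != knots.shape:
            raise ValueError("knots and values must have the same length")
        if not np.all(np.diff(knots) > 0):
            raise ValueError("knots must be strictly increasing")
        if not (np.all(np.isfinite(knots)) and np.all(np.isfinite(values))):
            raise ValueError("knots and values must be finite")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", values)

    def __call__(self, x):
        # np.interp clamps to the boundary ordinates outside the knot range,
        # which is exactly the contract here.
        return np.interp(x, self.knots, self.values)

    @classmethod
    def constant(cls, value: float, lo: float = 0.0, hi: float = 1.0) -> "PiecewiseLinearFn":
        return cls([lo, hi], [value, value])

    @classmethod
    def linear(cls, slope: float, hi: float) -> "PiecewiseLinearFn":
        """Line through the origin on [0, hi], clamped beyond ``hi``."""
        if hi <= 0:
            raise ValueError("hi must be positive")
        return cls([0.0, hi], [0.0, slope * hi])

    def slope_through_origin(self) -> float:
        """Least-squares slope of a line through the origin over the knots.

        Convenience for summarizing near-linear fitted functions (e.g. the
        velocity-damping weighting, which adaptation assumes is linear).
        """
        k, v = self.knots, self.values
        denom = float(np.dot(k, k))
        if denom == 0:
            return 0.0
        return float(np.dot(k, v) / denom)
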