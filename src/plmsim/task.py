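"""Task geometry: target layouts, dwell/timeout rules."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TaskSpec", "CenterOutLayout", "RandomTargetLayout", "FixedPairsLayout"]


class TargetLayout:
    """Rule producing per-trial (target position, target radius).

    The next trial starts where the previous trial's target was (the cursor
    is left on -- or reset to -- the acquired target), so a layout is a chain:
    ``initial_start`` gives the first cursor position and ``next_target``
    produces each successive target from the previous one.
    """

    dims: int = 2

    def initial_start(self) -> np.ndarray:
        raise NotImplementedError

    def next_target(self, prev: np.ndarray, k: int, rng: np.random.Generator):
        raise NotImplementedError

    def generate(self, n_trials: int, rng: np.random.Generator):
        """Chain out ``n_trials`` as (starts, targets, radii) arrays."""
        starts = np.empty((n_trials, self.dims))
        targets = np.empty((n_trials, self.dims))
        radii = np.empty(n_trials)
        pos = self.initial_start()
        for k in range(n_trials):
            starts[k] = pos
            t, r = self.next_target(pos, k, rng)
            targets[k] = t
            radii[k] = r
            pos = t
        return starts, targets, radii


@dataclass
class CenterOutLayout(TargetLayout):
    """Alternating center/outer targets on a ring of radially spaced locations."""

    distance: float = 1.0
    target_radius: float = 0.1
    n_directions: int = 8
    dims: int = 2

    def __post_init__(self):
        if self.dims != 2:
            raise ValueError("CenterOutLayout is 2-D")
        if not (self.distance > 0 and self.target_radius > 0):
            raise ValueError("distance and target_radius must be > 0")

    def initial_start(self) -> np.ndarray:
        return np.zeros(2)

    def _outer(self, i: int) -> np.ndarray:
        th = 2 * math.pi * i / self.n_directions
        return self.distance * np.array([math.cos(th), math.sin(th)])

    def next_target(self, prev, k, rng):
        at_center = np.linalg.norm(prev) < 1e-9
        if at_center:
            return self._outer(int(rng.integers(self.n_directions))), self.target_radius
        return np.zeros(2), self.target_radius


@dataclass
class RandomTargetLayout(TargetLayout):
    """Uniform targets in a square workspace with a minimum jump distance."""

    halfwidth: float = 1.0
    radii: tuple = (0.1,)
    min_distance: float = 0.2
    dims: int = 2

    def initial_start(self) -> np.ndarray:
        return np.zeros(self.dims)

    def next_target(self, prev, k, rng):
        r = float(rng.choice(np.asarray(self.radii, float)))
        for _ in range(1000):
            t = rng.uniform(-self.halfwidth, self.halfwidth, size=self.dims)
            if np.linalg.norm(t - prev) > max(self.min_distance, r):
                return t, r
        raise RuntimeError("could not place a target satisfying min_distance")


@dataclass
class FixedPairsLayout(TargetLayout):
    """An explicit list of (start, target, radius) trials, cycled."""

    pairs: tuple = ()
    dims: int = 2

    def generate(self, n_trials, rng):
        starts = np.empty((n_trials, self.dims))
        targets = np.empty((n_trials, self.dims))
        radii = np.empty(n_trials)
        for k in range(n_trials):
            s, t, r = self.pairs[k % len(self.pairs)]
            starts[k] = np.asarray(s, float)
            targets[k] = np.asarray(t, float)
            radii[k] = r
        return starts, targets, radii

    def initial_start(self):
        return np.asarray(self.pairs[0][0], float)

    def next_target(self, prev, k, rng):
        _, t, r = self.pairs[k % len(self.pairs)]
        return np.asarray(t, float), r


@dataclass
class TaskSpec:
    """Target-acquisition rules: layout, dwell, timeout.

    A target is acquired by keeping the cursor in unbroken contact with it
    (center within target radius + cursor radius) for ``dwell_s``.  A trial
    that exceeds ``max_trial_s`` fails and the cursor is reset to the target
    position for the next trial.
    """

    target_generator: TargetLayout = field(default_factory=CenterOutLayout)
    cursor_radius: float = 0.0
    dwell_s: float = 0.5
    max_trial_s: float = 10.0
    inter_trial_s: float = 0.0
    workspace_halfwidth: float | None = None  # clamp cursor if set (keyboards)

    def __post_init__(self):
        if self.cursor_radius < 0:
            raise ValueError("cursor_radius must be >= 0")
        if not self.dwell_s > 0:
            raise ValueError("dwell_s must be > 0")
        if not self.dwell_s < self.max_trial_s:
            raise ValueError("dwell_s must be < max_trial_s")
        if self.inter_trial_s < 0:
            raise ValueError("inter_trial_s must be >= 0")

    def effective_radius(self, target_radius: float) -> float:
        r = target_radius + self.cursor_radius
        if not r > 0:
            raise ValueError("effective radius must be > 0")
        return r

    def dwell_steps(self, dt: float) -> int:
        return int(math.ceil(self.dwell_s / dt - 1e-9))

    def max_steps(self, dt: float) -> int:
        return int(math.ceil(self.max_trial_s / dt - 1e-9))

    def with_(self, **kw) -> "TaskSpec":
        return replace(self, **kw)
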