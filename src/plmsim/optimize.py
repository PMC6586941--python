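"""Simulation-based decoder and task optimization.

Three tools built on the fitted user model:

* :func:`sweep_surface` -- 2-D performance surfaces over (gain, smoothing),
  with the user's damping re-adapted in every cell;
* :func:`optimize_keyboard` -- per-dwell-time gain/smoothing optimization of
  a grid keyboard, maximizing the achieved bit rate;
* :func:`optimize_speed_transform` -- design of a static nonlinear speed
  transform, either a piecewise-linear function found by derivative-free
  pattern search (restarted, averaged, isotonically projected) or a simple
  exponent ``s_out = s_in**p`` found by exhaustive joint grid search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .adaptation import AdaptationConfig, _objective_value, adapt_damping
from .decoder import DecoderParams, SpeedTransform
from .engine import _child_seeds, _StepKernel, simulate_condition
from .metrics import achieved_bit_rate, metrics_frame
from .task import CenterOutLayout, TaskSpec
from .user import UserModel

__all__ = ["SweepSpec", "SweepResult", "sweep_surface", "select_params",
           "KeyboardSpec", "simulate_keyboard", "optimize_keyboard",
           "TransformSearchSpec", "optimize_speed_transform"]


# ---------------------------------------------------------------------------
# gain x smoothing surfaces

@dataclass(frozen=True)
class SweepSpec:
    """Grid sweep settings over gain and smoothing."""

    gain_grid: tuple
    smoothing_grid: tuple
    n_trials_per_cell: int = 250
    objective: str = "movement_time"
    seed: int = 0
    adapt: bool = True
    adapt_cfg: AdaptationConfig | None = None

    def __post_init__(self):
        g = np.asarray(self.gain_grid, float)
        a = np.asarray(self.smoothing_grid, float)
        if g.size == 0 or a.size == 0:
            raise ValueError("grids must be non-empty")
        if np.any(g <= 0):
            raise ValueError("gains must be > 0")
        if np.any((a < 0) | (a >= 1)):
            raise ValueError("smoothing values must be in [0, 1)")

    @classmethod
    def around(cls, beta: float, n: int = 20, alpha_lo: float = 0.5,
               alpha_hi: float = 0.99, **kw) -> "SweepSpec":
        """Default grid: n log-spaced gains spanning 0.25x-4x ``beta`` and
        n smoothing values from ``alpha_lo`` to ``alpha_hi``."""
        gains = np.geomspace(0.25 * beta, 4 * beta, n)
        alphas = np.linspace(alpha_lo, alpha_hi, n)
        return cls(tuple(gains), tuple(alphas), **kw)


@dataclass
class SweepResult:
    """Long-format sweep table plus the spec that produced it."""

    table: pd.DataFrame     # columns: gain_beta, smoothing_alpha, metric means...
    spec: SweepSpec

    def surface(self, metric: str) -> pd.DataFrame:
        """Pivot one metric to a (gain x smoothing) 2-D table."""
        return self.table.pivot(index="gain_beta", columns="smoothing_alpha",
                                values=metric)

    def plot(self, metric: str = "movement_time", ax=None):
        """Heatmap of one metric over the (gain, smoothing) grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        surf = self.surface(metric)
        mesh = ax.pcolormesh(surf.columns.to_numpy(), surf.index.to_numpy(),
                             surf.to_numpy(), shading="nearest")
        ax.set_xlabel("smoothing alpha")
        ax.set_ylabel("gain beta")
        ax.set_yscale("log")
        plt.colorbar(mesh, ax=ax, label=metric)
        return ax


def _cell_metrics(user, decoder, task, n_trials, seed, adapt, adapt_cfg):
    u = adapt_damping(user, decoder, task, adapt_cfg, seed=seed) if adapt else user
    sess = simulate_condition(u, decoder, task, n_trials, seed=seed + 1)
    f = metrics_frame(sess)
    row = {}
    for m in ("movement_time", "translation_time", "dial_in_time", "path_efficiency"):
        x = f[m].to_numpy(float)
        ok = np.isfinite(x)
        row[m] = float(np.nanmean(x)) if ok.any() else np.nan
        row[m + "_se"] = (float(np.nanstd(x[ok], ddof=1) / math.sqrt(ok.sum()))
                          if ok.sum() > 1 else np.nan)
    row["success_rate"] = float(f["success"].mean())
    row["adapted_slope"] = u.policy.f_vel.slope_through_origin()
    return row


def sweep_surface(user: UserModel, task: TaskSpec, spec: SweepSpec,
                  base_decoder: DecoderParams | None = None) -> SweepResult:
    """Simulate every (gain, smoothing) cell and tabulate metric means."""
    base = base_decoder or DecoderParams(gain_beta=spec.gain_grid[0],
                                         smoothing_alpha=spec.smoothing_grid[0])
    rows = []
    for i, beta in enumerate(spec.gain_grid):
        for j, alpha in enumerate(spec.smoothing_grid):
            dec = base.with_(gain_beta=float(beta), smoothing_alpha=float(alpha))
            cell_seed = int(np.random.SeedSequence(spec.seed, spawn_key=(i, j)
                                                   ).generate_state(1)[0] % (2**31))
            row = _cell_metrics(user, dec, task, spec.n_trials_per_cell,
                                cell_seed, spec.adapt, spec.adapt_cfg)
            row.update(gain_beta=float(beta), smoothing_alpha=float(alpha))
            rows.append(row)
    cols = ["gain_beta", "smoothing_alpha"]
    table = pd.DataFrame(rows)
    table = table[cols + [c for c in table.columns if c not in cols]]
    return SweepResult(table=table, spec=spec)


_MAXIMIZE = {"path_efficiency", "success_rate", "bit_rate"}


def select_params(surface: SweepResult | pd.DataFrame, objective: str):
    """Pick the optimal (gain, smoothing) cell for one metric.

    Minimizes time metrics, maximizes path efficiency / success / bit rate;
    ties break toward lower gain, then higher smoothing.
    """
    table = surface.table if isinstance(surface, SweepResult) else surface
    vals = table[objective].to_numpy(float)
    if objective in _MAXIMIZE:
        vals = -vals
    vals = np.where(np.isfinite(vals), vals, np.inf)
    order = np.lexsort((-table["smoothing_alpha"].to_numpy(),
                        table["gain_beta"].to_numpy(), vals))
    row = table.iloc[order[0]]
    return float(row["gain_beta"]), float(row["smoothing_alpha"])


# ---------------------------------------------------------------------------
# keyboard optimization

@dataclass(frozen=True)
class KeyboardSpec:
    """Square grid keyboard selected by dwelling on keys.

    ``n_keys`` must be a perfect square; keys tile a square workspace with
    side ``sqrt(n_keys) * key_size`` without overlap.  Dwelling on any key
    for the dwell time selects it; selecting a non-target key (or timing
    out) is a failure.
    """

    n_keys: int = 36
    key_size: float = 0.25
    dwell_grid: tuple = field(default_factory=lambda: tuple(np.round(np.arange(0.1, 2.01, 0.1), 10)))
    max_select_s: float = 10.0

    def __post_init__(self):
        k = int(round(math.sqrt(self.n_keys)))
        if k * k != self.n_keys:
            raise ValueError("n_keys must be a perfect square")
        if not self.key_size > 0:
            raise ValueError("key_size must be > 0")

    @property
    def side(self) -> int:
        return int(round(math.sqrt(self.n_keys)))

    @property
    def halfwidth(self) -> float:
        return 0.5 * self.side * self.key_size

    def key_center(self, idx: np.ndarray) -> np.ndarray:
        """Centers of key indices (row-major) in workspace coordinates."""
        idx = np.asarray(idx)
        row, col = idx // self.side, idx % self.side
        x = (col + 0.5) * self.key_size - self.halfwidth
        y = (row + 0.5) * self.key_size - self.halfwidth
        return np.stack([x, y], axis=-1)

    def key_at(self, pos: np.ndarray) -> np.ndarray:
        """Key index under each position (positions are clamped on-grid)."""
        pos = np.asarray(pos, float)
        ij = np.clip(((pos + self.halfwidth) / self.key_size).astype(int),
                     0, self.side - 1)
        return ij[..., 1] * self.side + ij[..., 0]


def simulate_keyboard(user: UserModel, decoder: DecoderParams, kb: KeyboardSpec,
                      dwell_s: float, n_selections: int, seed: int) -> pd.DataFrame:
    """Simulate a series of key selections; returns a per-selection table.

    Each selection starts at the previous target key's center with the
    cursor at rest; the target key is uniform over the other keys.  The
    cursor is clamped to the keyboard workspace.
    """
    dt = decoder.dt
    required_run = int(math.ceil(dwell_s / dt - 1e-9)) + 1
    max_steps = int(math.ceil(kb.max_select_s / dt))
    geom_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))

    # chain of keys: target_k != target_{k-1}; start at previous target
    keys = np.empty(n_selections + 1, dtype=int)
    keys[0] = geom_rng.integers(kb.n_keys)
    for k in range(1, n_selections + 1):
        nxt = geom_rng.integers(kb.n_keys - 1)
        keys[k] = nxt + (nxt >= keys[k - 1])
    starts = kb.key_center(keys[:-1])
    target_keys = keys[1:]
    targets = kb.key_center(target_keys)

    seqs = _child_seeds(seed, n_selections)
    kern = _StepKernel(user, decoder, n_selections, starts, seqs, max_steps)

    start_keys = keys[:-1]
    cur_key = kb.key_at(kern.p)
    run = np.ones(n_selections, dtype=int)  # sitting on the start key
    selected = np.full(n_selections, -1, dtype=int)
    t_select = np.full(n_selections, np.nan)
    active = np.ones(n_selections, dtype=bool)
    left_start = np.zeros(n_selections, dtype=bool)

    for t in range(max_steps):
        kern.step(targets)
        kern.clamp(kb.halfwidth)
        key = kb.key_at(kern.p)
        run = np.where(key == cur_key, run + 1, 1)
        cur_key = key
        left_start |= key != start_keys
        # the just-selected key is ineligible until first exited (a dwell
        # keyboard cannot instantly reselect the key it starts on)
        eligible = left_start | (key != start_keys)
        done = active & eligible & (run >= required_run)
        selected[done] = key[done]
        t_select[done] = (t + 1) * dt
        active &= ~done
        if not active.any():
            break
    t_select = np.where(np.isnan(t_select), kb.max_select_s, t_select)
    return pd.DataFrame({
        "target_key": target_keys,
        "selected_key": selected,     # -1 = timeout
        "correct": selected == target_keys,
        "time_s": t_select,
    })


def _keyboard_eval(frame: pd.DataFrame, n_keys: int):
    n_correct = int(frame["correct"].sum())
    n_wrong = int(len(frame) - n_correct)  # wrong selections and timeouts
    elapsed = float(frame["time_s"].sum())
    rate = achieved_bit_rate(n_keys, n_correct, n_wrong, elapsed)
    return rate, n_correct / len(frame), float(frame["time_s"].mean())


def optimize_keyboard(user: UserModel, kb: KeyboardSpec, gain_grid, smoothing_grid,
                      seed: int = 0, n_selections: int = 200,
                      dt: float = 0.02, adapt: bool = True,
                      adapt_cfg: AdaptationConfig | None = None) -> pd.DataFrame:
    """Per-dwell-time gain/smoothing optimization maximizing bit rate.

    For each dwell time a full (gain, smoothing) sweep is run; the returned
    table has one row per dwell time with the bit-rate-optimal settings and
    their success rate and mean selection time.  Damping adaptation per cell
    uses a proxy circular target of the keyboard's key scale.
    """
    adapt_cfg = adapt_cfg or AdaptationConfig(n_sims_per_slope=30)
    mean_dist = 1.2 * kb.halfwidth  # typical key-to-key jump
    rows = []
    for di, dwell in enumerate(kb.dwell_grid):
        best = None
        for i, beta in enumerate(gain_grid):
            for j, alpha in enumerate(smoothing_grid):
                dec = DecoderParams(gain_beta=float(beta),
                                    smoothing_alpha=float(alpha), dt=dt)
                cell_seed = int(np.random.SeedSequence(seed, spawn_key=(di, i, j)
                                                       ).generate_state(1)[0] % (2**31))
                u = user
                if adapt:
                    proxy = TaskSpec(
                        target_generator=CenterOutLayout(distance=mean_dist,
                                                         target_radius=0.45 * kb.key_size),
                        dwell_s=float(dwell), max_trial_s=kb.max_select_s + float(dwell))
                    u = adapt_damping(user, dec, proxy, adapt_cfg, seed=cell_seed)
                frame = simulate_keyboard(u, dec, kb, float(dwell),
                                          n_selections, cell_seed + 1)
                rate, succ, mean_t = _keyboard_eval(frame, kb.n_keys)
                cand = (rate, -beta, alpha, succ, mean_t, float(beta), float(alpha))
                if best is None or cand[:3] > best[:3]:
                    best = cand
        rate, _, _, succ, mean_t, beta, alpha = best
        rows.append({"dwell_s": float(dwell), "gain_beta": beta,
                     "smoothing_alpha": alpha, "bit_rate": rate,
                     "success_rate": succ, "mean_select_time": mean_t})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nonlinear speed transform design

@dataclass(frozen=True)
class TransformSearchSpec:
    """Search settings for the nonlinear speed-transform design.

    The piecewise variant places ``n_breakpoints`` breakpoints evenly from 0
    to 1.25 on the normalized control-magnitude scale (the decoder applies
    gain after the transform, so this spans 0 to 1.25x the terminal speed)
    and pattern-searches their ordinates; ``n_restarts`` searches are run
    and the resulting functions averaged pointwise, then isotonically
    projected to be non-decreasing.  The exponent variant searches
    (gain, smoothing, p) exhaustively.
    """

    variant: str = "exponent"
    n_breakpoints: int = 14
    breakpoint_span: float = 1.25
    n_restarts: int = 24
    sims_per_eval: int = 200
    exponent_grid: tuple = (1.0, 1.25, 1.5, 1.75, 2.0, 2.5, 3.0)
    gain_grid: tuple | None = None       # default: around the base gain
    smoothing_grid: tuple | None = None
    max_pattern_iters: int = 40
    init_step: float = 0.3
    min_step: float = 0.02
    adapt: bool = True
    adapt_cfg: AdaptationConfig | None = None

    def __post_init__(self):
        if self.variant not in ("piecewise", "exponent"):
            raise ValueError("variant must be 'piecewise' or 'exponent'")


def _mean_movement_objective(user, decoder, task, n_sims, seed, adapt, adapt_cfg):
    u = adapt_damping(user, decoder, task, adapt_cfg, seed=seed) if adapt else user
    sess = simulate_condition(u, decoder, task, n_sims, seed=seed + 1)
    return _objective_value(metrics_frame(sess), "movement_time")


def _pattern_search(objective, x0: np.ndarray, init_step: float, min_step: float,
                    max_iters: int, lower: float = 0.0):
    """Coordinate pattern search: accept only improving +/- steps, shrink."""
    x = x0.copy()
    fx = objective(x)
    step = init_step
    for _ in range(max_iters):
        improved = False
        for k in range(len(x)):
            for sgn in (+1.0, -1.0):
                cand = x.copy()
                cand[k] = max(lower, cand[k] + sgn * step)
                if cand[k] == x[k]:
                    continue
                fc = objective(cand)
                if fc < fx - 1e-12:
                    x, fx = cand, fc
                    improved = True
                    break
        if not improved:
            step *= 0.5
            if step < min_step:
                break
    return x, fx


def optimize_speed_transform(user: UserModel, base_decoder: DecoderParams,
                             task: TaskSpec, spec: TransformSearchSpec,
                             seed: int = 0):
    """Design a speed transform minimizing mean simulated movement time.

    Returns ``(decoder, info)``: the decoder with the optimized transform
    (and, for the exponent variant, jointly optimized gain and smoothing),
    plus a dict of search diagnostics.  The objective for every candidate is
    the mean movement time of ``sims_per_eval`` simulated movements with
    common random numbers across candidates.
    """
    if spec.variant == "exponent":
        gains = (spec.gain_grid if spec.gain_grid is not None
                 else tuple(np.geomspace(0.5, 2.5, 6) * base_decoder.gain_beta))
        alphas = (spec.smoothing_grid if spec.smoothing_grid is not None
                  else tuple(np.linspace(0.82, 0.97, 6)))
        records = []
        best = None
        for p in spec.exponent_grid:
            tr = SpeedTransform.identity() if p == 1.0 else SpeedTransform.exponent(float(p))
            for beta in gains:
                for alpha in alphas:
                    dec = base_decoder.with_(gain_beta=float(beta),
                                             smoothing_alpha=float(alpha),
                                             speed_transform=tr)
                    val = _mean_movement_objective(user, dec, task,
                                                   spec.sims_per_eval, seed,
                                                   spec.adapt, spec.adapt_cfg)
                    records.append({"exponent_p": float(p), "gain_beta": float(beta),
                                    "smoothing_alpha": float(alpha),
                                    "movement_time": val})
                    key = (val, abs(p - 1.0), float(beta), -float(alpha))
                    if best is None or key < best[0]:
                        best = (key, dec)
        dec = best[1]
        return dec, {"table": pd.DataFrame(records),
                     "exponent_p": dec.speed_transform.exponent_p
                     if dec.speed_transform.variant == "exponent" else 1.0}

    # piecewise variant: ordinate pattern search at fixed (beta*, alpha*)
    s_in = np.linspace(0.0, spec.breakpoint_span, spec.n_breakpoints)
    solutions = []
    values = []
    for r in range(spec.n_restarts):
        r_seed = int(np.random.SeedSequence(seed, spawn_key=(7, r)
                                            ).generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(r_seed)

        def obj(ordinates, _seed=r_seed):
            tr = SpeedTransform.piecewise(s_in, ordinates)
            dec = base_decoder.with_(speed_transform=tr)
            return _mean_movement_objective(user, dec, task, spec.sims_per_eval,
                                            _seed, spec.adapt, spec.adapt_cfg)

        x0 = s_in.copy()  # start at identity
        if r > 0:  # jitter restarts
            x0 = np.clip(x0 * rng.uniform(0.5, 1.5, size=x0.shape), 0.0, None)
        x, fx = _pattern_search(obj, x0, spec.init_step, spec.min_step,
                                spec.max_pattern_iters)
        solutions.append(x)
        values.append(fx)
    avg = np.mean(solutions, axis=0)
    # averaging restarts can break monotonicity; project to non-decreasing
    mono = isotonic_regression(avg).x
    tr = SpeedTransform.piecewise(s_in, mono)
    return base_decoder.with_(speed_transform=tr), {
        "s_in": s_in, "ordinates": mono, "restart_values": values,
        "restart_solutions": np.asarray(solutions)}
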