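"""Closed-loop trial simulation.

Each simulated time step runs the full loop: delayed visual feedback ->
forward-model internal estimate -> control policy -> AR decoding noise ->
decoder smoothing/gain -> cursor update -> contact/dwell bookkeeping.

The engine is vectorized across trials: a batch of independent trials is
stepped synchronously, which keeps large parameter sweeps cheap without
changing any semantics.  Per-trial randomness comes from counter-derived
child streams of one top-level seed, so trial k is bit-reproducible
independently of batch size or trial order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoder import DecoderParams, build_state_space, transform_magnitude
from .task import TaskSpec
from .user import ZERO_NORM, UserModel, forward_model_operators

__all__ = ["TrialRecord", "SimulatedSession", "simulate_trial", "simulate_condition",
           "simulate_session_chain"]

#: AR-noise warm-up steps prepended to every trial so e_t starts near stationarity
NOISE_BURN_IN = 100


@dataclass
class TrialRecord:
    """Per-step trajectory of one target-acquisition attempt."""

    time: np.ndarray            # (T,) seconds from target onset
    position: np.ndarray        # (T, d)
    velocity: np.ndarray        # (T, d)
    u: np.ndarray               # (T, d) decoder output = c + e
    c: np.ndarray               # (T, d) encoded control
    e: np.ndarray               # (T, d) decoding error
    target: np.ndarray          # (T, d)
    target_radius: np.ndarray   # (T,)
    contact: np.ndarray         # (T,) bool
    outcome: str                # "success" | "timeout"
    t_first_contact: float | None
    t_acquire: float | None
    start: np.ndarray = None
    dwell_s: float = 0.0

    def path_length(self) -> float:
        steps = np.diff(self.position, axis=0, prepend=self.start[None, :])
        return float(np.linalg.norm(steps, axis=1).sum())


class _StepKernel:
    """Synchronous stepping of n closed-loop trials.

    Holds ring buffers for the delayed-feedback forward model and the AR
    noise history; innovations are pre-drawn per trial from independent
    streams so batched and single-trial simulation agree exactly.
    """

    def __init__(self, user: UserModel, decoder: DecoderParams, n: int,
                 starts: np.ndarray, seed_seqs, max_steps: int,
                 init_velocity: np.ndarray | None = None,
                 burn_in: int = NOISE_BURN_IN,
                 vel_slope: np.ndarray | None = None,
                 vel_slope_cap: float = np.inf):
        d = decoder.dims
        self.user, self.decoder, self.n, self.d = user, decoder, n, d
        self.tau = int(user.delay_tau)
        self.max_steps = max_steps
        ss = build_state_space(decoder)
        self.Atau, self.AiB = forward_model_operators(ss, self.tau)

        self.p = np.array(starts, dtype=float).reshape(n, d)
        self.v = (np.zeros((n, d)) if init_velocity is None
                  else np.array(init_velocity, dtype=float).reshape(n, d))

        # pre-draw standard-normal innovations per trial (burn-in + trial)
        Z = np.empty((n, burn_in + max_steps, d))
        for i in range(n):
            rng = np.random.default_rng(seed_seqs[i])
            Z[i] = rng.standard_normal((burn_in + max_steps, d))
        self.Z = Z
        self.L = user.noise.chol()
        self.Pis = [np.asarray(P) for P in user.noise.ar_coeffs]
        self.n_lags = len(self.Pis)

        # ring buffers: states x_{t-tau..t}, controls c_{t-tau..t-1}, errors
        x0 = np.hstack([self.p, self.v])
        self.state_ring = np.repeat(x0[None, :, :], self.tau + 1, axis=0)
        self.c_ring = np.zeros((max(self.tau, 1), n, d))
        self.e_ring = np.zeros((max(self.n_lags, 1), n, d))
        self.t = 0

        ft, fv = user.policy.f_targ, user.policy.f_vel
        self._ft_k, self._ft_v = ft.knots, ft.values
        self._fv_k, self._fv_v = fv.knots, fv.values
        # per-trial linear damping override (used by the adaptation search to
        # batch all slope candidates with common random numbers)
        self._vel_slope = None if vel_slope is None else np.asarray(vel_slope, float)
        self._vel_slope_cap = vel_slope_cap
        sdn = user.noise.sdn_fn
        self._sdn_k, self._sdn_v = sdn.knots, sdn.values

        # AR burn-in at rest (||c|| = 0)
        scale0 = math.sqrt(float(np.interp(0.0, self._sdn_k, self._sdn_v)))
        for b in range(burn_in):
            e = (self.Z[:, b] @ self.L.T) * scale0
            for i, P in enumerate(self.Pis):
                e = e + self.e_ring[(b - 1 - i) % max(self.n_lags, 1)] @ P.T
            if self.n_lags:
                self.e_ring[b % self.n_lags] = e
        self._burn = burn_in

        # latest-step outputs (filled by step())
        self.c = np.zeros((n, d))
        self.e = np.zeros((n, d))
        self.u = np.zeros((n, d))

    def _ar_term(self, slot_base: int) -> np.ndarray:
        e = np.zeros((self.n, self.d))
        for i, P in enumerate(self.Pis):
            e = e + self.e_ring[(slot_base - 1 - i) % self.n_lags] @ P.T
        return e

    def step(self, targets: np.ndarray) -> None:
        """Advance every trial one step toward its (per-trial) target."""
        n, d, tau = self.n, self.d, self.tau
        t = self.t
        # forward-model internal estimate
        if tau == 0:
            x_hat = np.hstack([self.p, self.v])
        else:
            x_del = self.state_ring[(t - tau) % (tau + 1)]
            x_hat = x_del @ self.Atau.T
            for i in range(tau):
                x_hat = x_hat + self.c_ring[(t - 1 - i) % tau] @ self.AiB[i].T
        p_hat, v_hat = x_hat[:, :d], x_hat[:, d:]

        # control policy
        err = targets - p_hat
        dist = np.linalg.norm(err, axis=1)
        w_t = np.interp(dist, self._ft_k, self._ft_v)
        safe_d = np.where(dist > ZERO_NORM, dist, 1.0)
        c = err * (np.where(dist > ZERO_NORM, w_t, 0.0) / safe_d)[:, None]
        spd = np.linalg.norm(v_hat, axis=1)
        if self._vel_slope is not None:
            w_v = self._vel_slope * np.minimum(spd, self._vel_slope_cap)
        else:
            w_v = np.interp(spd, self._fv_k, self._fv_v)
        safe_s = np.where(spd > ZERO_NORM, spd, 1.0)
        c = c + v_hat * (np.where(spd > ZERO_NORM, w_v, 0.0) / safe_s)[:, None]

        # AR decoding noise with signal-dependent innovation scale
        scale = np.sqrt(np.interp(np.linalg.norm(c, axis=1), self._sdn_k, self._sdn_v))
        eps = (self.Z[:, self._burn + t] @ self.L.T) * scale[:, None]
        e = eps
        for i, P in enumerate(self.Pis):
            e = e + self.e_ring[(self._burn + t - 1 - i) % max(self.n_lags, 1)] @ P.T
        u = c + e

        # decoder: speed transform, smoothing, integration
        tr = self.decoder.speed_transform
        if tr.is_identity:
            tu = u
        else:
            s = np.linalg.norm(u, axis=1)
            s_out = transform_magnitude(s, tr)
            tu = u * np.where(s > 0, s_out / np.where(s > 0, s, 1.0), 0.0)[:, None]
        a, b = self.decoder.smoothing_alpha, self.decoder.gain_beta
        self.v = a * self.v + (1 - a) * b * tu
        self.p = self.p + self.decoder.dt * self.v

        # commit histories
        if tau:
            self.c_ring[t % tau] = c
            self.state_ring[(t + 1) % (tau + 1)] = np.hstack([self.p, self.v])
        if self.n_lags:
            self.e_ring[(self._burn + t) % self.n_lags] = e
        self.c, self.e, self.u = c, e, u
        self.t = t + 1

    def clamp(self, halfwidth: float) -> None:
        np.clip(self.p, -halfwidth, halfwidth, out=self.p)


def _child_seeds(seed: int, n: int, stream: int = 0):
    """Counter-derived per-trial seed sequences (order-independent)."""
    return [np.random.SeedSequence(seed, spawn_key=(stream, k)) for k in range(n)]


@dataclass
class SimulatedSession:
    """A batch of simulated trials under one decoder/task condition."""

    trials: pd.DataFrame          # per-trial summary rows
    user: UserModel
    decoder: DecoderParams
    task: TaskSpec
    seed: int
    records: list = field(default_factory=list)  # TrialRecords if recorded

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _run_batch(user, decoder, task, starts, targets, radii, seed_seqs,
               record=False, vel_slope=None, vel_slope_cap=np.inf):
    """Simulate a batch of independent trials; returns per-trial summaries."""
    n, d = len(targets), decoder.dims
    dt = decoder.dt
    max_steps = task.max_steps(dt)
    # acquisition needs dwell_s of unbroken contact *after* the touching
    # sample: dwell_steps completed step-intervals, i.e. dwell_steps + 1
    # consecutive contact samples
    required_run = task.dwell_steps(dt) + 1
    r_eff = np.array([task.effective_radius(r) for r in np.atleast_1d(radii)])
    targets = np.asarray(targets, float).reshape(n, d)
    starts = np.asarray(starts, float).reshape(n, d)

    kern = _StepKernel(user, decoder, n, starts, seed_seqs, max_steps,
                       vel_slope=vel_slope, vel_slope_cap=vel_slope_cap)
    contact0 = np.linalg.norm(starts - targets, axis=1) <= r_eff
    dwell_count = contact0.astype(int)
    first_contact = np.where(contact0, 0.0, np.nan)
    t_acquire = np.full(n, np.nan)
    path_len = np.zeros(n)
    active = np.ones(n, dtype=bool)

    rec = {k: [] for k in ("p", "v", "u", "c", "e", "contact")} if record else None

    for t in range(max_steps):
        p_prev = kern.p.copy()
        kern.step(targets)
        if task.workspace_halfwidth is not None:
            kern.clamp(task.workspace_halfwidth)
        seg = np.linalg.norm(kern.p - p_prev, axis=1)
        path_len += seg * active
        dist = np.linalg.norm(kern.p - targets, axis=1)
        contact = dist <= r_eff
        dwell_count = np.where(contact, dwell_count + 1, 0)
        now = (t + 1) * dt
        newly = active & contact & np.isnan(first_contact)
        first_contact[newly] = now
        done = active & (dwell_count >= required_run)
        t_acquire[done] = now
        active &= ~done
        if record:
            for k, arr in (("p", kern.p), ("v", kern.v), ("u", kern.u),
                           ("c", kern.c), ("e", kern.e)):
                rec[k].append(arr.copy())
            rec["contact"].append(contact.copy())
        if not active.any():
            break

    success = ~np.isnan(t_acquire)
    frame = pd.DataFrame({
        "success": success,
        "t_first_contact": first_contact,
        "t_acquire": t_acquire,
        "path_length": path_len,
        "distance": np.linalg.norm(targets - starts, axis=1),
        "target_radius": np.atleast_1d(radii),
        "effective_radius": r_eff,
    })

    records = []
    if record:
        T = len(rec["p"])
        time = dt * np.arange(1, T + 1)
        for i in range(n):
            Ti = T if not success[i] else int(round(t_acquire[i] / dt))
            records.append(TrialRecord(
                time=time[:Ti],
                position=np.array([rec["p"][t][i] for t in range(Ti)]),
                velocity=np.array([rec["v"][t][i] for t in range(Ti)]),
                u=np.array([rec["u"][t][i] for t in range(Ti)]),
                c=np.array([rec["c"][t][i] for t in range(Ti)]),
                e=np.array([rec["e"][t][i] for t in range(Ti)]),
                target=np.repeat(targets[i][None, :], Ti, axis=0),
                target_radius=np.repeat(np.atleast_1d(radii)[i], Ti),
                contact=np.array([rec["contact"][t][i] for t in range(Ti)]),
                outcome="success" if success[i] else "timeout",
                t_first_contact=None if np.isnan(first_contact[i]) else float(first_contact[i]),
                t_acquire=None if np.isnan(t_acquire[i]) else float(t_acquire[i]),
                start=starts[i],
                dwell_s=task.dwell_s,
            ))
    return frame, records


def simulate_trial(user: UserModel, decoder: DecoderParams, task: TaskSpec,
                   start, target, radius: float, rng) -> TrialRecord:
    """Simulate a single target-acquisition trial and return its full record.

    ``rng`` may be an integer seed or a ``numpy.random.SeedSequence``.
    """
    if isinstance(rng, np.random.SeedSequence):
        seqs = [rng]
    else:
        seqs = [np.random.SeedSequence(int(rng))]
    start = np.asarray(start, float)
    target = np.asarray(target, float)
    _, records = _run_batch(user, decoder, task, start[None, :], target[None, :],
                            np.array([radius]), seqs, record=True)
    return records[0]


def simulate_condition(user: UserModel, decoder: DecoderParams, task: TaskSpec,
                       n_trials: int, seed: int, record: bool = False,
                       chunk: int = 4000) -> SimulatedSession:
    """Simulate ``n_trials`` independent trials under one condition.

    Targets follow the task layout chain (each trial starts at the previous
    target position with zero velocity); per-trial noise streams are derived
    by counter from ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    geom_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    starts, targets, radii = task.target_generator.generate(n_trials, geom_rng)
    seqs = _child_seeds(seed, n_trials)
    frames, records = [], []
    for lo in range(0, n_trials, chunk):
        hi = min(lo + chunk, n_trials)
        f, r = _run_batch(user, decoder, task, starts[lo:hi], targets[lo:hi],
                          radii[lo:hi], seqs[lo:hi], record=record)
        frames.append(f)
        records.extend(r)
    frame = pd.concat(frames, ignore_index=True)
    frame.insert(0, "trial", np.arange(n_trials))
    return SimulatedSession(trials=frame, user=user, decoder=decoder, task=task,
                            seed=seed, records=records)


def simulate_session_chain(user: UserModel, decoder: DecoderParams, task: TaskSpec,
                           duration_s: float, seed: int):
    """Simulate one continuous closed-loop block, as recorded online.

    Unlike :func:`simulate_condition`, the cursor state carries over across
    trials: when a target is acquired the next target appears immediately and
    the cursor keeps its position and velocity; on a timeout the cursor is
    reset to the (missed) target position.  Returns per-step arrays suitable
    for serialization and model fitting.

    Returns
    -------
    dict with keys ``time_s, position, velocity, u, c, e, target,
    target_radius, trial_id, outcomes`` (outcomes: per-trial list).
    """
    dt = decoder.dt
    n_steps = int(round(duration_s / dt))
    required_run = task.dwell_steps(dt) + 1
    max_steps = task.max_steps(dt)
    geom_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    seqs = _child_seeds(seed, 1, stream=2)

    layout = task.target_generator
    pos0 = layout.initial_start()
    kern = _StepKernel(user, decoder, 1, pos0[None, :], seqs, n_steps)

    target, radius = layout.next_target(pos0, 0, geom_rng)
    r_eff = task.effective_radius(radius)
    trial_k, dwell_count, trial_steps = 0, 0, 0

    d = decoder.dims
    out = {k: np.empty((n_steps, d)) for k in ("position", "velocity", "u", "c", "e", "target")}
    # each row logs the cursor state the decode acted on (pre-update) next
    # to the decoder output u_t computed at that step
    out["time_s"] = dt * np.arange(n_steps)
    out["target_radius"] = np.empty(n_steps)
    out["trial_id"] = np.empty(n_steps, dtype=int)
    outcomes = []

    for t in range(n_steps):
        out["position"][t] = kern.p[0]
        out["velocity"][t] = kern.v[0]
        kern.step(target[None, :])
        if task.workspace_halfwidth is not None:
            kern.clamp(task.workspace_halfwidth)
        p = kern.p[0]
        out["u"][t] = kern.u[0]
        out["c"][t] = kern.c[0]
        out["e"][t] = kern.e[0]
        out["target"][t] = target
        out["target_radius"][t] = radius
        out["trial_id"][t] = trial_k
        trial_steps += 1
        contact = np.linalg.norm(p - target) <= r_eff
        dwell_count = dwell_count + 1 if contact else 0
        acquired = dwell_count >= required_run
        timed_out = trial_steps >= max_steps
        if acquired or timed_out:
            outcomes.append("success" if acquired else "timeout")
            if timed_out and not acquired:
                # reset cursor to the missed target
                kern.p[0] = target
                kern.v[0] = 0.0
                kern.state_ring[(kern.t) % (kern.tau + 1)] = np.hstack([kern.p, kern.v])
            trial_k += 1
            target, radius = layout.next_target(target, trial_k, geom_rng)
            r_eff = task.effective_radius(radius)
            dwell_count, trial_steps = 0, 0
    return out, outcomes
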