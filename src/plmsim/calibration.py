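"""Calibration benchmark: why standard decoder calibration drifts.

A simulated neural user with linearly tuned features encodes a simple
position-error feedback policy, ``f_t = E (g_t - p_t) + eps_t``.  A velocity
Kalman filter is calibrated to predict the user's intended velocity, first
from open-loop (scripted cursor) data and then through repeated closed-loop
recalibration with ReFIT-style intention estimation (decoded velocities
rotated at the target and zeroed on it).  The steady-state filter is
re-expressed in gain/smoothing form so the effective gain (terminal speed
under a sustained unit command) and effective smoothing can be tracked
across recalibration rounds and compared against a sweep-optimal setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import TaskSpec

__all__ = ["SimulatedNeuralUser", "CalibratedDecoder", "generate_features",
           "calibrate_velocity_kf", "refit_intention", "recalibration_loop",
           "simulate_neural_block", "neural_movement_stats"]


@dataclass(frozen=True)
class SimulatedNeuralUser:
    """Linearly tuned neural features encoding the position error.

    ``tuning`` is (n_features x dims); preferred directions are spread
    uniformly on the circle (evenly spaced by construction) and scaled by
    ``modulation_depth``.  ``noise_sd`` is the per-feature i.i.d. Gaussian
    variability.
    """

    tuning: np.ndarray
    noise_sd: float

    @classmethod
    def create(cls, n_features: int = 50, modulation_depth: float = 1.0,
               noise_sd: float = 3.0, dims: int = 2) -> "SimulatedNeuralUser":
        if dims != 2:
            raise ValueError("the neural-user benchmark is 2-D")
        angles = 2 * np.pi * np.arange(n_features) / n_features
        E = modulation_depth * np.stack([np.cos(angles), np.sin(angles)], axis=1)
        return cls(tuning=E, noise_sd=float(noise_sd))

    @property
    def n_features(self) -> int:
        return self.tuning.shape[0]

    @property
    def dims(self) -> int:
        return self.tuning.shape[1]


def generate_features(user: SimulatedNeuralUser, g, p,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw f = E (g - p) + eps for a single step or an (n, d) batch."""
    err = np.asarray(g, float) - np.asarray(p, float)
    single = err.ndim == 1
    errb = np.atleast_2d(err)
    f = errb @ user.tuning.T + user.noise_sd * rng.standard_normal(
        (len(errb), user.n_features))
    return f[0] if single else f


@dataclass(frozen=True)
class CalibratedDecoder:
    """Steady-state velocity Kalman filter in gain/smoothing form.

    ``v_{t+1} = alpha_eff v_t + (1 - alpha_eff) beta_eff D f_t`` with D
    normalized so that a sustained unit-magnitude command (unit position
    error through the user's tuning) yields asymptotic speed ``beta_eff``.
    The representation is exactly equivalent to the steady-state filter
    ``v_t = a (1 - k) v_{t-1} + k y_t`` it was derived from.
    """

    D: np.ndarray
    alpha_eff: float
    beta_eff: float
    prior_a: float
    kalman_k: float


def calibrate_velocity_kf(features: np.ndarray, intended_velocities: np.ndarray,
                          tuning_for_norm: np.ndarray, prior_a: float | None = None,
                          ridge: float = 0.0) -> CalibratedDecoder:
    """Calibrate a steady-state velocity Kalman filter.

    The observation model ``f ~= H v`` is fit by least squares; observations
    are reduced to pseudo-velocities ``y = pinv(H) f = v + noise`` with an
    isotropic noise variance, and the scalar steady-state Kalman gain is
    found by iterating the Riccati recursion under a first-order velocity
    prior ``v_t = a v_{t-1} + w``.  The prior coefficient ``a`` is fit from
    the intended-velocity series itself (lag-1 regression pooled over
    dimensions), as in standard velocity-KF calibration, unless given.  The
    filter is then re-expressed in (D, alpha_eff, beta_eff) form,
    normalizing D so that ``beta_eff`` is the terminal speed under a
    sustained unit command (command measured through ``tuning_for_norm``,
    the user's true tuning).
    """
    F = np.asarray(features, float)
    V = np.asarray(intended_velocities, float)
    if len(F) != len(V) or len(F) < 30:
        raise ValueError("need >= 30 paired samples")
    d = V.shape[1]
    if prior_a is None:
        num = float(np.sum(V[1:] * V[:-1]))
        den = float(np.sum(V[:-1] ** 2))
        prior_a = min(max(num / den if den > 0 else 0.0, 0.0), 0.999)
    # observation model: F ~= V @ H.T (features are zero-mean by centering)
    Fc = F - F.mean(axis=0)
    Vc = V - V.mean(axis=0)
    G = Vc.T @ Vc
    if np.linalg.cond(G) > 1e10 or ridge > 0:
        if ridge == 0:
            ridge = 1e-8 * np.trace(G) / d
            warnings.warn("near-singular velocity covariance; ridge-regularizing",
                          stacklevel=2)
        G = G + ridge * np.eye(d)
    H = (np.linalg.solve(G, Vc.T @ Fc)).T            # (N, d)
    D0 = np.linalg.pinv(H)                            # (d, N): y = D0 f = v + noise
    resid = Fc - Vc @ H.T
    R = (resid.T @ resid) / max(len(F) - d, 1)        # feature noise cov
    Sigma_y = D0 @ R @ D0.T
    r = float(np.trace(Sigma_y)) / d                  # isotropic obs noise var

    # first-order random-walk prior matched to the intended-velocity scale
    s2 = float(np.mean(np.var(Vc, axis=0)))
    q = max((1 - prior_a**2) * s2, 1e-12)
    P = s2
    for _ in range(10000):
        P_pred = prior_a**2 * P + q
        k = P_pred / (P_pred + r)
        P_new = (1 - k) * P_pred
        if abs(P_new - P) < 1e-14 * max(P, 1.0):
            P = P_new
            break
        P = P_new
    alpha_eff = prior_a * (1 - k)
    Gmat = (k / (1 - alpha_eff)) * D0                 # v_inf = Gmat @ E s
    # terminal speed under sustained unit command, averaged over directions
    thetas = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
    speeds = np.linalg.norm(dirs @ (Gmat @ tuning_for_norm).T, axis=1)
    beta_eff = float(speeds.mean())
    D = Gmat / beta_eff
    return CalibratedDecoder(D=D, alpha_eff=float(alpha_eff), beta_eff=beta_eff,
                             prior_a=float(prior_a), kalman_k=float(k))


def refit_intention(decoded_velocities, cursor_positions, targets,
                    effective_radius, mode: str = "rotate_to_target"):
    """ReFIT-style intention estimation for recalibration.

    ``rotate_to_target``: each decoded velocity keeps its magnitude but its
    direction is replaced by the unit vector toward the target; vectors are
    zeroed when the cursor is on the target (center within the effective
    radius).  ``position_error`` returns ``g - p`` directly.
    """
    v = np.asarray(decoded_velocities, float)
    p = np.asarray(cursor_positions, float)
    g = np.asarray(targets, float)
    err = g - p
    if mode == "position_error":
        return err.copy()
    if mode != "rotate_to_target":
        raise ValueError("mode must be 'rotate_to_target' or 'position_error'")
    dist = np.linalg.norm(err, axis=1)
    on_target = dist <= np.asarray(effective_radius)
    safe = np.where(dist > 1e-12, dist, 1.0)
    dirs = err / safe[:, None]
    mags = np.linalg.norm(v, axis=1)
    out = dirs * mags[:, None]
    out[on_target] = 0.0
    return out


def _scripted_open_loop(task: TaskSpec, n_trials: int, dt: float, speed: float,
                        hold_s: float, rng: np.random.Generator):
    """Scripted cursor replay: straight constant-speed moves plus holds."""
    layout = task.target_generator
    pos = layout.initial_start()
    P, V, G = [], [], []
    for k in range(n_trials):
        target, _ = layout.next_target(pos, k, rng)
        err = target - pos
        dist = float(np.linalg.norm(err))
        direction = err / dist
        n_move = max(int(round(dist / (speed * dt))), 1)
        for _ in range(n_move):
            pos = pos + direction * speed * dt
            P.append(pos.copy()); V.append(direction * speed); G.append(target)
        pos = target.copy()
        for _ in range(int(round(hold_s / dt))):
            P.append(pos.copy()); V.append(np.zeros_like(pos)); G.append(target)
    return np.asarray(P), np.asarray(V), np.asarray(G)


def simulate_neural_block(neural_user: SimulatedNeuralUser, dec: CalibratedDecoder,
                          task: TaskSpec, duration_s: float, dt: float,
                          seed: int):
    """One continuous closed-loop block with the simple neural-policy user.

    Returns per-step (positions, cursor velocities, features, targets,
    radii) plus per-trial movement times and outcomes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    geom_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    layout = task.target_generator
    n_steps = int(round(duration_s / dt))
    required_run = task.dwell_steps(dt) + 1
    max_steps = task.max_steps(dt)

    d = neural_user.dims
    pos = layout.initial_start().astype(float)
    vel = np.zeros(d)
    target, radius = layout.next_target(pos, 0, geom_rng)
    r_eff = task.effective_radius(radius)

    P = np.empty((n_steps, d)); V = np.empty((n_steps, d))
    F = np.empty((n_steps, neural_user.n_features))
    Gt = np.empty((n_steps, d)); Rt = np.empty(n_steps)
    mts, outcomes = [], []
    trial_steps, dwell, trial_k = 0, 0, 0
    a, b, D = dec.alpha_eff, dec.beta_eff, dec.D
    # pre-draw feature noise for speed
    noise = neural_user.noise_sd * rng.standard_normal((n_steps, neural_user.n_features))
    for t in range(n_steps):
        f = (target - pos) @ neural_user.tuning.T + noise[t]
        vel = a * vel + (1 - a) * b * (D @ f)
        pos = pos + dt * vel
        P[t], V[t], F[t], Gt[t], Rt[t] = pos, vel, f, target, radius
        trial_steps += 1
        contact = np.linalg.norm(pos - target) <= r_eff
        dwell = dwell + 1 if contact else 0
        acquired = dwell >= required_run
        timed_out = trial_steps >= max_steps
        if acquired or timed_out:
            outcomes.append("success" if acquired else "timeout")
            mts.append(trial_steps * dt)
            if timed_out and not acquired:
                pos = target.copy(); vel = np.zeros(d)
            trial_k += 1
            target, radius = layout.next_target(target, trial_k, geom_rng)
            r_eff = task.effective_radius(radius)
            trial_steps, dwell = 0, 0
    return {"position": P, "velocity": V, "features": F, "target": Gt,
            "target_radius": Rt, "movement_times": mts, "outcomes": outcomes}


def neural_movement_stats(neural_user, alpha: float, beta: float, D, task,
                          duration_s: float, dt: float, seed: int):
    """Mean movement time (successes) and success rate at given settings."""
    dec = CalibratedDecoder(D=np.asarray(D), alpha_eff=float(alpha),
                            beta_eff=float(beta), prior_a=np.nan, kalman_k=np.nan)
    blk = simulate_neural_block(neural_user, dec, task, duration_s, dt, seed)
    mts = [m for m, o in zip(blk["movement_times"], blk["outcomes"]) if o == "success"]
    succ = np.mean([o == "success" for o in blk["outcomes"]]) if blk["outcomes"] else np.nan
    return (float(np.mean(mts)) if mts else np.inf), float(succ)


def sweep_optimum(neural_user: SimulatedNeuralUser, D, task: TaskSpec,
                  gain_grid, smoothing_grid, block_s: float = 60.0,
                  dt: float = 0.02, seed: int = 0,
                  min_success: float = 0.9) -> dict:
    """Exhaustive (gain, smoothing) sweep for the simple neural user.

    Uses a fixed decode matrix ``D`` (e.g. the round-0 calibration's) and
    returns the movement-time-minimizing cell among those whose success
    rate is at least ``min_success``.
    """
    best = None
    for beta in gain_grid:
        for alpha in smoothing_grid:
            mt, sr = neural_movement_stats(neural_user, float(alpha), float(beta),
                                           D, task, block_s, dt, seed)
            if sr >= min_success and (best is None or mt < best["movement_time"]):
                best = {"gain_beta": float(beta), "smoothing_alpha": float(alpha),
                        "movement_time": mt, "success_rate": sr}
    if best is None:
        raise RuntimeError("no sweep cell reached the minimum success rate")
    return best


def recalibration_loop(neural_user: SimulatedNeuralUser, task: TaskSpec,
                       n_rounds: int = 5, seed: int = 0, dt: float = 0.02,
                       block_s: float = 120.0, open_loop_speed: float = 0.5,
                       prior_a: float | None = None,
                       mode: str = "rotate_to_target",
                       return_decoders: bool = False):
    """Open-loop calibration followed by ``n_rounds`` of recalibration.

    Round 0 calibrates on scripted open-loop data (intended velocity = the
    scripted cursor velocity); each subsequent round simulates a closed-loop
    block with the previous decoder, re-estimates intention with
    :func:`refit_intention`, and recalibrates.  Returns one row per round
    with the effective smoothing/gain and closed-loop movement statistics.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    geom_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))

    P, V, G = _scripted_open_loop(task, max(int(block_s / 3.0), 20), dt,
                                  open_loop_speed, 0.5, geom_rng)
    F = generate_features(neural_user, G, P, rng)
    dec = calibrate_velocity_kf(F, V, neural_user.tuning, prior_a=prior_a)

    rows = []
    decoders = [dec]
    for rnd in range(n_rounds + 1):
        blk = simulate_neural_block(neural_user, dec, task, block_s, dt,
                                    seed=seed + 100 + rnd)
        mts = [m for m, o in zip(blk["movement_times"], blk["outcomes"])
               if o == "success"]
        rows.append({
            "round": rnd, "alpha_eff": dec.alpha_eff, "beta_eff": dec.beta_eff,
            "kalman_k": dec.kalman_k,
            "mean_movement_time": float(np.mean(mts)) if mts else np.inf,
            "success_rate": float(np.mean([o == "success" for o in blk["outcomes"]])),
        })
        if rnd == n_rounds:
            break
        r_eff = np.array([task.effective_radius(r) for r in blk["target_radius"]])
        v_int = refit_intention(blk["velocity"], blk["position"], blk["target"],
                                r_eff, mode=mode)
        dec = calibrate_velocity_kf(blk["features"], v_int, neural_user.tuning,
                                    prior_a=prior_a)
        decoders.append(dec)
    table = pd.DataFrame(rows)
    return (table, decoders) if return_decoders else table
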