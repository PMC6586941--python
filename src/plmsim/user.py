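"""The simulated iBCI user: control policy, internal state estimation, noise.

At each step the simulated user sees the cursor state ``tau`` steps in the
past (visual feedback delay) and runs a forward model -- matched exactly to
the decoder dynamics -- forward from that delayed state using efference
copies of its own recent commands::

    x_hat_t = A^tau x_{t-tau} + sum_{i=0}^{tau-1} A^i B c_{t-i-1}

From the internal estimate (p_hat, v_hat) it computes the encoded control
vector as a point-at-target push plus a speed-dependent damping term::

    c_t = dir(g - p_hat) * f_targ(||g - p_hat||) + dir(v_hat) * f_vel(||v_hat||)

Decoding error is an AR(p) Gaussian process added on top, ``u_t = c_t + e_t``,
optionally with signal-dependent innovation variance scaled by
``f_SDN(||c_t||)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .decoder import CursorState, StateSpace
from .piecewise import PiecewiseLinearFn

__all__ = [
    "ControlPolicy",
    "NoiseModel",
    "UserModel",
    "estimate_internal_state",
    "compute_control",
    "sample_noise",
]

#: magnitudes below this are treated as exactly zero when forming unit vectors
ZERO_NORM = 1e-9


@dataclass(frozen=True)
class ControlPolicy:
    """Piecewise-linear weighting functions for push and damping.

    ``f_targ`` maps distance-to-target (workspace units) to a non-negative
    control magnitude on the normalized command scale; ``f_vel`` maps the
    estimated cursor speed (units/s) to a signed damping weight, typically
    negative (damping opposes the current heading).
    """

    f_targ: PiecewiseLinearFn
    f_vel: PiecewiseLinearFn

    def __post_init__(self):
        if np.any(self.f_targ.values < 0):
            raise ValueError("f_targ values must be >= 0")


def _companion_spectral_radius(ar_coeffs: tuple, dims: int) -> float:
    p = len(ar_coeffs)
    if p == 0:
        return 0.0
    comp = np.zeros((p * dims, p * dims))
    for i, Pi in enumerate(ar_coeffs):
        comp[:dims, i * dims : (i + 1) * dims] = Pi
    if p > 1:
        comp[dims:, : (p - 1) * dims] = np.eye((p - 1) * dims)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass(frozen=True)
class NoiseModel:
    """AR(p) Gaussian decoding-noise model with optional signal dependence.

    ``e_t = Pi_1 e_{t-1} + ... + Pi_p e_{t-p} + eps_t`` with
    ``eps_t ~ N(0, f_SDN(||c_t||) * innovation_cov)``.
    """

    ar_coeffs: tuple  # tuple of (dims, dims) arrays
    innovation_cov: np.ndarray
    sdn_fn: PiecewiseLinearFn = field(
        default_factory=lambda: PiecewiseLinearFn.constant(1.0, 0.0, 1.5)
    )

    def __init__(self, ar_coeffs=(), innovation_cov=None, sdn_fn=None, dims: int = 2):
        ar_coeffs = tuple(np.asarray(P, dtype=float) for P in ar_coeffs)
        if innovation_cov is None:
            innovation_cov = np.zeros((dims, dims))
        innovation_cov = np.asarray(innovation_cov, dtype=float)
        d = innovation_cov.shape[0]
        if innovation_cov.shape != (d, d):
            raise ValueError("innovation_cov must be square")
        if not np.allclose(innovation_cov, innovation_cov.T, atol=1e-10):
            raise ValueError("innovation_cov must be symmetric")
        eigmin = float(np.min(np.linalg.eigvalsh(innovation_cov))) if d else 0.0
        if eigmin < -1e-10:
            raise ValueError("innovation_cov must be positive semidefinite")
        for P in ar_coeffs:
            if P.shape != (d, d):
                raise ValueError("AR coefficient matrices must be (dims, dims)")
        if sdn_fn is None:
            sdn_fn = PiecewiseLinearFn.constant(1.0, 0.0, 1.5)
        if np.any(sdn_fn.values < 0):
            raise ValueError("sdn_fn values must be >= 0")
        rho = _companion_spectral_radius(ar_coeffs, d)
        if rho >= 1.0:
            warnings.warn(
                f"AR noise model is non-stationary (companion spectral radius {rho:.3f} >= 1)",
                stacklevel=2,
            )
        object.__setattr__(self, "ar_coeffs", ar_coeffs)
        object.__setattr__(self, "innovation_cov", innovation_cov)
        object.__setattr__(self, "sdn_fn", sdn_fn)

    @property
    def n_lags(self) -> int:
        return len(self.ar_coeffs)

    @property
    def dims(self) -> int:
        return self.innovation_cov.shape[0]

    def chol(self) -> np.ndarray:
        """Cholesky-like factor L with L L^T = innovation_cov (PSD-safe)."""
        C = self.innovation_cov
        try:
            return np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(C)
            return V * np.sqrt(np.clip(w, 0.0, None))

    def stationary_cov(self, n_burn: int = 2000) -> np.ndarray:
        """Stationary covariance of e_t by iterating the Lyapunov recursion."""
        d = self.dims
        p = self.n_lags
        if p == 0:
            return self.innovation_cov.copy()
        # companion-form Lyapunov iteration
        F = np.zeros((p * d, p * d))
        for i, P in enumerate(self.ar_coeffs):
            F[:d, i * d : (i + 1) * d] = P
        if p > 1:
            F[d:, : (p - 1) * d] = np.eye((p - 1) * d)
        Q = np.zeros((p * d, p * d))
        Q[:d, :d] = self.innovation_cov
        S = Q.copy()
        for _ in range(n_burn):
            S_new = F @ S @ F.T + Q
            if np.allclose(S_new, S, rtol=1e-12, atol=1e-14):
                S = S_new
                break
            S = S_new
        return S[:d, :d]


@dataclass(frozen=True)
class UserModel:
    """A simulated iBCI user: policy, noise model, feedback delay (steps)."""

    policy: ControlPolicy
    noise: NoiseModel
    delay_tau: int = 10

    def __post_init__(self):
        if not (isinstance(self.delay_tau, (int, np.integer)) and self.delay_tau >= 0):
            raise ValueError("delay_tau must be an integer >= 0")

    def with_f_vel(self, f_vel: PiecewiseLinearFn) -> "UserModel":
        return replace(self, policy=ControlPolicy(self.policy.f_targ, f_vel))


def forward_model_operators(ss: StateSpace, tau: int):
    """Precompute (A^tau, [A^i B for i in 0..tau-1]) for the forward model."""
    A, B = ss.A, ss.B
    Atau = np.linalg.matrix_power(A, tau)
    AiB = []
    M = B.copy()
    for _ in range(tau):
        AiB.append(M)
        M = A @ M
    return Atau, AiB


def estimate_internal_state(state_history, control_history, tau: int, ss: StateSpace):
    """Forward-model estimate of the current cursor state.

    Parameters
    ----------
    state_history : sequence of CursorState (or stacked 2d-vectors)
        ``state_history[-1]`` is the current true state x_t; entries before
        the start of the record are padded with the first entry.
    control_history : sequence of d-vectors
        ``control_history[-1]`` is c_{t-1}; padded with zeros at startup.
    tau : int
        Feedback delay in steps.
    ss : StateSpace
        Decoder dynamics the forward model is matched to.

    Returns
    -------
    (p_hat, v_hat) : pair of d-vectors
    """
    d = ss.B.shape[1]

    def stacked(s):
        return s.stacked() if isinstance(s, CursorState) else np.asarray(s, float)

    states = [stacked(s) for s in state_history]
    if not states:
        raise ValueError("state_history must be non-empty")
    if tau == 0:
        x = states[-1]
        return x[:d], x[d:]
    # delayed state x_{t-tau}, padding with the initial state
    idx = len(states) - 1 - tau
    x_del = states[idx] if idx >= 0 else states[0]
    Atau, AiB = forward_model_operators(ss, tau)
    x_hat = Atau @ x_del
    controls = list(control_history)
    for i in range(tau):
        j = len(controls) - 1 - i  # c_{t-i-1}
        c = np.asarray(controls[j], float) if j >= 0 else np.zeros(d)
        x_hat = x_hat + AiB[i] @ c
    return x_hat[:d], x_hat[d:]


def compute_control(target, p_hat, v_hat, policy: ControlPolicy) -> np.ndarray:
    """Encoded control vector from the policy and internal state estimate."""
    target = np.asarray(target, float)
    p_hat = np.asarray(p_hat, float)
    v_hat = np.asarray(v_hat, float)
    err = target - p_hat
    dist = float(np.linalg.norm(err))
    c = np.zeros_like(err)
    if dist >= ZERO_NORM:
        c = c + (err / dist) * float(policy.f_targ(dist))
    speed = float(np.linalg.norm(v_hat))
    if speed >= ZERO_NORM:
        c = c + (v_hat / speed) * float(policy.f_vel(speed))
    return c


def sample_noise(noise: NoiseModel, e_history, c, rng: np.random.Generator) -> np.ndarray:
    """Draw the next decoding-error vector e_t.

    ``e_history[-1]`` is e_{t-1}; shorter histories are zero-padded.
    """
    d = noise.dims
    c = np.asarray(c, float)
    scale = float(noise.sdn_fn(float(np.linalg.norm(c))))
    if scale < 0:
        raise ValueError("signal-dependent noise scale must be >= 0")
    e = np.zeros(d)
    hist = list(e_history)
    for i, P in enumerate(noise.ar_coeffs):
        j = len(hist) - 1 - i
        if j >= 0:
            e = e + P @ np.asarray(hist[j], float)
    eps = noise.chol() @ rng.standard_normal(d) * np.sqrt(scale)
    return e + eps
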