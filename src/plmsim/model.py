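"""Fitting the feedback-control user model to closed-loop session data.

The estimation problem: given one block of observed cursor positions
``p_t``, velocities ``v_t``, decoder outputs ``u_t`` and target positions
``g_t`` recorded under known decoder settings, recover the user's control
policy (the piecewise-linear push and damping weightings), visual feedback
delay, and AR decoding-noise model.

The control policy and the user's internal state estimates are fit together
iteratively: estimates start as delayed true states; knot values of the
weighting functions are linear parameters (via interpolation weights) solved
by least squares against the observed ``u_t``; estimates are then recomputed
with the forward model driven by efference copies of the *modeled* control
vectors; repeat for a fixed number of iterations.  The noise model is fit to
the residuals ``e_t = u_t - c_t`` by least-squares AR regression with the
lag order chosen by blocked cross-validation, and the signal-dependent noise
scale is estimated from binned residual covariances.

The public surface follows the statsmodels convention:
``PiecewiseLinearControlModel(...).fit()`` returns :class:`PLMResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .adaptation import AdaptationConfig, adapt_damping
from .decoder import DecoderParams, build_state_space
from .engine import simulate_condition
from .metrics import METRIC_COLUMNS, metrics_frame, summarize_frame
from .piecewise import PiecewiseLinearFn
from .task import TaskSpec
from .user import ControlPolicy, NoiseModel, UserModel, forward_model_operators

__all__ = ["FitConfig", "FitReport", "fit_control_policy", "fit_noise_model",
           "fit_user_model", "predict_conditions", "bootstrap_prediction_ci",
           "PiecewiseLinearControlModel", "PLMResults"]

ZERO = 1e-9


@dataclass(frozen=True)
class FitConfig:
    """Fitting constants.

    ``delay_tau`` may be a fixed step count or the string ``"grid"`` to
    search 0..25 for the delay maximizing the final policy-fit R^2.
    """

    n_policy_iterations: int = 5
    n_f_targ_knots: int = 8
    n_f_vel_knots: int = 6
    f_targ_knots: tuple | None = None   # override abscissae
    f_vel_knots: tuple | None = None
    max_lags: int = 10
    cv_folds: int = 5
    cv_tolerance: float = 1e-3
    sdn_bins: int = 20
    sdn_range: tuple = (0.0, 1.5)
    sdn_min_samples: int = 30
    fit_sdn: bool = False
    delay_tau: int | str = 10
    tau_grid: tuple = tuple(range(0, 26))

    def __post_init__(self):
        if self.n_policy_iterations < 1:
            raise ValueError("n_policy_iterations must be >= 1")


@dataclass
class FitReport:
    """Fitted user model plus per-stage diagnostics."""

    user: UserModel
    tau: int
    policy_r2: list              # per-iteration R^2 of the policy regression
    policy_sse: list             # per-iteration training SSE
    n_lags: int
    cv_curve: list               # CV one-step R^2 for lag order 0..max tried
    innovation_cov: np.ndarray
    tau_scan: dict | None = None  # tau -> final policy R^2 (grid search only)
    estimates: np.ndarray | None = None  # (n, 2d) final internal estimates
    c_model: np.ndarray | None = None    # (n, d) modeled control series


def _hat_weights(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Clamped piecewise-linear interpolation weights: f(x) = W(x) @ values."""
    x = np.asarray(x, float)
    m = len(knots)
    idx = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, m - 2)
    span = knots[idx + 1] - knots[idx]
    t = np.clip((x - knots[idx]) / span, 0.0, 1.0)
    W = np.zeros((x.size, m))
    rows = np.arange(x.size)
    W[rows, idx] = 1.0 - t
    np.add.at(W, (rows, idx + 1), t)
    return W


def _unit(vectors: np.ndarray):
    norm = np.linalg.norm(vectors, axis=1)
    safe = np.where(norm > ZERO, norm, 1.0)
    unit = vectors / safe[:, None]
    unit[norm <= ZERO] = 0.0
    return unit, norm


def _forward_estimates(x: np.ndarray, c_model: np.ndarray, tau: int,
                       Atau: np.ndarray, AiB: list) -> np.ndarray:
    """x_hat_t = A^tau x_{t-tau} + sum_i A^i B c_{t-i-1}, padded at startup."""
    if tau == 0:
        return x.copy()
    n, d2 = x.shape
    x_del = np.vstack([np.repeat(x[:1], tau, axis=0), x[:-tau]])
    xh = x_del @ Atau.T
    d = c_model.shape[1]
    for i in range(tau):
        shift = i + 1
        c_shift = np.vstack([np.zeros((shift, d)), c_model[:-shift]])
        xh += c_shift @ AiB[i].T
    return xh


def fit_control_policy(p, v, u, g, tau: int, ss, cfg: FitConfig, valid=None):
    """Iteratively fit (f_targ, f_vel) and the internal-estimate series.

    Returns ``(policy, estimates, diagnostics)`` where ``estimates`` is the
    (n, 2d) stacked internal-state series and diagnostics carries the
    per-iteration R^2 / SSE and the modeled control series.  ``valid`` masks
    rows out of the regression (e.g. discontinuity seams in resampled data)
    while the estimate series still spans every row.
    """
    p = np.asarray(p, float); v = np.asarray(v, float)
    u = np.asarray(u, float); g = np.asarray(g, float)
    n, d = p.shape
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    vrows = np.repeat(valid, d)
    x = np.hstack([p, v])
    Atau, AiB = forward_model_operators(ss, tau)

    dist_all = np.linalg.norm(g - p, axis=1)
    targ_knots = (np.asarray(cfg.f_targ_knots, float) if cfg.f_targ_knots is not None
                  else np.linspace(0.0, float(dist_all.max()), cfg.n_f_targ_knots))
    speed_all = np.linalg.norm(v, axis=1)
    v95 = float(np.percentile(speed_all, 95))
    vel_knots = (np.asarray(cfg.f_vel_knots, float) if cfg.f_vel_knots is not None
                 else np.linspace(0.0, max(v95, 1e-6), cfg.n_f_vel_knots))

    # initialize internal estimates to delayed true states
    xh = np.vstack([np.repeat(x[:1], tau, axis=0), x[:-tau]]) if tau else x.copy()

    y = u.reshape(-1)
    sst = float(np.sum((u[valid] - u[valid].mean(axis=0)) ** 2))
    r2s, sses = [], []
    mt, mv = len(targ_knots), len(vel_knots)
    theta = None
    for _ in range(cfg.n_policy_iterations):
        ph, vh = xh[:, :d], xh[:, d:]
        dir_t, dist = _unit(g - ph)
        dir_v, spd = _unit(vh)
        Wt = _hat_weights(dist, targ_knots)
        Wv = _hat_weights(spd, vel_knots)
        # rows: (time, dim); columns: knot values of f_targ then f_vel
        Xt = (dir_t[:, :, None] * Wt[:, None, :]).reshape(n * d, mt)
        Xv = (dir_v[:, :, None] * Wv[:, None, :]).reshape(n * d, mv)
        X = np.hstack([Xt, Xv])[vrows]
        yv = y[vrows]

        col_norm = np.linalg.norm(X, axis=0)
        ident = col_norm > 1e-8 * max(col_norm.max(), 1.0)
        if not ident.all():
            warnings.warn(
                "unidentifiable policy knots (no samples nearby); tying to "
                "nearest identifiable neighbor", stacklevel=2)
        # sign-constrained least squares: push weights >= 0, damping <= 0.
        # Besides matching the policy's semantics, the sign constraint stops
        # the damping term from soaking up AR noise through the velocity
        # (decoded velocity is built from past noisy outputs, so an
        # unconstrained fit can "explain" noise with a positive f_vel).
        signs = np.concatenate([np.ones(mt), -np.ones(mv)])
        theta_full = np.zeros(mt + mv)
        sol, _ = nnls(X[:, ident] * signs[ident], yv)
        theta_full[ident] = sol * signs[ident]
        # tie dead knots to their nearest identifiable neighbor within block
        for block, lo in ((np.arange(mt), 0), (np.arange(mv), mt)):
            live = np.where(ident[lo + block])[0]
            if live.size == 0:
                continue
            for j in np.where(~ident[lo + block])[0]:
                nearest = live[np.argmin(np.abs(live - j))]
                theta_full[lo + j] = theta_full[lo + nearest]
        theta = theta_full

        resid = X @ theta - yv
        sse = float(resid @ resid)
        sses.append(sse)
        r2s.append(1.0 - sse / sst if sst > 0 else np.nan)

        # modeled control and forward-model re-estimation (efference copies)
        c_model = (dir_t * (Wt @ theta[:mt])[:, None]
                   + dir_v * (Wv @ theta[mt:])[:, None])
        xh = _forward_estimates(x, c_model, tau, Atau, AiB)

    f_targ_vals = np.clip(theta[:mt], 0.0, None)
    policy = ControlPolicy(
        f_targ=PiecewiseLinearFn(targ_knots, f_targ_vals),
        f_vel=PiecewiseLinearFn(vel_knots, theta[mt:]),
    )
    # final modeled control at the final estimates (for the residual series)
    ph, vh = xh[:, :d], xh[:, d:]
    dir_t, dist = _unit(g - ph)
    dir_v, spd = _unit(vh)
    c_final = (dir_t * policy.f_targ(dist)[:, None]
               + dir_v * policy.f_vel(spd)[:, None])
    diag = {"r2": r2s, "sse": sses, "c_model": c_final, "estimates": xh}
    return policy, xh, diag


def _ar_design(e: np.ndarray, order: int, valid=None):
    """Lagged design (X, Y, kept-target-index) for an AR(order) fit.

    Rows whose target or any lag is masked out by ``valid`` are dropped.
    """
    n, d = e.shape
    Y = e[order:]
    X = (np.hstack([e[order - i - 1: n - i - 1] for i in range(order)])
         if order else np.zeros((n - order, 0)))
    idx = np.arange(order, n)
    if valid is not None:
        keep = valid[order:].copy()
        for i in range(order):
            keep &= valid[order - i - 1: n - i - 1]
        X, Y, idx = X[keep], Y[keep], idx[keep]
    return X, Y, idx


def _fit_ar_design(X: np.ndarray, Y: np.ndarray, order: int):
    """Least-squares AR fit on a prepared design; returns (Pis, residuals)."""
    d = Y.shape[1]
    if order == 0:
        return (), Y
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)  # (order*d, d)
    Pis = tuple(coef[i * d:(i + 1) * d].T for i in range(order))
    return Pis, Y - X @ coef


def _cv_r2_design(X: np.ndarray, Y: np.ndarray, order: int, folds: int) -> float:
    """Blocked-CV one-step-ahead R^2, averaged over dimensions."""
    n = len(Y)
    edges = np.linspace(0, n, folds + 1).astype(int)
    sse = sst = 0.0
    mean = Y.mean(axis=0)
    for f in range(folds):
        lo, hi = edges[f], edges[f + 1]
        if hi <= lo:
            continue
        if order == 0:
            pred = np.zeros((hi - lo, Y.shape[1]))
        else:
            Xtr = np.vstack([X[:lo], X[hi:]])
            Ytr = np.vstack([Y[:lo], Y[hi:]])
            coef, *_ = np.linalg.lstsq(Xtr, Ytr, rcond=None)
            pred = X[lo:hi] @ coef
        sse += float(np.sum((Y[lo:hi] - pred) ** 2))
        sst += float(np.sum((Y[lo:hi] - mean) ** 2))
    return 1.0 - sse / sst if sst > 0 else 0.0


def fit_noise_model(residuals: np.ndarray, c_norms: np.ndarray | None,
                    cfg: FitConfig, valid=None) -> tuple[NoiseModel, dict]:
    """Fit the AR decoding-noise model with CV lag selection (and SDN).

    ``residuals`` is the (n, d) series e_t = u_t - c_t; ``c_norms`` the
    matching ||c_t|| series (may be None when SDN fitting is disabled).
    """
    e = np.asarray(residuals, float)
    n, d = e.shape
    if n < cfg.max_lags + 100:
        raise ValueError("need at least max_lags + 100 residual samples")
    designs = {q: _ar_design(e, q, valid) for q in range(cfg.max_lags + 1)}
    cv = [_cv_r2_design(designs[0][0], designs[0][1], 0, cfg.cv_folds)]
    order = 0
    for q in range(1, cfg.max_lags + 1):
        r2 = _cv_r2_design(designs[q][0], designs[q][1], q, cfg.cv_folds)
        cv.append(r2)
        if r2 - cv[order] > cfg.cv_tolerance:
            order = q
        else:
            break
    X, Y, idx = designs[order]
    Pis, resid = _fit_ar_design(X, Y, order)
    innovation_cov = np.cov(resid.T, ddof=1) if len(resid) > 1 else np.zeros((d, d))
    innovation_cov = np.atleast_2d(innovation_cov)

    sdn_fn = None
    sdn_scales = None
    if cfg.fit_sdn and c_norms is not None:
        lo, hi = cfg.sdn_range
        edges = np.linspace(lo, hi, cfg.sdn_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        cn = np.asarray(c_norms, float)[idx]
        which = np.clip(np.digitize(cn, edges) - 1, 0, cfg.sdn_bins - 1)
        denom = float(np.sum(innovation_cov * innovation_cov))
        scales = np.full(cfg.sdn_bins, np.nan)
        for b in range(cfg.sdn_bins):
            sel = which == b
            if sel.sum() >= cfg.sdn_min_samples:
                Sb = np.cov(resid[sel].T, ddof=1)
                scales[b] = float(np.sum(Sb * innovation_cov)) / denom if denom > 0 else 1.0
        pop = np.where(np.isfinite(scales))[0]
        if pop.size < 2:
            warnings.warn("fewer than 2 populated SDN bins; using constant scale 1",
                          stacklevel=2)
            sdn_fn = PiecewiseLinearFn.constant(1.0, lo, hi)
        else:
            for b in range(cfg.sdn_bins):
                if not np.isfinite(scales[b]):
                    scales[b] = scales[pop[np.argmin(np.abs(pop - b))]]
            scales = np.clip(scales, 0.0, None)
            sdn_fn = PiecewiseLinearFn(centers, scales)
        sdn_scales = scales
    noise = NoiseModel(ar_coeffs=Pis, innovation_cov=innovation_cov, sdn_fn=sdn_fn)
    return noise, {"cv_curve": cv, "n_lags": order, "sdn_scales": sdn_scales}


def fit_user_model(p, v, u, g, decoder: DecoderParams,
                   cfg: FitConfig | None = None, valid=None) -> FitReport:
    """Full fitting pipeline on one block of observed data."""
    cfg = cfg or FitConfig()
    p = np.asarray(p, float)
    if len(p) * decoder.dt < 60.0:
        warnings.warn("fewer than 60 s of data; fits may be poorly identified",
                      stacklevel=2)
    ss = build_state_space(decoder)

    tau_scan = None
    if cfg.delay_tau == "grid":
        tau_scan = {}
        best_tau, best_r2 = None, -np.inf
        for tau in cfg.tau_grid:
            _, _, diag = fit_control_policy(p, v, u, g, int(tau), ss, cfg,
                                            valid=valid)
            r2 = diag["r2"][-1]
            tau_scan[int(tau)] = r2
            if r2 > best_r2 + 1e-12:
                best_tau, best_r2 = int(tau), r2
        spread = max(tau_scan.values()) - min(tau_scan.values())
        if spread < 0.01:
            warnings.warn("flat R^2 across the delay grid; choosing the "
                          "smallest delay", stacklevel=2)
            best_tau = min(tau_scan)
        tau = best_tau
    else:
        tau = int(cfg.delay_tau)

    policy, xh, diag = fit_control_policy(p, v, u, g, tau, ss, cfg, valid=valid)
    e = u - diag["c_model"]
    c_norms = np.linalg.norm(diag["c_model"], axis=1)
    noise, ndiag = fit_noise_model(e, c_norms, cfg, valid=valid)
    user = UserModel(policy=policy, noise=noise, delay_tau=tau)
    return FitReport(user=user, tau=tau, policy_r2=diag["r2"], policy_sse=diag["sse"],
                     n_lags=ndiag["n_lags"], cv_curve=ndiag["cv_curve"],
                     innovation_cov=noise.innovation_cov, tau_scan=tau_scan,
                     estimates=xh, c_model=diag["c_model"])


def predict_conditions(fitted: UserModel, conditions, n_sims: int = 1000,
                       seed: int = 0, adapt: bool = True,
                       adapt_cfg: AdaptationConfig | None = None,
                       n_boot: int = 1000):
    """Simulate each (decoder, task) condition and summarize the metrics.

    Before simulating a condition, the user's damping slope is re-optimized
    for that condition (the adaptation model); pass ``adapt=False`` to keep
    the fitted damping unchanged.  Returns a list of dicts with the adapted
    user, the metric :class:`~plmsim.metrics.ConditionSummary`, and the
    per-trial metric frame.
    """
    out = []
    for k, (dec, task) in enumerate(conditions):
        user_k = fitted
        if adapt:
            user_k = adapt_damping(fitted, dec, task, adapt_cfg,
                                   seed=int(np.random.SeedSequence(seed, spawn_key=(3, k)).generate_state(1)[0] % (2**31)))
        sess = simulate_condition(user_k, dec, task, n_sims,
                                  seed=int(np.random.SeedSequence(seed, spawn_key=(4, k)).generate_state(1)[0] % (2**31)))
        frame = metrics_frame(sess)
        out.append({"user": user_k, "summary": summarize_frame(frame, n_boot=n_boot, seed=seed + k),
                    "frame": frame, "decoder": dec, "task": task})
    return out


def bootstrap_prediction_ci(p, v, u, g, trial_ids, decoder: DecoderParams,
                            cfg: FitConfig, conditions, n_boot: int = 100,
                            n_sims: int = 200, seed: int = 0, adapt: bool = True):
    """Trial-resampling bootstrap of the condition predictions.

    Training trials are resampled with replacement, the model refit (at the
    point estimate's delay, for stability and speed), and each condition
    re-predicted; returns per-condition 2.5/97.5 percentile intervals for
    each metric mean as a list of DataFrames (rows metric, cols lo/hi).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    trial_ids = np.asarray(trial_ids)
    uniq = pd.unique(trial_ids)
    base = fit_user_model(p, v, u, g, decoder, cfg)
    cfg_fixed = replace(cfg, delay_tau=base.tau)
    rng = np.random.default_rng(seed)
    samples = {k: {m: [] for m in METRIC_COLUMNS} for k in range(len(conditions))}
    seam_pad = int(base.tau) + cfg.max_lags + 1
    for b in range(n_boot):
        pick = rng.choice(uniq, size=len(uniq), replace=True)
        segments = [np.where(trial_ids == t)[0] for t in pick]
        idx = np.concatenate(segments)
        # mask the first rows after each concatenation seam: the delayed
        # feedback and AR lags there cross a discontinuity
        valid = np.ones(len(idx), bool)
        pos = 0
        for seg in segments:
            valid[pos:pos + seam_pad] = False
            pos += len(seg)
        rep = fit_user_model(p[idx], v[idx], u[idx], g[idx], decoder, cfg_fixed,
                             valid=valid)
        preds = predict_conditions(rep.user, conditions, n_sims=n_sims,
                                   seed=seed + 1000 + b, adapt=adapt, n_boot=10)
        for k, pr in enumerate(preds):
            for m in METRIC_COLUMNS:
                samples[k][m].append(pr["summary"].mean(m))
    out = []
    for k in range(len(conditions)):
        rows = {}
        for m in METRIC_COLUMNS:
            arr = np.asarray(samples[k][m], float)
            ok = np.isfinite(arr)
            lo, hi = (np.percentile(arr[ok], [2.5, 97.5]) if ok.any() else (np.nan, np.nan))
            rows[m] = {"ci_lo": lo, "ci_hi": hi}
        out.append(pd.DataFrame(rows).T)
    return out


# ---------------------------------------------------------------------------
# statsmodels-style surface

class PiecewiseLinearControlModel:
    """Feedback-control model of closed-loop cursor data, statsmodels-style.

    Parameters
    ----------
    positions, velocities, decoder_output, targets : (n, d) arrays
        Observed per-step series from one block of closed-loop control.
    decoder : DecoderParams
        The gain/smoothing settings the block was recorded under.
    config : FitConfig, optional
    trial_ids : (n,) array, optional
        Needed only for the trial-resampling bootstrap.
    """

    def __init__(self, positions, velocities, decoder_output, targets,
                 decoder: DecoderParams, config: FitConfig | None = None,
                 trial_ids=None):
        self.p = np.asarray(positions, float)
        self.v = np.asarray(velocities, float)
        self.u = np.asarray(decoder_output, float)
        self.g = np.asarray(targets, float)
        if not (self.p.shape == self.v.shape == self.u.shape == self.g.shape):
            raise ValueError("positions, velocities, decoder_output, targets "
                             "must share one (n, d) shape")
        self.decoder = decoder
        self.config = config or FitConfig()
        self.trial_ids = None if trial_ids is None else np.asarray(trial_ids)

    @classmethod
    def from_session(cls, session, block_id=None,
                     config: FitConfig | None = None) -> "PiecewiseLinearControlModel":
        """Build the model from a Session (see :mod:`plmsim.io`)."""
        if block_id is None:
            block_id = session.block_ids()[0]
        p, v, u, g, _ = session.arrays(block_id)
        dec = session.block_decoder(block_id)
        tid = session.block_frame(block_id)["trial_id"].to_numpy()
        return cls(p, v, u, g, dec, config=config, trial_ids=tid)

    def fit(self, delay_tau=None) -> "PLMResults":
        cfg = self.config if delay_tau is None else replace(self.config, delay_tau=delay_tau)
        report = fit_user_model(self.p, self.v, self.u, self.g, self.decoder, cfg)
        return PLMResults(self, report)


class PLMResults:
    """Results of a feedback-control model fit."""

    def __init__(self, model: PiecewiseLinearControlModel, report: FitReport):
        self.model = model
        self.report = report
        self.user = report.user

    @property
    def delay_tau(self) -> int:
        return self.report.tau

    @property
    def f_vel_slope(self) -> float:
        """Origin-constrained slope of the fitted damping weighting."""
        return self.user.policy.f_vel.slope_through_origin()

    @property
    def policy_r2(self) -> float:
        return self.report.policy_r2[-1]

    def predict_conditions(self, conditions, n_sims: int = 1000, seed: int = 0,
                           adapt: bool = True, adapt_cfg=None, n_boot: int = 1000):
        return predict_conditions(self.user, conditions, n_sims=n_sims, seed=seed,
                                  adapt=adapt, adapt_cfg=adapt_cfg, n_boot=n_boot)

    def bootstrap_prediction_ci(self, conditions, n_boot: int = 100,
                                n_sims: int = 200, seed: int = 0, adapt: bool = True):
        if self.model.trial_ids is None:
            raise ValueError("trial_ids are required for the trial bootstrap")
        m = self.model
        return bootstrap_prediction_ci(m.p, m.v, m.u, m.g, m.trial_ids, m.decoder,
                                       m.config, conditions, n_boot=n_boot,
                                       n_sims=n_sims, seed=seed, adapt=adapt)

    def simulate(self, task: TaskSpec, n_trials: int = 1000, seed: int = 0,
                 decoder: DecoderParams | None = None):
        return simulate_condition(self.user, decoder or self.model.decoder,
                                  task, n_trials, seed)

    def plot_policy(self, axes=None):
        """Plot the fitted push and damping weighting functions."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(8, 3))
        ft, fv = self.user.policy.f_targ, self.user.policy.f_vel
        for ax, fn, label, xlab in (
                (axes[0], ft, "f_targ", "distance to target"),
                (axes[1], fv, "f_vel", "estimated speed")):
            xs = np.linspace(fn.knots[0], fn.knots[-1], 200)
            ax.plot(xs, fn(xs))
            ax.plot(fn.knots, fn.values, "o", ms=4)
            ax.set_xlabel(xlab)
            ax.set_ylabel(label)
        return axes

    def summary(self) -> str:
        r = self.report
        lines = ["Piecewise-linear feedback control model fit",
                 "=" * 46,
                 f"observations:        {len(self.model.p)} steps "
                 f"({len(self.model.p) * self.model.decoder.dt:.1f} s, "
                 f"dt = {self.model.decoder.dt} s)",
                 f"decoder:             beta = {self.model.decoder.gain_beta:.4g}, "
                 f"alpha = {self.model.decoder.smoothing_alpha:.4g}",
                 f"feedback delay tau:  {r.tau} steps "
                 f"({r.tau * self.model.decoder.dt * 1e3:.0f} ms)"
                 + ("  [grid-searched]" if r.tau_scan else ""),
                 f"policy R^2:          " + " -> ".join(f"{x:.4f}" for x in r.policy_r2),
                 f"AR noise order:      {r.n_lags} "
                 f"(CV R^2 curve: {', '.join(f'{x:.4f}' for x in r.cv_curve)})",
                 f"innovation cov:      {np.array2string(r.innovation_cov, precision=5)}",
                 f"f_vel slope (origin-constrained): {self.f_vel_slope:.4f}",
                 "f_targ knots:        "
                 + np.array2string(self.user.policy.f_targ.knots, precision=3),
                 "f_targ values:       "
                 + np.array2string(self.user.policy.f_targ.values, precision=3)]
        return "\n".join(lines)
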