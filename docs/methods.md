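# Methods

This note documents the model, the estimation procedures, the synthetic
study conditions, and the numerical choices made where the design was open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model

**Decoder.** A linear velocity decoder with exponential smoothing,
`v_{t+1} = α v_t + (1−α) β T(u_t)`, `p_{t+1} = p_t + Δt v_{t+1}`, at
Δt = 0.02 s. The decode matrix is assumed normalized so that β is the
terminal speed under a sustained unit-magnitude command; gains can be
reported in target distances per second (TD/s). Position integrates the
*updated* velocity: the ordering is not dictated by the dynamics and this
choice makes the state-space form `x_t = A x_{t−1} + B u_t`
lower-block-triangular with consistent delay semantics. The optional static
speed transform `T` rescales the magnitude of `u_t` (never its direction)
and is applied **before** smoothing and gain, i.e. on the normalized command
scale ≈ [0, 1.5]; its piecewise variant linearly extrapolates its last
segment so there is no hard speed ceiling, whereas every other
piecewise-linear function in the package clamps at its boundary knots.

**User.** The simulated user receives the cursor state delayed by τ steps
(default 10 steps = 200 ms, a typical visuomotor delay) and estimates the
current state with a forward model matched exactly to the decoder, driven by
efference copies of its own recent commands. The control policy is a
point-at-target push weighted by `f_targ(distance)` plus a damping term
weighted by `f_vel(speed)` (non-positive: damping opposes the current
heading). When the governing magnitude is below 1e−9 the corresponding term
is the zero vector (unit vectors are undefined at zero). Decoding error is
AR(p) Gaussian, optionally with innovation covariance scaled by
`f_SDN(‖c_t‖)`.

**Task.** Targets are acquired by unbroken cursor–target contact
(center within target radius + cursor radius) for the dwell time; exceeding
the maximum trial time fails the trial and resets the cursor to the target.
Acquisition requires the dwell time to elapse *after* the first touching
sample (dwell_steps completed intervals = dwell_steps + 1 consecutive
contact samples), so that movement time decomposes exactly as
translation + dial-in + dwell, with dial-in = 0 for an unbroken acquisition.

## Simulation engine

Trials are simulated in vectorized batches: independent trials advance
synchronously, with per-trial noise streams derived by counter
(`SeedSequence(seed, spawn_key=(0, k))`) so trial k is bit-reproducible
regardless of batch size or order. Each trial's AR noise is warmed up with a
100-step burn-in at the rest-state innovation scale (`f_SDN(0)`) so `e_t`
starts near stationarity; histories before t = 0 are padded with the initial
state and zero controls. Batched trials are independent: each starts at the
previous target's nominal position with zero velocity (after a dwell the
cursor is nearly at rest, so this is a good approximation of the continuous
task). The session *chain* generator instead simulates one continuous block
in which the cursor state carries across trials — exactly how online blocks
are recorded — and this is what the synthetic-session fixture serializes.
Each logged row carries the pre-update cursor state next to the decoder
output computed from it, so fitting sees correctly aligned (state, output)
pairs. The workspace is unbounded except in keyboard simulations, where the
cursor is clamped to the key grid.

## Fitting

The policy and the internal-estimate series are fit together for five
iterations (configurable): estimates initialize to delayed true states; the
knot values of `f_targ`/`f_vel` enter linearly through interpolation
weights and are solved against the observed `u_t`; estimates are then
recomputed by the forward model using efference copies of the *modeled*
control vectors. The regression is sign-constrained (`f_targ ≥ 0`,
`f_vel ≤ 0`, solved by non-negative least squares with flipped columns).
The constraint matters: decoded velocity is built from past noisy outputs,
so an unconstrained fit can "explain" AR noise with a positive damping
weight, which biases the delay search toward τ = 0. With the constraint,
the final policy R² over a grid of delays peaks at the true delay, and the
grid search (0–25 steps) recovers it; a flat R² profile (spread < 0.01)
falls back to the smallest delay with a warning.

Knot placement is data-driven: 8 knots evenly spaced from 0 to the maximum
observed target distance for `f_targ`, 6 knots from 0 to the 95th-percentile
observed speed for `f_vel` — enough flexibility to be identifiable from
~3 minutes of data. Knots with no nearby samples are tied to their nearest
identifiable neighbor with a warning. The five-iteration scheme converges
geometrically to its fixed point; in zero-noise checks extra iterations are
used where machine-precision convergence is asserted.

The AR noise model is fit to `e_t = u_t − c_t` by least squares; the lag
order starts at 0 and increases while the blocked-cross-validated one-step
R² (5 contiguous folds — random folds would leak autocorrelation) improves
by more than 1e−3. The innovation covariance is the covariance of the AR
prediction errors. Signal-dependent noise is estimated from 20 bins of
`‖c_t‖` over [0, 1.5]; a bin needs ≥ 30 samples, sparse bins inherit the
nearest populated bin's scale, and the per-bin scale is the least-squares
Frobenius projection of the bin covariance onto the full-data covariance.
SDN fitting is off by default (the canonical synthetic user has
signal-independent noise) and enabled with `FitConfig(fit_sdn=True)`.

The trial-resampling bootstrap refits on trials resampled with replacement.
Concatenating resampled trials creates artificial discontinuities, so the
first τ + max_lags + 1 rows after each seam are masked out of both the
policy regression and the AR design (the estimate series still spans every
row).

## Adaptation

Users adapt their damping to new gain/smoothing settings. Prediction for a
held-out condition therefore replaces `f_vel` with a linear function through
the origin whose slope is chosen from a 0 to −3 grid in steps of 0.1 to
minimize mean simulated movement time at that condition (timeouts are
penalized). All 31 candidates are evaluated in a single batch sharing
per-trial targets and noise streams (common random numbers), and ties break
toward the slope nearest zero. The push weighting and the noise model are
never adapted, and no held-out data is used. The linear override is capped
at speed 2.5 β (speeds beyond that are not visited in practice).

## Synthetic study conditions

The canonical ground truth (`plmsim.presets`) defines the conditions used by
the tests and the acceptance analyses, on a workspace normalized so one
target distance = 1 unit:

| parameter | value | rationale |
|---|---|---|
| Δt | 0.02 s | 50 Hz decoder update |
| decoder | β = 1.2 units/s, α = 0.92 | mid-range gain (1.2 TD/s) and smoothing |
| task | center-out, 8 targets, radius 0.1, dwell 0.5 s, timeout 10 s | standard center-out-and-back |
| precision task | effective radius = distance/8, dwell 4 s, timeout 12 s | the stated high-precision regime |
| τ | 10 steps (200 ms) | typical visual feedback delay |
| f_targ | knots (0, 0.15, 0.4, 1.0) → (0, 0.6, 1.0, 1.0) | saturating push, full effort beyond 0.4 TD |
| f_vel | linear, slope −1.0 | damping comparable to the push at ~1 unit/s |
| noise | AR(1), Π = 0.5 I, innovation SD 0.25/dim | substantial, temporally correlated decoding noise |

With these values the decoding error's stationary RMS (≈ 0.41) is a large
fraction of the command scale, as is typical of intracortical decoders, and
movement times fall in the 1.5–4 s range. The generator emulates the
closed-loop statistics the model needs (decoder dynamics, delayed feedback,
piecewise-linear policy, AR noise with optional signal dependence); it does
**not** emulate neural features, nonstationarity within a block, learning
beyond the damping-adaptation model, or workspace boundaries. Passing tests
therefore demonstrate internal consistency and estimator correctness under
the model class, not performance on clinical recordings.

## Optimization benchmarks

**Gain × smoothing surfaces.** Every cell re-adapts the damping slope and
simulates fresh movements; the default grid is 20 log-spaced gains spanning
0.25–4× the fitted gain and 20 smoothing values 0.5–0.99. `select_params`
breaks ties toward lower gain, then higher smoothing.

**Keyboard.** A 36-key (6 × 6) dwell keyboard with key size 0.25 units —
key half-extent 0.125, matching the precision-task scale — and a dwell grid
0.1–2.0 s in 100 ms steps. The key a selection starts on is ineligible until
first exited (a dwell keyboard cannot instantly reselect the key it starts
on); dwelling on any other key selects it, wrong keys and timeouts count as
failures, and the achieved bit rate log₂(N−1)·max(correct − wrong, 0)/time
is the objective. Per-cell damping adaptation uses a circular proxy target
of the key scale (cheap, and within-cell differences dominate). Dwells this
short matter: crossing one key takes ≈ 0.17 s at typical speeds, so
sub-0.2-s dwells produce pass-through errors and the bit rate has an
interior optimum, with success rate below 1 there — the speed/accuracy
regime of interest. At larger key sizes or with the grid starting at 0.3 s
the adapted user makes no errors and the bit rate is monotone in dwell.

**Speed transform.** The exponent variant optimizes (β, α, p) jointly by
exhaustive grid search; ties prefer p closest to 1, then lower gain. The
piecewise variant fixes (β*, α*) pre-optimized for the linear decoder and
pattern-searches the 14 breakpoint ordinates (breakpoints evenly spaced
0–1.25 on the normalized command scale, i.e. 0–1.25 β in speed units): a
derivative-free coordinate search that accepts only improvements of a
common-random-number objective estimate and halves its step when no move
helps. 24 restarts are averaged pointwise; averaging can break monotonicity,
so the average is isotonically projected (PAVA) to be non-decreasing. The
objective everywhere is the mean movement time of 200 simulated movements
(timeout-penalized).

The benefit of the transform traces to the signal-independent noise floor:
with `s_out = s_in^p`, p > 1, noise-dominated commands (magnitude < 1) are
suppressed while full-effort commands are preserved, so stopping improves
without slowing travel. For a control user whose innovation variance scales
to zero at rest, the search returns p ≈ 1 and no benefit — the floor, not
the nonlinearity per se, is what the transform exploits.

## Calibration benchmark

A simulated neural user with 50 linearly tuned features (preferred
directions evenly spaced on the circle, per-feature Gaussian SD 3.0 — about
2:1 noise relative to the unit command signal) encodes the position error:
`f_t = E(g_t − p_t) + ε_t`. A steady-state velocity Kalman filter is
calibrated by (1) least-squares observation model `f ≈ H v`, (2) reduction
to pseudo-velocities `y = pinv(H) f` with isotropic observation noise
`r = tr(pinv(H) R pinv(H)ᵀ)/d`, (3) a first-order velocity prior
`v_t = a v_{t−1} + w` whose coefficient *a* is fit from the
intended-velocity series (lag-1 regression) as in standard velocity-KF
calibration, and (4) scalar Riccati iteration to the steady-state gain k.
The filter `v̂_t = a(1−k) v̂_{t−1} + k y_t` is re-expressed exactly as
gain/smoothing form with `α_eff = a(1−k)` and D normalized so that β_eff is
the terminal speed under a sustained unit command (direction-averaged).
The isotropic reduction makes the reparameterization exact by construction
(machine-precision equivalence is tested); the velocity prior not being
specified anywhere, the fitted first-order prior is the assumption.

Round 0 calibrates on scripted open-loop data (constant-speed straight
moves plus holds; intention = the scripted velocity); each later round runs
a 120-s closed-loop block with the previous decoder, re-estimates intention
by the rotate-to-target rule (decoded velocities keep their magnitude, point
at the target, and are zeroed when the cursor is within the effective
radius), and recalibrates. Two mechanisms drive the drift: rotated
magnitudes are attenuated copies of the decoder output, so each regression
shrinks the fitted velocity scale (β_eff ↓), and the intention kinematics
inherit the previous decoder's smoothness, so the fitted prior coefficient
— and with it α_eff — creeps up. With intention = the encoded control
signal `g − p` instead, the regression is exactly well-specified for this
simulated user and recalibration is statistically consistent: β_eff stays
bounded rather than drifting. That mode is implemented and tested for
stability, but the unbounded-drift demonstration uses the rotate-to-target
rule.

## Problem sizes

The test suite and acceptance script use scaled simulation sizes chosen for
statistical adequacy: 300-s sessions (15 000 steps) for fitting; 10 sessions
for recovery medians; 400 trials per condition and 60 adaptation trials per
slope for transfer; 250–400 trials per sweep cell; 150 selections per
keyboard cell on a 4 × 4 (β, α) grid over 6 dwell times; 120-s calibration
blocks; 80 trials per transform-search evaluation with a 500-trial final
comparison. Standard errors at these sizes are a few percent of the means,
comfortably inside the asserted margins.

## Known limitations

* Trials in batched prediction start at rest; very short dwell times plus
  high smoothing could make the carried-over velocity matter.
* The policy regression treats the internal-estimate series as fixed within
  each iteration; no uncertainty is propagated from it (the trial bootstrap
  covers end-to-end uncertainty instead).
* The SDN estimator assumes the AR structure is shared across bins; only
  the innovation scale varies.
* Dimensionality is generic in the decoder/user/engine (d ≥ 1), but the
  task layouts, the calibration benchmark, and all tests are 2-D.
* The keyboard adaptation proxy (circular target of key scale) approximates
  square-key dwell dynamics.
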