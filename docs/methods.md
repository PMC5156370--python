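# Methods

## Model

### Plant

Discrete-time planar point mass, time step `dt = 0.01 s`, horizon
`n = 102` steps (1.01 s of movement, matching the ~1 s reaches the task is
designed around), mass `m = 1 kg`. The 2-D control `u` drives the applied
force through a second-order muscle-like low-pass filter with time
constants `tau1 = tau2 = 0.04 s` (standard values in the LQG motor-control
literature) and unit steady-state gain. Per Cartesian axis:

    p' = p + dt v;   v' = v + dt f/m;
    f' = f + dt (g - f)/tau2;   g' = g + dt (u - g)/tau1.

The target position is appended to the state (two constant components), so
the terminal position penalty can be written as a quadratic form in the
state alone. State dimension 10, control dimension 2, observation dimension
6 (position, velocity, force).

### Noise model

* **Signal-dependent motor noise**: `B (I + F_t) u_t`, each element of the
  2x2 matrix `F_t` i.i.d. `N(0, sigma_f^2)` with `sigma_f = 0.2` — motor
  noise standard deviation 20% of the command, in the range typically used
  for reaching models. `sigma_f` may also be a 2x2 matrix of per-element
  stds (used by the sensitivity scan).
* **State-dependent sensory noise**: the observation is
  `y = H x + g_t (a + kappa d'x) + omega`, with `d'x = -v_theta` and `g_t`
  zero-mean with variance `sigma_g` on the two position channels only
  (vision informs position; velocity and force are sensed through the
  `omega` channels). The scalar scale `a - kappa v_theta` decreases with
  visibility and is clamped to zero (observer switches to the constant,
  state-independent form) above the threshold `v_theta = a/kappa`, where
  the cursor counts as fully detectable.
* **Additive noise**: dynamics noise `xi = 0` and observation noise
  `omega = 1e-12` per channel by default (the tiny floor also regularizes
  the filter inversions); both are scanned in the sensitivity analysis.
* **Internal estimation noise** `eta` (additive in the estimator update):
  variance `1e-4` (1 cm/step) on the two position-estimate channels, zero
  elsewhere.

### Cost

`Cost = x_n' Qn x_n + sum u_t' R u_t` with running state cost zero and
`R = I`. `Qn` carries three weights: `w_pos = 1e6` on the squared terminal
cursor-target error, `w_vel = 1e4` on terminal velocity, `w_force = 1e3` on
terminal force (1 : 0.01 : 0.001 ratios). Only ratios to `R` matter.

### Initial state

`x_1 ~ N(x1_nominal, Sigma_1)` with `Sigma_1` zero except a (2 cm)^2
variance per position axis, standing in for the experimental random
hand-cursor offset that forces reliance on vision; the initial estimate is
the nominal start (so the initial estimation error is exactly the unknown
offset).

## Parameter calibration

The published description of this class of task fixes the geometry, the
visibility mapping (`kappa`, `theta`) and the structural noise choices, but
not the numerical values of `a`, `sigma_g`, `eta`, or the cost weights.
These defaults were calibrated once, at design time, to place the model in
the regime where the characteristic optimal-control solutions appear, and
then frozen:

* `a = 0.2` — the full-detectability threshold sits at
  `v_theta = 0.2/kappa m/s`, *inside* the natural range of reach speeds
  (peak ~0.25 m/s). This is essential: with the alternative calibration
  `a = 1` (noise vanishing exactly where alpha saturates) the threshold is
  unreachable, the marginal value of visibility is shallow, and the optimal
  paths stay straight.
* `sigma_g = 1e-2` (std 0.1) on the position channels — rest-state
  (invisible-cursor) position feedback noise `sqrt(sigma_g) * a = 2 cm` per
  sample, i.e. proprioception-grade information about the hidden cursor.
* `eta` position-estimate drift of 1 cm/step — position knowledge decays
  unless refreshed by vision. This is the mechanism that makes *late*
  visibility specifically valuable (with no drift, early observations are
  as good as late ones and the alpha-regulation phenomenon disappears).
* `w_pos = 1e6` with `R = I` — the accuracy emphasis of a task whose
  success criterion is placing the cursor inside a sub-centimeter target.

With these defaults the model produces, without further tuning: curved
reaches whose curvature grows with the angle between movement and
visibility direction; straight reaches along the visibility direction;
overshoot-and-return for movements opposite it; across-direction alpha
variance collapsing after ~70% of the movement; and, across visibility
sensitivities, curvature and peak `v_theta` increasing as `kappa` decreases
while peak alpha stays nearly invariant.

## Solver

Coordinate descent between estimator and controller:

1. **Filter pass** (forward). The joint mean and covariance of
   `z = [x; xhat]` are propagated exactly: second moments close under
   linear dynamics with signal- and state-dependent noise, the multiplicative
   terms entering through `E[|u|^2]` and
   `E[s^2] = (a + kappa d'mu)^2 + kappa^2 d'Cov(x)d`. At each step the gain

       K_t = A Se H' (H Se H' + Omega_w + Sigma_g E[s_t^2])^-1

   minimizes the error covariance in the PSD order (hence the expected
   squared estimation error); it reduces to the classical Kalman recursion
   when the state-dependent terms vanish.
2. **Controller pass** (backward). The cost-to-go is maintained as a
   quadratic-plus-linear function of `z`; the affine sensory-noise term
   injects the linear part through `tr(S22 K Sigma_g K') * (a + kappa d'z)^2`,
   and minimizing the resulting quadratic in `u` gives the affine law
   `u = -L xhat - l`. The update is the *certainty-equivalent* one
   (the estimate is treated as conditionally unbiased): it is exact whenever
   the internal estimation noise is zero, and it keeps the feedforward
   confined to the visibility-modulated subsystem, so with `theta`
   axis-aligned the orthogonal axis is controlled by pure feedback — the
   decoupling property of the hybrid law. An opt-in `exact_blockmin`
   setting adds the estimate/error cross-covariance correction (the exact
   block minimizer given the filter); it is not the default because its
   optimum genuinely has a feedforward component in the orthogonal
   subsystem, trading the decoupling structure for a marginal cost
   improvement.
3. **Switching** between the affine and constant observation-noise forms is
   resolved per time step against the previous iterate's mean trajectory,
   keeping each iteration's subproblem linear-quadratic. Rollouts, by
   contrast, switch on the realized state (the physical cursor really is
   fully visible above threshold); this solver/simulator asymmetry is
   intentional and immaterial at default parameters, where mean speeds stay
   below the alpha saturation point.
4. **Monotonicity safeguard.** With internal noise the certainty-equivalent
   update minimizes a surrogate that can differ from the exact expected
   cost by ~1e-4 (relative) near its fixed point. Each candidate iterate is
   therefore evaluated against the exact cost (fresh moment pass); if it
   would increase it, the step is shortened geometrically along the joint
   gain-update direction until it descends, and the alternation stops when
   no shortening descends. The recorded cost history is therefore
   non-increasing by construction, and at the returned law random
   perturbation probes of (L, l) at 1e-3 relative scale find no improving
   direction on any study configuration.

Initialization is the classical additive-noise LQG solution (`l = 0`, the
filter built with the rest-state observation covariance
`Omega_w + sigma_g a^2`). Convergence: relative cost change below
`rel_tol = 1e-6`, `max_iters = 500` (typical runs converge in 3-7
iterations). All inverted matrices receive a `1e-12` diagonal damping, in
the same spirit as the `1e-12` observation-noise floor.

`expected_cost` is computed from the same exact moment propagation
(`tr(Qn Cov(x_n)) + mu_n' Qn mu_n + sum E[u'Ru]`), which is why it agrees
with Monte Carlo rollout means to sampling error.

## Simulator

Closed-loop rollouts draw, per trial: the initial position offset, then per
step the blocks `F, g, omega, eta, xi` (fixed order, always drawn and
scaled by their stds, so the random stream layout is invariant to parameter
values). Ensembles give each rollout an independent substream spawned from
one master seed and propagate all rollouts as a vectorized batch; repeated
calls are bitwise identical. `predict_mean` propagates the exact means
(zero-mean noises dropped) and equals the noiseless rollout.

## Analyses

* Paths are resampled to 300 points uniform in time; deviation
  correlations use 200 points uniform in time (the uniform-in-time choice
  mirrors the 300-point convention; uniform-in-arc-length was the
  alternative).
* Signed maximum perpendicular error (MPE): signed perpendicular distance
  of the largest-|deviation| point from the straight start-to-target line,
  counter-clockwise positive.
* Normalized time = t / movement duration; for fixed-horizon simulations
  the duration is the full horizon.
* The across-direction alpha-variance profile uses population (ddof=0)
  variance over the 12 per-direction mean alpha profiles.
* `direction_anova` is a one-way fixed-effects ANOVA
  (scipy.stats.f_oneway), applied timepoint-by-timepoint by callers; the
  degenerate all-equal case returns F = 0, p = 1. The subject-level
  averaging of the experimental analyses maps to per-direction ensemble
  means for model data.

## Sensitivity scan

24 parameters: 8 main — `a`, position `sigma_g` (std), the three cost
weights, `sigma_f`, the eta position std, `tau` — varied +-50% around their
defaults, and 16 additional zero-or-tied parameters — `xi` stds
(position/velocity/force/muscle), `omega_w` stds (position/velocity/force),
extra `eta` stds (four groups), four per-element `F_t` std factors
(+-50% around the shared `sigma_f`), and a velocity-channel `sigma_g` std —
with fixed absolute ranges (0.03 m, 0.03 m/s, 0.03 N per step for
position-, velocity- and force-related noise). Parameters are sampled
uniformly in the hypercube; for each sample the twelve movements are
re-solved (mean trajectories only, scan solver settings
`rel_tol = 1e-5, max_iters = 60`) and the across-direction sd profile of
alpha is recorded; failed solves are counted and excluded. The reference
profile for best-match (MSE) selection is supplied by the user; a synthetic
reference generated from the default model is used when none is given. The
reference analysis scale is 1e5 samples (`--full`); the package default is
a desk-scale 1000, and the aggregate profile shape is already stable at a
few hundred samples.

## Problem sizes used by the test suite

The shipped tests run the full solver on all 15 study configurations,
Monte Carlo checks at 2000 rollouts, experiment reproductions at 500
rollouts per direction, and the sensitivity scan at 200 samples — sizes
chosen so the whole suite completes in minutes while every statistical
check retains its stated resolution. The drivers default to the full
3000-rollout ensembles.

## What the synthetic data does and does not show

All inputs are generated by the model itself; there are no recorded
movements in the package. Passing tests therefore demonstrate internal
consistency (solver optimality, analytic-vs-sampled moments, metric
correctness) and that the *model* reproduces the qualitative phenomena
(curvature patterns, overshoot-return, late alpha regulation,
sensitivity-dependent curvature) — not that the model fits any particular
subject's data. Human comparisons (e.g. deviation R^2 against recorded
trajectories) are supported by the analysis functions but require the
user's own data.

## Known limitations

* Linear point-mass plant: no nonlinear two-joint arm dynamics, and the
  clean feedback/feedforward decoupling is specific to the linear isotropic
  plant.
* The certainty-equivalent controller update is exactly optimal only when
  the internal estimation noise is zero; with it, the solver is a monotone
  descent method whose fixed point is numerically — not provably —
  stationary (probed by perturbation in the tests).
* Fixed-horizon formulation: trials do not terminate on target acquisition.
* The filter gain minimizes unweighted estimation error; a cost-weighted
  error criterion is a possible variant and was left out deliberately (the
  unweighted form reduces to the classical filter and keeps the filter
  cost-independent).
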