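# visreach

Stochastic optimal control of reaching movements when *seeing* depends on
*moving*: a linear-quadratic-Gaussian (LQG) solver extended with
signal-dependent motor noise and **state-dependent sensory noise**, together
with the velocity-dependent visibility-field task it was built for,
closed-loop Monte Carlo simulation, kinematic/visibility analyses, and a
parameter-sensitivity scan.

## The problem

In many motor tasks the quality of sensory feedback depends on the action
itself. `visreach` models a planar reaching task in which the visibility
(alpha level) of the hand cursor depends on hand velocity:

    alpha = clip(kappa * v_theta, 0, 1),      v_theta = vx cos(theta) + vy sin(theta)

where `theta` is the *visibility modulation direction* and `kappa` (s/m) the
*visibility sensitivity*. Moving along `theta` makes the cursor visible;
standing still or moving against `theta` leaves it invisible. A controller
that wants to end the reach accurately must therefore decide whether to
trade extra effort (a curved or overshooting path) for better vision — a
form of active sensing inside an optimal control problem.

## The model

The plant is a discrete-time point mass driven through a second-order
muscle-like low-pass filter, with a 10-dimensional state
`x = [p, v, f, g, p*]` (cursor position, velocity, applied force, muscle
state, target):

    x_{t+1}  = A x_t + B (I + F_t) u_t + xi_t                    (dynamics)
    y_t      = H x_t + g_t (a + kappa d'x_t) + omega_t           (observation)
    xhat_{t+1} = A xhat_t + B u_t + K_t (y_t - H xhat_t) + eta_t (estimator)
    Cost     = x_n' Q_n x_n + sum_t u_t' R u_t

`F_t` is signal-dependent motor noise (each element i.i.d. N(0, sigma_f^2)),
and the observation noise scale `a + kappa d'x = a - kappa v_theta` shrinks
as visibility grows (`d'x = -v_theta`), switching to zero — the cursor is
fully detectable — above the threshold `v_theta = a/kappa`. Because sensory
noise depends on the state and motor noise on the control, the classical
separation principle fails; the solver alternates

* a **filter pass** — exact propagation of the joint closed-loop moments of
  `(x, xhat)`, choosing each Kalman gain `K_t` to minimize the expected
  squared estimation error under the state-dependent observation
  covariance, and
* a **controller pass** — a backward sweep on a quadratic-plus-linear
  cost-to-go in `z = [x; xhat]` whose affine part (generated by the
  `a + kappa d'x` term) yields a *hybrid* law

      u_t = -L_t xhat_t - l_t

  with both feedback (`L_t`) and feedforward (`l_t`) components,

until the expected cost converges (monotone by construction; a backtracking
safeguard shortens any iterate that would raise the exact cost). In the
additive-noise limit the solver reduces exactly to textbook LQR + Kalman
recursions, and with `theta` axis-aligned the feedforward is confined to the
visibility-modulated subsystem — the orthogonal axis is pure feedback.

## Worked example

```python
import numpy as np
from visreach import make_experiment, solve, ensemble, predict_mean
from visreach.analysis import signed_mpe, path_length

# 15 cm reach from the 270-degree start toward the center,
# visibility modulated along +x (orthogonal to the movement)
config = make_experiment("exp1", kappa=1.0, theta=0.0).single(9)
law = solve(config)
print(f"converged in {law.iterations} iterations, expected cost {law.expected_cost:.2f}")

mean = predict_mean(law, config)
print(f"signed MPE of the mean path: {signed_mpe(mean.position, config.start, config.target)*100:.2f} cm")
print(f"mean path length: {path_length(mean.position)*100:.2f} cm (straight reach: 15.00 cm)")
print(f"peak visibility alpha: {mean.alpha.max():.3f} at normalized time "
      f"{mean.t[np.argmax(mean.alpha)]/mean.t[-1]:.2f}")

mc = ensemble(law, config, n=3000, seed=0)
print(f"Monte Carlo (n=3000): mean cost {mc.cost.mean():.2f}, "
      f"terminal error {np.hypot(*(mc.x[:,-1,:2]-config.target).T).mean()*100:.2f} cm")
```

prints

```
converged in 3 iterations, expected cost 401.39
signed MPE of the mean path: 4.45 cm
mean path length: 18.10 cm (straight reach: 15.00 cm)
peak visibility alpha: 0.171 at normalized time 0.78
Monte Carlo (n=3000): mean cost 402.32, terminal error 0.36 cm
```

Instead of reaching straight (which would keep the cursor invisible,
`v_theta = 0`), the optimal movement bows 4.5 cm away from the straight
line so that the late phase of the reach carries a positive `v_theta`: the
cursor lights up just before arrival (peak alpha at 78% of movement time),
when fresh position information matters most. The analytic expected cost
agrees with the Monte Carlo mean.

Higher-level drivers reproduce the full simulated experiments:

```python
from visreach import run_experiment1, run_experiment2, sensitivity_scan
res1 = run_experiment1(n_rollouts=3000, seed=0)   # 12 directions + metrics
res2 = run_experiment2(seed=0)                    # kappa in {1.25, 1.0, 0.85}
```

`res1.metrics` tabulates path length, signed maximum perpendicular error,
velocity/alpha peaks per direction; `res1.variance_profile` shows the
across-direction variance of alpha collapsing in the last third of the
movement (the signature of late-visibility regulation). `res2.metrics`
shows curvature and peak `v_theta` increasing as `kappa` decreases while
peak alpha stays nearly constant.

A CLI mirrors these drivers:

```sh
visreach simulate --seed 1 --direction 9 --out out/
visreach exp1 --n-rollouts 3000 --out out_exp1/
visreach sensitivity --n-samples 1000 --out out_scan/
```

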