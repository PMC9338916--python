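# Methods

## Model

The package solves and fits the one-compartment extravascular
Michaelis–Menten model in amounts:

    dy1/dt = -ka * y1                         y1(0) = D
    dy2/dt =  ka * y1 - Vmax*C/(Km + C)       y2(0) = 0,   C = y2/V

with `ka` (/h) the first-order absorption rate constant, `V` (L) the
apparent volume, `Vmax` (mg/h) the maximum elimination velocity, `Km`
(mg/L) the concentration at half-maximal elimination, and `D` (mg) a
single oral dose at t = 0.  The nominal configuration is
ka = 1, V = 1, Vmax = 0.2, Km = 0.5, D = 3, with 13 sampling times
t = [0.1, 0.25, 0.5, 0.75, 1, 2, 4, 6, 8, 12, 16, 24, 30] h.
Units are fixed (h, mg, L, mg/L); there is no unit-conversion layer.

## Inductive linearization

The nonlinear system is solved as a fixed point of linear time-varying
(LTV) problems: iterate n replaces the concentration in the elimination
denominator with the previous iterate's series C[n-1](t), giving the
cascade

    K(c) = [[-ka, 0], [ka, -(1/V) * Vmax/(Km + c)]],

which is integrated on a step grid by freezing K per interval and
propagating with `exp(K*dt)` via eigendecomposition (scaling-and-squaring
fallback when the eigenvector matrix has condition number above 1e8 —
reachable, since the cascade is defective when ka equals the elimination
rate constant).  The cold-start plug-in is C[0] ≡ 0, making the first
iterate the constant-coefficient cascade (the Bateman solution with
k10 = Vmax/(V·Km)); tests exploit this closed form as an oracle.

The loop stops when the successive absolute relative error
`max_t |(C[n]-C[n-1])/C[n]|` falls below `epsilon` (default 1e-6), the
max taken over all grid nodes, excluding nodes where |C[n]| < 1e-12
mg/L (t = 0 always has C = 0).  Non-convergence at the iteration cap
(default n_max = 20) is a warning plus `converged=False`, not an
exception, so the estimator can continue.  On the nominal problem with
horizon T = 30 h the rule needs 15 iterations at epsilon = 1e-6; the
iterates reach an exact floating-point fixed point (successive error 0)
well before 60 iterations.  Convergence is horizon-limited in the usual
Picard sense: on T = 5 h the same tolerance needs 8 iterations.

### Where the plug-in is read (first- vs second-order stepping)

Within each interval the frozen K needs one plug-in value.  Two rules are
implemented (`plugin_eval`):

* `"left"` (default): previous iterate at the interval's left node.
  First-order in the step; at ss = 0.01 the converged solution is within
  ~1.3e-3 relative of a tight RK solution, at ss = 0.1 within ~1.2e-2.
* `"midpoint"`: mean of the two node values.  Second-order; ~1.3e-5 at
  ss = 0.01.

The left rule is the default because the package's simulation-estimation
behaviour is meant to exhibit the coarse-step estimation bias and the
tolerance-dependent OFV inflation that motivate the adaptive grid and the
stopping rule; with second-order stepping those effects largely vanish.
Accuracy-critical work should set `plugin_eval="midpoint"` (or a small
fixed step).  Both rules converge to the same fixed point as ss → 0 and
need the same iteration count on the nominal problem.

## Step grids

* **Fixed**: multiples of `ss` on [0, T], unioned with the requested
  output times (nodes closer than 1e-12 h merge, output values winning),
  so every output time is a node and predictions never interpolate.
* **Adaptive**: step inversely proportional to the local absolute slope,
  `ss(t) = clip(alpha/|dC*/dt|, ss_min, ss_max)` with defaults
  alpha = 0.01, ss_min = 1e-4 h, ss_max = 1 h.  The slope comes from
  central finite differences of the first (constant-coefficient) iterate
  computed on a uniform 0.01 h bootstrap grid; nodes are laid down
  cumulatively from 0 and merged with the output times.  Clipping is
  mandatory: the rule is unbounded where the profile is flat (its peak,
  and the terminal tail).  On the nominal problem the adaptive grid has
  ~340 nodes against 3001 at ss = 0.01, with steps from 0.0033 h during
  absorption to 1 h in the tail.

`alpha` is treated as a raw numeric scale in the model's units (h per
unit slope of a mg/L-per-h curve); no dimensional interpretation is
attached.

## Numerical fast path

The generic propagator batches the eigendecompositions of all interval
matrices and applies them sequentially.  For the 2×2 cascade the per-step
transition has a closed form (confluent limit handled explicitly when
|lam2 + ka| < 1e-10), and the resulting scalar linear recurrence for the
central amount is evaluated with a prefix-product scan in log space,
segmented whenever the running exponent spans more than 300 to avoid
overflow; the depot row is the exact exponential.  The fast path agrees
with the generic propagator to ~1e-12 relative (tested) and makes a full
ss = 0.01 solve ~milliseconds, which is what keeps the 300-replicate
study in minutes.

## Reference solver

An embedded Dormand–Prince RK 4(5) pair (scipy `solve_ivp`, method
`RK45`) integrates the exact nonlinear right-hand side at atol = 1e-6 mg
and rtol = 1e-3 by default.  Note the default-tolerance reference itself
carries ~1.3e-3 relative global error on the nominal problem (measured
against an rtol = 1e-10 run), so accuracy comparisons finer than ~1e-3
must tighten the reference tolerances; the test suite uses
atol = 1e-12 / rtol = 1e-10 as the truth oracle.

## Estimation

Ordinary least squares on the concentration scale,
OFV = Σ (y_i − g(θ, t_i, d))², minimised by unbounded
Levenberg–Marquardt (MINPACK) over θ = (ka, V, Vmax, Km) on the natural
scale, started at the nominal means unless overridden.  Non-positive or
non-finite proposals get constant residuals of 1e6 (soft rejection).
Termination defaults: ftol = xtol = 1e-8, max 400 evaluations.

**Smart update.** With `smart_update=True` the linearization of each
objective evaluation starts from the previous evaluation's converged
concentration series (linearly interpolated in time onto the new grid —
adaptive grids change with θ) instead of from zeros; the first evaluation
is always cold.  By default the finite-difference Jacobian probes share
and refresh the same cache.  That sharing makes g(θ) history-dependent at
O(epsilon), and since the FD step is ~1e-8·θ, derivative noise is of
order epsilon/1e-8 — at epsilon = 1e-6 the Jacobians are visibly noisy,
which inflates the fitted OFV scatter of the linearization variants
relative to the reference fits (and is why tightening epsilon shrinks
that gap).  `exempt_jacobian_probes=True` computes forward-difference
Jacobians with the cache frozen at the accepted point, restoring a
deterministic objective; mechanism tests (smart vs cold equivalence) use
that switch with epsilon = 1e-9, where the two fits agree to <1e-3 and
the warm start still saves most linearization iterations.

## Simulation–estimation study

Per replicate: θ_i = θ̄·exp(η), η ~ N(0, ω² = 0.1) i.i.d. per parameter;
one dataset y = g(θ_i, t)·exp(ε), ε ~ N(0, σ² = 0.1²), simulated with the
reference solver (predictions floored at 1e-10 mg/L: deep-tail RK output
of fast-eliminating individuals can undershoot zero within the absolute
tolerance); every configured variant fits the same dataset (paired
design).  RelDiff = 100·(θ̂ − θ_i)/θ_i uses the individual's own true
parameters as denominator (switchable design choice; the population means
are the obvious alternative).  Reproducibility: replicate i draws from a
child stream seeded by (seed, i), so the variant list and replicate count
can change without altering earlier replicates.  Summaries use sample
(n−1) SDs; failed fits are excluded with counts reported.  Runtimes are
recorded but never asserted (hardware-dependent).

The study size used by the acceptance script and heavy tests is 300
replicates (tolerance study: 100 paired replicates), chosen to put the
Monte-Carlo standard error of the mean OFV near 0.014 (mg/L)² while
keeping a full run in minutes on one core.

### What the generator does and does not emulate

It reproduces single-subject datasets with lognormal between-subject and
residual variability on a fixed design — no variability in dose or
sampling times, no censoring/LLOQ, no covariates, no population
(mixed-effects) structure.  Passing tests therefore speak to solver and
estimator behaviour under the stated error model, not to robustness
against model misspecification or real assay features.

## Degenerate inputs and tie-breaks

* `bateman` raises on ka = k10 rather than switching to the confluent
  formula (oracle-only code path); the integrator itself handles the
  confluent cascade via the explicit limit.
* Duplicate output times merge to one node; requesting a non-node time
  raises (it signals a grid bug, interpolation would hide it).
* An all-zero bootstrap slope requires a finite ss_max.
* Estimation datasets require strictly positive concentrations (the
  lognormal error model's support) and at least 4 points.

## Known limitations

* Single dose at t = 0 only; no infusions, multiple dosing or
  multi-compartment distribution.
* The left-endpoint default trades accuracy for fidelity to the
  coarse-step phenomenology (see above); it is first-order.
* Weighted/likelihood estimation, standard errors, and population
  analysis are out of scope.
* Km and Vmax are practically unidentifiable from single-subject data
  when the profile stays in the linear range (C << Km); the LM search
  then runs them jointly large with a stable ratio.  Such fits are kept
  (their OFV is fine) and dominate the RelDiff tails for those two
  parameters.
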