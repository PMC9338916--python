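# indlin

Inductive linearization for nonlinear pharmacokinetic ODEs, applied to the
one-compartment Michaelis–Menten model with first-order absorption — a
solver, a least-squares estimator, and a stochastic simulation–estimation
harness for pharmacometricians who want an LTV-based alternative to
time-stepping ODE solvers.

## The method

Saturable elimination makes the concentration ODE nonlinear:

    dC/dt = ka*D*exp(-ka*t)/V - (Vmax/V) * C/(Km + C),      C(0) = 0

Inductive linearization solves it as a fixed point of *linear
time-varying* problems: iterate n freezes the elimination coefficient at
the previous iterate's concentrations,

    dy[n]/dt = K(C[n-1](t)) y[n],
    K(c) = [[-ka, 0], [ka, -(1/V)*Vmax/(Km + c)]],

and integrates the frozen-coefficient cascade exactly on each grid
interval with eigendecomposition matrix exponentials.  The cold start
C[0] ≡ 0 makes the first iterate the Bateman function with
k10 = Vmax/(V·Km).  Three efficiency devices are built in:

* **stopping rule** — iterate until the successive relative error
  `max_t |(C[n]-C[n-1])/C[n]|` drops below a tolerance ε;
* **slope-adaptive steps** — step size `clip(α/|dC*/dt|, ss_min, ss_max)`
  from the first iterate's slope: fine during absorption, coarse in the
  tail;
* **smart update** — during Levenberg–Marquardt estimation, each objective
  evaluation restarts the linearization from the previous evaluation's
  converged prediction instead of from zeros.

An adaptive Runge–Kutta 4(5) reference solver (atol 1e-6, rtol 1e-3)
provides the benchmark solution and simulates the study datasets.
See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```
python examples/simulate_profile.py
```

prints (abridged):

```
converged: True after 15 iterations
final successive relative error: 6.685e-07

  t (h)   C indlin (mg/L)   C runge-kutta (mg/L)
   0.10          0.281191               0.281330
   1.00          1.770625               1.771487
   4.00          2.327435               2.328009
  12.00          1.148604               1.148834
  30.00          0.008407               0.008385

max relative difference vs the adaptive-RK reference: 2.66e-03
```

The 3 mg dose absorbs quickly (peak ≈ 2.33 mg/L near t = 4 h) and is
cleared by saturable elimination; the two independent solvers agree to
about the reference solver's own tolerance.  `examples/` also contains
scripts for the adaptive step grid, a single-subject fit with and without
the smart update, and a small simulation–estimation study.

The same workflows are available from the shell:

```
indlin simulate --seed 1 --out out/      # trajectory + noisy dataset CSV
indlin fit --data out/dataset.csv        # Levenberg-Marquardt OLS fit
indlin sse --reps 50 --seed 1            # simulation-estimation study
```

driven by a YAML config (defaults: ka=1 /h, V=1 L, Vmax=0.2 mg/h,
Km=0.5 mg/L, 3 mg dose, 13 sampling times over 30 h, ε=1e-6, α=0.01,
σ=0.1, ω²=0.1).

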