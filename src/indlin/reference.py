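"""Adaptive Runge–Kutta reference solution of the nonlinear system.

An embedded RK 4(5) pair (Dormand–Prince, via :func:`scipy.integrate.solve_ivp`)
integrates the exact nonlinear right-hand side at absolute tolerance 1e-6
(mg) and relative tolerance 1e-3 by default.  This is the accuracy
benchmark for the inductive-linearization solver and the simulation engine
for observed datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import DoseEvent, PKParameters, mm_rhs

__all__ = ["ReferenceConfig", "reference_solve", "reference_trajectory"]


@dataclass(frozen=True)
class ReferenceConfig:
    atol: float = 1e-6
    rtol: float = 1e-3
    dense_output: bool = False

    def __post_init__(self) -> None:
        if not (self.atol > 0 and self.rtol > 0):
            raise ValueError("tolerances must be > 0")


def reference_trajectory(
    theta: PKParameters,
    dose: DoseEvent,
    times,
    config: ReferenceConfig = ReferenceConfig(),
) -> np.ndarray:
    """Full (n_times, 2) amount trajectory at the requested times."""
    times = np.atleast_1d(np.asarray(times, float))
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    y0 = [dose.amount, 0.0]
    if times[-1] == 0.0:
        return np.array([y0])
    ka, V, Vmax, Km = theta.ka, theta.V, theta.Vmax, theta.Km

    def rhs(t, y):  # mm_rhs arithmetic without per-call validation
        c = y[1] / V
        return (-ka * y[0], ka * y[0] - Vmax * c / (Km + c))

    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])),
        y0,
        method="RK45",
        atol=config.atol,
        rtol=config.rtol,
        t_eval=times,
        dense_output=config.dense_output,
    )
    if not sol.success:
        raise RuntimeError(f"reference solver failed: {sol.message}")
    return sol.y.T


def reference_solve(
    theta: PKParameters,
    dose: DoseEvent,
    times,
    config: ReferenceConfig = ReferenceConfig(),
) -> np.ndarray:
    """Observed concentration C = y2/V (mg/L) at the requested times."""
    traj = reference_trajectory(theta, dose, times, config)
    return traj[:, 1] / theta.V
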