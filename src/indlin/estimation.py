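"""Ordinary least squares estimation with a Levenberg–Marquardt search.

The objective is the plain sum of squared concentration residuals

    OFV(theta) = sum_i (y_i - g(theta, t_i, d))**2

minimised over theta = (ka, V, Vmax, Km) on the natural scale with an
unbounded Levenberg–Marquardt search (MINPACK via
:func:`scipy.optimize.least_squares`).  The model prediction g comes from a
pluggable back-end: the adaptive-RK reference solver, or inductive
linearization with a fixed or adaptive EVD step.

The *smart update* threads a warm start through successive objective
evaluations: the first evaluation cold-starts the linearization from a
zero plug-in, every later one restarts it from the previous evaluation's
converged concentration series.  Because gradient-based search steps are
local, the warm start is usually one or two linearization iterations from
its own fixed point, which is where the speed gain comes from.  By default
the finite-difference Jacobian probes share the same cache (they read and
refresh it); ``exempt_jacobian_probes`` computes Jacobians with the cache
frozen at the accepted point instead.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .integrate import AdaptiveStepConfig
from .model import DoseEvent, MichaelisMentenSystem, PKParameters
from .reference import ReferenceConfig, reference_solve
from .solver import DivergenceError, IndLinConfig, inductive_linearize, predict_conc

__all__ = [
    "ObservedDataset",
    "EstimationConfig",
    "FitResult",
    "ofv",
    "predict",
    "fit",
    "PredictionCache",
]

#: residual magnitude returned for non-positive parameter proposals
SOFT_REJECT = 1e6


@dataclass(frozen=True)
class ObservedDataset:
    """Single-subject concentration-time observations."""

    times: np.ndarray  # h
    concentrations: np.ndarray  # mg/L
    dose: DoseEvent

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        c = np.asarray(self.concentrations, float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be matching 1-d arrays")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and positive")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive (lognormal error model)")
        if len(t) < 4:
            raise ValueError("need at least as many observations as parameters")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    @classmethod
    def from_csv(cls, path, dose: DoseEvent) -> "ObservedDataset":
        """Read a dataset CSV with columns ``time_h`` and ``conc_mg_L``."""
        df = pd.read_csv(path)
        missing = {"time_h", "conc_mg_L"} - set(df.columns)
        if missing:
            raise ValueError(f"dataset {path} is missing columns {sorted(missing)}")
        df = df.sort_values("time_h")
        return cls(df["time_h"].to_numpy(float), df["conc_mg_L"].to_numpy(float), dose)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.times, "conc_mg_L": self.concentrations}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class EstimationConfig:
    """Back-end selection and optimizer settings for one fit.

    ``backend`` is one of ``"reference"``, ``"indlin"``; for the latter,
    ``indlin`` carries the solver settings (fixed or adaptive step).
    """

    backend: str = "indlin"
    indlin: IndLinConfig = field(
        default_factory=lambda: IndLinConfig(adaptive=AdaptiveStepConfig(), ss=None)
    )
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    smart_update: bool = True
    exempt_jacobian_probes: bool = False
    theta0: PKParameters | None = None  # defaults to the nominal means
    max_nfev: int = 400
    ftol: float = 1e-8
    xtol: float = 1e-8

    def __post_init__(self) -> None:
        if self.backend not in ("reference", "indlin"):
            raise ValueError("backend must be 'reference' or 'indlin'")


@dataclass
class PredictionCache:
    """Most-recent converged concentration series, for the smart update."""

    times: np.ndarray | None = None
    concentrations: np.ndarray | None = None
    total_indlin_iterations: int = 0
    n_evaluations: int = 0
    n_warm_starts: int = 0

    @property
    def primed(self) -> bool:
        return self.times is not None


@dataclass(frozen=True)
class FitResult:
    theta_hat: PKParameters
    ofv: float
    n_function_evals: int
    success: bool
    message: str
    wall_time_s: float
    total_indlin_iterations: int
    mean_indlin_iterations: float

    def to_dict(self) -> dict:
        th = self.theta_hat
        return {
            "estimates": {"ka": th.ka, "V": th.V, "Vmax": th.Vmax, "Km": th.Km},
            "ofv": self.ofv,
            "n_function_evals": self.n_function_evals,
            "success": self.success,
            "message": self.message,
            "wall_time_s": self.wall_time_s,
            "total_indlin_iterations": self.total_indlin_iterations,
            "mean_indlin_iterations": self.mean_indlin_iterations,
        }


def ofv(observed, predicted) -> float:
    """Ordinary least squares objective: sum of squared residuals, (mg/L)^2."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape:
        raise ValueError("observed/predicted length mismatch")
    return float(np.sum((observed - predicted) ** 2))


def predict(
    theta: PKParameters,
    times,
    dose: DoseEvent,
    config: EstimationConfig,
    cache: PredictionCache | None = None,
    update_cache: bool = True,
) -> np.ndarray:
    """Model-predicted concentrations at the sampling times.

    With the smart update on and a primed cache, the linearization starts
    from the cached series instead of zeros; the cache is refreshed with
    the new converged series unless ``update_cache`` is False (frozen-cache
    Jacobian probes).
    """
    times = np.asarray(times, float)
    if config.backend == "reference":
        return reference_solve(theta, dose, times, config.reference)

    warm = None
    if cache is not None and config.smart_update and cache.primed:
        warm = (cache.times, cache.concentrations)
    T = float(times[-1])
    try:
        sol = inductive_linearize(
            MichaelisMentenSystem(),
            theta,
            dose,
            config.indlin,
            T=T,
            output_times=times,
            warm_start=warm,
        )
    except DivergenceError as exc:
        raise DivergenceError(exc.iteration, f"{exc} at theta={theta}") from exc
    if cache is not None:
        cache.total_indlin_iterations += sol.iterations
        cache.n_evaluations += 1
        if warm is not None:
            cache.n_warm_starts += 1
        if update_cache:
            cache.times = sol.grid.nodes
            cache.concentrations = sol.concentration
    return predict_conc(sol, times)


def fit(dataset: ObservedDataset, config: EstimationConfig) -> FitResult:
    """Minimise the OLS objective over (ka, V, Vmax, Km).

    Deterministic given the dataset and configuration.  Optimizer failure
    is reported in the result, never raised.
    """
    theta0 = config.theta0 or PKParameters(1.0, 1.0, 0.2, 0.5)
    y = dataset.concentrations
    times = dataset.times
    cache = PredictionCache()

    def residuals(x, update_cache=True):
        if np.any(x <= 0) or not np.all(np.isfinite(x)):
            return np.full(len(times), SOFT_REJECT)
        theta = PKParameters.from_array(x)
        try:
            g = predict(theta, times, dataset.dose, config, cache, update_cache)
        except (DivergenceError, RuntimeError):
            return np.full(len(times), SOFT_REJECT)
        return y - g

    kwargs = {}
    if config.exempt_jacobian_probes and config.backend == "indlin":

        def frozen_jac(x):
            # forward differences with the cache frozen at the accepted point
            f0 = residuals(x, update_cache=False)
            J = np.empty((len(times), len(x)))
            h = np.sqrt(np.finfo(float).eps) * np.maximum(np.abs(x), 1.0)
            for j in range(len(x)):
                xp = x.copy()
                xp[j] += h[j]
                J[:, j] = (residuals(xp, update_cache=False) - f0) / h[j]
            return J

        kwargs["jac"] = frozen_jac

    t0 = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = least_squares(
                residuals,
                theta0.as_array(),
                method="lm",
                ftol=config.ftol,
                xtol=config.xtol,
                max_nfev=config.max_nfev,
                **kwargs,
            )
            success, message, x, nfev = bool(res.success), res.message, res.x, res.nfev
            final_ofv = float(np.sum(res.fun**2))
        except Exception as exc:  # pragma: no cover - optimizer hard failure
            success, message, x, nfev = False, str(exc), theta0.as_array(), 0
            final_ofv = float("nan")
    wall = time.perf_counter() - t0

    x = np.where(np.isfinite(x) & (x > 0), x, theta0.as_array())
    n_eval = max(cache.n_evaluations, 1)
    return FitResult(
        theta_hat=PKParameters.from_array(x),
        ofv=final_ofv,
        n_function_evals=nfev,
        success=success,
        message=message,
        wall_time_s=wall,
        total_indlin_iterations=cache.total_indlin_iterations,
        mean_indlin_iterations=cache.total_indlin_iterations / n_eval,
    )
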