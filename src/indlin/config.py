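"""Run configuration: schema-validated YAML/JSON with the nominal defaults baked in.

The default configuration reproduces the worked single-dose example: a
3 mg oral dose, the nominal parameters (ka=1, V=1, Vmax=0.2, Km=0.5), the
13-point sampling design, an inductive-linearization solver with stopping
tolerance 1e-6 and adaptive EVD step (alpha=0.01), smart update on for
estimation, and sigma=0.1 / omega^2=0.1 for the simulation study — so
``simulate``, ``fit`` and ``sse`` run with no arguments.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .estimation import EstimationConfig
from .integrate import AdaptiveStepConfig
from .model import DoseEvent, PKParameters
from .reference import ReferenceConfig
from .solver import IndLinConfig

__all__ = ["RunConfig", "load_config"]

_SAMPLING = [0.1, 0.25, 0.5, 0.75, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 30.0]


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ka: float = 1.0
    V: float = 1.0
    Vmax: float = 0.2
    Km: float = 0.5


class SolverSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    backend: str = "indlin"  # "reference" | "indlin"
    epsilon: float = 1e-6
    n_max: int = 20
    use_stopping_rule: bool = True
    step_mode: str = "adaptive"  # "fixed" | "adaptive"
    ss: float = 0.01
    alpha: float = 0.01
    ss_min: float = 1e-4
    ss_max: float = 1.0
    plugin_eval: str = "left"
    ref_atol: float = 1e-6
    ref_rtol: float = 1e-3

    @model_validator(mode="after")
    def _check(self):
        if self.backend not in ("reference", "indlin"):
            raise ValueError("solver.backend must be 'reference' or 'indlin'")
        if self.step_mode not in ("fixed", "adaptive"):
            raise ValueError("solver.step_mode must be 'fixed' or 'adaptive'")
        return self


class EstimationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    smart_update: bool = True
    exempt_jacobian_probes: bool = False
    theta0: list[float] | None = None  # (ka, V, Vmax, Km); default: model section
    max_nfev: int = 400
    ftol: float = 1e-8
    xtol: float = 1e-8


class SSESection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_reps: int = 100
    omega2: float = 0.1
    sigma: float = 0.1
    seed: int = 12345
    variants: list[str] = Field(
        default_factory=lambda: ["reference", "indlin_ss_0.1", "indlin_adaptive"]
    )


class RunConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    model: ModelSection = Field(default_factory=ModelSection)
    dose_mg: float = 3.0
    sampling_times_h: list[float] = Field(default_factory=lambda: list(_SAMPLING))
    solver: SolverSection = Field(default_factory=SolverSection)
    estimation: EstimationSection = Field(default_factory=EstimationSection)
    sse: SSESection = Field(default_factory=SSESection)

    # ---- conversions to the library's domain objects ----

    def theta(self) -> PKParameters:
        m = self.model
        return PKParameters(ka=m.ka, V=m.V, Vmax=m.Vmax, Km=m.Km)

    def dose(self) -> DoseEvent:
        return DoseEvent(amount=self.dose_mg)

    def indlin_config(self) -> IndLinConfig:
        s = self.solver
        if s.step_mode == "adaptive":
            return IndLinConfig(
                epsilon=s.epsilon,
                n_max=s.n_max,
                use_stopping_rule=s.use_stopping_rule,
                ss=None,
                adaptive=AdaptiveStepConfig(alpha=s.alpha, ss_min=s.ss_min, ss_max=s.ss_max),
                plugin_eval=s.plugin_eval,
            )
        return IndLinConfig(
            epsilon=s.epsilon,
            n_max=s.n_max,
            use_stopping_rule=s.use_stopping_rule,
            ss=s.ss,
            plugin_eval=s.plugin_eval,
        )

    def reference_config(self) -> ReferenceConfig:
        return ReferenceConfig(atol=self.solver.ref_atol, rtol=self.solver.ref_rtol)

    def estimation_config(self, backend: str | None = None) -> EstimationConfig:
        e = self.estimation
        theta0 = PKParameters.from_array(e.theta0) if e.theta0 else self.theta()
        return EstimationConfig(
            backend=backend or self.solver.backend,
            indlin=self.indlin_config(),
            reference=self.reference_config(),
            smart_update=e.smart_update,
            exempt_jacobian_probes=e.exempt_jacobian_probes,
            theta0=theta0,
            max_nfev=e.max_nfev,
            ftol=e.ftol,
            xtol=e.xtol,
        )

    def sse_variants(self) -> dict[str, EstimationConfig]:
        """Named estimation configs for the simulation study."""
        out: dict[str, EstimationConfig] = {}
        for name in self.sse.variants:
            if name == "reference":
                out[name] = self.estimation_config(backend="reference")
            elif name.startswith("indlin_ss_"):
                ss = float(name.removeprefix("indlin_ss_"))
                cfg = self.estimation_config(backend="indlin")
                base = cfg.indlin
                out[name] = EstimationConfig(
                    backend="indlin",
                    indlin=IndLinConfig(
                        epsilon=base.epsilon,
                        n_max=base.n_max,
                        use_stopping_rule=base.use_stopping_rule,
                        ss=ss,
                        adaptive=None,
                        plugin_eval=base.plugin_eval,
                    ),
                    reference=cfg.reference,
                    smart_update=cfg.smart_update,
                    exempt_jacobian_probes=cfg.exempt_jacobian_probes,
                    theta0=cfg.theta0,
                    max_nfev=cfg.max_nfev,
                    ftol=cfg.ftol,
                    xtol=cfg.xtol,
                )
            elif name == "indlin_adaptive":
                cfg = self.estimation_config(backend="indlin")
                base = cfg.indlin
                out[name] = EstimationConfig(
                    backend="indlin",
                    indlin=IndLinConfig(
                        epsilon=base.epsilon,
                        n_max=base.n_max,
                        use_stopping_rule=base.use_stopping_rule,
                        ss=None,
                        adaptive=AdaptiveStepConfig(
                            alpha=self.solver.alpha,
                            ss_min=self.solver.ss_min,
                            ss_max=self.solver.ss_max,
                        ),
                        plugin_eval=base.plugin_eval,
                    ),
                    reference=cfg.reference,
                    smart_update=cfg.smart_update,
                    exempt_jacobian_probes=cfg.exempt_jacobian_probes,
                    theta0=cfg.theta0,
                    max_nfev=cfg.max_nfev,
                    ftol=cfg.ftol,
                    xtol=cfg.xtol,
                )
            else:
                raise ValueError(f"unknown SSE variant {name!r}")
        return out


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML or JSON config file; defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})
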