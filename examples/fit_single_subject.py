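"""Simulate one noisy single-subject dataset and estimate the four model
parameters by Levenberg-Marquardt least squares, with and without the
smart-update warm start.

The smart update re-enters the linearization from the previous objective
evaluation's converged prediction instead of from zeros, which cuts the
iterations each evaluation needs without changing the estimates
materially.
"""

import numpy as np

from indlin import (
    NOMINAL,
    SAMPLING_TIMES,
    DoseEvent,
    EstimationConfig,
    ObservedDataset,
    fit,
    reference_solve,
)
from dataclasses import replace

dose = DoseEvent(3.0)
rng = np.random.default_rng(7)
g = reference_solve(NOMINAL, dose, SAMPLING_TIMES)
data = ObservedDataset(SAMPLING_TIMES, g * np.exp(rng.normal(0, 0.1, 13)), dose)

smart = EstimationConfig(backend="indlin", smart_update=True)
for label, cfg in {
    "smart update": smart,
    "cold start": replace(smart, smart_update=False),
    "reference RK": EstimationConfig(backend="reference"),
}.items():
    r = fit(data, cfg)
    th = r.theta_hat
    print(
        f"{label:>13}: ka={th.ka:.3f} V={th.V:.3f} Vmax={th.Vmax:.3f} Km={th.Km:.3f} "
        f"OFV={r.ofv:.4f}  evals={r.n_function_evals} "
        f"linearization iterations={r.total_indlin_iterations}"
    )
print(f"\ntrue values: ka=1.0 V=1.0 Vmax=0.2 Km=0.5 (one noisy realisation, CV 10%)")
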