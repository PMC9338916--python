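"""A small stochastic simulation-estimation study (20 replicates).

Each replicate draws an individual with lognormal between-subject
variability (omega^2 = 0.1 per parameter), simulates 13 observations with
10% exponential residual error, and fits the same dataset with the
reference Runge-Kutta solver and two inductive-linearization variants.
The full study in the repository's acceptance script uses 300 replicates.
"""

from indlin import DoseEvent, NOMINAL, SAMPLING_TIMES, VariabilitySpec, run_sse
from indlin.config import RunConfig

result = run_sse(
    n_reps=20,
    variants=RunConfig().sse_variants(),
    spec=VariabilitySpec(omega2=0.1, sigma=0.1),
    times=SAMPLING_TIMES,
    dose=DoseEvent(3.0),
    theta_bar=NOMINAL,
    seed=42,
    progress_every=0,
)

for name, s in result.summary.items():
    rd = s["reldiff"]
    print(
        f"{name:>15}: mean OFV {s['ofv_mean']:6.3f} (sd {s['ofv_sd']:.3f})  "
        f"median RelDiff% ka={rd['ka']['median']:+6.1f} V={rd['V']['median']:+6.1f} "
        f"Vmax={rd['Vmax']['median']:+6.1f} Km={rd['Km']['median']:+6.1f}"
    )
print(
    "\nRelDiff = 100*(estimate - true)/true per parameter; the reference\n"
    "variant sets the attainable OFV level, the linearization variants sit\n"
    "slightly above it at stopping tolerance 1e-6."
)
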