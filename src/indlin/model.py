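"""Michaelis–Menten extravascular PK model in nonlinear and linearizable form.

The system tracked in amounts is a two-state cascade: a depot amount
``y1`` (mg) absorbed with first-order rate constant ``ka``, and a central
amount ``y2`` (mg) eliminated by a saturable Michaelis–Menten process
``Vmax*C/(Km + C)`` where ``C = y2/V`` is the observed concentration (mg/L).
Units throughout: hours, mg, L, mg/L.

The linearizable form replaces the concentration appearing in the
elimination denominator by a *plug-in* series from a previous iterate,
turning the system into a linear time-varying cascade with rate matrix

    K(c) = [[-ka,      0              ],
            [ ka, -(1/V)*Vmax/(Km + c)]]

which the EVD integrator propagates piecewise.  ``bateman`` provides the
closed-form solution of the constant-coefficient cascade used as a test
oracle (it is also, exactly, the first cold-start iterate with
``k10 = Vmax/(V*Km)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKParameters",
    "DoseEvent",
    "MichaelisMentenSystem",
    "mm_rhs",
    "build_K",
    "bateman",
]


@dataclass(frozen=True)
class PKParameters:
    """Michaelis–Menten model constants.

    Parameters
    ----------
    ka : float
        First-order absorption rate constant (/h).
    V : float
        Apparent volume of distribution (L).
    Vmax : float
        Maximum elimination velocity (mg/h).
    Km : float
        Michaelis–Menten constant: concentration at half-maximal
        elimination rate (mg/L).
    """

    ka: float
    V: float
    Vmax: float
    Km: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(
                f"all PK parameters must be strictly positive and finite, got {self}"
            )

    def as_array(self) -> np.ndarray:
        """Return (ka, V, Vmax, Km) as a float array."""
        return np.array([self.ka, self.V, self.Vmax, self.Km], float)

    @classmethod
    def from_array(cls, x) -> "PKParameters":
        ka, V, Vmax, Km = np.asarray(x, float)
        return cls(ka=float(ka), V=float(V), Vmax=float(Vmax), Km=float(Km))


#: Nominal parameter set used throughout the worked examples
#: (ka=1 /h, V=1 L, Vmax=0.2 mg/h, Km=0.5 mg/L).
NOMINAL = PKParameters(ka=1.0, V=1.0, Vmax=0.2, Km=0.5)

#: Standard 13-point single-dose sampling design (h).
SAMPLING_TIMES = np.array(
    [0.1, 0.25, 0.5, 0.75, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 30.0]
)


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose into the depot compartment at time zero."""

    amount: float = 3.0
    time: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.amount) or self.amount <= 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if self.time != 0.0:
            raise ValueError("only a single dose administered at t=0 is supported")


def mm_rhs(theta: PKParameters, dose: DoseEvent, t: float, state) -> np.ndarray:
    """Exact nonlinear right-hand side d(y1, y2)/dt in mg/h.

    ``dose`` fixes the initial condition only; it does not enter the rates.
    """
    state = np.asarray(state, float)
    if state.shape != (2,) or not np.all(np.isfinite(state)):
        raise ValueError(f"state must be a finite 2-vector, got {state!r}")
    y1, y2 = state
    c = y2 / theta.V
    elim = theta.Vmax * c / (theta.Km + c)
    return np.array([-theta.ka * y1, theta.ka * y1 - elim])


def build_K(theta: PKParameters, c_prev: float) -> np.ndarray:
    """Rate matrix of the linearized cascade at plug-in concentration ``c_prev``.

    Lower-triangular; eigenvalues are the diagonal
    ``(-ka, -(1/V)*Vmax/(Km + c_prev))``.
    """
    if not np.isfinite(c_prev) or c_prev < 0:
        raise ValueError(f"plug-in concentration must be >= 0, got {c_prev}")
    k22 = -(1.0 / theta.V) * theta.Vmax / (theta.Km + c_prev)
    return np.array([[-theta.ka, 0.0], [theta.ka, k22]])


def bateman(theta: PKParameters, k10: float, dose: DoseEvent, t) -> np.ndarray:
    """Closed-form concentration of the linear cascade with elimination ``k10``.

        C(t) = ka*D / (V*(ka - k10)) * (exp(-k10*t) - exp(-ka*t))

    Test oracle only.  Raises for the confluent case ``ka == k10`` rather
    than silently switching to the limit formula.
    """
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.isclose(theta.ka, k10, rtol=1e-12, atol=0.0):
        raise ValueError("bateman is degenerate at ka == k10")
    amp = theta.ka * dose.amount / (theta.V * (theta.ka - k10))
    return amp * (np.exp(-k10 * t) - np.exp(-theta.ka * t))


class MichaelisMentenSystem:
    """Linearizable form of the Michaelis–Menten cascade.

    Exposes the pieces the inductive-linearization solver needs: state
    dimension, initial state, per-interval rate matrices from a plug-in
    concentration series, and the output map ``C = y2/V``.
    """

    m = 2

    def initial_state(self, dose: DoseEvent) -> np.ndarray:
        return np.array([dose.amount, 0.0])

    def build_K(self, theta: PKParameters, c_prev: float) -> np.ndarray:
        return build_K(theta, c_prev)

    def k_sequence(self, theta: PKParameters, c_plug) -> np.ndarray:
        """Stack of rate matrices for a vector of plug-in concentrations."""
        c_plug = np.asarray(c_plug, float)
        if np.any(c_plug < -1e-12) or not np.all(np.isfinite(c_plug)):
            raise ValueError("plug-in concentrations must be finite and >= 0")
        c_plug = np.maximum(c_plug, 0.0)
        n = len(c_plug)
        K = np.zeros((n, 2, 2))
        K[:, 0, 0] = -theta.ka
        K[:, 1, 0] = theta.ka
        K[:, 1, 1] = self.elimination_eigenvalues(theta, c_plug)
        return K

    def elimination_eigenvalues(self, theta: PKParameters, c_plug) -> np.ndarray:
        """Vector of K(2,2) entries, the central-state eigenvalues (/h)."""
        c_plug = np.maximum(np.asarray(c_plug, float), 0.0)
        return -(1.0 / theta.V) * theta.Vmax / (theta.Km + c_plug)

    def output(self, theta: PKParameters, trajectory: np.ndarray) -> np.ndarray:
        """Observed concentration series from a (n_nodes, 2) state trajectory."""
        return trajectory[:, 1] / theta.V
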