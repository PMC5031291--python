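"""Canonical models of cell population dynamics.

Six models are provided, covering the common experimental readouts of a
proliferation assay:

``live`` / ``total``
    Exponential growth of the live (or live + dead) population at a net
    rate ``growth_rate`` (birth minus death, h^-1).
``live_logistic`` / ``total_logistic``
    Exponential growth damped by a carrying capacity (confluence or
    substrate depletion), i.e. the logistic equation.
``live_dead``
    Separate live and dead compartments: live cells divide at
    ``birth_rate`` and die at ``death_rate``; dead cells are cleared (or
    stop being recognized by cell-detection software) at
    ``clearance_rate``.
``live_dead_logistic``
    As ``live_dead`` with logistic damping of the birth term.

All models except ``live_dead_logistic`` have closed-form solutions and
are evaluated exactly; ``live_dead_logistic`` is integrated numerically
with an adaptive Runge-Kutta scheme.  Time is measured in hours and
trajectories are parameterized relative to the first requested time
point, so the "initial" population refers to the population at the first
observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ParameterEntry",
    "ParameterSet",
    "ModelSpec",
    "Trajectory",
    "simulate_exponential",
    "simulate_logistic",
    "simulate_live_dead",
    "simulate_live_dead_logistic",
    "model_registry",
    "get_model",
    "simulate_model",
    "doubling_time",
]

#: |birth - death + clearance| below this switches the live_dead dead-cell
#: solution to its resonant-limit branch.
DEGENERATE_RATE_TOL = 1e-12

#: Integrator tolerances for live_dead_logistic (cells are O(1e3), so an
#: absolute floor of 1e-6 cells is far below measurement resolution).
ODE_RTOL = 1e-8
ODE_ATOL = 1e-6


class InvalidInputError(ValueError):
    """Raised for inadmissible model inputs (negative rates, bad grids...)."""


class NumericalError(RuntimeError):
    """Raised when numerical integration fails."""


class UndefinedDoublingError(ValueError):
    """Raised when a doubling time is requested for a non-growing culture."""


@dataclass
class ParameterEntry:
    value: float
    unit: str = ""
    lower_bound: float = -math.inf
    upper_bound: float = math.inf


@dataclass
class ParameterSet:
    """Named, bounded model parameters.

    Recognized names: growth_rate, birth_rate, death_rate, clearance_rate
    (all 1/h); L_cap, T_cap, initial_live, initial_dead, initial_total
    (all cells).
    """

    entries: dict[str, ParameterEntry] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.entries[name].value

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def set(self, name: str, value: float, unit: str = "",
            lower: float = -math.inf, upper: float = math.inf) -> None:
        self.entries[name] = ParameterEntry(value, unit, lower, upper)

    def values(self) -> dict[str, float]:
        return {k: v.value for k, v in self.entries.items()}


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry for one growth model."""

    name: str
    observables: tuple[str, ...]
    parameter_names: tuple[str, ...]
    n_parameters: int
    description: str
    has_closed_form: bool


@dataclass
class Trajectory:
    """Model-predicted observable values on a time grid (hours)."""

    times: np.ndarray
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for name, arr in self.values.items():
            if arr.shape != self.times.shape:
                raise InvalidInputError(
                    f"observable {name!r} has {arr.size} values for "
                    f"{self.times.size} times"
                )


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidInputError("times must be a nonempty 1-D array")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    return t


def simulate_exponential(initial: float, growth_rate: float, times,
                         observable: str = "Live") -> Trajectory:
    """Exponential growth N(t) = N0 * exp(r * (t - t0)).

    The net rate ``growth_rate`` (birth minus death) may be negative for
    shrinking cultures.
    """
    t = _check_times(times)
    if initial < 0:
        raise InvalidInputError("initial population must be >= 0")
    n = initial * np.exp(growth_rate * (t - t[0]))
    return Trajectory(t, {observable: n})


def simulate_logistic(initial: float, growth_rate: float, cap: float, times,
                      observable: str = "Live") -> Trajectory:
    """Logistic growth towards a carrying capacity.

    Closed form N(t) = cap / (1 + (cap/N0 - 1) * exp(-r (t - t0))); the
    fixed points N0 = 0 and N0 = cap yield constant output.
    """
    t = _check_times(times)
    if cap <= 0:
        raise InvalidInputError("carrying capacity must be > 0")
    if initial < 0:
        raise InvalidInputError("initial population must be >= 0")
    if initial == 0:
        return Trajectory(t, {observable: np.zeros_like(t)})
    # N = cap*N0 / (N0 + (cap - N0) e^{-rt}); algebraically the textbook
    # form cap/(1 + (cap/N0 - 1) e^{-rt}) but without the catastrophic
    # cancellation when N0 >> cap
    decay = np.exp(-growth_rate * (t - t[0]))
    n = cap * initial / (initial + (cap - initial) * decay)
    return Trajectory(t, {observable: n})


def _live_dead_closed_form(t_rel, L0, D0, b, d, c):
    net = b - d
    live = L0 * np.exp(net * t_rel)
    k = net + c  # b - d + c
    if abs(k) < DEGENERATE_RATE_TOL:
        dead = D0 * np.exp(-c * t_rel) + d * L0 * t_rel * np.exp(-c * t_rel)
    else:
        dead = D0 * np.exp(-c * t_rel) + d * L0 * (
            np.exp(net * t_rel) - np.exp(-c * t_rel)
        ) / k
    return live, dead


def simulate_live_dead(initial_live: float, initial_dead: float,
                       birth_rate: float, death_rate: float,
                       clearance_rate: float, times) -> Trajectory:
    """Birth-death-clearance dynamics, evaluated in closed form.

    d[Live]/dt = (b - d) [Live];  d[Dead]/dt = d [Live] - c [Dead].
    The dead compartment is a linear ODE driven by the live exponential;
    the resonant case b - d + c = 0 is handled by its analytic limit.
    """
    t = _check_times(times)
    if min(birth_rate, death_rate, clearance_rate) < 0:
        raise InvalidInputError("birth, death and clearance rates must be >= 0")
    if min(initial_live, initial_dead) < 0:
        raise InvalidInputError("initial populations must be >= 0")
    live, dead = _live_dead_closed_form(
        t - t[0], initial_live, initial_dead, birth_rate, death_rate, clearance_rate
    )
    return Trajectory(t, {"Live": live, "Dead": dead})


def simulate_live_dead_logistic(initial_live: float, initial_dead: float,
                                birth_rate: float, death_rate: float,
                                clearance_rate: float, L_cap: float,
                                times) -> Trajectory:
    """Birth-death-clearance dynamics with logistic damping of birth.

    d[Live]/dt = b (1 - [Live]/L_cap) [Live] - d [Live];
    d[Dead]/dt = d [Live] - c [Dead].

    No closed form exists; integrated with adaptive RK45 at rtol=1e-8,
    atol=1e-6 cells.
    """
    t = _check_times(times)
    if min(birth_rate, death_rate, clearance_rate) < 0:
        raise InvalidInputError("birth, death and clearance rates must be >= 0")
    if min(initial_live, initial_dead) < 0:
        raise InvalidInputError("initial populations must be >= 0")
    if L_cap <= 0:
        raise InvalidInputError("carrying capacity must be > 0")

    b, d, c, cap = birth_rate, death_rate, clearance_rate, L_cap

    def rhs(_t, y):
        live, dead = y
        return [b * (1.0 - live / cap) * live - d * live,
                d * live - c * dead]

    t_rel = t - t[0]
    sol = solve_ivp(rhs, (t_rel[0], t_rel[-1]), [initial_live, initial_dead],
                    t_eval=t_rel, method="RK45", rtol=ODE_RTOL, atol=ODE_ATOL)
    if not sol.success:
        raise NumericalError(f"ODE integration failed: {sol.message}")
    live = np.clip(sol.y[0], 0.0, None)
    dead = np.clip(sol.y[1], 0.0, None)
    return Trajectory(t, {"Live": live, "Dead": dead})


_REGISTRY: tuple[ModelSpec, ...] = (
    ModelSpec(
        name="live",
        observables=("Live",),
        parameter_names=("growth_rate", "initial_live"),
        n_parameters=2,
        description=(
            "Exponential growth of the live cell population: the number of "
            "live cells grows (or shrinks) at a constant net rate, the "
            "difference between cell birth and death. Appropriate before "
            "confluence or nutrient limitation sets in."
        ),
        has_closed_form=True,
    ),
    ModelSpec(
        name="live_logistic",
        observables=("Live",),
        parameter_names=("growth_rate", "L_cap", "initial_live"),
        n_parameters=3,
        description=(
            "Logistic growth of the live cell population: growth slows as "
            "the culture approaches a carrying capacity, e.g. due to "
            "confluence or depletion of a growth substrate."
        ),
        has_closed_form=True,
    ),
    ModelSpec(
        name="live_dead",
        observables=("Live", "Dead"),
        parameter_names=("birth_rate", "death_rate", "clearance_rate",
                         "initial_live", "initial_dead"),
        n_parameters=5,
        description=(
            "Separate live and dead cell populations: live cells divide at "
            "a birth rate and die at a death rate; dead cells are cleared "
            "from the system (degrade, or cease to be recognized by cell "
            "detection software) at a clearance rate. 1/birth_rate is the "
            "mean time between cell divisions."
        ),
        has_closed_form=True,
    ),
    ModelSpec(
        name="live_dead_logistic",
        observables=("Live", "Dead"),
        parameter_names=("birth_rate", "death_rate", "clearance_rate",
                         "L_cap", "initial_live", "initial_dead"),
        n_parameters=6,
        description=(
            "Live and dead cell populations with logistic limitation of "
            "cell birth near a carrying capacity, combined with a constant "
            "death rate and clearance of dead cells."
        ),
        has_closed_form=False,
    ),
    ModelSpec(
        name="total",
        observables=("Total",),
        parameter_names=("growth_rate", "initial_total"),
        n_parameters=2,
        description=(
            "Exponential growth of the total (live + dead) cell count at a "
            "constant net rate."
        ),
        has_closed_form=True,
    ),
    ModelSpec(
        name="total_logistic",
        observables=("Total",),
        parameter_names=("growth_rate", "T_cap", "initial_total"),
        n_parameters=3,
        description=(
            "Logistic growth of the total (live + dead) cell count towards "
            "a carrying capacity."
        ),
        has_closed_form=True,
    ),
)


def model_registry() -> list[ModelSpec]:
    """Return the six registered growth models."""
    return list(_REGISTRY)


def get_model(name: str) -> ModelSpec:
    for spec in _REGISTRY:
        if spec.name == name:
            return spec
    raise KeyError(f"unknown model {name!r}; known: "
                   f"{[s.name for s in _REGISTRY]}")


def simulate_model(spec: ModelSpec | str, params: dict[str, float] | ParameterSet,
                   times) -> Trajectory:
    """Evaluate a registered model's trajectory from a parameter mapping."""
    if isinstance(spec, str):
        spec = get_model(spec)
    p = params.values() if isinstance(params, ParameterSet) else dict(params)
    name = spec.name
    if name == "live":
        return simulate_exponential(p["initial_live"], p["growth_rate"], times, "Live")
    if name == "total":
        return simulate_exponential(p["initial_total"], p["growth_rate"], times, "Total")
    if name == "live_logistic":
        return simulate_logistic(p["initial_live"], p["growth_rate"], p["L_cap"],
                                 times, "Live")
    if name == "total_logistic":
        return simulate_logistic(p["initial_total"], p["growth_rate"], p["T_cap"],
                                 times, "Total")
    if name == "live_dead":
        return simulate_live_dead(p["initial_live"], p["initial_dead"],
                                  p["birth_rate"], p["death_rate"],
                                  p["clearance_rate"], times)
    if name == "live_dead_logistic":
        return simulate_live_dead_logistic(p["initial_live"], p["initial_dead"],
                                           p["birth_rate"], p["death_rate"],
                                           p["clearance_rate"], p["L_cap"], times)
    raise KeyError(f"unknown model {name!r}")


def doubling_time(growth_rate: float) -> float:
    """Population doubling time ln(2)/r in hours, for r > 0."""
    if growth_rate <= 0:
        raise UndefinedDoublingError(
            "doubling time is undefined for non-positive growth rates"
        )
    return math.log(2.0) / growth_rate
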