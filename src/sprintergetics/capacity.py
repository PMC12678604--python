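"""Duration-dependent anaerobic energy availability and capacity estimation.

Even in maximal efforts an athlete cannot draw the full anaerobic store in
every race: how much alactic (ATP/PCr) and lactic (glycolytic) energy is
available depends on race duration T.

* Alactic: the average alactic power over a race follows a log-normal in T,
  ``P_al,avg(T) = (E_al,max / T) * exp(-(ln T - mu)^2 / (2 sigma^2))``
  with mu = 1.75 and sigma = 1.5, so the released energy never exceeds the
  maximal capacity ``E_al,max`` and the average power peaks near 0.6 s.
* Lactic: the released energy follows a peak-normalized bi-exponential in
  T with a 3 s onset delay, 20 s rise and 1500 s decay; the full capacity
  ``E_la,max`` is only available around T ~ 90 s.

Both models are linear in their capacity, so fitting them to per-race
energies has a closed-form least-squares solution. Lactate equivalences
convert lactic energy into expected blood-lactate accumulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .metabolic_model import (
    MEN_PARAMS,
    PathwayParams,
    _alactic_shape,
    _lactic_shape,
    biexp_peak_time,
    knorm,
)

__all__ = [
    "AlacticCapacityModel",
    "LacticCapacityModel",
    "LactateEquivalence",
    "REFERENCE_RANGES",
    "alactic_energy",
    "alactic_average_power",
    "lactic_energy",
    "lactic_peak_duration",
    "fit_alactic_capacity",
    "fit_lactic_capacity",
    "amplitude_from_energy",
    "lactate_from_energy",
    "capacity_warnings",
]

O2_ENERGY = 20.9  # J per mL O2


@dataclass(frozen=True)
class AlacticCapacityModel:
    """Log-normal availability of the alactic store as a function of duration."""

    e_al_max: float  # J kg^-1
    mu: float = 1.75  # ln-seconds
    sigma: float = 1.5  # ln-seconds

    def __post_init__(self) -> None:
        if self.e_al_max <= 0:
            raise ValueError("capacity must be positive")


@dataclass(frozen=True)
class LacticCapacityModel:
    """Bi-exponential availability of the lactic store; zero below ``onset``."""

    e_la_max: float  # J kg^-1
    k_rise: float = 20.0  # s
    k_decay: float = 1500.0  # s
    onset: float = 3.0  # s, no glycolytic energy before this duration

    def __post_init__(self) -> None:
        if self.e_la_max <= 0:
            raise ValueError("capacity must be positive")

    @property
    def k_norm2(self) -> float:
        return knorm(self.k_rise, self.k_decay)


@dataclass(frozen=True)
class LactateEquivalence:
    """Energy equivalent of 1 mmol L^-1 accumulated blood lactate."""

    o2_energy: float = O2_ENERGY  # J mL^-1
    o2_per_mm: float = 3.0  # mL O2 per kg body mass per mmol L^-1 (men)

    @property
    def energy_per_mm(self) -> float:
        return self.o2_energy * self.o2_per_mm  # J kg^-1 per mmol L^-1


# The 2.7 mL O2 kg^-1 per mmol L^-1 for women reflects their smaller lactate
# space; the energy equivalent is the product of the two constants.
LACTATE_EQUIVALENCE = {"m": LactateEquivalence(), "f": LactateEquivalence(o2_per_mm=2.7)}

# Physiological reference ranges (J kg^-1); used for warnings only, never to clamp.
REFERENCE_RANGES = {
    "alactic": {"m": (310.0, 390.0), "f": (230.0, 292.0)},
    "lactic": {"m": (940.0, 1250.0), "f": (850.0, 1130.0)},
}


def alactic_energy(T, model: AlacticCapacityModel):
    """Alactic energy (J kg^-1) released in a maximal race of duration ``T``."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("duration must be positive")
    out = model.e_al_max * np.exp(
        -((np.log(T) - model.mu) ** 2) / (2.0 * model.sigma**2)
    )
    return out if out.ndim else float(out)


def alactic_average_power(T, model: AlacticCapacityModel):
    """Average alactic power over the race; peaks at ``exp(mu - sigma^2)`` s."""
    T = np.asarray(T, dtype=float)
    out = alactic_energy(T, model) / T
    return out if out.ndim else float(out)


def lactic_energy(T, model: LacticCapacityModel):
    """Lactic energy (J kg^-1) released in a maximal race of duration ``T``."""
    T = np.asarray(T, dtype=float)
    dtb = T - model.onset
    with np.errstate(over="ignore"):
        val = (
            model.e_la_max
            * model.k_norm2
            * (1.0 - np.exp(-dtb / model.k_rise))
            * np.exp(-dtb / model.k_decay)
        )
    out = np.where(T <= model.onset, 0.0, val)
    return out if out.ndim else float(out)


def lactic_peak_duration(model: LacticCapacityModel) -> float:
    """Duration maximizing :func:`lactic_energy`: ``onset + k_rise ln(1 + k_decay/k_rise)``."""
    return model.onset + biexp_peak_time(model.k_rise, model.k_decay)


def fit_alactic_capacity(
    durations,
    energies,
    mu: float = 1.75,
    sigma: float = 1.5,
) -> AlacticCapacityModel:
    """Least-squares capacity from per-race alactic energies.

    The fit is performed on average powers (energy / duration), matching the
    log-normal average-power model; with the shape fixed it is linear in the
    capacity and solved in closed form.
    """
    T = np.asarray(durations, dtype=float)
    E = np.asarray(energies, dtype=float)
    if T.size == 0 or T.size != E.size:
        raise ValueError("need matching, non-empty durations and energies")
    if np.any(T <= 0):
        raise ValueError("durations must be positive")
    y = E / T
    m = np.exp(-((np.log(T) - mu) ** 2) / (2.0 * sigma**2)) / T
    e_max = float(np.dot(y, m) / np.dot(m, m))
    return AlacticCapacityModel(e_al_max=e_max, mu=mu, sigma=sigma)


def fit_lactic_capacity(
    durations,
    energies,
    k_rise: float = 20.0,
    k_decay: float = 1500.0,
    onset: float = 3.0,
) -> LacticCapacityModel:
    """Least-squares capacity from per-race lactic energies (closed form)."""
    T = np.asarray(durations, dtype=float)
    E = np.asarray(energies, dtype=float)
    if T.size == 0 or T.size != E.size:
        raise ValueError("need matching, non-empty durations and energies")
    if np.any(T <= onset):
        raise ValueError(f"durations must exceed the {onset} s glycolytic onset")
    ref = LacticCapacityModel(1.0, k_rise=k_rise, k_decay=k_decay, onset=onset)
    m = lactic_energy(T, ref)
    e_max = float(np.dot(E, m) / np.dot(m, m))
    return LacticCapacityModel(e_la_max=e_max, k_rise=k_rise, k_decay=k_decay, onset=onset)


def amplitude_from_energy(
    e_target: float,
    T: float,
    shape: str,
    params: PathwayParams = MEN_PARAMS,
    dt: float = 0.01,
) -> float:
    """Pathway amplitude whose power pulse integrates to ``e_target`` over ``(0, T]``.

    Both pathway pulses are linear in their amplitude, so the amplitude is
    the target energy divided by the unit-amplitude pulse integral
    (trapezoidal, on the same grid used by the energy bookkeeping).
    """
    if e_target < 0:
        raise ValueError("target energy must be non-negative")
    if T <= 0:
        raise ValueError("duration must be positive")
    if e_target == 0:
        return 0.0
    n = max(int(round(T / dt)), 2)
    t = np.linspace(0.0, T, n + 1)
    if shape == "alactic":
        unit = _alactic_shape(t, params)
    elif shape == "lactic":
        unit = _lactic_shape(t, params)
    else:
        raise ValueError("shape must be 'alactic' or 'lactic'")
    integral = float(np.trapezoid(unit, t))
    if integral <= 0:
        raise ValueError("unit pulse integral vanishes for this duration")
    return e_target / integral


def lactate_from_energy(e_la: float, sex: str = "m") -> float:
    """Blood-lactate accumulation (mmol L^-1) equivalent to a lactic energy."""
    if e_la < 0:
        raise ValueError("lactic energy must be non-negative")
    return e_la / LACTATE_EQUIVALENCE[sex].energy_per_mm


def capacity_warnings(
    alactic: AlacticCapacityModel | None = None,
    lactic: LacticCapacityModel | None = None,
    sex: str = "m",
) -> list[str]:
    """Warnings for capacities outside physiological reference ranges."""
    notes: list[str] = []
    if alactic is not None:
        lo, hi = REFERENCE_RANGES["alactic"][sex]
        if not lo <= alactic.e_al_max <= hi:
            notes.append(
                f"alactic capacity {alactic.e_al_max:.0f} J/kg outside "
                f"reference range {lo:.0f}-{hi:.0f} J/kg"
            )
    if lactic is not None:
        lo, hi = REFERENCE_RANGES["lactic"][sex]
        if not lo <= lactic.e_la_max <= hi:
            notes.append(
                f"lactic capacity {lactic.e_la_max:.0f} J/kg outside "
                f"reference range {lo:.0f}-{hi:.0f} J/kg"
            )
    return notes
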