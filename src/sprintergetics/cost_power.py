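"""Energy cost of accelerated running and instantaneous metabolic power.

Accelerated running on flat terrain is energetically equivalent to uphill
running at constant speed up the "equivalent slope" ES = a / g. Two cost
functions are offered:

``minetti2002_em``
    The gradient-cost polynomial of Minetti and colleagues for constant-speed
    slope running, multiplied by the equivalent mass EM = sqrt(ES^2 + 1).
    The polynomial was calibrated for |ES| <= 0.45; beyond that it is
    extrapolated linearly with matched slope so elite-sprint accelerations
    (ES up to ~1) remain well behaved.

``minetti_pavei``
    A closed-form cost of accelerated running valid up to a ~ 8.2 m s^-2,
    expressed directly in the forward acceleration.

Instantaneous metabolic power is cost (J kg^-1 m^-1) times velocity
(m s^-1), with an air-resistance term 0.01 v^2 added to the per-metre cost.
After the acceleration phase the per-metre cost is pinned at the
constant-speed flat-running value of 3.8 J kg^-1 m^-1, which produces a
small documented power discontinuity at the phase boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import VelocityProfile

__all__ = [
    "CostModelConfig",
    "PowerSeries",
    "equivalent_slope",
    "cost_accelerated",
    "metabolic_power",
]

STANDARD_GRAVITY = 9.81  # m s^-2

# gradient-cost polynomial coefficients, highest order first (J kg^-1 m^-1
# as a function of the dimensionless slope)
_POLY = np.array([155.4, -30.4, -43.3, 46.3, 19.5, 3.6])
_DPOLY = np.polyder(_POLY)


@dataclass(frozen=True)
class CostModelConfig:
    """Constants of the energy-cost model.

    ``es_linear_limit`` is the |ES| beyond which the gradient polynomial is
    extrapolated linearly (slope-matched); the polynomial itself was only
    calibrated on moderate slopes.
    """

    variant: str = "minetti2002_em"
    gravity: float = STANDARD_GRAVITY
    air_coeff: float = 0.01  # J s^2 kg^-1 m^-3, per-metre cost term 0.01 v^2
    flat_cost: float = 3.8  # J kg^-1 m^-1 constant-speed running, post-acceleration
    es_linear_limit: float = 0.45

    def __post_init__(self) -> None:
        if self.variant not in ("minetti2002_em", "minetti_pavei"):
            raise ValueError(f"unknown cost variant {self.variant!r}")
        if min(self.gravity, self.air_coeff, self.flat_cost, self.es_linear_limit) <= 0:
            raise ValueError("all cost-model constants must be positive")


DEFAULT_COST_CONFIG = CostModelConfig()


@dataclass(frozen=True)
class PowerSeries:
    """Metabolic power (W kg^-1) on a uniform time grid.

    ``source`` records provenance: ``"from_kinematics"`` for power derived
    from a velocity profile, ``"from_model"`` for power generated by the
    bioenergetic pathway model. ``t_discontinuity`` marks the acceleration/
    deceleration cost switch of kinematics-derived series (None when the
    series is smooth).
    """

    time_grid: np.ndarray
    power: np.ndarray
    source: str
    peak_power: float
    mean_power: float
    total_energy: float
    t_discontinuity: float | None = None

    @classmethod
    def from_samples(
        cls,
        time_grid: np.ndarray,
        power: np.ndarray,
        source: str,
        t_discontinuity: float | None = None,
    ) -> "PowerSeries":
        time_grid = np.asarray(time_grid, dtype=float)
        power = np.asarray(power, dtype=float)
        if np.any(power < -1e-12):
            raise ValueError("metabolic power must be non-negative")
        total = float(np.trapezoid(power, time_grid))
        duration = float(time_grid[-1] - time_grid[0])
        return cls(
            time_grid=time_grid,
            power=power,
            source=source,
            peak_power=float(power.max()),
            mean_power=total / duration if duration > 0 else 0.0,
            total_energy=total,
            t_discontinuity=t_discontinuity,
        )

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])


def equivalent_slope(a, gravity: float = STANDARD_GRAVITY):
    """Dimensionless equivalent slope: forward acceleration over gravity."""
    a = np.asarray(a, dtype=float)
    out = a / gravity
    return out if out.ndim else float(out)


def _gradient_cost(es: np.ndarray, limit: float) -> np.ndarray:
    """Gradient-cost polynomial with slope-matched linear wings beyond |ES|=limit."""
    es = np.asarray(es, dtype=float)
    c = np.polyval(_POLY, np.clip(es, -limit, limit))
    hi = es > limit
    lo = es < -limit
    if np.any(hi):
        c = np.where(hi, np.polyval(_POLY, limit) + np.polyval(_DPOLY, limit) * (es - limit), c)
    if np.any(lo):
        c = np.where(lo, np.polyval(_POLY, -limit) + np.polyval(_DPOLY, -limit) * (es + limit), c)
    return c


def cost_accelerated(a, config: CostModelConfig = DEFAULT_COST_CONFIG):
    """Energy cost of accelerated running (J kg^-1 m^-1), without air term."""
    a = np.asarray(a, dtype=float)
    if config.variant == "minetti_pavei":
        out = 0.102 * np.sqrt(a**2 + 96.2) * (4.03 * a + 3.6 * np.exp(-0.408 * a))
    else:
        es = a / config.gravity
        em = np.sqrt(es**2 + 1.0)
        out = _gradient_cost(es, config.es_linear_limit) * em
    return out if out.ndim else float(out)


def metabolic_power(
    profile: VelocityProfile,
    config: CostModelConfig = DEFAULT_COST_CONFIG,
) -> PowerSeries:
    """Instantaneous metabolic power along a velocity profile.

    During the acceleration phase the accelerated-running cost applies;
    after ``t_peak`` the constant flat-running cost does. Air resistance
    contributes ``air_coeff * v^2`` to the per-metre cost throughout. The
    resulting step change in power at ``t_peak`` is genuine model structure
    and is flagged on the returned series rather than smoothed.
    """
    t = profile.time_grid
    v = profile.velocity
    accel_mask = t <= profile.t_peak
    cost = np.where(
        accel_mask,
        cost_accelerated(profile.acceleration, config),
        config.flat_cost,
    )
    power = (cost + config.air_coeff * v**2) * v
    has_decel = profile.duration > profile.t_peak
    return PowerSeries.from_samples(
        t,
        power,
        source="from_kinematics",
        t_discontinuity=profile.t_peak if has_decel else None,
    )
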