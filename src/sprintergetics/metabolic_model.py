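"""Three-pathway decomposition of sprint metabolic power.

Total metabolic power is modelled as the sum of three independent
contributions:

* aerobic: exponential rise to MAP - BMR with time constant ``k_aer``;
* anaerobic lactic (glycolytic): peak-normalized bi-exponential
  ``P_la,max * k_norm * (1 - exp(-t/k1)) * exp(-t/k2)``;
* anaerobic alactic (ATP/PCr splitting): log-normal pulse
  ``P_al,max * exp(-(ln t - mu)^2 / (2 sigma^2))``.

The shape constants are fixed; only the two anaerobic amplitudes are free,
so fitting the model to an observed power series is a non-negative linear
least-squares problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import nnls

from .cost_power import PowerSeries

__all__ = [
    "PathwayParams",
    "ModelAmplitudes",
    "MEN_PARAMS",
    "WOMEN_PARAMS",
    "knorm",
    "biexp_peak_time",
    "aerobic_power",
    "aerobic_energy",
    "lactic_power",
    "alactic_power",
    "total_power",
    "fit_amplitudes",
    "pathway_energies",
]


class BiexpNormalization(NamedTuple):
    t_peak: float
    k_norm: float


def biexp_peak_time(k1: float, k2: float) -> float:
    """Time at which ``(1 - exp(-t/k1)) * exp(-t/k2)`` peaks: ``k1 ln(1 + k2/k1)``."""
    if k1 <= 0 or k2 <= 0:
        raise ValueError("time constants must be positive")
    return k1 * np.log1p(k2 / k1)


def knorm(k1: float, k2: float) -> float:
    """Normalization constant making the bi-exponential's maximum equal its amplitude."""
    ts = biexp_peak_time(k1, k2)
    return 1.0 / ((1.0 - np.exp(-ts / k1)) * np.exp(-ts / k2))


@dataclass(frozen=True)
class PathwayParams:
    """Fixed constants of the three-pathway model.

    ``sigma_al`` is stored as a magnitude; it only ever enters squared.
    ``k_norm`` is derived from (k1, k2), never free.
    """

    maximal_aerobic_power: float = 24.5  # W kg^-1 (MAP), men default
    bmr: float = 1.2  # W kg^-1 basal metabolic rate
    k_aer: float = 23.0  # s, aerobic on-kinetics time constant
    k1: float = 2.75  # s, glycolytic activation
    k2: float = 35.0  # s, glycolytic inhibition
    mu_al: float = -0.4  # ln-seconds, alactic peak at exp(mu_al) ~ 0.67 s
    sigma_al: float = 1.0  # ln-seconds, alactic pulse width

    def __post_init__(self) -> None:
        if self.maximal_aerobic_power <= self.bmr:
            raise ValueError("MAP must exceed BMR")
        if self.k1 >= self.k2:
            raise ValueError("glycolytic rise constant k1 must be below decay constant k2")

    @property
    def k_norm(self) -> float:
        return knorm(self.k1, self.k2)


MEN_PARAMS = PathwayParams(maximal_aerobic_power=24.5)
WOMEN_PARAMS = PathwayParams(maximal_aerobic_power=21.0)


@dataclass(frozen=True)
class ModelAmplitudes:
    """Free amplitudes of the anaerobic pathways with the fit's adjusted R^2."""

    p_al_max: float
    p_la_max: float
    adjusted_r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.p_al_max < 0 or self.p_la_max < 0:
            raise ValueError("amplitudes must be non-negative")


def aerobic_power(t, params: PathwayParams = MEN_PARAMS):
    """Aerobic power above basal rate: ``(MAP - BMR) (1 - exp(-t/k_aer))``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = (params.maximal_aerobic_power - params.bmr) * (1.0 - np.exp(-t / params.k_aer))
    return out if out.ndim else float(out)


def aerobic_energy(T: float, params: PathwayParams = MEN_PARAMS) -> float:
    """Closed-form integral of :func:`aerobic_power` over ``[0, T]`` (J kg^-1)."""
    if T < 0:
        raise ValueError("duration must be non-negative")
    amp = params.maximal_aerobic_power - params.bmr
    return amp * (T - params.k_aer * (1.0 - np.exp(-T / params.k_aer)))


def _lactic_shape(t, params: PathwayParams):
    """Unit-amplitude glycolytic pulse (maximum 1 by normalization)."""
    return params.k_norm * (1.0 - np.exp(-t / params.k1)) * np.exp(-t / params.k2)


def _alactic_shape(t, params: PathwayParams):
    """Unit-amplitude log-normal pulse; defined as 0 at t = 0 by its limit."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    with np.errstate(divide="ignore"):
        out[pos] = np.exp(
            -((np.log(t[pos]) - params.mu_al) ** 2) / (2.0 * params.sigma_al**2)
        )
    return out


def lactic_power(t, p_la_max: float, params: PathwayParams = MEN_PARAMS):
    """Glycolytic power; peaks at ``p_la_max`` at ``k1 ln(1 + k2/k1)`` seconds."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = p_la_max * _lactic_shape(t, params)
    return out if out.ndim else float(out)


def alactic_power(t, p_al_max: float, params: PathwayParams = MEN_PARAMS):
    """ATP/PCr power; peaks at ``p_al_max`` at ``exp(mu_al)`` seconds."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = p_al_max * _alactic_shape(t, params)
    return out if out.ndim else float(out)


def total_power(t, amplitudes: ModelAmplitudes, params: PathwayParams = MEN_PARAMS):
    """Sum of alactic, lactic and aerobic power at ``t``."""
    return (
        alactic_power(t, amplitudes.p_al_max, params)
        + lactic_power(t, amplitudes.p_la_max, params)
        + aerobic_power(t, params)
    )


def fit_amplitudes(
    observed: PowerSeries,
    params: PathwayParams = MEN_PARAMS,
) -> ModelAmplitudes:
    """Fit the two anaerobic amplitudes to an observed power series.

    With the shape constants fixed the model is linear in
    ``(P_al,max, P_la,max)``, so the fit is solved as non-negative linear
    least squares of the aerobic-corrected residual on the two unit-amplitude
    pulse shapes. Adjusted R^2 is computed against the full observed series
    with p = 2 free parameters.
    """
    t = observed.time_grid
    y = observed.power
    if not np.any(y > 0):
        raise ValueError("observed power series is identically zero")
    resid = y - aerobic_power(t, params)
    design = np.column_stack([_alactic_shape(t, params), _lactic_shape(t, params)])
    coef, _ = nnls(design, resid)
    yhat = design @ coef + aerobic_power(t, params)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n = len(y)
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 3)
    return ModelAmplitudes(
        p_al_max=float(coef[0]), p_la_max=float(coef[1]), adjusted_r2=float(adj)
    )


def pathway_energies(
    amplitudes: ModelAmplitudes,
    params: PathwayParams,
    T: float,
    dt: float = 0.01,
) -> dict[str, float]:
    """Trapezoidal pathway energies over ``(0, T]`` with percentage breakdown.

    The alactic integrand is evaluated from ``t = 0`` with its limiting
    value 0 there; the mass lost on the first sub-interval is bounded by
    ``p_al_max * dt`` and is negligible at the default grid.
    """
    if T <= 0:
        raise ValueError("duration must be positive")
    n = max(int(round(T / dt)), 2)
    t = np.linspace(0.0, T, n + 1)
    e_al = float(np.trapezoid(alactic_power(t, amplitudes.p_al_max, params), t))
    e_la = float(np.trapezoid(lactic_power(t, amplitudes.p_la_max, params), t))
    e_aer = float(np.trapezoid(aerobic_power(t, params), t))
    total = e_al + e_la + e_aer
    out = {"alactic": e_al, "lactic": e_la, "aerobic": e_aer, "total": total}
    if total > 0:
        out.update(
            {
                "pct_alactic": 100.0 * e_al / total,
                "pct_lactic": 100.0 * e_la / total,
                "pct_aerobic": 100.0 * e_aer / total,
            }
        )
    return out
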