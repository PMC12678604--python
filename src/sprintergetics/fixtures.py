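"""Synthetic split tables and the catalogue of published reference constants.

:func:`make_split_table` inverts the forward velocity model (exponential
acceleration followed by linear deceleration) to produce cumulative times at
regular distance marks — the structure of championship split tables — with
optional seeded Gaussian noise on interval average velocities. Because the
tables are generated from known (tau, v_f), they serve as ground truth for
round-trip tests of the fitting pipeline.

:func:`bundled_parameters` returns the published reference constants used
throughout the package: acceleration-fit parameters and finish times for
the six Berlin 2009 championship performances, per-event pathway energies,
fitted and optimized anaerobic capacities, and simulated race times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .kinematics import DEFAULT_REACTION_TIME, AccelerationFit, SplitTable

__all__ = ["FixtureSpec", "make_split_table", "bundled_parameters"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic split table.

    ``peak_fraction`` sets where the acceleration phase ends: the runner
    switches to the linear deceleration once velocity reaches that fraction
    of ``v_f``. The final velocity then follows from requiring the profile
    to cover ``total_distance`` in exactly the running time.
    ``noise_sd`` perturbs interval average velocities (m s^-1) with the
    given seed; 0 gives a noiseless, exactly model-consistent table.
    """

    tau: float
    v_f: float
    total_distance: float
    finish_time: float
    split_interval: float
    noise_sd: float = 0.0
    seed: int = 0
    reaction_time: float = DEFAULT_REACTION_TIME
    peak_fraction: float = 0.995

    def __post_init__(self) -> None:
        if min(self.tau, self.v_f, self.total_distance, self.finish_time,
               self.split_interval) <= 0:
            raise ValueError("tau, v_f, distances and times must be positive")
        if not 0.5 < self.peak_fraction < 1.0:
            raise ValueError("peak_fraction must lie in (0.5, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_split_table(spec: FixtureSpec) -> SplitTable:
    """Generate a split table from the forward two-phase velocity model."""
    T = spec.finish_time - spec.reaction_time
    if T <= 0:
        raise ValueError("finish time must exceed reaction time")
    fit = AccelerationFit(v_f=spec.v_f, tau=spec.tau)
    D = spec.total_distance

    def accel_distance(t: float) -> float:
        return spec.v_f * (t - spec.tau * (1.0 - np.exp(-t / spec.tau)))

    if accel_distance(T) < D:
        raise ValueError(
            "infeasible fixture: even uninterrupted acceleration does not "
            f"cover {D} m in {T:.2f} s with v_f={spec.v_f}, tau={spec.tau}"
        )

    t_peak = -spec.tau * np.log(1.0 - spec.peak_fraction)
    if t_peak >= T:
        raise ValueError("peak_fraction is not reached within the race duration")
    v_peak = spec.v_f * spec.peak_fraction
    d_peak = accel_distance(t_peak)
    # linear deceleration closing the distance budget exactly
    v_final = 2.0 * (D - d_peak) / (T - t_peak) - v_peak
    if not 0.0 < v_final <= v_peak:
        raise ValueError(
            "infeasible fixture: distance budget implies a final velocity of "
            f"{v_final:.2f} m/s; adjust peak_fraction or finish_time"
        )
    slope = (v_final - v_peak) / (T - t_peak)

    def distance_at(t: float) -> float:
        if t <= t_peak:
            return accel_distance(t)
        dt = t - t_peak
        return d_peak + v_peak * dt + 0.5 * slope * dt * dt

    marks = np.arange(spec.split_interval, D + 1e-9, spec.split_interval)
    if not np.isclose(marks[-1], D):
        marks = np.append(marks, D)
    times = np.array(
        [T if np.isclose(m, D) else brentq(lambda t, m=m: distance_at(t) - m, 1e-9, T)
         for m in marks]
    )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        dd = np.diff(np.concatenate(([0.0], marks)))
        dtimes = np.diff(np.concatenate(([0.0], times)))
        v_avg = dd / dtimes + rng.normal(0.0, spec.noise_sd, size=len(dd))
        if np.any(v_avg <= 0):
            raise ValueError("noise produced a non-positive interval velocity")
        times = np.cumsum(dd / v_avg)

    cumulative = times + spec.reaction_time
    return SplitTable(
        distance_marks=marks,
        cumulative_times=cumulative,
        total_distance=D,
        finish_time=float(cumulative[-1]),
        reaction_time=spec.reaction_time,
    )


def bundled_parameters() -> dict:
    """Published reference constants for the six Berlin 2009 performances.

    The catalogue groups the acceleration-fit parameters, maximal aerobic
    powers, per-race pathway energies, fitted/optimized anaerobic capacities
    and simulated race times that the package's validation suite checks
    against.
    """
    return {
        "acceleration_fits": {
            "men_100": {"tau": 1.27, "v_f": 12.34, "finish_time": 9.58,
                        "split_interval": 10.0, "distance": 100.0},
            "men_200": {"tau": 1.59, "v_f": 11.57, "finish_time": 19.19,
                        "split_interval": 50.0, "distance": 200.0},
            "men_400": {"tau": 1.54, "v_f": 9.88, "finish_time": 44.06,
                        "split_interval": 50.0, "distance": 400.0},
            "women_100": {"tau": 1.34, "v_f": 10.58, "finish_time": 10.73,
                          "split_interval": 20.0, "distance": 100.0},
            "women_200": {"tau": 1.59, "v_f": 10.18, "finish_time": 22.02,
                          "split_interval": 50.0, "distance": 200.0},
            "women_400": {"tau": 1.52, "v_f": 9.12, "finish_time": 49.32,
                          "split_interval": 50.0, "distance": 400.0},
        },
        "maximal_aerobic_power": {"m": 24.5, "f": 21.0},
        "pathway_energies": {
            # per-race energies (J/kg) from the three-pathway decomposition
            "men_100": {"alactic": 362.0, "lactic": 364.0, "aerobic": 40.0, "total": 766.0},
            "men_200": {"alactic": 239.0, "lactic": 790.0, "aerobic": 142.0, "total": 1171.0},
            "men_400": {"alactic": 170.0, "lactic": 1189.0, "aerobic": 566.0, "total": 1925.0},
            "women_100": {"alactic": 237.0, "lactic": 357.0, "aerobic": 42.0, "total": 636.0},
            "women_200": {"alactic": 179.0, "lactic": 743.0, "aerobic": 153.0, "total": 1076.0},
            "women_400": {"alactic": 144.0, "lactic": 1155.0, "aerobic": 571.0, "total": 1870.0},
        },
        "model_amplitudes": {
            # fitted (P_al,max, P_la,max) in W/kg
            "men_100": (137.7, 47.6),
            "men_200": (87.2, 49.1),
            "men_400": (61.5, 39.9),
            "women_100": (89.0, 40.7),
            "women_200": (65.2, 40.9),
            "women_400": (52.0, 36.6),
        },
        "fitted_capacities": {
            # capacities from the duration-availability fits (J/kg)
            "m": {"alactic": 376.0, "lactic": 1314.0},
            "f": {"alactic": 259.0, "lactic": 1194.0},
        },
        "optimized_capacities": {
            # capacities from the distance-error optimization (J/kg)
            "m": {"alactic": 328.0, "lactic": 1460.0},
            "f": {"alactic": 218.0, "lactic": 1295.0},
        },
        "optimized_event_energies": {
            # per-race energies (J/kg) at the optimized capacities
            "men_100": {"alactic": 311.0, "lactic": 429.0, "aerobic": 40.0},
            "men_200": {"alactic": 238.0, "lactic": 856.0, "aerobic": 142.0},
            "men_400": {"alactic": 131.0, "lactic": 1327.0, "aerobic": 566.0},
            "women_100": {"alactic": 201.0, "lactic": 436.0, "aerobic": 42.0},
            "women_200": {"alactic": 147.0, "lactic": 838.0, "aerobic": 154.0},
            "women_400": {"alactic": 79.0, "lactic": 1214.0, "aerobic": 572.0},
        },
        "simulated_times": {
            "m": {60.0: 6.29, 100.0: 9.58, 200.0: 19.01, 300.0: 30.44, 400.0: 44.05},
            "f": {60.0: 7.04, 100.0: 10.73, 200.0: 21.39, 300.0: 34.66, 400.0: 50.85},
        },
        "modeled_distances": {
            # integral of the modeled velocity profiles (m)
            "men_100": 99.93, "men_200": 195.69, "men_400": 389.49,
            "women_100": 96.84, "women_200": 197.31, "women_400": 395.54,
        },
        "power_summaries": {
            # (peak power W/kg, total energy J/kg) of the kinematic power series
            "men_100": (157.0, 772.0), "men_200": (99.0, 1172.0), "men_400": (73.0, 1942.0),
            "women_100": (101.0, 638.0), "women_200": (75.0, 1075.0), "women_400": (63.0, 1459.0),
        },
    }
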