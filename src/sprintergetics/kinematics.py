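"""Sprint kinematics: exponential acceleration fits and full-race velocity profiles.

The velocity of an elite sprinter accelerating from the blocks is well
described by a mono-exponential rise ``v(t) = v_f * (1 - exp(-t / tau))``
towards the peak velocity ``v_f`` with time constant ``tau``. After peak
velocity is reached, runners decelerate approximately linearly until the
finish line. This module fits the exponential model to split tables
(cumulative times at fixed distance marks) and assembles the two-phase
velocity/acceleration profile used by the energy-cost computations.

All times are in seconds, distances in metres, velocities in m s^-1 and
accelerations in m s^-2. Reaction time is subtracted before any model
evaluation, so the model clock starts at movement onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SplitTable",
    "AccelerationFit",
    "VelocityProfile",
    "model_velocity",
    "model_acceleration",
    "fit_acceleration",
    "adjust_peak_velocity",
    "build_velocity_profile",
    "integrate_distance",
    "pure_acceleration_distance",
]

DEFAULT_REACTION_TIME = 0.15  # s, assumed when the actual start reaction is unknown


@dataclass(frozen=True)
class SplitTable:
    """Distance marks and cumulative (gun) times for one race.

    ``cumulative_times`` are measured from the gun; ``reaction_time`` is the
    delay between the gun and movement onset and is subtracted before any
    model fitting. The first interval runs from the start line to the first
    mark.
    """

    distance_marks: np.ndarray
    cumulative_times: np.ndarray
    total_distance: float
    finish_time: float
    reaction_time: float = DEFAULT_REACTION_TIME

    def __post_init__(self) -> None:
        marks = np.asarray(self.distance_marks, dtype=float)
        times = np.asarray(self.cumulative_times, dtype=float)
        object.__setattr__(self, "distance_marks", marks)
        object.__setattr__(self, "cumulative_times", times)
        if marks.ndim != 1 or times.ndim != 1 or marks.size != times.size:
            raise ValueError("distance marks and times must be 1-D and equal length")
        if marks.size < 3:
            raise ValueError("need at least 3 splits to fit the acceleration model")
        if np.any(np.diff(marks) <= 0) or np.any(np.diff(times) <= 0):
            raise ValueError("splits must be strictly increasing in distance and time")
        if marks[0] <= 0:
            raise ValueError("first distance mark must be positive")
        if not np.isclose(marks[-1], self.total_distance):
            raise ValueError("last distance mark must equal total_distance")
        if not np.isclose(times[-1], self.finish_time):
            raise ValueError("last cumulative time must equal finish_time")
        if np.any(times <= self.reaction_time):
            raise ValueError("all cumulative times must exceed the reaction time")

    @classmethod
    def from_marks(
        cls,
        distance_marks,
        cumulative_times,
        reaction_time: float = DEFAULT_REACTION_TIME,
    ) -> "SplitTable":
        marks = np.asarray(distance_marks, dtype=float)
        times = np.asarray(cumulative_times, dtype=float)
        return cls(marks, times, float(marks[-1]), float(times[-1]), reaction_time)

    # -- interval helpers -------------------------------------------------
    def running_times(self) -> np.ndarray:
        """Cumulative times with reaction time removed (movement clock)."""
        return self.cumulative_times - self.reaction_time

    def interval_midpoints(self) -> np.ndarray:
        """Time midpoints of each split interval on the movement clock."""
        t = np.concatenate(([0.0], self.running_times()))
        return 0.5 * (t[:-1] + t[1:])

    def interval_average_velocities(self) -> np.ndarray:
        d = np.concatenate(([0.0], self.distance_marks))
        t = np.concatenate(([0.0], self.running_times()))
        return np.diff(d) / np.diff(t)


@dataclass(frozen=True)
class AccelerationFit:
    """Parameters of the exponential velocity rise with fit diagnostics."""

    v_f: float
    tau: float
    rse: float = float("nan")
    rmse: float = float("nan")

    def __post_init__(self) -> None:
        if self.v_f <= 0 or self.tau <= 0:
            raise ValueError("v_f and tau must be positive")


@dataclass(frozen=True)
class VelocityProfile:
    """Velocity and acceleration on a uniform time grid.

    The profile follows the exponential rise on ``[0, t_peak]`` and a linear
    deceleration from ``v(t_peak)`` to ``v_final`` on ``(t_peak, duration]``.
    The time axis is the movement clock (reaction time already removed).
    """

    time_grid: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    t_peak: float
    v_final: float
    duration: float
    v_final_exceeds_peak: bool = False

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])


def model_velocity(t, fit: AccelerationFit):
    """Exponential rise ``v_f * (1 - exp(-t/tau))``; ``t`` may be an array."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = fit.v_f * (1.0 - np.exp(-t / fit.tau))
    return out if out.ndim else float(out)


def model_acceleration(t, fit: AccelerationFit):
    """Analytic derivative ``(v_f/tau) * exp(-t/tau)`` of :func:`model_velocity`."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = (fit.v_f / fit.tau) * np.exp(-t / fit.tau)
    return out if out.ndim else float(out)


def fit_acceleration(
    splits: SplitTable,
    max_distance: float | None = None,
) -> AccelerationFit:
    """Fit the exponential rise to interval average velocities.

    Interval average velocities are assigned to the interval time midpoints
    (reaction time removed) and fitted by damped (Levenberg-Marquardt)
    non-linear least squares. For long races where the late-race slowdown
    would corrupt the fit, ``max_distance`` restricts the fit to intervals
    ending at or before that mark (e.g. 200 m for 200/400 m races).
    """
    tm = splits.interval_midpoints()
    va = splits.interval_average_velocities()
    if max_distance is not None:
        keep = splits.distance_marks <= max_distance + 1e-9
        if keep.sum() < 3:
            raise ValueError("max_distance leaves fewer than 3 intervals")
        tm, va = tm[keep], va[keep]

    def _model(t, v_f, tau):
        return v_f * (1.0 - np.exp(-t / tau))

    p0 = (float(va.max()), 1.5)
    try:
        popt, _ = curve_fit(
            _model, tm, va, p0=p0, method="lm", xtol=1e-12, ftol=1e-12, maxfev=20000
        )
    except RuntimeError as err:  # pragma: no cover - scipy reports the trace
        raise RuntimeError(f"acceleration fit did not converge: {err}") from err
    v_f, tau = float(popt[0]), float(popt[1])
    if v_f <= 0 or tau <= 0:
        raise RuntimeError("acceleration fit converged to non-physical parameters")
    resid = va - _model(tm, v_f, tau)
    ss = float(np.sum(resid**2))
    n = len(va)
    rse = np.sqrt(ss / (n - 2)) if n > 2 else float("nan")
    rmse = np.sqrt(ss / n)
    return AccelerationFit(v_f=v_f, tau=tau, rse=rse, rmse=float(rmse))


def adjust_peak_velocity(
    fit: AccelerationFit,
    splits: SplitTable,
    max_instantaneous: float | None = None,
) -> AccelerationFit:
    """Correct ``v_f`` for the deceleration-induced underestimate.

    Because late-race deceleration drags the fitted asymptote down, ``v_f``
    is replaced by the highest observed instantaneous velocity when
    available, otherwise by the highest interval average velocity. The
    correction is only ever upward; ``tau`` is unchanged.
    """
    observed = (
        float(max_instantaneous)
        if max_instantaneous is not None
        else float(splits.interval_average_velocities().max())
    )
    return replace(fit, v_f=max(fit.v_f, observed))


def build_velocity_profile(
    fit: AccelerationFit,
    splits: SplitTable,
    dt: float = 0.01,
) -> VelocityProfile:
    """Assemble the two-phase velocity profile for a full race.

    The acceleration phase ends at ``t_peak``, taken as the time midpoint of
    the interval with the highest average velocity. The final velocity is
    derived from the last interval's average velocity by linear
    interpolation, and the deceleration phase interpolates linearly between
    ``v(t_peak)`` and ``v_final``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    T = splits.finish_time - splits.reaction_time
    mids = splits.interval_midpoints()
    vavg = splits.interval_average_velocities()
    t_peak = float(mids[int(np.argmax(vavg))])
    v_peak = model_velocity(t_peak, fit)

    # final velocity from the last interval's average velocity
    t_last_start = float(splits.running_times()[-2]) if len(splits.distance_marks) > 1 else 0.0
    v_avg_last = float(vavg[-1])
    if t_last_start <= t_peak:
        v_start = model_velocity(t_last_start, fit)
        v_final = 2.0 * v_avg_last - v_start
    else:
        # whole last interval lies in the linear phase: its average velocity
        # equals the model velocity at the interval's time midpoint
        mid = 0.5 * (t_last_start + T)
        slope = (v_avg_last - v_peak) / (mid - t_peak)
        v_final = v_peak + slope * (T - t_peak)

    exceeds = bool(v_final > fit.v_f)
    if exceeds:
        warnings.warn(
            "derived final velocity exceeds peak velocity; the two-phase "
            "model is inconsistent with these splits",
            RuntimeWarning,
            stacklevel=2,
        )

    n = max(int(round(T / dt)), 2)
    t = np.linspace(0.0, T, n + 1)
    accel_mask = t <= t_peak
    v = np.empty_like(t)
    a = np.empty_like(t)
    v[accel_mask] = model_velocity(t[accel_mask], fit)
    a[accel_mask] = model_acceleration(t[accel_mask], fit)
    if T > t_peak:
        slope = (v_final - v_peak) / (T - t_peak)
    else:
        slope = 0.0
    v[~accel_mask] = v_peak + slope * (t[~accel_mask] - t_peak)
    a[~accel_mask] = slope
    v = np.maximum(v, 0.0)
    return VelocityProfile(
        time_grid=t,
        velocity=v,
        acceleration=a,
        t_peak=t_peak,
        v_final=float(v_final),
        duration=float(T),
        v_final_exceeds_peak=exceeds,
    )


def integrate_distance(profile: VelocityProfile) -> float:
    """Trapezoidal integral of the velocity profile (metres)."""
    return float(np.trapezoid(profile.velocity, profile.time_grid))


def pure_acceleration_distance(fit: AccelerationFit, T: float) -> float:
    """Closed-form distance of the exponential rise over ``[0, T]``.

    Integrating ``v_f (1 - exp(-t/tau))`` gives
    ``v_f * (T - tau * (1 - exp(-T/tau)))``.
    """
    return fit.v_f * (T - fit.tau * (1.0 - np.exp(-T / fit.tau)))
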