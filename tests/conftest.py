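import numpy as np
import pytest

import sprintergetics as sg


@pytest.fixture(scope="session")
def catalogue():
    return sg.bundled_parameters()


def _event_fixture_spec(catalogue, key):
    """Fixture spec for one championship event.

    The synthetic table reproduces the event's published acceleration
    parameters and finish time; its total distance is the published integral
    of the modeled velocity profile (the two-phase model does not cover the
    full nominal distance for every event).
    """
    fit = catalogue["acceleration_fits"][key]
    return sg.FixtureSpec(
        tau=fit["tau"],
        v_f=fit["v_f"],
        total_distance=catalogue["modeled_distances"][key],
        finish_time=fit["finish_time"],
        split_interval=fit["split_interval"],
    )


@pytest.fixture(scope="session")
def event_profiles(catalogue):
    """Two-phase velocity profiles for all six championship events."""
    profiles = {}
    for key, fit_info in catalogue["acceleration_fits"].items():
        spec = _event_fixture_spec(catalogue, key)
        splits = sg.make_split_table(spec)
        fit = sg.AccelerationFit(v_f=fit_info["v_f"], tau=fit_info["tau"])
        profiles[key] = sg.build_velocity_profile(fit, splits, dt=0.01)
    return profiles


@pytest.fixture(scope="session")
def men100_splits(catalogue):
    fit = catalogue["acceleration_fits"]["men_100"]
    spec = sg.FixtureSpec(
        tau=fit["tau"], v_f=fit["v_f"], total_distance=100.0,
        finish_time=fit["finish_time"], split_interval=10.0,
    )
    return sg.make_split_table(spec)


@pytest.fixture(scope="session")
def men100_fit(catalogue):
    fit = catalogue["acceleration_fits"]["men_100"]
    return sg.AccelerationFit(v_f=fit["v_f"], tau=fit["tau"])


@pytest.fixture(scope="session")
def men100_profile(men100_fit, men100_splits):
    return sg.build_velocity_profile(men100_fit, men100_splits, dt=0.01)


@pytest.fixture(scope="session")
def men100_power(men100_profile):
    return sg.metabolic_power(men100_profile)


@pytest.fixture(scope="session")
def midpoint_exact_splits():
    """Split table whose interval average velocities equal the exponential
    model exactly at the interval midpoints (bias-free fitting target)."""
    tau, v_f, reaction = 1.5, 10.0, 0.15
    t = np.arange(1.0, 11.0)  # running-clock interval edges
    edges = np.concatenate(([0.0], t))
    mids = 0.5 * (edges[:-1] + edges[1:])
    v_mid = v_f * (1.0 - np.exp(-mids / tau))
    marks = np.cumsum(v_mid * np.diff(edges))
    return sg.SplitTable.from_marks(marks, t + reaction, reaction_time=reaction), tau, v_f
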