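"""CSV/JSON/TOML plumbing for the command-line interface."""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .cost_power import PowerSeries
from .kinematics import DEFAULT_REACTION_TIME, SplitTable


def read_split_csv(
    path: str | Path,
    reaction_time: float = DEFAULT_REACTION_TIME,
) -> SplitTable:
    """Read a split table CSV with columns ``distance_m, cumulative_time_s``."""
    df = pd.read_csv(path)
    missing = {"distance_m", "cumulative_time_s"} - set(df.columns)
    if missing:
        raise ValueError(f"split CSV missing columns: {sorted(missing)}")
    return SplitTable.from_marks(
        df["distance_m"].to_numpy(float),
        df["cumulative_time_s"].to_numpy(float),
        reaction_time=reaction_time,
    )


def write_split_csv(path: str | Path, table: SplitTable) -> None:
    pd.DataFrame(
        {"distance_m": table.distance_marks, "cumulative_time_s": table.cumulative_times}
    ).to_csv(path, index=False)


def read_power_csv(path: str | Path, source: str = "from_kinematics") -> PowerSeries:
    """Read a power series CSV with columns ``time_s, power_wkg``."""
    df = pd.read_csv(path)
    missing = {"time_s", "power_wkg"} - set(df.columns)
    if missing:
        raise ValueError(f"power CSV missing columns: {sorted(missing)}")
    return PowerSeries.from_samples(
        df["time_s"].to_numpy(float), df["power_wkg"].to_numpy(float), source=source
    )


def write_power_csv(path: str | Path, columns: dict[str, np.ndarray]) -> None:
    pd.DataFrame(columns).to_csv(path, index=False)


def load_config(path: str | Path | None) -> dict:
    """Load the TOML configuration (sections: cost_model, pathways, capacity)."""
    if path is None:
        return {}
    with open(path, "rb") as fh:
        return tomllib.load(fh)
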