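"""CSV dialects shared by the pipeline stages.

All inputs are plain CSV with ISO-8601 timestamps: body temperatures
(fish_id, timestamp, temp_c; empty cell = missing), thermographs (depth_m,
timestamp, temp_c), telemetry fixes (fish_id, timestamp, period, easting,
northing) and excursion records as produced by
:func:`thermotactics.movement_tree.excursion_frequency`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .eigenbasis import TimeGrid
from .lake_layers import ThermalProfile
from .scalogram import BodyTempSeries

__all__ = [
    "read_body_temps",
    "write_body_temps",
    "read_thermograph",
    "read_telemetry",
    "read_excursions",
]


def read_body_temps(path) -> tuple[list[BodyTempSeries], TimeGrid]:
    """Load per-fish hourly series, aligned to the common hourly grid.

    The grid spans the earliest to the latest timestamp in the file; hours
    a fish lacks are missing for that fish.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    ts = pd.date_range(df["timestamp"].min(), df["timestamp"].max(), freq="h")
    grid = TimeGrid(n_hours=len(ts), start=ts[0])
    lookup = pd.DataFrame({"timestamp": ts})
    series = []
    for fish, grp in df.groupby("fish_id", sort=True):
        merged = lookup.merge(grp[["timestamp", "temp_c"]], on="timestamp", how="left")
        series.append(BodyTempSeries(fish_id=str(fish),
                                     temps=merged["temp_c"].to_numpy(float)))
    return series, grid


def write_body_temps(path, series: list[BodyTempSeries], grid: TimeGrid) -> None:
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "fish_id": s.fish_id,
            "timestamp": grid.timestamps,
            "temp_c": np.where(np.isfinite(s.temps), s.temps, np.nan),
        }))
    pd.concat(frames).to_csv(path, index=False)


def read_thermograph(path) -> ThermalProfile:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return ThermalProfile.from_frame(df)


def read_telemetry(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])


def read_excursions(path) -> pd.DataFrame:
    return pd.read_csv(path)
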