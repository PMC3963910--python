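"""Thermal-layer detection from lake thermograph profiles.

A summer-stratified lake column is split at each hour into an epilimnion
(warm, well-mixed surface water) and a metalimnion, defined as the portion
of the water column below the epilimnion whose vertical temperature gradient
exceeds 1 degC per metre of depth.  The metalimnion is located as the
shallowest maximal contiguous run of super-threshold 0.5 m intervals; the
epilimnion is everything above it.

Because the transmitters report temperature rather than depth, a fix is
classed as epilimnetic when the fish's body temperature matches the
epilimnion's temperature range that hour, within a small tolerance that
absorbs transmitter equilibration lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import MissingProfileError, UndefinedOccupancyError

__all__ = [
    "ThermalProfile",
    "LayerBounds",
    "HourLayers",
    "LayerDaily",
    "detect_layers",
    "hourly_layers",
    "daily_layer_means",
    "classify_fix_epilimnion",
    "GRADIENT_THRESHOLD",
]

#: Metalimnion criterion: vertical gradient above this (degC per metre).
GRADIENT_THRESHOLD = 1.0


@dataclass
class ThermalProfile:
    """Hourly thermograph matrix: depths (m, positive downward) x timestamps."""

    depths: np.ndarray           # strictly increasing, metres
    temps: np.ndarray            # (n_depths, n_hours), degC; NaN = missing
    timestamps: pd.DatetimeIndex

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.temps = np.asarray(self.temps, dtype=float)
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if self.temps.shape != (self.depths.size, len(self.timestamps)):
            raise ValueError("temps must be (n_depths, n_hours)")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ThermalProfile":
        """Build from long-format records (depth_m, timestamp, temp_c)."""
        wide = df.pivot_table(index="depth_m", columns="timestamp",
                              values="temp_c", aggfunc="mean")
        wide = wide.sort_index()
        return cls(depths=wide.index.to_numpy(float), temps=wide.to_numpy(float),
                   timestamps=pd.DatetimeIndex(wide.columns))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.temps, index=self.depths, columns=self.timestamps)
        long = df.stack(future_stack=True).reset_index()
        long.columns = ["depth_m", "timestamp", "temp_c"]
        return long


@dataclass(frozen=True)
class LayerBounds:
    """Layer boundaries for a single hour; depths are profile depths."""

    stratified: bool
    meta_top: float | None = None
    meta_bottom: float | None = None


@dataclass(frozen=True)
class HourLayers:
    """Per-hour bounds plus the layer temperature summaries used downstream."""

    timestamp: pd.Timestamp
    bounds: LayerBounds
    epi_min: float | None
    epi_mean: float | None
    meta_mean: float | None


def detect_layers(depths: np.ndarray, temps: np.ndarray) -> LayerBounds:
    """Locate the metalimnion in one hourly profile column.

    The downward gradient of interval j is ``(T_j - T_{j+1}) / (z_{j+1} -
    z_j)`` (positive when temperature drops with depth).  The metalimnion is
    the shallowest maximal contiguous run of intervals with gradient above
    1 degC/m; ``meta_top``/``meta_bottom`` are the run's outer depths.
    """
    depths = np.asarray(depths, dtype=float)
    temps = np.asarray(temps, dtype=float)
    ok = np.isfinite(temps)
    if ok.sum() < 3:
        raise MissingProfileError("need at least 3 observed depths in the column")
    z = depths[ok]
    t = temps[ok]
    grad = (t[:-1] - t[1:]) / (z[1:] - z[:-1])
    hot = grad > GRADIENT_THRESHOLD
    if not hot.any():
        return LayerBounds(stratified=False)
    # first (shallowest) maximal contiguous run of super-threshold intervals
    start = int(np.argmax(hot))
    end = start
    while end + 1 < hot.size and hot[end + 1]:
        end += 1
    return LayerBounds(stratified=True, meta_top=float(z[start]),
                       meta_bottom=float(z[end + 1]))


def _hour_summary(depths: np.ndarray, col: np.ndarray,
                  ts: pd.Timestamp) -> HourLayers:
    try:
        bounds = detect_layers(depths, col)
    except MissingProfileError:
        return HourLayers(ts, LayerBounds(stratified=False), None, None, None)
    if not bounds.stratified:
        return HourLayers(ts, bounds, None, None, None)
    ok = np.isfinite(col)
    epi = ok & (depths < bounds.meta_top)
    meta = ok & (depths >= bounds.meta_top) & (depths <= bounds.meta_bottom)
    epi_vals = col[epi]
    meta_vals = col[meta]
    return HourLayers(
        timestamp=ts,
        bounds=bounds,
        epi_min=float(epi_vals.min()) if epi_vals.size else None,
        epi_mean=float(epi_vals.mean()) if epi_vals.size else None,
        meta_mean=float(meta_vals.mean()) if meta_vals.size else None,
    )


def hourly_layers(profile: ThermalProfile) -> list[HourLayers]:
    """Layer bounds and summaries for every hourly column of the profile."""
    return [
        _hour_summary(profile.depths, profile.temps[:, j], profile.timestamps[j])
        for j in range(len(profile.timestamps))
    ]


@dataclass(frozen=True)
class LayerDaily:
    """Daily layer summary: mean temperatures and median layer bounds."""

    date: pd.Timestamp
    epi_mean: float
    meta_mean: float
    meta_top: float
    meta_bottom: float
    n_hours: int


def daily_layer_means(profile: ThermalProfile) -> list[LayerDaily]:
    """Aggregate hourly layer detections into calendar-day summaries.

    A day's epilimnion (metalimnion) mean pools every observed (depth, hour)
    cell inside that layer across the day's stratified hours; boundary depths
    are daily medians.  Days without any stratified hour are omitted with a
    warning.
    """
    hours = hourly_layers(profile)
    by_day: dict[pd.Timestamp, list[int]] = {}
    for j, h in enumerate(hours):
        by_day.setdefault(h.timestamp.normalize(), []).append(j)
    out: list[LayerDaily] = []
    for day in sorted(by_day):
        idx = [j for j in by_day[day] if hours[j].bounds.stratified]
        if not idx:
            warnings.warn(f"{day.date()}: no stratified hour; day omitted", stacklevel=2)
            continue
        epi_cells, meta_cells, tops, bottoms = [], [], [], []
        for j in idx:
            b = hours[j].bounds
            col = profile.temps[:, j]
            ok = np.isfinite(col)
            epi_cells.append(col[ok & (profile.depths < b.meta_top)])
            meta_cells.append(col[ok & (profile.depths >= b.meta_top)
                                  & (profile.depths <= b.meta_bottom)])
            tops.append(b.meta_top)
            bottoms.append(b.meta_bottom)
        epi_all = np.concatenate(epi_cells)
        meta_all = np.concatenate(meta_cells)
        out.append(LayerDaily(
            date=day,
            epi_mean=float(epi_all.mean()) if epi_all.size else np.nan,
            meta_mean=float(meta_all.mean()),
            meta_top=float(np.median(tops)),
            meta_bottom=float(np.median(bottoms)),
            n_hours=len(idx),
        ))
    return out


def layers_to_frame(daily: list[LayerDaily]) -> pd.DataFrame:
    return pd.DataFrame([{
        "date": d.date.date().isoformat(),
        "epi_mean": d.epi_mean,
        "meta_mean": d.meta_mean,
        "meta_top": d.meta_top,
        "meta_bottom": d.meta_bottom,
        "n_hours": d.n_hours,
    } for d in daily])


def classify_fix_epilimnion(body_temp: float, hour: HourLayers,
                            tolerance: float = 0.5) -> bool:
    """Is a fish with this body temperature inside the epilimnion this hour?

    True iff ``body_temp >= min(epilimnion temperature) - tolerance``.  The
    default 0.5 degC tolerance absorbs the transmitters' ~20 min thermal
    equilibration.  Undefined (raises) for unstratified hours.
    """
    if not hour.bounds.stratified or hour.epi_min is None:
        raise UndefinedOccupancyError(
            f"{hour.timestamp}: epilimnion occupancy undefined (no stratification)")
    return bool(body_temp >= hour.epi_min - tolerance)
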