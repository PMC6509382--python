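"""Reading, screening and season-partitioning of GPS telemetry.

A telemetry table has one row per fix with columns ``animal_id``, ``herd``,
``timestamp`` (UTC), ``x`` and ``y`` (projected planar metres, e.g. UTM).
Fixes are screened for gross positional errors, restricted to fixed seasonal
windows, and aligned into "rounds" of (near-)simultaneous fixes across
animals, which are the sampling occasions of the association analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, OrderingError

FIX_COLUMNS = ["animal_id", "herd", "timestamp", "x", "y"]

#: Default screening thresholds: sustained speed above ``MAX_SPEED`` m/hr or an
#: out-and-back spike longer than ``MAX_STEP`` m marks a fix as erroneous.
MAX_SPEED = 15_000.0
MAX_STEP = 10_000.0


@dataclass(frozen=True)
class SeasonWindow:
    """A recurring within-year window, e.g. winter = 15 Jan - 3 Mar.

    ``start`` and ``end`` are (month, day) tuples; both endpoints are
    inclusive. Windows must not wrap around the year boundary.
    """

    label: str
    start: tuple[int, int]
    end: tuple[int, int]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidParameterError(
                f"season window {self.label!r} must have start < end within a year"
            )

    def contains(self, ts: pd.Timestamp) -> bool:
        return self.start <= (ts.month, ts.day) <= self.end

    def start_date(self, year: int) -> pd.Timestamp:
        return pd.Timestamp(year=year, month=self.start[0], day=self.start[1], tz="UTC")

    def n_days(self, year: int = 2001) -> int:
        end = pd.Timestamp(year=year, month=self.end[0], day=self.end[1], tz="UTC")
        return int((end - self.start_date(year)).days) + 1


WINTER = SeasonWindow("winter", (1, 15), (3, 3))
SUMMER = SeasonWindow("summer", (7, 15), (9, 1))
DEFAULT_SEASONS = (WINTER, SUMMER)


def read_telemetry(path) -> pd.DataFrame:
    """Read a telemetry CSV and validate its schema."""
    fixes = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in FIX_COLUMNS if c not in fixes.columns]
    if missing:
        raise InvalidParameterError(f"telemetry file lacks columns {missing}")
    if fixes["timestamp"].dt.tz is None:
        fixes["timestamp"] = fixes["timestamp"].dt.tz_localize("UTC")
    if not np.isfinite(fixes[["x", "y"]].to_numpy()).all():
        raise InvalidParameterError("non-finite coordinates in telemetry")
    return fixes.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(drop=True)


def write_telemetry(fixes: pd.DataFrame, path) -> None:
    out = fixes[FIX_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def _screen_one(track: pd.DataFrame, max_speed: float, max_step: float) -> np.ndarray:
    """Boolean keep-mask for one animal's time-sorted track."""
    hours = track["timestamp"].astype("int64").to_numpy() / 3.6e12  # ns -> hr
    if len(hours) > 1 and (np.diff(hours) <= 0).any():
        raise OrderingError(
            f"timestamps not strictly increasing for animal {track['animal_id'].iat[0]!r}"
        )
    xy = track[["x", "y"]].to_numpy(float)
    n = len(xy)
    keep = np.ones(n, dtype=bool)
    if n < 3:
        pass
    else:
        # Spike rule: a long out-and-back excursion lasting a single fix.
        d_prev = np.hypot(*(xy[1:] - xy[:-1]).T)  # distance i-1 -> i
        spike = (
            (d_prev[:-1] > max_step)
            & (d_prev[1:] > max_step)
            & (np.hypot(*(xy[2:] - xy[:-2]).T) < max_step)
        )
        keep[1:-1][spike] = False
    # Speed rule: sequential pass against the previous kept fix.
    idx = np.flatnonzero(keep)
    last = idx[0] if len(idx) else None
    for i in idx[1:]:
        dt = hours[i] - hours[last]
        dist = float(np.hypot(*(xy[i] - xy[last])))
        if dt > 0 and dist / dt > max_speed:
            keep[i] = False
        else:
            last = i
    return keep


def screen_fixes(
    fixes: pd.DataFrame,
    max_speed: float = MAX_SPEED,
    max_step: float = MAX_STEP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split fixes into (kept, rejected) using a speed + spike screen.

    A fix is rejected either as a single-fix spike (an implausibly long step
    immediately reversed) or because it implies a sustained movement rate
    above ``max_speed`` m/hr relative to the previous retained fix. The union
    of the two returned frames is the input.
    """
    if max_speed <= 0 or max_step <= 0:
        raise InvalidParameterError("screening thresholds must be positive")
    if fixes.empty:
        return fixes.copy(), fixes.copy()
    keep = np.ones(len(fixes), dtype=bool)
    for _, track in fixes.groupby("animal_id", sort=False):
        keep[track.index.to_numpy()] = _screen_one(track, max_speed, max_step)
    return fixes[keep].copy(), fixes[~keep].copy()


def assign_season(
    fixes: pd.DataFrame, windows: tuple[SeasonWindow, ...] = DEFAULT_SEASONS
) -> pd.DataFrame:
    """Tag each fix with (season, year); fixes outside every window are dropped.

    The year key is the calendar year in which the window falls (winter of
    year Y runs 15 Jan - 3 Mar of Y). Window endpoints are inclusive.
    """
    month_day = list(zip(fixes["timestamp"].dt.month, fixes["timestamp"].dt.day))
    season = np.array([None] * len(fixes), dtype=object)
    for w in windows:
        hit = np.array([w.start <= md <= w.end for md in month_day])
        season[hit] = w.label
    out = fixes[season != None].copy()  # noqa: E711 -- elementwise object compare
    out["season"] = season[season != None]  # noqa: E711
    out["year"] = out["timestamp"].dt.year
    return out.reset_index(drop=True)


def build_rounds(fixes: pd.DataFrame, tolerance: str | pd.Timedelta = "5min") -> pd.DataFrame:
    """Assign every fix to a sampling round of simultaneous fixes.

    Rounds anchor on the whole hour: a fix whose timestamp is within
    ``tolerance`` of its nearest hour joins that round. Off-schedule fixes
    that miss every hourly anchor are greedily clustered among themselves
    (first fix of a cluster anchors it). If an animal contributes two fixes
    to one round, the one nearer the anchor is kept and the other dropped.

    Returns the fixes with an added ``round_time`` column.
    """
    tolerance = pd.Timedelta(tolerance)
    out = fixes.copy()
    ts = out["timestamp"]
    anchor = ts.dt.round("h")
    on_sched = (ts - anchor).abs() <= tolerance
    round_time = anchor.where(on_sched, pd.NaT)

    leftovers = out.index[~on_sched]
    if len(leftovers):
        order = ts.loc[leftovers].sort_values(kind="stable").index
        current = None
        for i in order:
            if current is None or ts[i] - current > tolerance:
                current = ts[i]
            round_time[i] = current
    out["round_time"] = round_time

    # one fix per animal per round: keep the fix nearest its anchor
    off = (out["timestamp"] - out["round_time"]).abs()
    out = (
        out.assign(_off=off)
        .sort_values("_off", kind="stable")
        .drop_duplicates(subset=["animal_id", "round_time"], keep="first")
        .drop(columns="_off")
        .sort_values(["round_time", "animal_id"], kind="stable")
        .reset_index(drop=True)
    )
    return out
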