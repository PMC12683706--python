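"""GPS trajectory preparation: trip segmentation, rediscretization, steps.

A *complete foraging trip* is a run of fixes from the moment a bird first
moves beyond the colony radius to its first re-entry, kept only when
departure and return fall on the same calendar day. Trips are rediscretized
to an even time interval (default 15 min) by linear interpolation along the
recorded path before step lengths and turning angles are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Trip", "segment_trips", "rediscretize", "steps_and_turns", "prepare_steps"]

TRAJ_COLUMNS = ("bird_id", "timestamp", "x", "y")


@dataclass
class Trip:
    """Ordered fixes of one complete colony-to-colony foraging trip."""

    bird_id: str
    fixes: pd.DataFrame  # columns timestamp, x, y
    trip_id: str = ""
    year: int | None = None

    def __post_init__(self):
        if self.year is None and len(self.fixes):
            self.year = int(pd.Timestamp(self.fixes["timestamp"].iloc[0]).year)

    def __len__(self) -> int:
        return len(self.fixes)


def _check_trajectory(traj: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRAJ_COLUMNS) - set(traj.columns)
    if missing:
        raise ValueError(f"trajectory missing columns: {sorted(missing)}")
    traj = traj.copy()
    traj["timestamp"] = pd.to_datetime(traj["timestamp"])
    if not np.all(np.isfinite(traj[["x", "y"]].to_numpy(dtype=float))):
        raise ValueError("non-finite coordinates in trajectory")
    return traj


def segment_trips(
    traj: pd.DataFrame,
    colony_xy: tuple[float, float],
    colony_radius: float = 500.0,
    tz: str | None = None,
) -> list[Trip]:
    """Extract complete same-day foraging trips from one or more birds.

    Parameters
    ----------
    traj : DataFrame
        Columns bird_id, timestamp, x, y (meters, projected).
    colony_xy : (x, y)
        Colony location in the trajectory CRS.
    colony_radius : float, default 500
        Distance from the colony within which a bird counts as "at colony".
    tz : str, optional
        Timezone in which the calendar day is evaluated (naive timestamps
        are treated as already local).

    A trip runs from the last at-colony fix before departure to the first
    at-colony fix after return; runs that never return, or that span a day
    boundary, are discarded (counted in the log).
    """
    if colony_radius <= 0:
        raise ValueError("colony_radius must be > 0")
    if len(traj) == 0:
        return []
    traj = _check_trajectory(traj)
    trips: list[Trip] = []
    n_incomplete = 0
    for bird_id, grp in traj.groupby("bird_id", sort=False):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        d = np.hypot(grp["x"] - colony_xy[0], grp["y"] - colony_xy[1])
        inside = (d <= colony_radius).to_numpy()
        ts = grp["timestamp"]
        if tz is not None:
            ts = ts.dt.tz_localize(tz) if ts.dt.tz is None else ts.dt.tz_convert(tz)
        days = ts.dt.date.to_numpy()
        i = 0
        k = 0
        n = len(grp)
        while i < n - 1:
            if inside[i] and not inside[i + 1]:
                # departure between i and i+1; find first re-entry
                j = i + 1
                while j < n and not inside[j]:
                    j += 1
                if j < n and days[i] == days[j]:
                    fixes = grp.iloc[i : j + 1][["timestamp", "x", "y"]].reset_index(drop=True)
                    trips.append(Trip(bird_id=str(bird_id), fixes=fixes, trip_id=f"{bird_id}_{k}"))
                    k += 1
                else:
                    n_incomplete += 1
                i = j if j < n else n
            else:
                i += 1
    if n_incomplete:
        logger.info("segment_trips: discarded %d incomplete/overnight runs", n_incomplete)
    return trips


def rediscretize(trip: Trip, dt: pd.Timedelta | str = "15min", max_gap: pd.Timedelta | str = "60min") -> list[Trip]:
    """Resample a trip to an even time lattice by linear interpolation.

    Positions are interpolated piecewise-linearly in time along the recorded
    path, producing fixes at t0, t0+dt, ... The final recorded fix is always
    kept so rediscretization conserves both endpoints. Recording gaps longer
    than ``max_gap`` split the trip into separately lattice'd segments (with
    a logged warning); the return value is therefore a list.
    """
    dt = pd.Timedelta(dt)
    max_gap = pd.Timedelta(max_gap)
    fixes = trip.fixes
    if len(fixes) < 2:
        raise ValueError("rediscretize needs at least 2 fixes")
    t = fixes["timestamp"].to_numpy()
    gaps = np.diff(t) > max_gap.to_numpy()
    bounds = [0, *list(np.nonzero(gaps)[0] + 1), len(fixes)]
    if len(bounds) > 2:
        logger.warning(
            "rediscretize: trip %s split at %d gaps > %s", trip.trip_id, len(bounds) - 2, max_gap
        )
    out = []
    for seg_i in range(len(bounds) - 1):
        seg = fixes.iloc[bounds[seg_i] : bounds[seg_i + 1]]
        if len(seg) < 2:
            continue
        ts = seg["timestamp"].to_numpy()
        rel = (ts - ts[0]) / np.timedelta64(1, "s")
        step_s = dt.total_seconds()
        n_steps = int(np.floor(rel[-1] / step_s + 1e-9))
        grid = np.arange(n_steps + 1) * step_s
        if grid[-1] < rel[-1] - 1e-9:
            grid = np.append(grid, rel[-1])  # conserve the final endpoint
        x = np.interp(grid, rel, seg["x"].to_numpy(dtype=float))
        y = np.interp(grid, rel, seg["y"].to_numpy(dtype=float))
        new = pd.DataFrame(
            {
                "timestamp": pd.Timestamp(ts[0]) + pd.to_timedelta(grid, unit="s"),
                "x": x,
                "y": y,
            }
        )
        tid = trip.trip_id if len(bounds) == 2 else f"{trip.trip_id}.{seg_i}"
        out.append(Trip(bird_id=trip.bird_id, fixes=new, trip_id=tid, year=trip.year))
    return out


def steps_and_turns(trip: Trip) -> pd.DataFrame:
    """Step lengths and signed turning angles of a trip.

    Returns one row per step with columns x0, y0, x1, y1, timestamp (of the
    step start), length, heading, turn, bird_id, trip_id, year. The first
    step's turn is missing; a zero-length step has no heading, so the turn of
    the following step is missing too. Turns are wrapped to (-pi, pi],
    counter-clockwise positive.
    """
    fixes = trip.fixes
    if len(fixes) < 2:
        return pd.DataFrame(
            columns=["x0", "y0", "x1", "y1", "timestamp", "length", "heading", "turn", "bird_id", "trip_id", "year"]
        )
    xy = fixes[["x", "y"]].to_numpy(dtype=float)
    diffs = np.diff(xy, axis=0)
    length = np.hypot(diffs[:, 0], diffs[:, 1])
    heading = np.where(length > 0, np.arctan2(diffs[:, 1], diffs[:, 0]), np.nan)
    turn = np.full(len(length), np.nan)
    prev = heading[:-1]
    cur = heading[1:]
    raw = cur - prev
    # wrap to (-pi, pi]
    wrapped = -(np.mod(-raw + np.pi, 2 * np.pi) - np.pi)
    turn[1:] = np.where(np.isfinite(prev) & np.isfinite(cur), wrapped, np.nan)
    return pd.DataFrame(
        {
            "x0": xy[:-1, 0],
            "y0": xy[:-1, 1],
            "x1": xy[1:, 0],
            "y1": xy[1:, 1],
            "timestamp": fixes["timestamp"].iloc[:-1].to_numpy(),
            "length": length,
            "heading": heading,
            "turn": turn,
            "bird_id": trip.bird_id,
            "trip_id": trip.trip_id,
            "year": trip.year,
        }
    )


def prepare_steps(
    traj: pd.DataFrame,
    colony_xy: tuple[float, float],
    colony_radius: float = 500.0,
    dt: str = "15min",
    max_gap: str = "60min",
    tz: str | None = None,
) -> pd.DataFrame:
    """Full preprocessing chain: trips -> rediscretized -> step series.

    The result carries a globally unique ``stratum`` id per step, the
    matched-set key used by the step-selection analysis.
    """
    trips = segment_trips(traj, colony_xy, colony_radius, tz=tz)
    frames = []
    for trip in trips:
        for seg in rediscretize(trip, dt=dt, max_gap=max_gap):
            steps = steps_and_turns(seg)
            if len(steps):
                frames.append(steps)
    if not frames:
        return pd.DataFrame(
            columns=["x0", "y0", "x1", "y1", "timestamp", "length", "heading", "turn", "bird_id", "trip_id", "year", "stratum"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["stratum"] = np.arange(len(out))
    return out
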