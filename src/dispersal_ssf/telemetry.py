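"""Trajectory data model: screening, regular steps, movement rates, NSD.

A trajectory is a tidy DataFrame with columns ``animal_id``,
``collar_type`` (optional), ``timestamp`` (UTC), ``x``, ``y`` (projected
planar metres).  Collars aim for a 2-h fix schedule; steps between
consecutive retained fixes are "regular" when their duration is within
10 minutes of that nominal interval, and only regular steps enter
step-length and step-selection analyses.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "trim_trajectory",
    "screen_outliers",
    "build_steps",
    "compute_nsd",
]

NOMINAL_INTERVAL_MIN = 120.0
REGULAR_TOLERANCE_MIN = 10.0
#: default rate-implied outlier leg threshold: 5 km per 2-h interval, i.e.
#: an out-and-back round trip exceeding 10 km within 4 h
DEFAULT_LEG_THRESHOLD_M_PER_2H = 5000.0

TRAJECTORY_COLUMNS = ["animal_id", "collar_type", "timestamp", "x", "y"]


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def write_trajectory_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    cols = [c for c in TRAJECTORY_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False)


def _check_sorted(traj: pd.DataFrame) -> pd.DataFrame:
    traj = traj.sort_values("timestamp").reset_index(drop=True)
    dup = traj["timestamp"].duplicated()
    if dup.any():
        t = traj.loc[dup.idxmax(), "timestamp"]
        raise ValueError(f"duplicate timestamp {t} for animal {traj['animal_id'].iat[0]!r}")
    return traj


def trim_trajectory(traj: pd.DataFrame, hours: float = 48.0) -> pd.DataFrame:
    """Drop the first *hours* after deployment (capture-effect trimming)."""
    out = []
    for _, g in traj.groupby("animal_id", sort=False):
        g = g.sort_values("timestamp")
        cutoff = g["timestamp"].iloc[0] + pd.Timedelta(hours=hours)
        out.append(g[g["timestamp"] >= cutoff])
    return pd.concat(out, ignore_index=True)


def screen_outliers(
    traj: pd.DataFrame,
    leg_threshold_m_per_2h: float = DEFAULT_LEG_THRESHOLD_M_PER_2H,
    leg_threshold_cap_m: float = 10_000.0,
    max_iter: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove gross position outliers (out-and-back spikes).

    A fix is removed when both the leg from the previous fix and the leg to
    the next fix exceed a rate-implied threshold (default 5,000 m per 2-h
    interval, scaled by the actual gap durations — the "10s of km round
    trips in 4 hrs" signature) while the previous and next fixes are an
    ordinary distance apart.  The gap-scaled leg threshold is capped at
    *leg_threshold_cap_m*: sustained travel cannot mimic an out-and-back
    spike however long the fix gap, so the cap keeps long-gap spikes
    detectable.  Screening iterates until stable and is idempotent.
    Removed fixes are returned, never silently dropped.
    """
    kept_parts, removed_parts = [], []
    for animal, g in traj.groupby("animal_id", sort=False):
        g = _check_sorted(g)
        if len(g) < 3:
            import warnings

            warnings.warn(f"animal {animal!r}: fewer than 3 fixes, screening skipped")
            kept_parts.append(g)
            continue
        for _ in range(max_iter):
            t = pd.DatetimeIndex(g["timestamp"]).asi8
            x = g["x"].to_numpy(float)
            y = g["y"].to_numpy(float)
            gap_h = np.diff(t) / 3.6e12
            leg = np.hypot(np.diff(x), np.diff(y))
            thr = np.minimum(leg_threshold_m_per_2h * gap_h / 2.0, leg_threshold_cap_m)
            # candidate spikes: both adjacent legs over threshold,
            # prev->next distance ordinary for the combined gap
            direct = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2])
            thr_direct = np.minimum(
                leg_threshold_m_per_2h * (gap_h[:-1] + gap_h[1:]) / 2.0, 2 * leg_threshold_cap_m
            )
            spike = (leg[:-1] > thr[:-1]) & (leg[1:] > thr[1:]) & (direct < thr_direct)
            if not spike.any():
                break
            idx = np.flatnonzero(spike) + 1
            # remove non-adjacent spikes in one pass, then re-evaluate
            chosen = [int(idx[0])]
            for i in idx[1:]:
                if i > chosen[-1] + 1:
                    chosen.append(int(i))
            rem = g.iloc[chosen].copy()
            rem["reason"] = "round_trip_spike"
            removed_parts.append(rem)
            g = g.drop(g.index[chosen]).reset_index(drop=True)
        kept_parts.append(g)
    kept = pd.concat(kept_parts, ignore_index=True)
    removed = (
        pd.concat(removed_parts, ignore_index=True)
        if removed_parts
        else pd.DataFrame(columns=list(traj.columns) + ["reason"])
    )
    return kept, removed


def build_steps(
    traj: pd.DataFrame,
    expected_interval_min: float = NOMINAL_INTERVAL_MIN,
    tolerance_min: float = REGULAR_TOLERANCE_MIN,
) -> pd.DataFrame:
    """One step per consecutive fix pair, with length, duration, rates,
    signed turning angle (counter-clockwise positive, degrees) and the
    regular-interval flag."""
    steps = []
    for animal, g in traj.groupby("animal_id", sort=False):
        g = _check_sorted(g)
        if len(g) < 2:
            continue
        t = pd.DatetimeIndex(g["timestamp"]).asi8
        x = g["x"].to_numpy(float)
        y = g["y"].to_numpy(float)
        dx, dy = np.diff(x), np.diff(y)
        dur_min = np.diff(t) / 6e10
        length = np.hypot(dx, dy)
        heading = np.degrees(np.arctan2(dy, dx))
        turn = np.full(len(dx), np.nan)
        dh = heading[1:] - heading[:-1]
        turn[1:] = (dh + 180.0) % 360.0 - 180.0
        # map -180 to +180 so the angle lies in (-180, 180]
        turn[turn == -180.0] = 180.0
        df = pd.DataFrame(
            {
                "animal_id": animal,
                "t_start": g["timestamp"].iloc[:-1].to_numpy(),
                "t_end": g["timestamp"].iloc[1:].to_numpy(),
                "x_start": x[:-1],
                "y_start": y[:-1],
                "x_end": x[1:],
                "y_end": y[1:],
                "length_m": length,
                "duration_min": dur_min,
                "heading_deg": heading,
                "turn_deg": turn,
            }
        )
        steps.append(df)
    if not steps:
        return pd.DataFrame()
    out = pd.concat(steps, ignore_index=True)
    if (out["duration_min"] <= 0).any():
        raise ValueError("non-positive step duration (duplicate timestamps?)")
    out["rate_m_per_hr"] = out["length_m"] / (out["duration_min"] / 60.0)
    out["rate_m_per_min"] = out["length_m"] / out["duration_min"]
    out["regular"] = (out["duration_min"] - expected_interval_min).abs() <= tolerance_min
    return out


def compute_nsd(traj: pd.DataFrame) -> pd.DataFrame:
    """Net squared displacement profile per animal: km² from the first
    retained fix, against elapsed days."""
    parts = []
    for animal, g in traj.groupby("animal_id", sort=False):
        g = _check_sorted(g)
        x = g["x"].to_numpy(float)
        y = g["y"].to_numpy(float)
        t = pd.DatetimeIndex(g["timestamp"]).asi8
        elapsed_days = (t - t[0]) / 8.64e13
        nsd_km2 = ((x - x[0]) ** 2 + (y - y[0]) ** 2) / 1e6
        parts.append(
            pd.DataFrame(
                {
                    "animal_id": animal,
                    "timestamp": g["timestamp"].to_numpy(),
                    "elapsed_days": elapsed_days,
                    "nsd_km2": nsd_km2,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)
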