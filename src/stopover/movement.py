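"""Daily segmentation of raptor GPS tracks and migration endpoint detection.

A spring-migration track is reduced to one row per local solar day (daylight
fixes only, subsampled to a fixed interval).  Each day carries total path
length, roost-to-roost beeline (rhumb line), beeline azimuth and the turning
angle against the previous day, and is classified migratory or stopover by
distance thresholds.  Tracks end in exactly one of three ways:

* ``arrival`` — long-distance northbound daily movement ceases and the track
  direction turns sharply, with no northbound long-distance day following
  within a lookahead window;
* ``death`` — displacement collapses to (near) zero while the accelerometer
  signal flatlines for a sustained window;
* ``loss`` — the fix stream simply ends with no prior behavioural change.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings

import numpy as np
import pandas as pd

from .geodesy import (
    in_northern_sector,
    rhumb_bearing,
    rhumb_distance,
    turning_angle,
)
from .solar import solar_dates, sunrise_sunset

FIX_COLUMNS = ["individual_id", "timestamp", "lat", "lon", "acc_var"]


def _naive_utc(ts: pd.Series) -> np.ndarray:
    """UTC timestamps as a tz-naive datetime64[ns] array (for numpy math)."""
    ts = pd.to_datetime(ts, utc=True)
    return ts.dt.tz_localize(None).to_numpy()


@dataclasses.dataclass
class SegmentationConfig:
    """Thresholds of the daily classification and endpoint rules.

    Distances in km, angles in degrees, windows in hours/days.  A day is
    migratory when its total path exceeds ``migratory_total_km`` and/or its
    beeline exceeds ``migratory_beeline_km``.  Arrival requires cessation of
    long (> ``arrival_longdist_km`` beeline) northbound movement plus a turn
    greater than ``arrival_turn_deg``, confirmed over ``arrival_lookahead_days``.
    """

    migratory_total_km: float = 40.0
    migratory_beeline_km: float = 19.0
    arrival_longdist_km: float = 50.0
    northern_sector: tuple[float, float] = (270.0, 90.0)
    arrival_turn_deg: float = 100.0
    subsample_interval_min: float = 60.0
    arrival_lookahead_days: int = 5
    death_acc_epsilon: float = 0.01
    death_window_h: float = 24.0
    death_displacement_km: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "migratory_total_km",
            "migratory_beeline_km",
            "arrival_longdist_km",
            "arrival_turn_deg",
            "subsample_interval_min",
            "arrival_lookahead_days",
            "death_acc_epsilon",
            "death_window_h",
            "death_displacement_km",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclasses.dataclass
class TrackOutcome:
    """How a track ended: exactly one endpoint per individual."""

    endpoint: str  # arrival | death | loss
    endpoint_date: dt.date | None
    endpoint_lat: float = float("nan")
    endpoint_lon: float = float("nan")


@dataclasses.dataclass
class MigrationSummary:
    post_eilat_distance_km: float
    n_migratory_days: int
    n_stopover_days: int
    total_migration_distance_km: float = float("nan")
    distance_until_death_km: float = float("nan")
    days_until_death: float = float("nan")


def read_fixes(path, columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a Movebank-style fix table; ``columns`` maps ours -> file's."""
    df = pd.read_csv(path)
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    missing = [c for c in FIX_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"fix table missing columns: {missing}")
    if "acc_var" not in df.columns:
        df["acc_var"] = np.nan
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df = df.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)
    return df[FIX_COLUMNS]


def subsample_daylight(fixes: pd.DataFrame, config: SegmentationConfig) -> pd.DataFrame:
    """Keep one fix per interval slot between local sunrise and sunset.

    Slots start at sunrise of each solar day at the day's median position and
    are spaced ``subsample_interval_min`` apart up to sunset; the fix nearest
    to each slot centre (within half an interval) is retained.  Fixes already
    on the slot grid pass through unchanged.
    """
    if fixes.empty:
        return fixes.copy()
    fixes = fixes.sort_values(["individual_id", "timestamp"], kind="stable")
    out: list[pd.DataFrame] = []
    half = pd.Timedelta(minutes=config.subsample_interval_min / 2.0)
    step = pd.Timedelta(minutes=config.subsample_interval_min)
    dates = solar_dates(fixes["timestamp"], fixes["lon"])
    for (_, date), day in fixes.groupby([fixes["individual_id"], dates], sort=True):
        lat0 = float(day["lat"].median())
        lon0 = float(day["lon"].median())
        rise, set_ = sunrise_sunset(date, lat0, lon0)
        keep_idx: list = []
        slot = rise
        ts = _naive_utc(day["timestamp"])
        while slot <= set_:
            delta = np.abs(ts - np.datetime64(slot.replace(tzinfo=None)))
            i = int(np.argmin(delta))
            if delta[i] <= half.to_numpy():
                keep_idx.append(day.index[i])
            slot = slot + step
        if keep_idx:
            out.append(day.loc[sorted(set(keep_idx))])
    if not out:
        return fixes.iloc[0:0].copy()
    return pd.concat(out).sort_values(["individual_id", "timestamp"], kind="stable")


def daily_metrics(day_fixes: pd.DataFrame, previous: pd.Series | None = None) -> pd.Series:
    """Movement metrics for one solar day of (subsampled) fixes.

    ``previous`` is the prior day's metric row, used for the turning angle.
    Days with fewer than two fixes become degenerate zero-distance segments.
    """
    lat = day_fixes["lat"].to_numpy(dtype=float)
    lon = day_fixes["lon"].to_numpy(dtype=float)
    date = solar_dates(day_fixes["timestamp"], day_fixes["lon"]).iloc[0]
    degenerate = len(day_fixes) < 2
    if degenerate:
        total = beeline = 0.0
    else:
        total = float(np.sum(rhumb_distance(lat[:-1], lon[:-1], lat[1:], lon[1:])))
        beeline = rhumb_distance(lat[0], lon[0], lat[-1], lon[-1])
    if beeline > 1e-9:
        azimuth = rhumb_bearing(lat[0], lon[0], lat[-1], lon[-1])
    else:
        azimuth = np.nan
    turn = np.nan
    if previous is not None and not np.isnan(azimuth) and not np.isnan(previous["azimuth_deg"]):
        turn = turning_angle(previous["azimuth_deg"], azimuth)
    return pd.Series(
        {
            "date": date,
            "roost_start_lat": lat[0],
            "roost_start_lon": lon[0],
            "roost_end_lat": lat[-1],
            "roost_end_lon": lon[-1],
            "total_distance_km": total,
            "beeline_km": beeline,
            "azimuth_deg": azimuth,
            "turning_angle_deg": turn,
            "degenerate": degenerate,
        }
    )


def classify_day(segment: pd.Series, config: SegmentationConfig) -> str:
    """Threshold rule: migratory iff total > 40 km and/or beeline > 19 km."""
    if (
        segment["total_distance_km"] > config.migratory_total_km
        or segment["beeline_km"] > config.migratory_beeline_km
    ):
        return "migratory"
    return "stopover"


def segment_track(fixes: pd.DataFrame, config: SegmentationConfig | None = None) -> pd.DataFrame:
    """Subsample one individual's fixes and build the per-day segment table."""
    config = config or SegmentationConfig()
    if fixes["individual_id"].nunique() > 1:
        raise ValueError("segment_track expects a single individual")
    sub = subsample_daylight(fixes, config)
    rows: list[pd.Series] = []
    prev: pd.Series | None = None
    dates = solar_dates(sub["timestamp"], sub["lon"]) if not sub.empty else pd.Series(dtype=object)
    for _, day in sub.groupby(dates, sort=True):
        seg = daily_metrics(day, prev)
        seg["day_class"] = classify_day(seg, config)
        rows.append(seg)
        prev = seg
    if not rows:
        return pd.DataFrame(
            columns=[
                "date",
                "roost_start_lat",
                "roost_start_lon",
                "roost_end_lat",
                "roost_end_lon",
                "total_distance_km",
                "beeline_km",
                "azimuth_deg",
                "turning_angle_deg",
                "degenerate",
                "day_class",
            ]
        )
    return pd.DataFrame(rows).reset_index(drop=True)


def _is_northern_longdist(seg: pd.Series, config: SegmentationConfig) -> bool:
    w, e = config.northern_sector
    return seg["beeline_km"] > config.arrival_longdist_km and in_northern_sector(
        seg["azimuth_deg"], w, e
    )


def _detect_death(fixes: pd.DataFrame, config: SegmentationConfig) -> dt.date | None:
    """First instant opening a full window of flat ACC and near-zero movement."""
    acc = fixes["acc_var"].to_numpy(dtype=float)
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    t = _naive_utc(fixes["timestamp"])
    window = np.timedelta64(int(config.death_window_h * 3600), "s")
    # j_end[i]: first index past the window opened at i
    j_end = np.searchsorted(t, t + window, side="left")
    for i in range(len(t)):
        j = j_end[i]
        if j >= len(t) and (len(t) == 0 or t[-1] - t[i] < window):
            break  # stream ends before a full window can be confirmed
        j = min(j, len(t) - 1)
        sl = slice(i, j + 1)
        if np.any(~(acc[sl] < config.death_acc_epsilon)):
            continue
        disp = rhumb_distance(lat[i], lon[i], lat[sl], lon[sl])
        if np.max(disp) < config.death_displacement_km:
            return solar_dates(
                fixes["timestamp"].iloc[[i]], fixes["lon"].iloc[[i]]
            ).iloc[0]
    return None


def _detect_arrival(segments: pd.DataFrame, config: SegmentationConfig) -> int | None:
    """Index of the arrival day, or None."""
    w, e = config.northern_sector
    n = len(segments)
    for d in range(1, n):
        seg = segments.iloc[d]
        turn = seg["turning_angle_deg"]
        ceased = seg["beeline_km"] <= config.arrival_longdist_km or not in_northern_sector(
            seg["azimuth_deg"], w, e
        )
        if not (ceased and not np.isnan(turn) and turn > config.arrival_turn_deg):
            continue
        look = segments.iloc[d + 1 : d + 1 + config.arrival_lookahead_days]
        if any(_is_northern_longdist(row, config) for _, row in look.iterrows()):
            continue
        return d
    return None


def detect_endpoint(
    segments: pd.DataFrame, fixes: pd.DataFrame, config: SegmentationConfig | None = None
) -> TrackOutcome:
    """Decide arrival / death / loss for one track.

    Death is scanned on the raw fixes (ACC flatline + near-zero displacement
    over a sustained window); arrival on the daily segments.  If both rules
    fire, the earlier date wins, ties resolving to death.
    """
    config = config or SegmentationConfig()
    if segments.empty:
        ts = fixes["timestamp"].min() if not fixes.empty else None
        date = None if ts is None else solar_dates(fixes["timestamp"].iloc[[0]], fixes["lon"].iloc[[0]]).iloc[0]
        return TrackOutcome("loss", date)
    death_date = _detect_death(fixes, config)
    arr_idx = _detect_arrival(segments, config)
    arrival_date = None if arr_idx is None else segments["date"].iloc[arr_idx]
    if death_date is not None and (arrival_date is None or death_date <= arrival_date):
        last = fixes.iloc[-1]
        return TrackOutcome("death", death_date, float(last["lat"]), float(last["lon"]))
    if arr_idx is not None:
        prev = segments.iloc[arr_idx - 1]
        return TrackOutcome(
            "arrival", arrival_date, float(prev["roost_end_lat"]), float(prev["roost_end_lon"])
        )
    last = fixes.iloc[-1]
    last_date = solar_dates(fixes["timestamp"].iloc[[-1]], fixes["lon"].iloc[[-1]]).iloc[0]
    return TrackOutcome("loss", last_date)


def migration_summary(
    segments: pd.DataFrame,
    outcome: TrackOutcome,
    capture_point: tuple[float, float],
    winter_point: tuple[float, float] | None = None,
    breeding_point: tuple[float, float] | None = None,
) -> MigrationSummary:
    """Distance accounting for one track.

    Post-stopover migration distance sums daily total path length over days
    classified migratory before the endpoint.  The total migration distance
    (wintering -> capture stopover -> breeding beelines) is only defined when
    both remote sites are known; requesting it with a breeding site on a
    non-arrival track yields a missing value with a warning.
    """
    if outcome.endpoint in ("arrival", "death") and outcome.endpoint_date is not None:
        pre = segments[segments["date"] < outcome.endpoint_date]
    else:
        pre = segments
    migratory = pre[pre["day_class"] == "migratory"]
    post_eilat = float(migratory["total_distance_km"].sum())
    total = float("nan")
    if breeding_point is not None and outcome.endpoint != "arrival":
        warnings.warn("breeding point supplied for a non-arrival track; total distance left missing")
        breeding_point = None
    if winter_point is not None and breeding_point is not None:
        total = rhumb_distance(*winter_point, *capture_point) + rhumb_distance(
            *capture_point, *breeding_point
        )
    dist_death = days_death = float("nan")
    if outcome.endpoint == "death":
        dist_death = rhumb_distance(*capture_point, outcome.endpoint_lat, outcome.endpoint_lon)
        if not segments.empty and outcome.endpoint_date is not None:
            days_death = float((outcome.endpoint_date - segments["date"].iloc[0]).days)
    return MigrationSummary(
        post_eilat_distance_km=post_eilat,
        n_migratory_days=int((pre["day_class"] == "migratory").sum()),
        n_stopover_days=int((pre["day_class"] == "stopover").sum()),
        total_migration_distance_km=total,
        distance_until_death_km=dist_death,
        days_until_death=days_death,
    )


def survival_rate(outcomes: list[TrackOutcome]) -> dict:
    """Survival proportion among tracked birds with a resolved fate.

    Individuals whose tags lost connection are excluded; survivors are those
    that completed migration (arrival endpoint).  Returns counts and the
    percentage of survivors.
    """
    resolved = [o for o in outcomes if o.endpoint in ("arrival", "death")]
    n_surv = sum(o.endpoint == "arrival" for o in resolved)
    pct = float("nan") if not resolved else 100.0 * n_surv / len(resolved)
    return {"n_tracked": len(resolved), "n_survived": n_surv, "survival_pct": pct}
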