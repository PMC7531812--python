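"""Traditional frequency-based home-location methods and their migration rule.

Prior work infers migration by assigning each user a *monthly home* — the
location maximising some activity statistic that month — and flagging a
migration when the home changes between (runs of) months.  Six statistics
are implemented:

1. number of events;
2. number of distinct days with events;
3. number of events in the night window (7 p.m.–9 a.m.);
4. events aggregated over all towers within 1,000 m of each tower
   (requires tower coordinates);
5. method 4 restricted to the night window;
6. hierarchical modes: hourly modal location → daily mode of hourly
   modes → monthly mode of daily modes.

These serve as comparators for the segment-based detector; they have no
day resolution, so a baseline migration is dated to a month boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .events import MigrationEvent
from .io import DEFAULT_EPOCH, TowerSite, TraceIOError

EARTH_RADIUS_M = 6_371_008.8

NIGHT_START_HOUR = 19  # events at hour >= 19 or hour < 9 count as "night"
NIGHT_END_HOUR = 9


@dataclass
class MonthlyHomeSeries:
    """Per-user month → home location, as produced by one baseline method.

    ``homes`` maps a calendar month (``pandas.Period``, freq ``M``) to a
    location id, or ``None`` for months whose share of active days fell
    below ``min_month_prop``.  Months with no events at all are absent.
    """

    user_id: str
    method_id: int
    min_month_prop: float = 0.0
    homes: dict[pd.Period, str | None] = field(default_factory=dict)


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres between coordinate arrays (degrees)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def aggregate_tower_counts(
    counts: Mapping[str, int],
    towers: Iterable[TowerSite],
    radius_m: float = 1000.0,
) -> dict[str, int]:
    """Sum each tower's count with the counts of all towers within ``radius_m``.

    The perimeter is inclusive and contains the tower itself, so a tower's
    aggregated count is at least its own, and two towers within the radius
    contribute to each other symmetrically.
    """
    sites = sorted(counts)
    coords = {t.site_id: (t.lat, t.lon) for t in towers}
    missing = [s for s in sites if s not in coords]
    if missing:
        raise TraceIOError(f"no coordinates for counted sites: {missing}")
    lat = np.array([coords[s][0] for s in sites])
    lon = np.array([coords[s][1] for s in sites])
    vals = np.array([counts[s] for s in sites], dtype=float)
    dist = haversine_m(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    within = dist <= radius_m
    agg = within @ vals
    return {s: int(round(v)) for s, v in zip(sites, agg)}


def _argmax_key(stat: Mapping[str, float], raw_counts: Mapping[str, float]) -> str:
    """Deterministic argmax: statistic, then raw event count, then smallest id."""
    return min(stat, key=lambda k: (-stat[k], -raw_counts.get(k, 0), k))


def _night_mask(ts: pd.Series) -> pd.Series:
    hour = ts.dt.hour
    return (hour >= NIGHT_START_HOUR) | (hour < NIGHT_END_HOUR)


def _home_modal_hierarchy(month_df: pd.DataFrame) -> str:
    """Method 6: hourly modal location → daily mode of those → monthly mode."""
    df = month_df.copy()
    df["date"] = df["timestamp"].dt.date
    df["hour"] = df["timestamp"].dt.hour
    raw_month = df["location_id"].value_counts().to_dict()
    daily_modes: dict[date, str] = {}
    for day, day_df in df.groupby("date"):
        raw_day = day_df["location_id"].value_counts().to_dict()
        hourly_modes = []
        for _, hour_df in day_df.groupby("hour"):
            counts = hour_df["location_id"].value_counts().to_dict()
            hourly_modes.append(_argmax_key(counts, counts))
        mode_counts = pd.Series(hourly_modes).value_counts().to_dict()
        daily_modes[day] = _argmax_key(mode_counts, raw_day)
    month_mode_counts = pd.Series(list(daily_modes.values())).value_counts().to_dict()
    return _argmax_key(month_mode_counts, raw_month)


def _home_for_month(
    month_df: pd.DataFrame,
    method_id: int,
    towers: Iterable[TowerSite] | None,
) -> str | None:
    raw = month_df["location_id"].value_counts().to_dict()
    if method_id in (3, 5):
        active = month_df[_night_mask(month_df["timestamp"])]
        if active.empty:
            return None
    else:
        active = month_df

    if method_id in (1, 3):
        stat = active["location_id"].value_counts().to_dict()
        return _argmax_key(stat, raw)
    if method_id == 2:
        stat = (
            active.assign(d=active["timestamp"].dt.date)
            .groupby("location_id")["d"]
            .nunique()
            .to_dict()
        )
        return _argmax_key(stat, raw)
    if method_id in (4, 5):
        if towers is None:
            raise TraceIOError(f"method {method_id} requires tower coordinates")
        if "site_id" not in active.columns or active["site_id"].isna().any():
            raise TraceIOError(f"method {method_id} requires site_id on every record")
        site_counts = active["site_id"].value_counts().to_dict()
        agg = aggregate_tower_counts(site_counts, towers)
        best_site = _argmax_key(agg, site_counts)
        site_to_loc = {t.site_id: t.location_id for t in towers}
        return site_to_loc[best_site]
    if method_id == 6:
        return _home_modal_hierarchy(month_df)
    raise ValueError(f"unknown baseline method id: {method_id}")


def monthly_home(
    records: pd.DataFrame,
    towers: Iterable[TowerSite] | None = None,
    method_id: int = 2,
    min_month_prop: float = 0.0,
) -> MonthlyHomeSeries:
    """Monthly home locations for a single user's resolved records.

    Months whose share of days with at least one event is below
    ``min_month_prop`` are left undefined (``None``); the share uses the
    month's calendar length as denominator.
    """
    users = records["user_id"].unique()
    if len(users) != 1:
        raise ValueError(f"monthly_home expects one user's records, got {len(users)} users")
    series = MonthlyHomeSeries(
        user_id=str(users[0]), method_id=method_id, min_month_prop=min_month_prop
    )
    months = records["timestamp"].dt.tz_localize(None).dt.to_period("M")
    for month, month_df in records.groupby(months):
        n_active_days = month_df["timestamp"].dt.date.nunique()
        if n_active_days / month.days_in_month < min_month_prop:
            series.homes[month] = None
            continue
        series.homes[month] = _home_for_month(month_df, method_id, towers)
    return series


def monthly_homes(
    records: pd.DataFrame,
    towers: Iterable[TowerSite] | None = None,
    method_id: int = 2,
    min_month_prop: float = 0.0,
) -> dict[str, MonthlyHomeSeries]:
    """:func:`monthly_home` applied per user over a multi-user record table."""
    return {
        str(user): monthly_home(grp, towers, method_id, min_month_prop)
        for user, grp in records.groupby("user_id", sort=True)
    }


def detect_frequency_migrations(
    series: MonthlyHomeSeries,
    k_months: int = 1,
    epoch: date = DEFAULT_EPOCH,
) -> list[MigrationEvent]:
    """Emit a migration whenever a ≥``k_months`` run of one home is followed
    immediately by a ≥``k_months`` run of a different home.

    ``k_months=1`` is the classic "home changed between subsequent months"
    rule.  Undefined months (below the activity threshold, or absent
    entirely) break runs.  The migration date is the last day of the final
    origin month; events carry no segments.
    """
    if k_months < 1:
        raise ValueError(f"k_months must be >= 1, got {k_months}")
    # maximal runs of consecutive, defined, same-home months
    runs: list[tuple[str, pd.Period, pd.Period]] = []  # (home, first, last)
    for month in sorted(series.homes):
        home = series.homes[month]
        if home is None:
            continue
        if runs and runs[-1][0] == home and month == runs[-1][2] + 1:
            runs[-1] = (home, runs[-1][1], month)
        else:
            runs.append((home, month, month))
    events: list[MigrationEvent] = []
    for (h1, f1, l1), (h2, f2, l2) in zip(runs, runs[1:]):
        if h1 == h2 or f2 != l1 + 1:
            continue
        len1 = (l1 - f1).n + 1
        len2 = (l2 - f2).n + 1
        if len1 < k_months or len2 < k_months:
            continue
        last_day = l1.end_time.date()
        migration_day = (last_day - epoch).days
        events.append(
            MigrationEvent(
                user_id=series.user_id,
                origin_location=h1,
                destination_location=h2,
                migration_day=migration_day,
                uncertainty_gap_days=0,
            )
        )
    return events
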