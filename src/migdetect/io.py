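"""Reading, validating and normalising raw trace records.

A *trace record* is one timestamped observation of one user: a call-detail
record, a geo-tagged post, or any other event that places a user at a
location at an instant.  Locations are opaque identifiers for pre-existing
administrative units (districts, cities, ...); when the raw data carries
only a tower/site id, a site→location mapping table resolves it.

The central derived structure is the *daily presence* of a user: for each
calendar day on which the user was observed at all, the set of locations
observed that day.  Days are represented as integer indices — days since a
configurable epoch date, with calendar days taken in a single configured
timezone — so that all downstream arithmetic is plain integer arithmetic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DEFAULT_EPOCH = date(1970, 1, 1)
DEFAULT_TZ = "UTC"

RECORD_COLUMNS = ["user_id", "timestamp", "location_id"]


class TraceIOError(ValueError):
    """Raised for malformed or unresolvable trace inputs."""


@dataclass(frozen=True)
class SchemaConfig:
    """Column names, timezone and tolerance settings for record ingestion.

    Parameters
    ----------
    user_col, time_col, location_col, site_col:
        Column names in the input CSV.  Exactly one of ``location_col`` /
        ``site_col`` must be present in the file; if only ``site_col`` is
        present a tower table is needed to resolve locations.
    timezone:
        IANA timezone in which calendar days are taken.  Defaults to UTC.
    epoch:
        Day-index origin; day ``0`` is this date.
    bad_row_tolerance:
        Maximum tolerated fraction of rows with unparseable timestamps or
        missing fields.  Above it, ingestion fails hard.
    study_start, study_end:
        Optional inclusive date bounds; records outside are dropped (and
        counted as malformed for tolerance purposes they are *not* — they
        are reported separately).
    """

    user_col: str = "user_id"
    time_col: str = "timestamp"
    location_col: str = "location_id"
    site_col: str = "site_id"
    timezone: str = DEFAULT_TZ
    epoch: date = DEFAULT_EPOCH
    bad_row_tolerance: float = 0.0
    study_start: date | None = None
    study_end: date | None = None


@dataclass(frozen=True)
class TowerSite:
    """A cell tower / observation site with coordinates and its admin unit."""

    site_id: str
    lat: float
    lon: float
    location_id: str

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise TraceIOError(f"latitude out of range for site {self.site_id!r}: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise TraceIOError(f"longitude out of range for site {self.site_id!r}: {self.lon}")


@dataclass
class DailyPresence:
    """Per-user mapping from day index to the set of locations seen that day."""

    user_id: str
    presence: dict[int, frozenset[str]] = field(default_factory=dict)

    def days(self) -> list[int]:
        return sorted(self.presence)

    def appearance_days(self, location_id: str) -> list[int]:
        """Sorted days on which this user was observed at ``location_id``."""
        return sorted(d for d, locs in self.presence.items() if location_id in locs)

    def locations(self) -> set[str]:
        out: set[str] = set()
        for locs in self.presence.values():
            out |= locs
        return out

    def n_entries(self) -> int:
        """Number of distinct (day, location) presence entries."""
        return sum(len(locs) for locs in self.presence.values())


# ---------------------------------------------------------------------------
# Record ingestion


def read_records(path: str | Path, schema: SchemaConfig | None = None) -> pd.DataFrame:
    """Read raw trace records from CSV into a normalised DataFrame.

    Returns a DataFrame with columns ``user_id``, ``timestamp`` (tz-aware,
    localised to ``schema.timezone``) and whichever of ``location_id`` /
    ``site_id`` the file provides, sorted by ``(user_id, timestamp)``.
    The number of dropped malformed rows is stored in
    ``df.attrs["n_malformed"]``.
    """
    schema = schema or SchemaConfig()
    path = Path(path)
    if not path.exists():
        raise TraceIOError(f"records file not found: {path}")
    raw = pd.read_csv(path, dtype=str)
    for col in (schema.user_col, schema.time_col):
        if col not in raw.columns:
            raise TraceIOError(f"required column {col!r} missing from {path}")
    has_loc = schema.location_col in raw.columns
    has_site = schema.site_col in raw.columns
    if not has_loc and not has_site:
        raise TraceIOError(
            f"neither {schema.location_col!r} nor {schema.site_col!r} present in {path}"
        )

    df = pd.DataFrame({"user_id": raw[schema.user_col].astype(str)})
    try:
        ts = pd.to_datetime(raw[schema.time_col], errors="coerce", format="ISO8601")
    except (ValueError, TypeError):
        ts = pd.to_datetime(raw[schema.time_col], errors="coerce", utc=True, format="ISO8601")
    if ts.dt.tz is None:
        # naive stamps are wall-clock times in the configured zone
        ts = ts.dt.tz_localize(schema.timezone, nonexistent="NaT", ambiguous="NaT")
    df["timestamp"] = ts.dt.tz_convert(schema.timezone)
    if has_loc:
        df["location_id"] = raw[schema.location_col]
    if has_site:
        df["site_id"] = raw[schema.site_col]

    key_cols = [c for c in ("location_id", "site_id") if c in df.columns]
    bad = df["timestamp"].isna() | raw[schema.user_col].isna()
    bad |= df[key_cols].isna().all(axis=1)
    n_bad = int(bad.sum())
    if len(df) > 0 and n_bad / len(df) > schema.bad_row_tolerance:
        raise TraceIOError(
            f"{n_bad}/{len(df)} malformed rows exceeds tolerance "
            f"{schema.bad_row_tolerance:g} in {path}"
        )
    df = df.loc[~bad]

    if schema.study_start is not None:
        df = df[df["timestamp"].dt.date >= schema.study_start]
    if schema.study_end is not None:
        df = df[df["timestamp"].dt.date <= schema.study_end]

    df = df.sort_values(["user_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    df.attrs["n_malformed"] = n_bad
    return df


def read_towers(path: str | Path) -> list[TowerSite]:
    """Read a ``site_id,lat,lon,location_id`` CSV into TowerSite objects."""
    path = Path(path)
    if not path.exists():
        raise TraceIOError(f"tower file not found: {path}")
    df = pd.read_csv(path, dtype={"site_id": str, "location_id": str})
    for col in ("site_id", "lat", "lon", "location_id"):
        if col not in df.columns:
            raise TraceIOError(f"required column {col!r} missing from {path}")
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise TraceIOError(f"duplicate site ids in {path}: {dups}")
    return [
        TowerSite(str(r.site_id), float(r.lat), float(r.lon), str(r.location_id))
        for r in df.itertuples(index=False)
    ]


def resolve_sites(
    records: pd.DataFrame, towers: Iterable[TowerSite] | Mapping[str, str] | None
) -> pd.DataFrame:
    """Fill ``location_id`` from ``site_id`` using a tower table or mapping.

    Records that already carry a ``location_id`` are left untouched.
    """
    df = records.copy()
    if "location_id" not in df.columns:
        df["location_id"] = pd.NA
    need = df["location_id"].isna()
    if not need.any():
        return df
    if "site_id" not in df.columns:
        raise TraceIOError("records lack location_id and have no site_id to resolve")
    if towers is None:
        raise TraceIOError("site ids present but no site→location mapping supplied")
    if isinstance(towers, Mapping):
        site_map = dict(towers)
    else:
        site_map = {t.site_id: t.location_id for t in towers}
    resolved = df.loc[need, "site_id"].map(site_map)
    missing = df.loc[need, "site_id"][resolved.isna()].unique().tolist()
    if missing:
        raise TraceIOError(f"unresolvable site ids: {sorted(missing)}")
    df.loc[need, "location_id"] = resolved
    return df


# ---------------------------------------------------------------------------
# Day indexing and daily presence


def day_index(timestamps: pd.Series, epoch: date = DEFAULT_EPOCH) -> pd.Series:
    """Integer day index (local calendar date minus epoch) of tz-aware timestamps."""
    dates = timestamps.dt.tz_localize(None).dt.normalize()
    return ((dates - pd.Timestamp(epoch)) // pd.Timedelta(days=1)).astype(int)


def day_to_date(day: int, epoch: date = DEFAULT_EPOCH) -> date:
    return (pd.Timestamp(epoch) + pd.Timedelta(days=int(day))).date()


def build_daily_presence(
    records: pd.DataFrame,
    towers: Iterable[TowerSite] | Mapping[str, str] | None = None,
    epoch: date = DEFAULT_EPOCH,
) -> dict[str, DailyPresence]:
    """Collapse resolved records into one :class:`DailyPresence` per user.

    A day is present for a user iff at least one record fell on that local
    calendar day; multiple locations on one day are kept as a set and
    duplicate (user, day, location) triples collapse.  The result is
    independent of input record order.
    """
    df = resolve_sites(records, towers)
    if df.empty:
        return {}
    days = day_index(df["timestamp"], epoch)
    triples = pd.DataFrame(
        {"user_id": df["user_id"].to_numpy(), "day": days.to_numpy(),
         "location_id": df["location_id"].to_numpy()}
    ).drop_duplicates()
    out: dict[str, DailyPresence] = {}
    for user, grp in triples.groupby("user_id", sort=True):
        presence = {
            int(day): frozenset(sub["location_id"])
            for day, sub in grp.groupby("day", sort=True)
        }
        out[str(user)] = DailyPresence(user_id=str(user), presence=presence)
    return out


# ---------------------------------------------------------------------------
# Presence CSV round trip


def write_presence_csv(
    presences: Mapping[str, DailyPresence], path: str | Path, epoch: date = DEFAULT_EPOCH
) -> None:
    """Write presence as ``user_id,day,location_id`` rows, day as ISO date."""
    rows = []
    for user in sorted(presences):
        dp = presences[user]
        for day in dp.days():
            for loc in sorted(dp.presence[day]):
                rows.append((user, day_to_date(day, epoch).isoformat(), loc))
    pd.DataFrame(rows, columns=["user_id", "day", "location_id"]).to_csv(path, index=False)


def read_presence_csv(path: str | Path, epoch: date = DEFAULT_EPOCH) -> dict[str, DailyPresence]:
    """Inverse of :func:`write_presence_csv`."""
    df = pd.read_csv(path, dtype={"user_id": str, "location_id": str})
    for col in ("user_id", "day", "location_id"):
        if col not in df.columns:
            raise TraceIOError(f"required column {col!r} missing from {path}")
    df["day_idx"] = (
        (pd.to_datetime(df["day"]) - pd.Timestamp(epoch)) // pd.Timedelta(days=1)
    ).astype(int)
    out: dict[str, DailyPresence] = {}
    for user, grp in df.groupby("user_id", sort=True):
        presence = {
            int(day): frozenset(sub["location_id"])
            for day, sub in grp.groupby("day_idx", sort=True)
        }
        out[str(user)] = DailyPresence(user_id=str(user), presence=presence)
    return out


def presence_to_frame(presences: Mapping[str, DailyPresence]) -> pd.DataFrame:
    """Long-form DataFrame of (user_id, day, location_id) presence triples."""
    rows = [
        (user, day, loc)
        for user, dp in presences.items()
        for day in dp.days()
        for loc in sorted(dp.presence[day])
    ]
    return pd.DataFrame(rows, columns=["user_id", "day", "location_id"])
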