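"""Seeded synthetic trace cohorts with known migration ground truth.

Real labelled trajectories from phone or social-media data cannot be
shipped, so every detector here is exercised against generated cohorts
whose truth is known by construction.  Four behavioural profiles cover the
regimes that matter for migration detection:

``stayer``
    one home location for the whole panel — the true negative;
``migrant``
    origin up to and including a known migration day, destination after —
    the true positive, with an exact date to recover;
``commuter``
    every active day drawn between two fixed locations (the border-commuter
    pattern that frequency-based methods mistake for migration);
``tripper``
    home with one contiguous away interval shorter than the residency
    threshold (a displacement, not a migration).

Observation sparsity (``p_obs``), multi-location noise days (``p_noise``)
and event volume are configurable; generation is deterministic given
``(seed, user_index)`` via independent RNG substreams, so cohorts are
reproducible regardless of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DEFAULT_EPOCH, TowerSite

PROFILES = ("stayer", "migrant", "commuter", "tripper")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a moderately sparse, moderately noisy cohort: a
    400-day panel, a 70% chance of any trace on a given day, a 10% chance
    that an active day also shows a spurious second location, and about
    three events per active day — roughly the texture of call-detail
    records for a regularly active subscriber.
    """

    n_users: int = 500
    n_days: int = 400
    locations: tuple[str, ...] = ("L00", "L01", "L02", "L03", "L04")
    p_obs: float = 0.7
    events_per_active_day: int = 3
    p_noise: float = 0.1
    profile: str = "stayer"
    migration_day_range: tuple[int, int] | None = None  # default: middle half of the panel
    trip_length_days: int = 30
    commuter_split: float = 0.5
    night_bias: float = 0.0  # fraction of events forced into the 19h–9h window
    seed: int = 0
    epoch: date = DEFAULT_EPOCH

    def __post_init__(self) -> None:
        for name in ("p_obs", "p_noise", "commuter_split", "night_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; expected one of {PROFILES}")
        if self.migration_day_range is None:
            object.__setattr__(
                self, "migration_day_range", (self.n_days // 4, 3 * self.n_days // 4)
            )
        lo, hi = self.migration_day_range
        if not (0 < lo <= hi < self.n_days - 1):
            raise ValueError(
                f"migration_day_range {self.migration_day_range} must lie strictly "
                f"inside the {self.n_days}-day panel"
            )
        if len(self.locations) < 2:
            raise ValueError("need at least two locations")
        if self.events_per_active_day < 1:
            raise ValueError("events_per_active_day must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """What actually happened to one synthetic user."""

    user_id: str
    profile: str
    is_migrant: bool
    true_origin: str | None = None
    true_destination: str | None = None
    true_migration_day: int | None = None


def _rng_for_user(seed: int, user_index: int) -> np.random.Generator:
    # independent substream per user: reproducible under any generation order
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(user_index,)))


def _daily_locations(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[dict[int, str], GroundTruth, str]:
    """Primary location per panel day (0-based), plus the user's truth."""
    locs = list(cfg.locations)
    if cfg.profile == "stayer":
        home = locs[rng.integers(len(locs))]
        return {d: home for d in range(cfg.n_days)}, ("stayer", False, None, None, None), home
    if cfg.profile == "migrant":
        origin, dest = rng.choice(len(locs), size=2, replace=False)
        origin, dest = locs[origin], locs[dest]
        lo, hi = cfg.migration_day_range
        mday = int(rng.integers(lo, hi + 1))
        daily = {d: (origin if d <= mday else dest) for d in range(cfg.n_days)}
        return daily, ("migrant", True, origin, dest, mday), origin
    if cfg.profile == "commuter":
        a, b = rng.choice(len(locs), size=2, replace=False)
        a, b = locs[a], locs[b]
        daily = {
            d: (a if rng.random() < cfg.commuter_split else b) for d in range(cfg.n_days)
        }
        return daily, ("commuter", False, None, None, None), a
    # tripper
    home_i, away_i = rng.choice(len(locs), size=2, replace=False)
    home, away = locs[home_i], locs[away_i]
    trip_start = int(rng.integers(1, cfg.n_days - cfg.trip_length_days - 1))
    daily = {
        d: (away if trip_start <= d < trip_start + cfg.trip_length_days else home)
        for d in range(cfg.n_days)
    }
    return daily, ("tripper", False, None, None, None), home


def _event_times(rng: np.random.Generator, n: int, night_bias: float) -> np.ndarray:
    """Seconds-of-day for ``n`` events, optionally biased into the night window."""
    secs = rng.uniform(0, 86400, size=n)
    if night_bias > 0:
        # night window covers 19:00–24:00 and 00:00–09:00 (14 h of the day)
        night = rng.random(n) < night_bias
        night_secs = rng.uniform(0, 14 * 3600, size=n)
        night_secs = np.where(night_secs < 5 * 3600, night_secs + 19 * 3600, night_secs - 5 * 3600)
        secs = np.where(night, night_secs, secs)
    return secs


def generate_trace(
    config: GeneratorConfig, user_index: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """One user's records and ground truth, deterministic under (seed, user_index).

    Days are observed independently with probability ``p_obs``; an active
    day yields ``events_per_active_day`` events (all at that day's primary
    location) plus, with probability ``p_noise``, one extra event at a
    random other location the same day.
    """
    rng = _rng_for_user(config.seed, user_index)
    user_id = f"U{user_index:05d}"
    daily, (profile, is_migrant, origin, dest, mday), _ = _daily_locations(config, rng)
    truth = GroundTruth(
        user_id=user_id,
        profile=profile,
        is_migrant=is_migrant,
        true_origin=origin,
        true_destination=dest,
        # ground-truth day on the package's day-index scale (epoch offset applied)
        true_migration_day=None if mday is None else mday,
    )

    active = rng.random(config.n_days) < config.p_obs
    rows_day: list[int] = []
    rows_loc: list[str] = []
    locs = list(config.locations)
    for d in range(config.n_days):
        if not active[d]:
            continue
        n_ev = config.events_per_active_day
        rows_day.extend([d] * n_ev)
        rows_loc.extend([daily[d]] * n_ev)
        if rng.random() < config.p_noise:
            others = [l for l in locs if l != daily[d]]
            rows_day.append(d)
            rows_loc.append(others[rng.integers(len(others))])

    secs = _event_times(rng, len(rows_day), config.night_bias)
    base = pd.Timestamp(config.epoch, tz="UTC")
    timestamps = base + pd.to_timedelta(np.array(rows_day) * 86400 + np.floor(secs), unit="s")
    records = pd.DataFrame(
        {"user_id": user_id, "timestamp": timestamps, "location_id": rows_loc}
    ).sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    return records, truth


def generate_cohort(
    config: GeneratorConfig,
    profile_mix: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A cohort of ``n_users`` traces with profiles in stated proportions.

    Profile counts use largest-remainder allocation, so a 50% share of an
    even cohort is exactly half.  Returns the concatenated records and a
    truth table with one row per user.
    """
    mix = profile_mix if profile_mix is not None else {config.profile: 1.0}
    bad = set(mix) - set(PROFILES)
    if bad:
        raise ValueError(f"unknown profiles in mix: {sorted(bad)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"profile fractions must sum to 1, got {total}")

    profiles = sorted(mix)
    quotas = [mix[p] * config.n_users for p in profiles]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = config.n_users - sum(counts)
    by_frac = sorted(range(len(profiles)), key=lambda i: (-(quotas[i] - counts[i]), profiles[i]))
    for i in by_frac[:remainder]:
        counts[i] += 1

    assignment: list[str] = []
    for p, c in zip(profiles, counts):
        assignment.extend([p] * c)

    all_records: list[pd.DataFrame] = []
    truth_rows: list[GroundTruth] = []
    for user_index, profile in enumerate(assignment):
        cfg = dataclasses.replace(config, profile=profile)
        rec, truth = generate_trace(cfg, user_index)
        all_records.append(rec)
        truth_rows.append(truth)
    records = pd.concat(all_records, ignore_index=True)
    truth = pd.DataFrame([dataclasses.asdict(t) for t in truth_rows])
    return records, truth


def default_towers(
    locations: tuple[str, ...], towers_per_location: int = 2
) -> list[TowerSite]:
    """A deterministic tower layout: locations ~0.5° apart (inter-location
    distances far above 1 km), towers within a location ~500 m apart."""
    towers: list[TowerSite] = []
    for i, loc in enumerate(locations):
        base_lat, base_lon = 0.0, 0.5 * i
        for j in range(towers_per_location):
            towers.append(
                TowerSite(
                    site_id=f"{loc}_T{j}",
                    lat=base_lat + 0.0045 * j,
                    lon=base_lon,
                    location_id=loc,
                )
            )
    return towers


def write_cohort(
    records: pd.DataFrame, truth: pd.DataFrame, records_path: str | Path, truth_path: str | Path
) -> None:
    """Write a cohort to the record/truth CSV forms the CLI consumes."""
    out = records.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(records_path, index=False)
    truth.to_csv(truth_path, index=False)
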