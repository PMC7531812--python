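"""Migration events: residency filtering, date inference, uncertainty.

A migration is a pair of neighbouring segments at different locations where
the user resided at least ``k_days`` (inclusive span) in each — the
residency threshold.  The migration *date* is the day between the end of
the origin segment and the start of the destination segment that minimises
the number of misclassified presence days (destination appearances on or
before the date, origin appearances after it), with ties broken toward the
latest day; on a cleanly split trace this is simply the last day observed
at the origin.  The *uncertainty* of the date is the number of wholly
unobserved gap days between the two segments.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .io import DailyPresence
from .segments import Segment


@dataclass(frozen=True)
class ResidencyParams:
    """Minimum residency duration for both ends of a migration.

    ``k_days=90`` treats a three-month stay as residence; larger values
    restrict to longer-term migration, smaller ones admit shorter moves.
    """

    k_days: int = 90

    def __post_init__(self) -> None:
        if self.k_days < 1:
            raise ValueError(f"k_days must be >= 1, got {self.k_days}")


@dataclass
class MigrationEvent:
    """An origin→destination move with inferred date and gap-day uncertainty.

    ``migration_day`` is the last day of residence at the origin; it lies
    in ``[origin_segment.end_day, destination_segment.start_day]``.
    Frequency-baseline events carry ``None`` segments (they have no
    day-resolved segment bounds).
    """

    user_id: str
    origin_location: str
    destination_location: str
    migration_day: int
    uncertainty_gap_days: int
    origin_segment: Segment | None = None
    destination_segment: Segment | None = None


def migration_uncertainty(origin: Segment, destination: Segment) -> int:
    """Unobserved gap days between the segments: ``dest.start − origin.end − 1``.

    Zero for segments on adjacent days; larger gaps mean the true move date
    is less well pinned down.
    """
    if origin.end_day > destination.start_day:
        raise ValueError("origin segment ends after destination starts")
    return max(0, destination.start_day - origin.end_day - 1)


def infer_migration_date(
    origin: Segment, destination: Segment, presence: DailyPresence
) -> int:
    """The day minimising misclassified presence days; ties → latest day.

    Candidates are ``t`` in ``[origin.end_day, destination.start_day]``.
    The cost of ``t`` counts origin-location appearance days after ``t``
    plus destination-location appearance days on or before ``t``, both
    within ``[origin.start_day, destination.end_day]`` — days outside both
    segments say nothing about which side of the move a day belongs to.
    """
    if origin.end_day > destination.start_day:
        raise ValueError("origin segment ends after destination starts")
    lo_win, hi_win = origin.start_day, destination.end_day
    origin_days = [
        d for d in presence.appearance_days(origin.location_id) if lo_win <= d <= hi_win
    ]
    dest_days = [
        d for d in presence.appearance_days(destination.location_id) if lo_win <= d <= hi_win
    ]
    best_t = origin.end_day
    best = _misclass(origin_days, dest_days, best_t)
    for t in range(origin.end_day + 1, destination.start_day + 1):
        m = _misclass(origin_days, dest_days, t)
        if m <= best:
            best, best_t = m, t
    return best_t


def _misclass(origin_days: list[int], dest_days: list[int], t: int) -> int:
    return (len(origin_days) - bisect.bisect_right(origin_days, t)) + bisect.bisect_right(
        dest_days, t
    )


def detect_migrations(
    segments: list[Segment],
    presence: DailyPresence,
    params: ResidencyParams | None = None,
) -> list[MigrationEvent]:
    """Turn one user's ordered, non-overlapping segments into migration events.

    Every adjacent pair of segments at different locations whose inclusive
    spans both reach ``k_days`` yields one event; adjacent same-location
    pairs (possible after a middle segment was dropped during overlap
    removal) yield nothing.
    """
    params = params or ResidencyParams()
    for a, b in zip(segments, segments[1:]):
        if b.start_day <= a.end_day or a.start_day > b.start_day:
            raise ValueError(
                f"segments must be chronologically ordered and non-overlapping: "
                f"[{a.start_day},{a.end_day}] then [{b.start_day},{b.end_day}]"
            )
    events: list[MigrationEvent] = []
    for a, b in zip(segments, segments[1:]):
        if a.location_id == b.location_id:
            continue
        if a.span < params.k_days or b.span < params.k_days:
            continue
        events.append(
            MigrationEvent(
                user_id=a.user_id,
                origin_location=a.location_id,
                destination_location=b.location_id,
                migration_day=infer_migration_date(a, b, presence),
                uncertainty_gap_days=migration_uncertainty(a, b),
                origin_segment=a,
                destination_segment=b,
            )
        )
    return events
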