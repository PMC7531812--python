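"""Scoring, parameter tuning, migration-rate series and trajectory rasters.

The harness scores any detector (segment-based or frequency-based) against
ground truth or human labels with the usual four classification criteria,
summarises migration-date errors, sweeps and cross-validates the segment
parameters, computes monthly migration-rate series, and renders the
row-per-location / column-per-day trajectory rasters used throughout for
visual inspection and labelling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import MigrationEvent, ResidencyParams, detect_migrations
from .io import DailyPresence
from .segments import Segment, SegmentParams, detect_segments

# ---------------------------------------------------------------------------
# Classification metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy, precision, recall and F1; ``degenerate`` flags a zero
    denominator in precision or recall (reported as 0, not an error)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def confusion_metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """The four standard criteria from confusion counts.

    accuracy = (TP+TN)/all, precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2·precision·recall/(precision+recall); F1 is 0 when precision and
    recall are both 0.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero scored samples")
    accuracy = (counts.tp + counts.tn) / counts.total
    degenerate = False
    if counts.tp + counts.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return ClassificationMetrics(accuracy, precision, recall, f1, degenerate)


def score_binary(
    predicted: Mapping[str, bool], truth: Mapping[str, bool]
) -> ConfusionCounts:
    """Confusion counts over the users present in ``truth``.

    A user missing from ``predicted`` counts as a non-migrant prediction.
    """
    tp = fp = fn = tn = 0
    for user, is_migrant in truth.items():
        pred = bool(predicted.get(user, False))
        if pred and is_migrant:
            tp += 1
        elif pred and not is_migrant:
            fp += 1
        elif not pred and is_migrant:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# Running the segment detector over a cohort


def detect_cohort(
    presences: Mapping[str, DailyPresence],
    seg_params: SegmentParams | None = None,
    res_params: ResidencyParams | None = None,
) -> dict[str, list[MigrationEvent]]:
    """Segments + migration events for every user in a presence table."""
    seg_params = seg_params or SegmentParams()
    res_params = res_params or ResidencyParams()
    out: dict[str, list[MigrationEvent]] = {}
    for user, presence in presences.items():
        segs = detect_segments(presence, seg_params)
        out[user] = detect_migrations(segs, presence, res_params)
    return out


def truth_migrant_map(truth: pd.DataFrame) -> dict[str, bool]:
    return dict(zip(truth["user_id"].astype(str), truth["is_migrant"].astype(bool)))


# ---------------------------------------------------------------------------
# Label adjudication


def adjudicate_labels(label_table: pd.DataFrame) -> pd.DataFrame:
    """Resolve multiple labelers' judgements per user by majority vote.

    Expects columns ``user_id, labeler_id, is_migrant`` and optionally
    ``migration_day`` and ``confidence``.  The adjudicated migration day is
    the median day among majority-side labelers who dated the move; the
    adjudicated confidence is the mean.
    """
    rows = []
    for user, grp in label_table.groupby("user_id", sort=True):
        votes = grp["is_migrant"].astype(bool)
        is_migrant = votes.sum() * 2 > len(votes)
        day = None
        if is_migrant and "migration_day" in grp.columns:
            dated = grp.loc[votes & grp["migration_day"].notna(), "migration_day"]
            if len(dated):
                day = float(np.median(dated))
        conf = float(grp["confidence"].mean()) if "confidence" in grp.columns else None
        rows.append((user, is_migrant, day, conf))
    return pd.DataFrame(rows, columns=["user_id", "is_migrant", "migration_day", "confidence"])


# ---------------------------------------------------------------------------
# Migration-date error summary


@dataclass
class DateErrorSummary:
    """Distribution of |inferred − true| migration-date errors in days."""

    errors: pd.Series  # index: user_id, values: absolute error in days
    share_within: dict[int, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.errors)

    def histogram(self) -> pd.Series:
        return self.errors.value_counts().sort_index()


def date_error_summary(
    events_by_user: Mapping[str, Sequence[MigrationEvent]],
    truth: pd.DataFrame,
    thresholds: Sequence[int] = (2, 15),
) -> DateErrorSummary:
    """Per-migrant absolute date error, restricted to true positives.

    For users the truth marks as migrants and for whom the detector emitted
    at least one event, the error is |first inferred date − true date|.
    """
    errs = {}
    for row in truth.itertuples(index=False):
        if not bool(row.is_migrant) or pd.isna(row.true_migration_day):
            continue
        events = events_by_user.get(str(row.user_id), [])
        if not events:
            continue
        errs[str(row.user_id)] = abs(events[0].migration_day - int(row.true_migration_day))
    if not errs:
        raise ValueError("no matched migrants to summarise")
    series = pd.Series(errs, dtype=int).sort_index()
    share = {int(t): float((series <= t).mean()) for t in thresholds}
    return DateErrorSummary(errors=series, share_within=share)


# ---------------------------------------------------------------------------
# Parameter sweep and cross-validated tuning


def _f1_for_params(
    presences: Mapping[str, DailyPresence],
    truth_map: Mapping[str, bool],
    seg_params: SegmentParams,
    k_days: int,
    users: Iterable[str] | None = None,
) -> float:
    events = detect_cohort(presences, seg_params, ResidencyParams(k_days=k_days))
    predicted = {u: len(ev) > 0 for u, ev in events.items()}
    if users is not None:
        truth_map = {u: truth_map[u] for u in users}
    return confusion_metrics(score_binary(predicted, truth_map)).f1


def parameter_sweep(
    presences: Mapping[str, DailyPresence],
    truth: pd.DataFrame,
    grid: Sequence[SegmentParams],
    k_days: int = 90,
) -> pd.DataFrame:
    """F1 of the full detector at every grid point, scored against truth."""
    if not grid:
        raise ValueError("empty parameter grid")
    tmap = truth_migrant_map(truth)
    rows = [
        (p.epsilon, p.min_days, p.prop_days, _f1_for_params(presences, tmap, p, k_days))
        for p in grid
    ]
    return pd.DataFrame(rows, columns=["epsilon", "min_days", "prop_days", "f1"])


def make_grid(
    epsilons: Sequence[int], min_days: Sequence[int], prop_days: Sequence[float]
) -> list[SegmentParams]:
    return [
        SegmentParams(epsilon=e, min_days=m, prop_days=p)
        for e, m, p in itertools.product(epsilons, min_days, prop_days)
    ]


@dataclass
class CrossvalResult:
    best_params: SegmentParams
    mean_train_f1: float
    mean_test_f1: float
    fold_test_f1: list[float]
    fold_assignment: dict[str, int]  # user_id -> fold index


def stratified_folds(
    samples: pd.DataFrame, n_folds: int, seed: int = 0
) -> dict[str, int]:
    """Assign each user to a fold, stratified by the ``group`` column.

    Within each stratum users are shuffled deterministically and dealt
    round-robin, so fold sizes differ by at most one per stratum.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for _, grp in samples.groupby("group", sort=True):
        users = sorted(grp["user_id"].astype(str))
        if len(users) < n_folds:
            raise ValueError(
                f"stratum with {len(users)} samples cannot be split into {n_folds} folds"
            )
        order = rng.permutation(len(users))
        for i, idx in enumerate(order):
            assignment[users[idx]] = i % n_folds
    return assignment


def crossval_tune(
    presences: Mapping[str, DailyPresence],
    samples: pd.DataFrame,
    grid: Sequence[SegmentParams],
    k_days: int = 90,
    n_folds: int = 5,
    seed: int = 0,
) -> CrossvalResult:
    """Grid search with stratified k-fold cross-validation.

    ``samples`` carries ``user_id``, ``is_migrant`` and a stratification
    ``group`` tag.  For each fold, the best grid point on the training
    portion is evaluated on the held-out portion; the reported best
    parameters maximise mean training F1 across folds (ties → earliest
    grid point).
    """
    if not grid:
        raise ValueError("empty parameter grid")
    tmap = dict(zip(samples["user_id"].astype(str), samples["is_migrant"].astype(bool)))
    folds = stratified_folds(samples, n_folds, seed)

    # predictions per grid point are fold-independent: compute once
    pred_by_params: list[dict[str, bool]] = []
    for p in grid:
        events = detect_cohort(
            {u: presences[u] for u in tmap}, p, ResidencyParams(k_days=k_days)
        )
        pred_by_params.append({u: len(ev) > 0 for u, ev in events.items()})

    def f1_on(users: list[str], pred: Mapping[str, bool]) -> float:
        sub = {u: tmap[u] for u in users}
        return confusion_metrics(score_binary(pred, sub)).f1

    train_f1 = np.zeros((n_folds, len(grid)))
    test_f1_best: list[float] = []
    for f in range(n_folds):
        train_users = [u for u, fold in folds.items() if fold != f]
        test_users = [u for u, fold in folds.items() if fold == f]
        for gi, pred in enumerate(pred_by_params):
            train_f1[f, gi] = f1_on(train_users, pred)
        best_gi = int(np.argmax(train_f1[f]))
        test_f1_best.append(f1_on(test_users, pred_by_params[best_gi]))

    mean_train = train_f1.mean(axis=0)
    best_overall = int(np.argmax(mean_train))
    return CrossvalResult(
        best_params=grid[best_overall],
        mean_train_f1=float(mean_train[best_overall]),
        mean_test_f1=float(np.mean(test_f1_best)),
        fold_test_f1=[float(x) for x in test_f1_best],
        fold_assignment=folds,
    )


# ---------------------------------------------------------------------------
# Migration-rate series


def migration_rate_series(
    events: Iterable[MigrationEvent],
    active_users_per_month: Mapping[pd.Period, int],
    epoch=None,
) -> pd.Series:
    """Monthly migration rate: events dated in the month / active users.

    Months with zero (or unreported) active users get ``NaN``, not zero —
    an undefined rate is not a zero rate.
    """
    from .io import DEFAULT_EPOCH, day_to_date

    epoch = epoch or DEFAULT_EPOCH
    months = sorted(active_users_per_month)
    counts = {m: 0 for m in months}
    for ev in events:
        m = pd.Period(day_to_date(ev.migration_day, epoch), freq="M")
        if m in counts:
            counts[m] += 1
    vals = [
        counts[m] / active_users_per_month[m] if active_users_per_month[m] > 0 else np.nan
        for m in months
    ]
    return pd.Series(vals, index=pd.PeriodIndex(months, freq="M"), name="migration_rate")


def active_users_by_month(
    presences: Mapping[str, DailyPresence], epoch=None
) -> dict[pd.Period, int]:
    """Number of users with any presence in each calendar month."""
    from .io import DEFAULT_EPOCH, day_to_date

    epoch = epoch or DEFAULT_EPOCH
    out: dict[pd.Period, set] = {}
    for user, dp in presences.items():
        for day in dp.presence:
            m = pd.Period(day_to_date(day, epoch), freq="M")
            out.setdefault(m, set()).add(user)
    return {m: len(users) for m, users in sorted(out.items())}


# ---------------------------------------------------------------------------
# Trajectory rasters


def _ordered_locations(presence: DailyPresence) -> list[str]:
    totals = {loc: len(presence.appearance_days(loc)) for loc in presence.locations()}
    return sorted(totals, key=lambda loc: (-totals[loc], loc))


def text_raster(
    presence: DailyPresence,
    events: Sequence[MigrationEvent] | None = None,
    window: tuple[int, int] | None = None,
) -> str:
    """Plain-text raster: one row per location (descending total presence),
    one column per consecutive day; ``#`` marks presence.

    A header records the user and day window so the raster can be parsed
    back into a :class:`DailyPresence`.  If events are given, a final
    marker line carries ``^`` under each migration-date column.
    """
    if not presence.presence:
        raise ValueError("cannot render empty presence")
    days = presence.days()
    lo, hi = window if window is not None else (days[0], days[-1])
    lines = [f"user {presence.user_id}", f"days {lo} {hi}"]
    width = max(len(loc) for loc in presence.locations())
    for loc in _ordered_locations(presence):
        loc_days = set(presence.appearance_days(loc))
        row = "".join("#" if d in loc_days else "." for d in range(lo, hi + 1))
        lines.append(f"{loc.ljust(width)} |{row}|")
    if events:
        marks = {ev.migration_day for ev in events}
        row = "".join("^" if d in marks else " " for d in range(lo, hi + 1))
        lines.append(f"{' ' * width} |{row}|")
    return "\n".join(lines) + "\n"


def parse_text_raster(text: str) -> DailyPresence:
    """Inverse of :func:`text_raster` (the marker line, if any, is ignored)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 3 or not lines[0].startswith("user ") or not lines[1].startswith("days "):
        raise ValueError("not a trajectory raster")
    user_id = lines[0][5:].strip()
    lo, hi = (int(x) for x in lines[1].split()[1:3])
    presence: dict[int, set[str]] = {}
    for line in lines[2:]:
        label, _, row = line.partition("|")
        loc = label.strip()
        row = row.rstrip("|")
        if not loc:  # marker line
            continue
        for offset, ch in enumerate(row):
            if ch == "#":
                presence.setdefault(lo + offset, set()).add(loc)
    return DailyPresence(
        user_id=user_id, presence={d: frozenset(s) for d, s in sorted(presence.items())}
    )


def render_trajectory(
    presence: DailyPresence,
    segments: Sequence[Segment] | None = None,
    events: Sequence[MigrationEvent] | None = None,
    out: str | None = None,
    window: tuple[int, int] | None = None,
):
    """Raster plot of one user's trajectory (rows = locations, columns = days).

    Detected segments are outlined as red boxes and each migration date is
    marked with a vertical orange line.  Returns the matplotlib figure;
    writes it to ``out`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if not presence.presence:
        raise ValueError("cannot render empty presence")
    days = presence.days()
    lo, hi = window if window is not None else (days[0], days[-1])
    locs = _ordered_locations(presence)
    row_of = {loc: i for i, loc in enumerate(locs)}
    grid = np.zeros((len(locs), hi - lo + 1))
    for loc in locs:
        for d in presence.appearance_days(loc):
            if lo <= d <= hi:
                grid[row_of[loc], d - lo] = 1.0

    fig, ax = plt.subplots(figsize=(max(6, (hi - lo + 1) / 40), 1 + 0.4 * len(locs)))
    ax.imshow(grid, aspect="auto", cmap="Greys", interpolation="none", vmin=0, vmax=1)
    ax.set_yticks(range(len(locs)), locs)
    ax.set_xlabel(f"day index ({lo}..{hi})")
    ax.set_title(f"user {presence.user_id}")
    if segments:
        for seg in segments:
            if seg.location_id not in row_of:
                continue
            r = row_of[seg.location_id]
            ax.add_patch(
                Rectangle(
                    (seg.start_day - lo - 0.5, r - 0.5),
                    seg.span,
                    1.0,
                    fill=False,
                    edgecolor="red",
                    linewidth=1.5,
                )
            )
    if events:
        for ev in events:
            ax.axvline(ev.migration_day - lo, color="orange", linewidth=1.5)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig
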