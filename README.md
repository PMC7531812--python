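# migdetect

Segment-based detection of **migration events** in spatiotemporal digital-trace
data — call-detail records (CDR), geo-tagged social-media posts, or any event
stream in which each record carries a user id, a timestamp, and a location.

Demographers and epidemiologists increasingly estimate internal and
international migration from such by-product data. The common
*frequency-based* recipe — assign each user a modal "home" location per
month, call any month-to-month change a migration — is fragile: it flags
border commuters who routinely appear in two neighbouring districts, misses
movers whose monthly mode is distorted by travel, and cannot date a move to
better than a month. `migdetect` implements a *segment-based* alternative
that works at daily resolution, plus those six traditional baselines, a
ground-truthed synthetic trajectory generator, and an evaluation and tuning
harness.

## The method

For each user, raw records are collapsed to **daily presence**: for every
calendar day, the set of locations observed that day. Segments of continuous
residence are then detected in three steps:

1. **Contiguous segments.** Per location, appearance days are clustered,
   splitting wherever consecutive appearance days differ by more than
   *ε* days. A cluster spanning *[first, last]* is kept iff the user was
   seen there on at least *propDays* of the spanned days and the span is at
   least *minDays* days long.
2. **Merge.** Neighbouring same-location segments merge when no segment of
   another location lies between them.
3. **Overlap removal.** When segments of two locations overlap in time, the
   boundary day *t\** minimising the number of *misclassified days* —
   origin-location appearances after *t* plus destination-location
   appearances on or before *t* — cuts the overlap (ties resolved toward
   the latest day).

A **migration event** is a pair of neighbouring segments at different
locations, each spanning at least the residency threshold *k* days
(default 90). Its **date** is inferred with the same misclassified-days
criterion over the window between the segments, and its **uncertainty** is
the number of unobserved gap days between the truncated origin segment's end
and the destination segment's start. Defaults: ε = 7, minDays = 30,
propDays = 0.6, k = 90.

## Worked example

```python
from migdetect import (GeneratorConfig, generate_trace, build_daily_presence,
                       detect_segments, detect_migrations, day_to_date)

cfg = GeneratorConfig(n_users=1, n_days=200, p_obs=0.75, p_noise=0.05,
                      profile="migrant", migration_day_range=(95, 105), seed=3)
records, truth = generate_trace(cfg, 0)          # one synthetic migrant
presence = build_daily_presence(records)[truth.user_id]
segments = detect_segments(presence)             # ε=7, minDays=30, propDays=0.6
events = detect_migrations(segments, presence)   # k=90

for s in segments:
    print(f"segment {s.location_id}: days {s.start_day}-{s.end_day} "
          f"({s.n_days}/{s.span} days observed)")
for e in events:
    print(f"migration {e.origin_location} -> {e.destination_location} on day "
          f"{e.migration_day} ({day_to_date(e.migration_day)}), "
          f"gap uncertainty {e.uncertainty_gap_days} day(s)")
print(f"true migration day: {truth.true_migration_day}")
```

```
segment L04: days 1-99 (73/99 days observed)
segment L02: days 100-198 (71/99 days observed)
migration L04 -> L02 on day 99 (1970-04-10), gap uncertainty 0 day(s)
true migration day: 99
```

Despite observing only ~75% of days and occasional spurious second
locations, the detector recovers two residence segments, the move between
them, and the exact move day; the zero gap says the date is well pinned
down.

The same pipeline is available from the shell:

```bash
migdetect simulate --config sim.yaml --out records.csv --truth truth.csv
migdetect ingest   --records records.csv --tz UTC --out presence.csv
migdetect segments --presence presence.csv --out segments.csv
migdetect detect   --segments segments.csv --presence presence.csv --out migrations.csv
migdetect baseline --records records.csv --method 2 --out freq_migrations.csv
migdetect evaluate --pred migrations.csv --truth truth.csv --out report.json
migdetect plot     --user U00000 --presence presence.csv --segments segments.csv \
                   --events migrations.csv --out trajectory.png
```

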