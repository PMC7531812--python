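# Methods

## Problem and model

A digital trace is a sequence of (user, timestamp, location) observations
generated as a by-product of device use. We define migration empirically: a
user's primary location remains stable at one place for at least *k* days,
then remains stable at a different place for at least *k* days. The
algorithm operationalises "stable" through *residence segments* detected on
the user's daily-presence raster (rows = locations, columns = days, a cell
filled iff the user was observed there that day).

All computation happens on integer day indices — days since a configurable
epoch (default 1970-01-01), with calendar days taken in a single configured
timezone (default UTC). Source data rarely state a timezone; fixing one
makes day boundaries deterministic and portable. Presence is a *set* of
locations per day: event counts within a day carry no weight in the segment
algorithm (they do in the frequency baselines, which are defined on counts).

## Segment detection

**Step 1 — contiguous segments.** Per location, sorted appearance days are
split into clusters wherever consecutive appearance days differ by more
than ε days; each cluster spans its first to last day. A cluster survives
iff its appearance share (appearances / span) is at least propDays and its
span at least minDays. Two readings of the gap tolerance are possible; we
split when `next − current > ε`, i.e. ε = 7 tolerates up to six wholly
unobserved days. Filter order is cluster → propDays → minDays.

**Step 2 — merging.** Same-location neighbours merge iff no other
location's segment intersects the open interval between them, repeated to a
fixed point. The merged span is not re-checked against propDays: merging is
pure concatenation of residence evidence, and re-filtering would let a
sparse middle stretch destroy two individually valid segments.

**Step 3 — overlap removal.** For consecutive different-location segments
with intersecting spans, a boundary day *t\** within the intersection
window minimises misclassified days (old-location appearances after *t*,
new-location appearances on or before *t*), ties toward the latest day —
deliberately the same criterion used for date inference, so the cut and the
inferred date never contradict each other. The earlier segment is truncated
to its last appearance on or before *t\**, the later to its first
appearance after it. A segment nested inside another's span is dropped — we
read it as a visit within a residence. Truncated segments below minDays are
retained; residency is enforced once, by *k*, at event detection. When
three segments overlap transitively, cuts are applied left to right with
the boundary window clamped inside the (possibly already truncated) earlier
segment; pairwise overlaps, by far the common case, are unaffected.

Each step makes a constant number of passes over per-location appearance
lists, so total work is linear in presence entries (the suite includes a
coarse timing check).

## Events, dates, uncertainty

Adjacent segment pairs at different locations with both spans ≥ *k* become
events. *k* applies to the inclusive span, not the appearance count: span
is residency duration; sparsity is already policed by propDays.

The migration date minimises misclassified days over candidates between the
origin's end and the destination's start, counting appearances within
[origin start, destination end] — days outside both segments carry no
information about the move. On a cleanly split trace this yields the last
day observed at the origin. Ties go to the latest candidate. Date
uncertainty is the gap `destination.start − origin.end − 1` (floored at 0):
the number of days within which the true move is unobservable.

## Frequency baselines

Monthly home = argmax over locations of: (1) event count; (2) distinct
active days; (3) night-window event count; (4) event count aggregated over
all towers within 1,000 m (haversine, inclusive radius, self included);
(5) method 4 restricted to the night window; (6) hierarchical modes,
hour → day → month. The night window is hour ≥ 19 or hour < 9 on the local
calendar date of the event (day assignment across midnight is not specified
in the literature; using the timestamp's own date is the simplest
deterministic rule). All argmax/mode ties resolve by higher raw event count
in the period, then lexicographically smallest id. Months whose share of
active days falls below `min_month_prop` (default 0, the pure modal rule of
prior work) are undefined. The migration rule emits an event when a run of
≥ *k* consecutive defined months at one home is immediately followed by
such a run elsewhere; undefined months break runs (a conservative reading
of "consecutive"); `k_months = 1` is the classic subsequent-month-change
rule. Baseline events are dated to the last day of the final origin month —
these methods have no day resolution, which is precisely the comparison's
point.

## Synthetic cohorts

The generator emulates the behavioural regimes that matter for validating a
migration detector, with known truth: *stayers* (one home), *migrants*
(origin through a known day, destination after), *commuters* (each day
drawn between two fixed locations — the border pattern that fools modal
methods), and *trippers* (one contiguous sub-*k* displacement). Days are
observed independently with probability `p_obs`; an active day yields a
fixed number of events at the day's primary location and, with probability
`p_noise`, one extra event at a random other location. Timestamps are
uniform over the day unless a night bias is requested (to exercise methods
3/5).

Reference conditions (the defaults): 500 users, a 400-day panel,
`p_obs = 0.7`, `p_noise = 0.1`, three events per active day, five
locations, migration days drawn from the middle half of the panel so both
residences can satisfy *k* = 90. These approximate a regularly active CDR
subscriber panel: most users generate traces most days, and roughly one day
in ten shows a spurious second location. The mixed evaluation cohort is 50%
migrants, 25% stayers, 15% commuters, 10% trippers — the non-migrant half
deliberately includes both documented failure modes of modal methods rather
than only easy stayers. Profile counts use largest-remainder allocation;
each user has an independent RNG substream keyed by (seed, user index), so
cohorts are bit-reproducible under any generation order.

What the generator does **not** emulate: bursty call volumes, weekday/
weekend rhythm, tower load-balancing, gradual or circular moves, attrition,
or correlated multi-user mobility. Passing tests on these cohorts shows the
algorithm recovers planted structure under sparsity and noise; it does not
certify accuracy on real traces, which is why the evaluation harness
accepts external human-label tables in the same format.

## Evaluation harness

Classification uses accuracy, precision, recall and F1 over per-user
migrant/non-migrant calls; degenerate precision/recall (zero denominator)
is reported as 0 with an explicit flag rather than NaN. A user counts as a
true positive iff both prediction and truth say migrant; date errors are
computed only on true positives, by the first predicted event. Multi-labeler
tables are adjudicated by majority vote with the median date among
majority-side labelers. Parameter tuning offers a plain grid sweep and
stratified k-fold cross-validation (folds dealt round-robin after a seeded
shuffle within each stratum; the winning grid point maximises mean training
F1, ties to the earliest grid point). Migration-rate series divide events
dated in a month by that month's active users; a month with no active users
is undefined, not zero. Trajectory rasters order rows by descending total
presence and render matplotlib rasters with segment boxes and date lines,
plus a plain-text form that parses back to the exact presence for
diff-based testing.

## Problem sizes

The shipped tests and the acceptance script run the reference 500-user
cohort, a 400-user commuter/stayer cohort, a 100-user clean-limit cohort,
and 200 random 60-day traces against a brute-force Step-1 oracle over a
3×3×3 parameter grid — sizes chosen so the full pipeline, including
generation, runs in well under a minute each on one core while keeping
binomial noise in the measured shares small.

## Known limitations

- ε, minDays and propDays interact with observation frequency; the defaults
  suit near-daily traces and should be re-tuned (see `crossval_tune`) for
  sparser sources.
- The pairwise event rule does not chain or classify return/circular
  migration.
- Overlap removal for three-way overlapping segments is resolved greedily
  left to right; such traces are pathological under sensible Step-1
  parameters but not impossible.
- The uncertainty measure counts unobserved gap days only; it does not
  model conflicting presence inside segments.
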