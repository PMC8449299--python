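# Methods

## The measurement model

The package operationalizes *latent collaboration* — coordination among
health-care workers (HCWs) that leaves no explicit communication record —
as **concurrent use of the same patient's EHR**. The chain of definitions:

- **Event**: one audit-log row `(hcw_id, patient_id, action_id, timestamp)`
  at second resolution. Timestamps are naive local time; the logs carry no
  zone, so daylight-saving transitions can create apparent gaps or overlaps
  and are deliberately not corrected. Duplicate rows are kept: repeated
  identical actions are legitimate audit events.
- **Interval**: a maximal run of one HCW's events on one patient with every
  inter-event gap ≤ the cutoff. The comparison is strict — a gap exactly
  equal to the cutoff stays inside the interval — so the interval count is
  non-increasing and total duration non-decreasing in the cutoff. A
  single-event interval has duration 0. Two intervals of the same HCW on
  the same patient can never overlap, by construction.
- **Concurrent session**: a connected component (≥ 2 intervals, ≥ 2 distinct
  HCWs) of the graph linking same-patient, different-HCW interval pairs with
  strictly positive overlap (`min(stop) − max(start) > 0`; touching
  endpoints do not count). The component reading allows chained overlaps to
  form one session without requiring every pair to overlap; because that is
  an interpretive choice, `assemble_sessions(rule="clique")` provides a
  greedy mutual-overlap partition as an alternative. Session membership is
  always a partition of the concurrent intervals.
- **Concurrent intensity** (per HCW per active day): the fraction of
  intervals that are concurrent and the fraction of EHR time spent in them.
  A concurrent interval contributes its full duration — partial overlap is
  not prorated — because the session, not the overlap window, is the unit
  of collaboration.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| gap cutoff | estimated (s) | splits event runs into intervals; the knee of the interval-count curve over candidates 10–1800 s |
| workday cutoff | 15 min | minimum summed interval time for an *active* EHR day; intensity uses active days only (value appropriate to intensive-care settings) |
| session rule | component | connected-component vs greedy-clique session semantics |
| k (k-core) | caller-set | minimum within-subgraph degree (unweighted) for the network core |
| variance target | 0.97 | cumulative explained variance retained by the linear reduction before embedding |
| k grid | 5,10,…,100 | candidate cluster counts scanned for the WSS elbow |

### Cutoff estimation

The knee is computed on the curve *number of intervals vs cutoff* — the
natural sessionization trade-off curve, which falls steeply while the cutoff
is below the within-task gap scale and flattens beyond it. (Which curve the
knee algorithm should see is genuinely open; the curve object is exposed via
`sessionize.cutoff_curve` for inspection.) The Kneedle construction is used:
smooth with a centered moving average (window 5 by default; a simplification
of the original spline step, kept as a knob), min–max normalize both axes,
flip a decreasing curve to increasing, and take the x maximizing the
difference curve `y_norm − x_norm`. Ties return the smallest x —
conservative sessionization. Flat or linear curves raise a "no knee" error
rather than fabricating a cutoff. `discrete_curvature` exposes the
closed-form curvature `y″/(1+y′²)^{3/2}` via central differences for
cross-checking; on a piecewise-linear corner it localizes the knee only to
within one grid step because the steep flank suppresses curvature at the
breakpoint sample itself.

### Workdays and day attribution

A workday is a calendar day in log-local time. Intervals crossing midnight
contribute their duration to each day proportionally (the accounting is
shared between workday flagging and intensity, so the two always agree);
their interval *count* registers on every day they touch, while their
actions are attributed to the start day. Whether the activity threshold
should apply per patient or across all patients is unstated in the source
material; durations are summed over all patients, following the plain
reading of "all interval durations in that day".

### Temporal patterns

Hour slots are offsets from the anchor (hours since admission / until
discharge), not clock hours. An interval lands in the slot containing its
start time; `attribute="overlap"` prorates by overlap seconds instead.
Patients are grouped by the day type (weekend = Saturday/Sunday) of the
anchoring event; the intermediate phase uses the calendar day containing
the stay midpoint, widened by a configurable radius (default 0 — the single
midpoint day — because a ±1-day radius mixes weekday hours into weekend
windows and vice versa, diluting any weekday/weekend contrast). Stays
shorter than 24 h are excluded from the admission/discharge phases and
counted. Pattern comparison uses the Wilcoxon rank-sum test on the two
24-value sequences plus a Welch t-test on their means; exactly identical
patterns report p = 1 rather than NaN.

### Networks

Edge weight is the co-session count (dot product of HCW rows of the
HCW × session indicator). K-core uses unweighted degree, the standard
definition. Role aggregation sums pair weights into role pairs, with
within-role weight kept as self-loops so total edge weight is conserved
exactly. The high/low likelihood split for survey validation ranks distinct
role pairs by aggregate weight and takes the extremes (ties broken
lexicographically, so the labeling is deterministic); within-role self-pairs
are excluded by default, which makes eight roles yield 28 candidate pairs.

### Clustering

Features are raw within-interval action counts (no TF–IDF or scaling —
the count profile itself is the object of interest). PCA retains components
to the variance target, t-SNE (seeded; mandatory seed recorded in outputs)
embeds to 2-D, and K-means (10 restarts, best WSS kept) runs on the
embedded coordinates. Clustering in the embedding mirrors common practice
for this data type but is statistically fragile — t-SNE distorts density —
so the PCA scores are also returned for clustering in the linear space.
The cluster count is the knee of the WSS-vs-k curve; WSS is asserted
non-increasing on the grid (violations indicate restart starvation).
Session complexity is computed as the cluster × interval indicator times the
interval × session indicator; positive entries per session column count the
distinct clusters.

### Survey model

`likert = α + θ·β` with θ ∈ {0 (low), 1 (high)} is fit by least squares on
individual responses; respondent clustering is ignored by design (each
rating is one observation). With a single binary predictor, α equals the
low-group mean and α + β the high-group mean to machine precision, and the
ANOVA F-test of β ≠ 0 equals the squared t-test — both identities are
asserted in the test suite. Group CIs use t-quantiles on response-level
data. On the bundled 12-relationship panel-mean example the groups differ
by β ≈ 0.89 Likert points; with only 12 aggregated observations that
difference sits at the edge of significance, whereas response-level data
(one row per rater × relationship) sharpens the test.

### Specialty summaries

Summaries are two-stage: per-HCW means over active days first, then the
specialty mean and 95% t-interval over its HCWs, so HCWs with many workdays
do not dominate. Whether CIs should be over HCWs or HCW-days is not
determined by the source material; over-HCWs is the default and the records
table lets callers aggregate otherwise. Standard tests (ANOVA, Spearman,
Wilcoxon, t) are delegated to scipy/statsmodels — the contribution here is
the quantities tested, not the tests. No multiple-testing correction is
applied.

## The synthetic generator

`simulate.SimConfig` defines the study conditions; defaults describe a
two-week window of a small intensive-care unit:

- 40 HCWs in eight role categories, 12 patients with admission/discharge
  spans (≈ 2 + Exp(4) day stays), six non-team HCWs per patient;
- bursty streams: bursts of ≈ 2 + Poisson(4) events with Exp(30 s)
  within-burst gaps; a bout continues with probability 0.35 after an
  Exp(1200 s) pause, giving the bimodal gap structure sessionization
  exploits;
- four planted two-HCW teams that, with propensity 0.9, start overlapping
  bursts (offsets < 30 s, shared action template) on shared patients about
  3 times per patient-day;
- weekends run at 5% of weekday intensity (a 20:1 ratio);
- each burst draws actions from one of 8 templates concentrated on 8 of 60
  action codes; team-bout members share a template, so sessions are
  action-homogeneous by construction.

All randomness flows from one seeded generator; identical seeds give
byte-identical logs.

**What it does not emulate:** clinical content (diagnoses, acuity, action
semantics), shift schedules, shared workstations, HCW turnover, or
coincidental-overlap confounding beyond uniform background activity.
Passing recovery tests therefore show the *algorithms* recover planted
structure under realistic statistical shapes — not that concurrent EHR use
is a validated proxy for collaboration in any particular unit; on real
data, overlapping shifts can still produce false-positive ties.

## Validation problem sizes

The end-to-end suite checks: oracle equivalence for sessionization (1,000
random streams, up to 10⁴ events), overlap/session detection (500 instances,
up to 2,000 intervals) and k-core (200 graphs, ≤ 300 nodes); planted-team
edge precision and cutoff recovery over 200 default-condition replicates;
the 20:1 weekday/weekend ratio pooled over 20 replicates of a 60-patient,
3-week configuration (counts are pooled before the ratio because per-replicate
weekend counts are small Poisson totals); elbow selection on 30 seeded
5-blob instances; and the single-cluster session fraction on
team-only-activity runs. These sizes keep the whole suite around two
minutes on one CPU while leaving each check statistically meaningful.

## Known limitations

- Sub-second timestamp handling is untested against real log exports.
- The Kneedle smoothing window and the candidate grid bound the estimated
  cutoff's resolution; curves with multiple bends return the global
  difference-curve maximum only.
- t-SNE-space clustering is seed-dependent by nature; only the seeded
  pipeline is reproducible, not the geometry across seeds.
- The clique session rule is a greedy partition, not maximal-clique
  enumeration (which would let intervals belong to several sessions).
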