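# Methods

## The monitoring model

The package analyses camera-trap data collected on wildlife crossing
structures over a fenced motorway. Because the fence channels animal
movement through the structures, the frequency of recorded crossings is
treated as a *relative abundance index* (RAI): changes in the number of
independent detections are read as changes in the abundance of the animals
using the structure. This reading rests on assumptions the package makes
explicit but cannot itself verify on field data:

- animals are habituated to the structures for the whole period (no trend
  in willingness to cross);
- pack home ranges are stable, so the same pack uses the same structures
  throughout;
- detection probability per crossing is constant over time (no camera
  degradation trend).

Two indices are computed per pack and monitoring year:

1. **Event count** — the number of deduplicated detections of the species.
2. **Minimal pack size** — the largest individual count observed in any
   single event of the year. This is a hard lower bound on the true pack
   size: the whole pack need not cross together, but a group larger than
   the pack cannot.

A *monitoring year* runs April 1 – March 31 (aligned to the
hunting/breeding season) and is labelled `YYYY/YYYY+1`. Effort arithmetic
uses 365 days per monitoring year; leap days are ignored so that a
four-camera structure monitored five years gives the conventional 7300
trap-days.

## Event deduplication

A trigger record is a single camera activation. Animals often dwell on a
structure beyond the camera's minimum inter-record delay (1 minute) and are
filmed repeatedly, and several cameras can film one passage. Records are
therefore collapsed per **structure** (pooling its cameras): a record joins
the open event for its `(species, individual count)` pair if it falls
within the deduplication window of the event's **first** record, otherwise
it opens a new event. Defaults and tie-breaks:

- window: 10 minutes; the boundary is inclusive (a record exactly at the
  window limit merges). Arbitrary but fixed and tested.
- anchoring: at the event's first record, so a slow procession cannot chain
  an event indefinitely. A gap-based variant (`chained=True`) anchors at
  the last merged record instead; both are exposed because the rule's
  plain-language statement does not distinguish them.
- a zero window disables merging entirely (one event per record), which
  keeps the event count a strictly non-increasing function of the window;
  with an inclusive boundary a zero window would otherwise still merge
  simultaneous records from two cameras.
- simultaneous records are ordered stably by `(timestamp, camera_id)`.
- records differing in species *or* in individual count never merge; a
  frame showing two species must be entered as two records (schema
  limitation, documented).

Consequences used as test invariants: the sum of `n_records` over events
equals the input record count; collapsing the events of a collapse is the
identity; for any input the event count is non-increasing in the window.

## Regression analysis

Each abundance index is regressed on each covariate by simple linear
regression (ordinary least squares, two parameters). Reported per fit:
slope, intercept, r², adjusted r² = 1 − (1 − r²)(n − 1)/(n − 2), the slope
*t* statistic and its two-sided *P* value on n − 2 degrees of freedom.
Adjusted r² is the headline fit statistic because at the series lengths
this design produces (n ≈ 5 monitoring years) unadjusted r² is grossly
optimistic; adjusted r² may legitimately be negative for no-signal fits.
Numerical policy:

- significance is flagged at two-sided *P* < 0.05; no multiple-testing
  correction by default (`holm=True` adds a Holm adjustment);
- a constant regressor raises an error (slope undefined); a constant
  *response* degenerates gracefully to slope 0, *P* = 1, r² = 0 — a flat
  minimal-pack-size series is a legitimate input, not an error;
- the OLS fit itself is delegated to statsmodels; tests verify it against
  independently coded normal equations to 1e-10.

The battery pools a pack subset per monitoring year before fitting: event
counts are summed over the packs, the pooled minimal pack size is the
maximum over packs, so n equals the number of monitoring years. The
events-vs-minimal-pack-size correlation check uses the same pooling. An
optional `lag` aligns a covariate observed in year *t* with the response in
year *t + lag* (default 0, same-year alignment); which alignment is
ecologically right is an open question the user must decide.

Mortality is partitioned into **legal cull** vs **accidental casualties**
(vehicle collisions, poaching, poisoning, unknown), with within-accidental
shares; percentages use half-up rounding (1 decimal for shares, 2 for
species percentages and camera densities) because conventional reporting
rounds ties up, unlike Python's default banker's rounding.

County-level mortality and livestock tables are aligned to packs by a
configurable county ↔ pack mapping; the overlap between administrative
counties and pack home ranges is acknowledged to be imperfect.

## The synthetic-data generator

`simulate_trigger_records` emulates the detection process the analysis
assumes, one draw stream from one seed (identical configuration ⇒
byte-identical output):

- **Crossings** per structure, species and day are Poisson. The wolf mean
  is `crossing_rate_per_wolf × pack size` of the pack mapped to the
  structure; prey species ("roe_deer", "red_deer", "wild_boar") and the
  "other" bucket have fixed per-structure daily rates.
- **Group size** is zero-truncated Poisson — mean
  `mean_group_fraction × pack size`, capped at the pack size, for wolves;
  mean `prey_group_mean` for other species. The cap is what makes the
  observed minimal pack size a provable lower bound in tests.
- **Dwell and repeated triggering**: dwell is exponential
  (`dwell_mean_s`); a camera records `1 + floor(dwell / trigger_delay_s)`
  times at the inter-record delay. Each camera on the structure films the
  crossing independently with probability `camera_detect_prob` (at least
  one always does), exercising the cross-camera pooling of the dedup rule.
- **Camera refractory period**: records from one camera are never closer
  than `trigger_delay_s`. When a crossing collides with the refractory tail
  of the previous one, its first record on a camera is shifted to the end
  of the refractory period (and always kept, so a non-missed crossing emits
  at least one record); dwell repeats that cannot fire while the animal is
  still present are dropped.
- **Loss processes**: a crossing is missed outright with probability
  `miss_prob`; optional per-structure outage windows suppress records (but
  not ground truth — animals cross whether or not cameras work); an
  optional `undercount_prob` lets a record under-report the group by one.

The ground-truth table carries, per pack-year, the true pack size, the
number of crossing episodes and the largest group that crossed. When
nothing is lost (`miss_prob = 0`, dwell short relative to the window,
crossings separated beyond the window) the pipeline recovers exactly one
event per crossing; with losses it recovers at most the truth count.

Default parameter values (crossing rate 0.01 per wolf per structure-day,
group fraction 0.4, dwell 90 s, miss probability 0.1, camera detection
0.8, prey rates 0.25–1.6 per day) are **illustrative**: the detection
process is not parameterized by any published study. They were chosen once
so that a structure-year produces event counts of the order a motorway
crossing structure yields (hundreds to thousands of events per structure
per year, wolves a fraction of a percent to a few percent of events) and
are not tuned thereafter. `study_default_config` arranges the study-shaped
design: 6 green bridges × 4 cameras monitored five years, 4 viaducts (2,
3, 1, 4 cameras — back-derived from their published trap-day totals)
monitored two years, 34 cameras in all, five packs with declining northern
and partially recovering southern trajectories.

What the generator deliberately does **not** emulate: spatial movement and
home-range geometry, habituation trends, seasonal or diel activity cycles,
weather-dependent detection quality, species misidentification, and camera
clock drift. Passing tests therefore demonstrate that the pipeline
correctly recovers abundance signals *from data satisfying the RAI
assumptions*; they cannot show that field data satisfy those assumptions.

The companion `simulate_cull_effect_series` builds 5-year annual summaries
in which wolf events equal `intercept − cull_effect × cull + noise`
(defaults 60, 4, Gaussian σ = 5 against a cull series of 10, 4, 12, 2, 5)
while the remaining covariates are independent draws (re-drawn if constant,
since a constant covariate is not regressable). With these values the
designed effect is comfortably detectable at n = 5 — the slope *t* has a
noncentrality near 6 — so the recovery-rate check is a test of the battery,
not of borderline power.

## Problem sizes

The test suite and the acceptance script run at sizes chosen for tight
feedback loops: dedup oracle comparisons on up to 20 records × 500–1000
random instances; OLS oracle on 500–1000 random designs of n = 3–14;
parameter recovery over 500 replicate 5-year series; monotonicity of record
counts over 200 single-structure-year replicates per pack size; one full
study-shaped simulation (≈ 240 k records, ≈ 39 k events at seed 1). The
whole suite runs in well under a minute on one core.

## Known limitations

- The RAI premise (events ∝ abundance) is assumed, not estimated; the
  package provides the events-vs-minimal-pack-size correlation check as a
  consistency probe, which is itself weak at n = 5.
- No capture-recapture or density estimation: wolves lack individually
  identifying coat patterns and crossing-structure cameras are not placed
  randomly with respect to movement, so event counts are indices, not
  densities.
- n ≈ 5 forbids time-series modelling; the regressions treat years as
  independent observations and make no causal claim.
- The supplementary-data importer auto-detects trigger-level vs aggregate
  sheets by header; it is exercised against synthetic workbooks only.
- Published per-structure event totals can disagree between sections of a
  report (differing pooling windows or screening); the pipeline always
  recomputes counts from records and makes no attempt to reconcile
  externally printed totals.
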