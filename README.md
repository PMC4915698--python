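# crossingmon

Camera-trap monitoring of wildlife on **wildlife crossing structures** —
green bridges and viaducts spanning fenced motorways. Because the fence
funnels animal movement through these structures, cameras mounted on them
achieve far higher trapping success per unit effort than randomly placed
grids, which makes them attractive long-term monitoring stations for rare,
wide-ranging carnivores such as the gray wolf (*Canis lupus*).

`crossingmon` is for ecologists and wildlife managers who run such a
monitoring scheme and want a reproducible path from raw camera trigger logs
to abundance-trend indices and their statistical evaluation. It provides:

- **Event deduplication.** A trigger record is one camera activation
  (photograph + movie). Repeated triggers within a 10-minute window at one
  structure, with the same species and the same individual count, collapse
  into a single independent *event*. The window is anchored at the event's
  first record; a gap-based (chained) variant is available.
- **Abundance indices per pack and monitoring year** (April 1 – March 31):
  the number of wolf events (a relative abundance index) and the *minimal
  pack size* — the largest group seen in any single event that year, a
  lower bound on true pack size.
- **Covariate regression.** Simple linear regression of each index on prey
  event counts, livestock depredation, and human-caused wolf mortality
  split into legal cull vs. accidental casualties. Each fit reports the
  slope, r², adjusted r² = 1 − (1 − r²)(n − 1)/(n − 2), the slope *t*
  statistic and its two-sided *P* on n − 2 df, flagged at *P* < 0.05.
- **Effort and cost-efficiency metrics**: trap-days (cameras × days) and
  camera density per km².
- **A seeded simulator** of the whole detection process — Poisson crossing
  processes whose wolf rate scales with pack size, zero-truncated Poisson
  group sizes capped at pack size, exponential dwell with repeated
  triggering, multi-camera redundancy, missed detections, outage windows —
  with a ground-truth table, so every pipeline stage is testable end to end
  without field data.

## Worked example

Simulate a study-shaped dataset (6 green bridges with 4 cameras monitored
five years, 4 viaducts monitored two, 5 packs), collapse it to events and
summarise one pack:

```python
from crossingmon import (study_default_config, simulate_trigger_records,
                         collapse_events, annual_pack_summary, trend_table,
                         count_events, species_percentage)

cfg = study_default_config(seed=1)
records, truth = simulate_trigger_records(cfg)
cal = cfg.calendar()
events = collapse_events(records, window_minutes=10, calendar=cal)
print(f"{len(records)} trigger records -> {len(events)} events")

n_wolf = count_events(events, {"wolf"})
print(f"wolf events: {n_wolf} ({species_percentage(n_wolf, len(events))}%)")

summaries = annual_pack_summary(events, cfg.structure_infos(), cal.labels)
table = trend_table(summaries)
print(table[table.pack_id == "Vucevica"].to_string(index=False))
```

```
237353 trigger records -> 39116 events
wolf events: 536 (1.37%)
 pack_id monitoring_year  n_events_wolf  minimal_pack_size  n_events_prey  n_events_total
Vucevica       2009/2010             32                  5            459            1055
Vucevica       2010/2011             26                  6            490            1011
Vucevica       2011/2012             12                  4            521            1062
Vucevica       2012/2013              8                  2            495            1063
Vucevica       2013/2014              4                  1            498            1033
```

The simulated Vučevica pack declines from 7 to 1 members over the five
years; both indices track it — wolf events fall 32 → 4 while prey events
stay flat, and the minimal pack size never exceeds the true size.

Regressing the indices on covariates (here a synthetic 5-year series with a
designed negative legal-cull effect; independent noise for the others):

```python
from crossingmon import simulate_cull_effect_series
from crossingmon.regression import RegressionBattery

summaries, covariates = simulate_cull_effect_series(seed=11)
results = RegressionBattery(summaries, covariates, ["SIM"]).fit()
print(results.summary())
```

```
Abundance-covariate regression battery (packs SIM)
dependent           independent           adj_r2       t       P
n_events_wolf       n_events_prey          -0.32    0.14    0.90
n_events_wolf       domestic_killed        -0.32   -0.16    0.89
n_events_wolf       accidental             -0.10    0.80    0.48
n_events_wolf       legal_cull              0.91   -6.42    0.01 *
n_events_wolf       total_mortality         0.50   -2.23    0.11
minimal_pack_size   n_events_prey          -0.33   -0.01    0.99
minimal_pack_size   domestic_killed        -0.31    0.25    0.82
minimal_pack_size   accidental             -0.27    0.39    0.72
minimal_pack_size   legal_cull              0.93   -7.24    0.01 *
minimal_pack_size   total_mortality         0.74   -3.51    0.04 *
```

The battery isolates the designed cull effect (negative slope, *P* < 0.05)
while the zero-effect covariates stay non-significant; negative adjusted r²
values are the expected behaviour of no-signal fits at n = 5.

## Command line

```
crossingmon demo      --out out/ --seed 1        # simulate + full report
crossingmon simulate  --out sim/ --seed 4
crossingmon collapse  --in triggers.csv --out events.csv --window-min 10
crossingmon summarize --events events.csv --structures structures.csv \
                      --out summary.csv --first-year 2009 --n-years 5
crossingmon regress   --summary summary.csv --mortality mortality.csv \
                      --livestock livestock.csv --packs Vucevica,Mosor \
                      --out table1.csv
crossingmon report    --config run.yaml
```

`demo` writes the complete bundle (events, per-pack summaries, trend table,
regression table, mortality shares, cost metrics, run log with input
digests) and is byte-for-byte reproducible for a fixed seed.

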