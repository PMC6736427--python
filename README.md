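# chronofeed

Temporal feeding-pattern delivery and analysis for automated rodent feeding
studies — schedule control, balance-scan analytics, meal microstructure, and
24-h corticosterone profile analysis.

## The problem

How the *timing* of food intake (grazing on many small portions versus eating
a few discrete meals) affects physiology is hard to study in rodents: pelleted
food can be hoarded, so hopper loss does not equal intake, and most feeding
systems cannot deliver smoothed, researcher-defined access patterns for weeks.
Instrumented cages solve this with an under-floor hopper of crushed diet on an
electronic balance, weighed every 90 s, behind a servo-controlled access lid
that can be programmed by time *and* by amount consumed.

`chronofeed` implements that delivery logic and the complete analysis stack as
a tested, reusable library for people designing or analysing such studies:

* **Schedules** (`chronofeed.schedule`) — three protocols as explicit
  access-control programs: *ad libitum* (one unlimited 24-h window),
  *grazing* (30-min windows tiling the 12-h dark phase, each capped at
  1/24 of the total daily food intake, tdF/I, of an ad libitum control
  cohort — or a fixed 0.5 g for mice), and *meal-feeding* (three 1-h
  unlimited windows at 1800, 2330 and 0500). The lid is open iff the clock
  is inside a window and the window's allowance is not yet consumed.
* **Simulator** (`chronofeed.simulate`) — a seeded stand-in for the
  instrument and the animals: 90-s scan streams under any schedule
  (two-state bout/pause renewal behavior), mouse step-on/off balance
  artifacts, manual daily weighings, and corticosterone profiles
  (circadian sinusoid + ultradian pulses + meal-locked pulses + assay
  noise) with full ground truth.
* **Intake analytics** (`chronofeed.intake`) — displacement correction for
  mouse artifacts, per-scan feeding events, cumulative/daily intake, meal
  size/duration/first-30-min metrics (duration: last time point at which
  ≥ 0.02 g was consumed), accuracy versus manual weighing (pooled R² and
  per-animal %), and pointwise day-vs-day microstructure comparison on the
  480-point dark-phase grid.
* **Hormone analytics** (`chronofeed.hormones`) — AUC (trapezoidal, over the
  full 24 h, µg·mL⁻¹·min), the OC₅ baseline (nearest-rank 5th percentile),
  a fixed-24-h-period sine fit `m + a·sin(2πt/1440) + b·cos(2πt/1440)`
  solved by linear least squares (amplitude √(a²+b²), peak time at the
  fitted maximum), and cluster ultradian pulse detection (nadir cluster 2,
  peak cluster 1, t↑ = t↓ = 2.0, minimum peak size 0 ng/mL, assay-CV
  variance model).

## Worked example

```python
import chronofeed as cf

# pair-fed grazing: 24 x 30-min windows, each 1/24 of a 24 g/d control tdF/I
sched = cf.build_grazing_schedule(policy=cf.AllowancePolicy(control_tdfi=24.0))
res = cf.simulate_session(sched, cf.rat_model(), days=2, seed=1, noise_sd=0.0)
events = cf.extract_events(res.series)
print(res.series.n_scans, cf.daily_totals(events).round(2).to_dict())

# the mouse step-on/off artifact correction, on its canonical delta sequence
corrected, _ = cf.correct_deltas([-30.62, -0.38, +31.13, 0.0], threshold=1.0)
print(corrected)

# corticosterone: simulate 22 ultradian pulses and recover them
prof, truth = cf.simulate_corticosterone(cf.HormoneSimConfig(seed=3))
summary, fit, pulses = cf.summarize_profile(prof)
print(len(truth["pulse_centers"]), len(pulses), round(summary.auc, 1),
      round(fit.peak_time))
```

prints

```
1920 {0: 24.0, 1: 24.0}
[0.   0.   0.   0.13]
22 21 245.4 751
```

— 1920 scans (960/day), both days' intake exactly the 24 g pair-fed cap; the
two ~31 g step-on/off displacements zeroed with the 0.13 g of true intake
carried into the next data point; 21 of 22 simulated pulses detected, a
24-h AUC of 245.4 µg·mL⁻¹·min and a fitted circadian peak 751 min after 0600.

There is also a CLI for end-to-end runs:

```sh
chronofeed simulate --protocol meal --days 2 --seed 5 --tdfi 24 --out run/
chronofeed analyze-intake --scans run/scans_A1.csv --manual run/manual.csv \
    --schedule run/schedule.yaml --out run/
chronofeed analyze-hormone --profiles run/hormone.csv --out run/
chronofeed report --run run/
```

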