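# Methods

This note documents the models, conventions and defaults behind `chronofeed`,
and what the synthetic-data tests do and do not demonstrate about real data.

## Clock and day conventions

Schedule clock times are minutes from midnight; the light cycle is 12 h:12 h
with lights on at 0600 and dark onset at 1800 (minute 1080). Analysis days are
anchored at 0600 so a dark phase is never split across days; session time 0 is
0600 of day 0. Windows are half-open `[start, start + duration)` on the 24-h
circle and may wrap midnight (the canonical second meal, 2330–0030, does);
wrap is handled by modular arithmetic rather than by splitting the window.
Hormone profiles use minutes after 0600 to match the blood-sampling start.

## Schedule engine

A schedule is an ordered set of non-overlapping access windows with optional
consumption allowances. The lid predicate is total: OPEN iff the clock lies in
a window and (the allowance is unlimited or the mass consumed in the current
window is strictly below it). Consuming exactly the allowance closes the lid.

The grazing allowance policy is either pair-fed (`fraction` × control tdF/I,
default 1/24, so 24 windows over a 12-h dark phase sum to exactly one control
tdF/I) or fixed-mass (default 0.5 g/window, the adult-mouse protocol, which is
deliberately *not* pair-fed). `update_allowance` refreshes the pair-fed cap
from the mean of the control cohort's latest daily intakes; because the
instrument weighs hoppers between 0900 and 1000, the intended cadence is one
update per day using the previous day's control mean (a running multi-day mean
can be had by passing more values), applying from the next dark onset.
Allowances keep full floating precision — instrument granularity is a
simulator concern, not a schedule one.

## Simulator

**Feeding behavior** is a two-state renewal process. While the lid is open, a
pause ends with constant hazard (`bout_rate`/h in the dark, `light_bout_rate`
in the light; per-scan start probability `1 − exp(−rate·Δt)`); a bout draws a
gamma-distributed target size (shape 4 by default) and eats at `eat_rate`
g/min until the target, the window's satiety cap, the window allowance, or lid
closure ends it. Default parameters (rat: 25 bouts/h dark, 0.6 g bouts,
0.2 g/min, 7 g/window cap; mouse: 12 bouts/h, 0.12 g, 0.08 g/min, 1 g cap)
are **non-physiological stand-ins** chosen once to reproduce the qualitative
microstructure of scheduled feeding — grazing windows consumed front-loaded
within the first ~9 min, three ramped meals of similar size, grazing and
meal-fed rats eating daily amounts of the same order, and less-restricted
grazing mice eating more than meal-fed mice. No bout-level claim about real
animals follows from them.

**Instrument model.** One weight record per 90 s (960/day); the true weight is
non-increasing except at the daily 0900 refill, which restores the initial
load and is flagged `REFILL` in the stream. Observed weights add i.i.d.
Gaussian balance noise (SD 0.02 g rat, 0.01 g mouse by default; this scale is
what motivates the 0.02 g meal-duration threshold downstream). Mouse step-on/
off artifacts add ≈ body mass (±0.5 g, with 0.3 g per-scan posture wobble) to
1–3 consecutive scans; because the added mass cancels on step-off, net weight
change over any artifact-bracketed interval is preserved and the ground-truth
consumption log is untouched.

**Hormone generator.** Concentration = mesor + amplitude·cos(2π(t − peak)/1440)
+ Σ Gaussian pulses + multiplicative noise, clamped at 0. Free pulse centers
are placed quasi-periodically with ±20 % spacing jitter so that, at the
default rate of 22/24 h with 30-min FWHM, ground-truth pulses are individually
resolvable — the generator exists to provide recoverable truth, not to model
HPA feedback dynamics. Pulse heights are gamma (shape 9) around
`pulse_height_mean`. In meal-locked mode one pulse is placed uniformly in the
30 min preceding each meal window, with the total count held at `pulse_rate`.
Defaults (mesor 100, amplitude 60 ng/mL, peak 741 min after 0600, height
150 ng/mL, CV 3.25 %) sit in the range reported for ad libitum-fed rats.

**Seeding.** Every generator takes one integer seed, split via
`numpy.random.SeedSequence.spawn` (behavior stream, noise stream); identical
seeds give byte-identical output files.

## Intake analysis

**Displacement correction.** Per-scan consumption deltas `w[i−1] − w[i]` with
magnitude above the threshold (default 1.0 g for mice: artifacts are ~30 g,
true 90-s intake ≪ 1 g, two orders of magnitude of separation) are zeroed and
their running sum carried forward; the episode closes at the first point where
carry + delta is back below threshold, where the sum is deposited. An episode
still open at the end of the series deposits its remainder at the last point
with a warning. The procedure preserves net mass, is idempotent, and is
applied independently within each refill-to-refill segment so an episode never
swallows a genuine refill step. The 90-s microstructure inside an episode is
not recoverable — only window-level and daily totals are.

**Events and totals.** Event grams are `max(0, delta)` with refill steps
excluded; the unclamped delta is kept alongside (`net_g`) and daily totals sum
it, because the clamped sum carries a one-sided noise bias of roughly
`n·sd·√2/√(2π)` per day while the unclamped sum telescopes to the exact net
hopper loss. Meal duration runs from window opening to the end of the last
scan with ≥ 0.02 g consumed (one-scan, 1.5-min granularity, reported in
minutes); a window with no such scan has duration 0.

**Accuracy.** The instrument-vs-manual comparison reports the squared Pearson
correlation over all animal-days pooled, and a per-animal accuracy defined as
the mean over days of system/manual × 100, summarized as mean ± SEM across
animals. This definition is declared, not derived: "percent accurate" admits
several formulas and this is the simplest consistent one.

**Microstructure comparison** bins each animal's dark phase onto the common
90-s grid (480 points for 12 h) and runs a paired t-test per point across
animals. P-values are uncorrected by default — the matched historical practice
— with Benjamini–Hochberg available behind a flag; zero-variance points count
as not significant.

## Hormone analysis

**AUC** is the trapezoidal area of the 24-h profile in µg·mL⁻¹·min, with the
profile treated as 24-h periodic: the trapezoid is closed with the first
sample at t = 1440 so a constant 100 ng/mL profile integrates to exactly
144 µg·mL⁻¹·min. No baseline is subtracted (it is a *total* output measure).
A consequence of the periodic closure is that AUCs of the two half-days do not
sum exactly to the full-day AUC; linearity in concentration holds exactly.

**OC₅** is the nearest-rank 5th percentile — the ⌈0.05 n⌉-th smallest
concentration — with no interpolation, matching its verbal definition ("the
cutoff below which 5 % of the samples fall"). It needs ≥ 20 samples so the
rank is at least 1, and accepts a time mask for subwindow baselines (e.g.
1200–1800).

**Circadian fit.** `m + a·sin(2πt/1440) + b·cos(2πt/1440)` by linear least
squares (normal equations via `lstsq`); amplitude = √(a² + b²), peak time =
clock position of the fitted maximum, peak/nadir = mesor ± amplitude. The
phase-offset parameterization is implied by "fitted sine with fixed 24-h
period"; a pure zero-phase sine could not place the peak freely, so the
two-harmonic-coefficient form is used. Constant profiles return amplitude 0
with an undefined (None) peak time.

**Cluster pulse detection.** At each boundary between samples the algorithm
compares the preceding nadir cluster (2 samples) with the following peak
cluster (1 sample) and vice versa, using a pooled t statistic. Since each time
point carries a single measurement, the variance comes from an assay model:
SD = CV × concentration (CV 3.25 %, the printed intra-assay variation),
floored at 1 ng/mL near the 0.98 ng/mL assay sensitivity bound. A boundary
with t ≥ 2.0 marks a significant rise; the pulse runs until a boundary with
t ≥ 2.0 marks the significant fall, and the region between the bounding nadir
clusters is one pulse. Height is the maximum concentration in the region;
mass is the trapezoidal area above the chord joining the bounding nadirs (the
original method leaves "peak mass" undefined; the chord baseline is this
package's declared choice); pulses below `min_peak_size` (default 0) are
discarded. Missing samples (≤ 10 % of a profile) are linearly interpolated
and flagged; worse profiles are rejected.

## Problem sizes used in the tests

The validation suite runs 1–2-day simulated sessions (960–1,920 scans) for
conservation/compliance properties over 20 seeds, one 42-day session for the
record-count check, 20 seeds for pulse-recovery and 50 for false-positive
calibration (144-sample profiles), and 200 replicate null grids (6 animals ×
480 points) for the type-I calibration of the microstructure comparison —
sizes chosen to estimate each property's statistic stably.

## What passing tests do and do not show

The simulator shares the schedule engine with the analysis under test, so
compliance properties (no consumption while the lid is closed, per-window caps)
validate the *logic*, not the hardware. Balance noise is i.i.d. Gaussian —
real load cells drift and quantize; artifact episodes are clean rectangles —
real mice produce messier traces; the hormone generator has no secretory
feedback. Recovery results on synthetic data therefore bound what the
analyses can do under the stated noise model, not under laboratory conditions.

## Known limitations

* Grazing mice under the fixed 0.5 g policy can be offered more than they
  would eat ad libitum; the simulator's behavioral caps, not homeostasis,
  limit their intake.
* The displacement correction deposits an episode's remainder at the series
  end if a mouse is still on the hopper when recording stops, biasing the last
  partial window.
* `REPLICATE_SD` cluster variance is declared but unusable on single-replicate
  profiles (it raises); it exists so replicated assays can be added without an
  interface change.
* Group-level inferential statistics beyond the pointwise paired tests
  (ANOVA, post-hoc families) are out of scope; standard statistical packages
  handle the summary tables this package emits.
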