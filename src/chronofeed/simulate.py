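"""Synthetic feeding-station sessions and corticosterone profiles.

This module stands in for the animals and the instrument: it generates
seeded balance-scan streams under any :class:`~chronofeed.schedule.FeedingSchedule`,
mouse step-on/off weight artifacts, manual daily weighings, and 24-h
corticosterone profiles with known ground truth, so every analysis stage can
be validated without laboratory data.

The behavioral model is deliberately minimal: a two-state renewal process in
which feeding bouts start with an exponential hazard (higher in the dark
phase), bout sizes are gamma distributed, and intake proceeds at a constant
eating rate until the bout is finished, the stomach-fill cap for the window
is reached, or the lid closes.  The defaults reproduce the qualitative
microstructure of scheduled feeding — grazing windows consumed front-loaded
within the first minutes, three ramped meals — and are not calibrated to any
physiological dataset.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence.spawn``: stream 0 drives behavior, stream 1
balance noise, and separate seeds are required for artifact injection and
manual-weighing error so each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .schedule import (FeedingSchedule, LidState, Protocol, MINUTES_PER_DAY)
from .series import (ScanSeries, Species, SCAN_INTERVAL_MIN, SCANS_PER_DAY,
                     DAY_ANCHOR_CLOCK_MIN, REFILL_FLAG)

REFILL_CLOCK_MIN = 540  # hoppers topped up daily at 0900
#: additive balance noise SD per scan (g)
DEFAULT_NOISE_SD = {Species.RAT: 0.02, Species.MOUSE: 0.01}
DEFAULT_HOPPER_LOAD = {Species.RAT: 60.0, Species.MOUSE: 15.0}


class SimulationError(ValueError):
    pass


@dataclass
class AnimalModel:
    """Behavioral stand-in for one animal (non-physiological; see docs/methods.md)."""

    species: Species
    body_mass: float  # g
    bout_rate: float  # bout initiations/h while the lid is open, dark phase
    light_bout_rate: float  # same, light phase
    bout_size_mean: float  # g per bout (gamma mean)
    eat_rate: float  # g/min while in a bout
    satiety_capacity: float  # max g per access window ("stomach fill")
    bout_size_shape: float = 4.0  # gamma shape; higher = less variable bouts

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        for name in ("body_mass", "bout_size_mean", "eat_rate", "satiety_capacity"):
            if not getattr(self, name) > 0:
                raise SimulationError(f"{name} must be > 0")
        if self.bout_rate < 0 or self.light_bout_rate < 0:
            raise SimulationError("bout rates must be >= 0")
        if not self.bout_size_mean < self.satiety_capacity:
            raise SimulationError("bout_size_mean must be < satiety_capacity")


def rat_model(**overrides) -> AnimalModel:
    """Default growing-rat parameters (~24 g/d ad libitum intake scale)."""
    kw = dict(species=Species.RAT, body_mass=250.0, bout_rate=25.0,
              light_bout_rate=1.0, bout_size_mean=0.6, eat_rate=0.2,
              satiety_capacity=7.0)
    kw.update(overrides)
    return AnimalModel(**kw)


def mouse_model(**overrides) -> AnimalModel:
    """Default adult-mouse parameters (~4 g/d intake scale, ~33 g body mass)."""
    kw = dict(species=Species.MOUSE, body_mass=33.0, bout_rate=12.0,
              light_bout_rate=1.0, bout_size_mean=0.12, eat_rate=0.08,
              satiety_capacity=1.0)
    kw.update(overrides)
    return AnimalModel(**kw)


@dataclass
class SimulationResult:
    """A simulated session: the scan stream plus its ground truth."""

    series: ScanSeries
    events: pd.DataFrame  # columns time_min, grams — true intake per scan interval
    daily_totals: pd.Series  # index: 0600-anchored day -> true grams eaten
    seed: int
    noise_sd: float
    hopper_load: float

    def truth_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "noise_sd": float(self.noise_sd),
            "hopper_load": float(self.hopper_load),
            "events": [[float(t), float(g)] for t, g in
                       zip(self.events["time_min"], self.events["grams"])],
            "daily_totals": {str(int(d)): float(g)
                             for d, g in self.daily_totals.items()},
        }


def simulate_session(schedule: FeedingSchedule, animal: AnimalModel, days: int,
                     seed: int, *, noise_sd: Optional[float] = None,
                     hopper_load: Optional[float] = None,
                     animal_id: str = "sim") -> SimulationResult:
    """Simulate ``days`` cage-days of 90-s balance scans under a schedule.

    Emits one record per 90 s (960/day; 42 d -> 40,320 records).  The true
    hopper weight is non-increasing except at the daily 0900 refill (flagged
    ``REFILL``); consumption occurs only while the schedule's lid is open and
    per-window consumption never exceeds the window allowance.  ``noise_sd``
    (default per species) adds i.i.d. Gaussian balance noise to the observed
    weights; pass 0 for an exact trace.
    """
    if seed is None:
        raise SimulationError("a seed is mandatory (reproducibility contract)")
    if days < 1:
        raise SimulationError("days must be >= 1")
    if noise_sd is None:
        noise_sd = DEFAULT_NOISE_SD[animal.species]
    if hopper_load is None:
        hopper_load = DEFAULT_HOPPER_LOAD[animal.species]

    ss = np.random.SeedSequence(seed)
    rng_behavior, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))

    n = days * SCANS_PER_DAY
    times = np.arange(n) * SCAN_INTERVAL_MIN
    weights = np.empty(n)
    lid_col = np.empty(n, dtype=object)
    flags = np.full(n, "", dtype=object)

    true_w = hopper_load
    bout_remaining = 0.0
    cur_widx: Optional[int] = None
    consumed = 0.0
    ev_t: list[float] = []
    ev_g: list[float] = []

    refill_day_min = (REFILL_CLOCK_MIN - DAY_ANCHOR_CLOCK_MIN) % MINUTES_PER_DAY

    weights[0] = true_w
    lid_col[0] = schedule.lid_state(DAY_ANCHOR_CLOCK_MIN, 0.0).value

    for k in range(1, n):
        t0 = times[k - 1]
        t1 = times[k]
        if t1 % MINUTES_PER_DAY == refill_day_min:
            true_w = hopper_load
            flags[k] = REFILL_FLAG
        else:
            clock0 = (t0 + DAY_ANCHOR_CLOCK_MIN) % MINUTES_PER_DAY
            hit = schedule.window_at(clock0)
            widx = hit[0] if hit else None
            if widx != cur_widx:
                consumed = 0.0
                cur_widx = widx
            eat = 0.0
            if hit is not None:
                w = hit[1]
                is_open = w.unlimited or consumed < w.allowance
                if is_open:
                    headroom = animal.satiety_capacity - consumed
                    if not w.unlimited:
                        headroom = min(headroom, w.allowance - consumed)
                    if bout_remaining <= 0.0:
                        rate = (animal.bout_rate if schedule.is_dark(clock0)
                                else animal.light_bout_rate)
                        p_start = 1.0 - math.exp(-rate * SCAN_INTERVAL_MIN / 60.0)
                        if p_start > 0 and rng_behavior.random() < p_start:
                            bout_remaining = rng_behavior.gamma(
                                animal.bout_size_shape,
                                animal.bout_size_mean / animal.bout_size_shape)
                    if bout_remaining > 0.0 and headroom > 0.0:
                        eat = min(animal.eat_rate * SCAN_INTERVAL_MIN,
                                  bout_remaining, headroom, true_w)
                        bout_remaining -= eat
                else:
                    bout_remaining = 0.0
            else:
                bout_remaining = 0.0
            if eat > 0.0:
                consumed += eat
                true_w -= eat
                ev_t.append(t1)
                ev_g.append(eat)
        weights[k] = true_w
        clock1 = (t1 + DAY_ANCHOR_CLOCK_MIN) % MINUTES_PER_DAY
        hit1 = schedule.window_at(clock1)
        c1 = consumed if (hit1 and cur_widx == hit1[0]) else 0.0
        lid_col[k] = schedule.lid_state(clock1, c1).value

    if noise_sd > 0:
        weights = weights + rng_noise.normal(0.0, noise_sd, size=n)

    series = ScanSeries(times=times, weights=weights, lid=lid_col, flags=flags,
                        animal_id=animal_id, species=animal.species,
                        schedule=schedule)
    events = pd.DataFrame({"time_min": np.asarray(ev_t), "grams": np.asarray(ev_g)})
    if len(events):
        day = (np.ceil(events["time_min"] / MINUTES_PER_DAY) - 1).astype(int)
        daily = events["grams"].groupby(day).sum()
    else:
        daily = pd.Series(dtype=float)
    daily = daily.reindex(range(days), fill_value=0.0)
    daily.index.name = "day"
    return SimulationResult(series=series, events=events, daily_totals=daily,
                            seed=seed, noise_sd=noise_sd, hopper_load=hopper_load)


@dataclass
class ArtifactResult:
    series: ScanSeries
    episodes: pd.DataFrame  # columns start_idx, span, mass


def inject_mouse_artifacts(series: ScanSeries, animal: AnimalModel,
                           artifact_rate: float, seed: int,
                           *, max_span: int = 3) -> ArtifactResult:
    """Superimpose mouse step-on/off balance artifacts onto a scan stream.

    A mouse standing on the hopper adds roughly its body mass to the reading
    for 1-3 consecutive scans (with per-scan posture wobble), producing the
    characteristic large negative-then-positive consumption deltas.  The true
    consumption log is untouched and the net weight change across any
    artifact-bracketed interval is preserved, because the added mass cancels
    once the mouse steps off.
    """
    if animal.species is not Species.MOUSE:
        raise SimulationError("step-on/off artifacts are a mouse phenomenon; "
                              "got species RAT")
    if artifact_rate < 0:
        raise SimulationError("artifact_rate must be >= 0")
    out = series.copy()
    episodes: list[tuple[int, int, float]] = []
    if artifact_rate > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        hours = (len(series) - 1) * SCAN_INTERVAL_MIN / 60.0
        n_events = rng.poisson(artifact_rate * hours)
        refills = set(np.flatnonzero(series.refill_mask()))
        occupied: set[int] = set()
        for _ in range(n_events):
            start = int(rng.integers(1, len(series) - max_span - 1))
            span = int(rng.integers(1, max_span + 1))
            footprint = set(range(start - 1, start + span + 1))
            if footprint & occupied or footprint & refills:
                continue  # skip overlapping/refill-adjacent placements
            mass = animal.body_mass + rng.normal(0.0, 0.5)
            wobble = rng.normal(0.0, 0.3, size=span)
            out.weights[start:start + span] += mass + wobble
            occupied |= footprint
            episodes.append((start, span, mass))
    ep = pd.DataFrame(episodes, columns=["start_idx", "span", "mass"])
    return ArtifactResult(series=out, episodes=ep)


# ---------------------------------------------------------------------------
# corticosterone profiles
# ---------------------------------------------------------------------------

HORMONE_DT_MIN = 10.0
HORMONE_SAMPLES = 144  # 24 h of 10-min sampling starting 0600


@dataclass
class HormoneSimConfig:
    """Generative parameters for a 24-h corticosterone profile.

    The profile is a fixed-24-h sinusoid (mesor/amplitude/peak time) plus
    ~hourly ultradian Gaussian pulses plus multiplicative assay noise, clamped
    at zero.  Defaults sit in the range reported for ad libitum-fed rats:
    circadian peak in the early dark phase (~741 min after 0600), 20-24
    pulses/24 h, pulse heights of order 150-250 ng/mL.
    """

    mesor: float = 100.0  # ng/mL
    circadian_amplitude: float = 60.0  # ng/mL
    circadian_peak_time: float = 741.0  # minutes after 0600
    pulse_rate: int = 22  # pulses per 24 h
    pulse_height_mean: float = 150.0  # ng/mL
    pulse_width: float = 30.0  # FWHM, minutes
    meal_locked: bool = False
    noise_cv: float = 0.0325  # multiplicative assay noise
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mesor, self.circadian_amplitude, self.pulse_height_mean,
               self.pulse_width) < 0 or self.pulse_rate < 0:
            raise SimulationError("hormone parameters must be >= 0")
        if not 0 <= self.noise_cv < 1:
            raise SimulationError("noise_cv must be in [0, 1)")


def simulate_corticosterone(config: HormoneSimConfig,
                            schedule: Optional[FeedingSchedule] = None):
    """Generate one 24-h profile on the 10-min grid plus its pulse ground truth.

    Returns ``(profile, truth)`` where ``profile`` is a
    :class:`~chronofeed.hormones.HormoneProfile` and ``truth`` a dict with
    ``pulse_centers`` and ``pulse_heights`` (minutes after 0600 / ng/mL).  In
    ``meal_locked`` mode one pulse is placed in the 30 min preceding each meal
    window of ``schedule``; the total pulse count stays ``pulse_rate``.
    """
    from .hormones import HormoneProfile  # deferred: hormones imports nothing from here

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    t = np.arange(HORMONE_SAMPLES) * HORMONE_DT_MIN

    conc = config.mesor + config.circadian_amplitude * np.cos(
        2 * np.pi * (t - config.circadian_peak_time) / MINUTES_PER_DAY)

    centers: list[float] = []
    if config.meal_locked:
        if schedule is None or schedule.protocol is not Protocol.MEAL_FED:
            raise SimulationError("meal_locked requires a MEAL_FED schedule")
        for w in schedule.windows:
            start = (w.start - DAY_ANCHOR_CLOCK_MIN) % MINUTES_PER_DAY
            centers.append(float(start - 30.0 + 30.0 * rng.random()) % MINUTES_PER_DAY)
    n_free = max(0, config.pulse_rate - len(centers))
    if n_free:
        spacing = MINUTES_PER_DAY / n_free
        base = (np.arange(n_free) + 0.5) * spacing
        # +/-20% spacing jitter keeps adjacent pulses >= ~1.3 FWHM apart at the
        # default rate, so ground-truth pulses are individually resolvable
        jitter = rng.uniform(-0.2, 0.2, size=n_free) * spacing
        centers.extend(float(c % MINUTES_PER_DAY) for c in base + jitter)
    centers = sorted(centers)[:config.pulse_rate]

    heights = []
    sigma = config.pulse_width / 2.3548  # FWHM -> SD
    for c in centers:
        h = float(rng.gamma(9.0, config.pulse_height_mean / 9.0)) \
            if config.pulse_height_mean > 0 else 0.0
        heights.append(h)
        if h > 0 and sigma > 0:
            # wrap on the 24-h circle so pulses near 0/1440 stay intact
            d = np.abs((t - c + MINUTES_PER_DAY / 2) % MINUTES_PER_DAY
                       - MINUTES_PER_DAY / 2)
            conc = conc + h * np.exp(-0.5 * (d / sigma) ** 2)

    if config.noise_cv > 0:
        conc = conc * (1.0 + config.noise_cv * rng.standard_normal(HORMONE_SAMPLES))
    conc = np.maximum(conc, 0.0)

    profile = HormoneProfile(times=t, conc=conc)
    truth = {"pulse_centers": centers, "pulse_heights": heights,
             "seed": int(config.seed)}
    return profile, truth


def emit_manual_weighings(daily_truth: pd.DataFrame, error_sd: float,
                          seed: int) -> pd.DataFrame:
    """Manual daily hopper weighings: true daily totals plus Gaussian error.

    ``daily_truth`` has columns ``animal_id, day, grams`` (e.g. built from
    :attr:`SimulationResult.daily_totals`); ``error_sd`` 0 reproduces the
    truth exactly.
    """
    if error_sd < 0:
        raise SimulationError("error_sd must be >= 0")
    out = daily_truth.loc[:, ["animal_id", "day", "grams"]].copy()
    if error_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        out["grams"] = out["grams"] + rng.normal(0.0, error_sd, size=len(out))
    return out


def daily_frame(result: SimulationResult, animal_id: Optional[str] = None) -> pd.DataFrame:
    """Ground-truth daily totals of one simulated session as a tidy frame."""
    aid = animal_id if animal_id is not None else result.series.animal_id
    return pd.DataFrame({"animal_id": aid,
                         "day": result.daily_totals.index.to_numpy(),
                         "grams": result.daily_totals.to_numpy()})
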