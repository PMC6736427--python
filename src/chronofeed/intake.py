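"""Feeding-event analytics for balance-scan streams.

Turns raw 90-s hopper-weight traces into the study's feeding results:

* displacement correction for mouse step-on/off balance artifacts (large
  paired negative/positive deltas zeroed, with the running difference carried
  into the next retained data point, so 30-min and daily totals stay correct);
* per-scan feeding events and 0600-anchored cumulative/daily intake;
* meal microstructure for meal-fed animals — size, duration (last time point
  at which >= 0.02 g was consumed) and first-30-min intake per meal;
* accuracy of the automated output against manual daily hopper weighing
  (pooled regression R^2 plus per-animal percent accuracy);
* pointwise day-vs-day comparison of the dark-phase 90-s grid (480 points for
  a 12-h dark phase) by paired t-tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import FeedingSchedule, Protocol, MINUTES_PER_DAY
from .series import (ScanSeries, SCAN_INTERVAL_MIN, DAY_ANCHOR_CLOCK_MIN,
                     REFILL_FLAG)

#: Meal-duration rule: a scan "counts" when >= this mass was consumed (g).
MEAL_EVENT_THRESHOLD_G = 0.02
#: Default artifact threshold for mice (g): artifacts are ~body mass (~30 g),
#: true 90-s intake is << 1 g, so 1 g separates them by orders of magnitude.
DEFAULT_DISPLACEMENT_THRESHOLD_G = 1.0
#: Weight *rise* larger than this without a REFILL flag aborts event extraction.
DEFAULT_REFILL_DETECT_G = 5.0


class IntakeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# displacement correction
# ---------------------------------------------------------------------------


def correct_deltas(deltas: Sequence[float], threshold: float
                   ) -> tuple[np.ndarray, bool]:
    """Carry-forward correction of per-scan consumption deltas.

    Any delta whose magnitude exceeds ``threshold`` opens (or continues) an
    artifact episode and is set to zero, with the running sum of zeroed
    values carried forward; the episode closes at the first point where the
    carry plus the incoming delta is back below threshold, and that sum is
    deposited there.  Returns ``(corrected, episode_open_at_end)``; an open
    episode's remainder is deposited at the last point with a warning.
    """
    if not threshold > 0:
        raise IntakeError("threshold must be > 0")
    d = np.asarray(deltas, dtype=float)
    out = np.zeros_like(d)
    carry = 0.0
    for i, x in enumerate(d):
        if abs(x) > threshold:
            out[i] = 0.0
            carry += x
        elif carry != 0.0:
            candidate = carry + x
            if abs(candidate) <= threshold:
                out[i] = candidate
                carry = 0.0
            else:
                out[i] = 0.0
                carry = candidate
        else:
            out[i] = x
    open_at_end = carry != 0.0
    if open_at_end:
        warnings.warn("artifact episode open at end of series; remainder "
                      "deposited at the last data point", stacklevel=2)
        out[-1] += carry
    return out, open_at_end


def correct_displacements(series: ScanSeries,
                          threshold: float = DEFAULT_DISPLACEMENT_THRESHOLD_G
                          ) -> ScanSeries:
    """Remove step-on/off balance artifacts from a scan stream.

    Applies :func:`correct_deltas` to the per-scan consumption deltas within
    each refill-to-refill segment (refill steps are kept as they are) and
    rebuilds the weight trace.  Net weight change over any artifact-bracketed
    interval is preserved, and the operation is idempotent.
    """
    refill = series.refill_mask()
    d = series.deltas()
    corrected = d.copy()
    # correct each inter-refill segment independently so an episode never
    # swallows a genuine refill step
    bounds = [0, *np.flatnonzero(refill), len(series)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        lo = a + 1  # delta at index a is the refill step (or the t=0 zero)
        if b > lo:
            seg, _ = correct_deltas(d[lo:b], threshold)
            corrected[lo:b] = seg
    weights = np.empty_like(series.weights)
    weights[0] = series.weights[0]
    for i in range(1, len(weights)):
        if refill[i]:
            weights[i] = series.weights[i]  # keep the observed refill level
        else:
            weights[i] = weights[i - 1] - corrected[i]
    return series.copy(weights=weights)


# ---------------------------------------------------------------------------
# events and profiles
# ---------------------------------------------------------------------------


def extract_events(series: ScanSeries,
                   refill_detect: float = DEFAULT_REFILL_DETECT_G) -> pd.DataFrame:
    """Per-scan feeding events: grams = max(0, w[i-1] - w[i]), refills excluded.

    Event ``grams`` are clamped at zero (small negative deltas are balance
    noise, not intake); the unclamped delta is kept in ``net_g`` so that sums
    of ``net_g`` telescope to the exact net hopper loss — daily totals use it
    to avoid the one-sided clamp bias.  A large *unflagged* positive weight
    step raises, pointing at missing REFILL flags or uncorrected artifacts.
    Returns a frame with ``time_min, grams, net_g``.
    """
    d = series.deltas()
    refill = series.refill_mask()
    bad = (~refill) & (d < -refill_detect)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise IntakeError(
            f"unflagged weight rise of {-d[i]:.2f} g at scan {i}: flag hopper "
            "refills or run correct_displacements first")
    net = np.where(refill, 0.0, d)
    net[0] = 0.0
    grams = np.maximum(net, 0.0)
    return pd.DataFrame({"time_min": series.times, "grams": grams,
                         "net_g": net})


def daily_totals(events: pd.DataFrame) -> pd.Series:
    """Grams per 0600-anchored analysis day (the scan at t = k*1440 closes day k-1).

    Uses the unclamped ``net_g`` column when present (exact net hopper loss,
    free of clamp bias); falls back to the clamped events otherwise.
    """
    t = events["time_min"].to_numpy()
    day = np.maximum(np.ceil(t / MINUTES_PER_DAY) - 1, 0).astype(int)
    col = "net_g" if "net_g" in events.columns else "grams"
    s = events[col].groupby(day).sum()
    s.index.name = "day"
    return s


def cumulative_profile(events: pd.DataFrame) -> pd.DataFrame:
    """Running intake within each 0600-anchored day.

    Returns ``time_min, day, cumulative_g``; the final value of each day
    equals that day's total.
    """
    t = events["time_min"].to_numpy()
    day = np.maximum(np.ceil(t / MINUTES_PER_DAY) - 1, 0).astype(int)
    out = events.copy()
    out["day"] = day
    out["cumulative_g"] = out.groupby("day")["grams"].cumsum()
    return out


@dataclass(frozen=True)
class MealSummary:
    """Per-meal metrics for one meal window of one day."""

    day: int
    meal_index: int  # 1-based position of the window in the schedule
    size: float  # g, all events in the window
    duration: float  # min, to the last scan with >= 0.02 g consumed
    first30: float  # g consumed in the first 30 min of the window
    empty: bool = False


def meal_metrics(events: pd.DataFrame, schedule: FeedingSchedule,
                 threshold: float = MEAL_EVENT_THRESHOLD_G) -> pd.DataFrame:
    """Meal size/duration/first-30-min intake per meal window and day.

    Duration runs from window opening to the end of the last 90-s scan at
    which at least ``threshold`` (default 0.02 g) was consumed; a window with
    no such scan has duration 0, and a window with no events at all is
    flagged ``empty``.
    """
    if schedule.protocol is not Protocol.MEAL_FED:
        raise IntakeError("meal_metrics requires a MEAL_FED schedule")
    t = events["time_min"].to_numpy()
    g = events["grams"].to_numpy()
    if len(t) == 0:
        return pd.DataFrame(columns=["day", "meal_index", "size", "duration",
                                     "first30", "empty"])
    n_days = int(np.ceil(t.max() / MINUTES_PER_DAY))
    rows = []
    for day in range(max(n_days, 1)):
        for mi, w in enumerate(schedule.windows, start=1):
            # session time at which this day's instance of the window opens
            t0 = day * MINUTES_PER_DAY + (w.start - DAY_ANCHOR_CLOCK_MIN) % MINUTES_PER_DAY
            # an event at scan time tau covers (tau - 1.5, tau]; it belongs to
            # the window when its interval start lies in [t0, t0 + duration)
            sel = (t - SCAN_INTERVAL_MIN >= t0 - 1e-9) \
                & (t - SCAN_INTERVAL_MIN < t0 + w.duration - 1e-9)
            size = float(g[sel].sum())
            qual = sel & (g >= threshold)
            if qual.any():
                duration = float(t[qual].max() - t0)
            else:
                duration = 0.0
            first30 = float(g[sel & (t - SCAN_INTERVAL_MIN < t0 + 30.0 - 1e-9)].sum())
            rows.append(MealSummary(day=day, meal_index=mi, size=size,
                                    duration=duration, first30=first30,
                                    empty=not sel.any() or size == 0.0))
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# accuracy and microstructure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccuracyReport:
    """System-vs-manual agreement of daily intake totals."""

    r_squared: float  # pooled squared Pearson correlation
    accuracy_mean: float  # mean over animals of per-animal mean % (system/manual x 100)
    accuracy_sem: float  # SEM across animals (0 for a single animal)
    per_animal: dict  # animal_id -> mean daily % accuracy
    n_days: int


def accuracy_vs_manual(system: pd.DataFrame, manual: pd.DataFrame) -> AccuracyReport:
    """Regress automated daily totals on manual hopper weighings.

    Both frames need ``animal_id, day, grams``.  R^2 is the squared Pearson
    correlation over all animal-days pooled; per-animal accuracy is the mean
    over days of system/manual x 100, summarized as mean +/- SEM across
    animals.
    """
    merged = system.merge(manual, on=["animal_id", "day"],
                          suffixes=("_system", "_manual"))
    if len(merged) < 2:
        raise IntakeError("need >= 2 paired animal-days")
    x = merged["grams_manual"].to_numpy(dtype=float)
    y = merged["grams_system"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise IntakeError("zero-variance daily totals: regression undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if np.any(x <= 0):
        raise IntakeError("manual daily totals must be > 0 for % accuracy")
    merged["pct"] = y / x * 100.0
    per_animal = merged.groupby("animal_id")["pct"].mean()
    sem = float(stats.sem(per_animal)) if len(per_animal) > 1 else 0.0
    return AccuracyReport(r_squared=r * r,
                          accuracy_mean=float(per_animal.mean()),
                          accuracy_sem=sem,
                          per_animal=per_animal.to_dict(),
                          n_days=len(merged))


@dataclass
class MicrostructureComparison:
    """Pointwise day-vs-day comparison on the dark-phase scan grid."""

    n_timepoints: int
    n_significant: int
    alpha: float
    per_point_p: np.ndarray


def dark_phase_grid(events: pd.DataFrame, day: int,
                    schedule: FeedingSchedule) -> np.ndarray:
    """One day's dark-phase intake on the 90-s grid (480 points for 12 h dark)."""
    t0 = day * MINUTES_PER_DAY \
        + (schedule.dark_onset - DAY_ANCHOR_CLOCK_MIN) % MINUTES_PER_DAY
    n = int(round(schedule.dark_duration / SCAN_INTERVAL_MIN))
    grid = np.zeros(n)
    t = events["time_min"].to_numpy()
    g = events["grams"].to_numpy()
    idx = np.round((t - SCAN_INTERVAL_MIN - t0) / SCAN_INTERVAL_MIN).astype(int)
    keep = (idx >= 0) & (idx < n)
    np.add.at(grid, idx[keep], g[keep])
    return grid


def microstructure_compare(grid_a: np.ndarray, grid_b: np.ndarray,
                           alpha: float = 0.05, *,
                           correct: bool = False) -> MicrostructureComparison:
    """Paired t-test at every grid point between two days across animals.

    ``grid_a``/``grid_b`` are (n_animals, n_points) arrays on a common 90-s
    dark-phase grid.  Points where every animal shows the same difference
    (zero variance) are not significant.  By default the p-values are
    uncorrected; ``correct=True`` applies Benjamini-Hochberg before counting.
    """
    a = np.atleast_2d(np.asarray(grid_a, dtype=float))
    b = np.atleast_2d(np.asarray(grid_b, dtype=float))
    if a.shape != b.shape:
        raise IntakeError("day grids must have matching shapes")
    if a.shape[0] < 2:
        raise IntakeError("need >= 2 animals per group for paired tests")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_rel(a, b, axis=0)
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if correct:
        from statsmodels.stats.multitest import multipletests
        adj = np.full_like(p, np.nan)
        if finite.any():
            adj[finite] = multipletests(p[finite], alpha=alpha, method="fdr_bh")[1]
        p = adj
    n_sig = int(np.nansum(p < alpha))
    return MicrostructureComparison(n_timepoints=a.shape[1], n_significant=n_sig,
                                    alpha=alpha, per_point_p=p)
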