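"""Feeding-access schedules for automated rodent feeding stations.

A schedule is an explicit access-control program for a servo-lidded food
hopper: an ordered set of clock windows during which the lid may open, each
carrying an optional consumption allowance.  Three protocols are supported:

``AD_LIBITUM``
    one 24-h window with no allowance cap;
``GRAZING``
    contiguous 30-min windows tiling the dark phase, each capped at a small
    allowance (classically 1/24 of the total daily food intake, tdF/I, of an
    ad libitum-fed control cohort, or a fixed mass for mice);
``MEAL_FED``
    a small number of 1-h unlimited-access windows inside the dark phase
    (classically three, at dark onset, mid-dark and late dark).

All clock times are minutes from midnight; windows may wrap midnight (the
canonical second meal runs 2330-0030) and carry no explicit wrap flag — the
interval is interpreted on the 24-h circle.  Window intervals are half-open
``[start, start + duration)`` and a window's lid closes the moment the
consumed mass reaches the allowance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import yaml

MINUTES_PER_DAY = 1440
#: Sentinel allowance meaning "no consumption cap in this window".
UNLIMITED = math.inf

DEFAULT_DARK_ONSET = 1080  # 1800 h, lights off
DEFAULT_DARK_DURATION = 720  # 12-h dark phase
DEFAULT_MEAL_STARTS = (1080, 1410, 300)  # 1800, 2330 and 0500 h
DEFAULT_MEAL_DURATION = 60
GRAZING_WINDOW_MIN = 30


class Protocol(str, Enum):
    AD_LIBITUM = "AD_LIBITUM"
    GRAZING = "GRAZING"
    MEAL_FED = "MEAL_FED"


class LidState(str, Enum):
    OPEN = "OPEN"
    CLOSED = "CLOSED"


class AllowanceMode(str, Enum):
    #: allowance = fraction x mean daily intake of an ad libitum control cohort
    PAIR_FED_FRACTION = "PAIR_FED_FRACTION"
    #: allowance = a fixed mass per window (the mouse grazing protocol)
    FIXED_MASS = "FIXED_MASS"


class ScheduleError(ValueError):
    """Invalid schedule, window or allowance configuration."""


def hhmm_to_minutes(hhmm: str | int) -> int:
    """Convert a clock string/int like ``"2330"`` or ``530`` to minutes from midnight."""
    s = f"{int(hhmm):04d}"
    h, m = int(s[:2]), int(s[2:])
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ScheduleError(f"not a valid HHMM clock time: {hhmm!r}")
    return 60 * h + m


def minutes_to_hhmm(minutes: float) -> str:
    m = int(round(minutes)) % MINUTES_PER_DAY
    return f"{m // 60:02d}{m % 60:02d}"


@dataclass(frozen=True)
class AccessWindow:
    """One lid-open interval: ``[start, start + duration)`` minutes on the 24-h circle."""

    start: float  # minutes from midnight, [0, 1440)
    duration: float  # minutes, > 0
    allowance: float = UNLIMITED  # grams, > 0, or UNLIMITED

    def __post_init__(self) -> None:
        if not 0 <= self.start < MINUTES_PER_DAY:
            raise ScheduleError(f"window start {self.start} outside [0, 1440)")
        if not 0 < self.duration <= MINUTES_PER_DAY:
            raise ScheduleError(f"window duration {self.duration} not in (0, 1440]")
        if not self.allowance > 0:
            raise ScheduleError(f"allowance must be > 0 or UNLIMITED, got {self.allowance}")

    @property
    def end(self) -> float:
        """End clock time (may wrap past midnight)."""
        return (self.start + self.duration) % MINUTES_PER_DAY

    @property
    def wraps_midnight(self) -> bool:
        return self.start + self.duration > MINUTES_PER_DAY

    @property
    def unlimited(self) -> bool:
        return math.isinf(self.allowance)

    def contains(self, clock: float) -> bool:
        """True if clock time (minutes from midnight) lies in the half-open window."""
        return (clock - self.start) % MINUTES_PER_DAY < self.duration


def _windows_overlap(a: AccessWindow, b: AccessWindow) -> bool:
    # circular half-open interval intersection
    return ((b.start - a.start) % MINUTES_PER_DAY < a.duration
            or (a.start - b.start) % MINUTES_PER_DAY < b.duration)


@dataclass(frozen=True)
class FeedingSchedule:
    """An access-control program: protocol label, windows and the dark phase it serves."""

    protocol: Protocol
    windows: tuple[AccessWindow, ...]
    dark_onset: float = DEFAULT_DARK_ONSET
    dark_duration: float = DEFAULT_DARK_DURATION

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(self.windows))
        object.__setattr__(self, "protocol", Protocol(self.protocol))
        if not self.windows:
            raise ScheduleError("schedule needs at least one access window")
        if not 0 < self.dark_duration < MINUTES_PER_DAY:
            raise ScheduleError("dark_duration must be in (0, 1440)")
        for i, a in enumerate(self.windows):
            for b in self.windows[i + 1:]:
                if _windows_overlap(a, b):
                    raise ScheduleError(
                        f"windows overlap: {minutes_to_hhmm(a.start)}+{a.duration} and "
                        f"{minutes_to_hhmm(b.start)}+{b.duration}")
        self._validate_protocol()

    def _validate_protocol(self) -> None:
        p = self.protocol
        if p is Protocol.AD_LIBITUM:
            if len(self.windows) != 1 or self.windows[0].duration != MINUTES_PER_DAY \
                    or not self.windows[0].unlimited:
                raise ScheduleError("AD_LIBITUM requires one unlimited 24-h window")
        elif p is Protocol.GRAZING:
            expected = int(self.dark_duration // GRAZING_WINDOW_MIN)
            if len(self.windows) != expected:
                raise ScheduleError(
                    f"GRAZING with {self.dark_duration}-min dark phase needs "
                    f"{expected} windows, got {len(self.windows)}")
            if self.windows[0].start != self.dark_onset:
                raise ScheduleError("first grazing window must start at dark onset")
            for w in self.windows:
                if w.duration != GRAZING_WINDOW_MIN:
                    raise ScheduleError("grazing windows must be 30 min")
                if w.unlimited:
                    raise ScheduleError("grazing windows need a finite allowance")
                self._require_in_dark(w)
        elif p is Protocol.MEAL_FED:
            durations = {w.duration for w in self.windows}
            if len(durations) != 1:
                raise ScheduleError("meal windows must share one duration")
            for w in self.windows:
                if not w.unlimited:
                    raise ScheduleError("meal windows are ad libitum (UNLIMITED allowance)")
                self._require_in_dark(w)

    def _require_in_dark(self, w: AccessWindow) -> None:
        rel = (w.start - self.dark_onset) % MINUTES_PER_DAY
        if rel + w.duration > self.dark_duration:
            raise ScheduleError(
                f"window {minutes_to_hhmm(w.start)}+{w.duration} min extends outside "
                f"the dark phase ({minutes_to_hhmm(self.dark_onset)} + {self.dark_duration} min)")

    # -- queries ---------------------------------------------------------

    def window_at(self, clock: float) -> Optional[tuple[int, AccessWindow]]:
        """Return ``(index, window)`` covering clock time, or None."""
        c = clock % MINUTES_PER_DAY
        for i, w in enumerate(self.windows):
            if w.contains(c):
                return i, w
        return None

    def lid_state(self, clock: float, consumed_in_window: float = 0.0) -> LidState:
        return lid_state(self, clock, consumed_in_window)

    def is_dark(self, clock: float) -> bool:
        return (clock - self.dark_onset) % MINUTES_PER_DAY < self.dark_duration

    def total_daily_allowance(self) -> float:
        """Sum of window allowances over one day (inf for any unlimited window)."""
        return sum(w.allowance for w in self.windows)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol.value,
            "dark_onset": float(self.dark_onset),
            "dark_duration": float(self.dark_duration),
            "windows": [
                {"start": float(w.start), "duration": float(w.duration),
                 "allowance": "unlimited" if w.unlimited else float(w.allowance)}
                for w in self.windows
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeedingSchedule":
        windows = tuple(
            AccessWindow(
                start=float(w["start"]), duration=float(w["duration"]),
                allowance=UNLIMITED if w.get("allowance", "unlimited") == "unlimited"
                else float(w["allowance"]))
            for w in d["windows"])
        return cls(protocol=Protocol(d["protocol"]), windows=windows,
                   dark_onset=float(d.get("dark_onset", DEFAULT_DARK_ONSET)),
                   dark_duration=float(d.get("dark_duration", DEFAULT_DARK_DURATION)))

    def to_config(self) -> str:
        """Plain-text (YAML) schedule config; round-trips exactly."""
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_config(cls, text: str) -> "FeedingSchedule":
        return cls.from_dict(yaml.safe_load(text))

    def window_table(self) -> str:
        lines = [f"{'#':>2}  {'open':>5}  {'close':>5}  {'allowance (g)':>13}"]
        for i, w in enumerate(self.windows, 1):
            allow = "unlimited" if w.unlimited else f"{w.allowance:.3f}"
            lines.append(f"{i:>2}  {minutes_to_hhmm(w.start):>5}  "
                         f"{minutes_to_hhmm(w.end):>5}  {allow:>13}")
        return "\n".join(lines)


@dataclass(frozen=True)
class AllowancePolicy:
    """How the per-window grazing allowance is set.

    ``PAIR_FED_FRACTION`` pair-feeds against an ad libitum control cohort:
    allowance = ``fraction`` x ``control_tdfi`` (mean control daily intake,
    grams/day), classically 1/24 so a 12-h dark phase of 30-min windows sums
    to exactly one control tdF/I.  ``FIXED_MASS`` dispenses a constant mass
    per window (0.5 g in the mouse protocol).
    """

    mode: AllowanceMode = AllowanceMode.PAIR_FED_FRACTION
    fraction: float = 1.0 / 24.0
    fixed_mass: float = 0.5
    control_tdfi: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", AllowanceMode(self.mode))
        if self.mode is AllowanceMode.PAIR_FED_FRACTION:
            if not self.fraction > 0:
                raise ScheduleError("fraction must be > 0")
            if self.control_tdfi is not None and not self.control_tdfi > 0:
                raise ScheduleError("control_tdfi must be > 0")
        else:
            if not self.fixed_mass > 0:
                raise ScheduleError("fixed_mass must be > 0")

    def per_window_allowance(self) -> float:
        if self.mode is AllowanceMode.FIXED_MASS:
            return self.fixed_mass
        if self.control_tdfi is None:
            raise ScheduleError("PAIR_FED_FRACTION policy needs control_tdfi "
                                "(mean daily intake of the control cohort)")
        return self.fraction * self.control_tdfi


def build_grazing_schedule(dark_onset: float = DEFAULT_DARK_ONSET,
                           dark_duration: float = DEFAULT_DARK_DURATION,
                           policy: AllowancePolicy | None = None) -> FeedingSchedule:
    """Contiguous 30-min allowance-capped windows tiling the dark phase.

    The first window opens at dark onset (lights out); each window's allowance
    comes from ``policy`` (default: pair-fed 1/24 tdF/I, which requires
    ``control_tdfi`` to be set).
    """
    if dark_duration <= 0 or dark_duration % GRAZING_WINDOW_MIN:
        raise ScheduleError("dark_duration must be a positive multiple of 30 min")
    policy = policy or AllowancePolicy()
    allowance = policy.per_window_allowance()
    n = int(dark_duration // GRAZING_WINDOW_MIN)
    windows = tuple(
        AccessWindow(start=(dark_onset + k * GRAZING_WINDOW_MIN) % MINUTES_PER_DAY,
                     duration=GRAZING_WINDOW_MIN, allowance=allowance)
        for k in range(n))
    return FeedingSchedule(Protocol.GRAZING, windows, dark_onset, dark_duration)


def build_meal_schedule(meal_starts: Sequence[float] = DEFAULT_MEAL_STARTS,
                        meal_duration: float = DEFAULT_MEAL_DURATION,
                        dark_onset: float = DEFAULT_DARK_ONSET,
                        dark_duration: float = DEFAULT_DARK_DURATION) -> FeedingSchedule:
    """Unlimited-access meal windows inside the dark phase.

    Defaults reproduce the canonical three-meal protocol: 1-h meals opening at
    1800 (dark onset), 2330 (mid-dark, wrapping midnight) and 0500 (late dark).
    ``meal_starts`` must be strictly ordered in dark-phase clock order.
    """
    rel = [(s - dark_onset) % MINUTES_PER_DAY for s in meal_starts]
    if sorted(rel) != rel or len(set(rel)) != len(rel):
        raise ScheduleError("meal_starts must be strictly ordered within the dark phase")
    windows = tuple(AccessWindow(start=s % MINUTES_PER_DAY, duration=meal_duration)
                    for s in meal_starts)
    return FeedingSchedule(Protocol.MEAL_FED, windows, dark_onset, dark_duration)


def build_ad_libitum_schedule(dark_onset: float = DEFAULT_DARK_ONSET,
                              dark_duration: float = DEFAULT_DARK_DURATION) -> FeedingSchedule:
    """A single unlimited 24-h window (control protocol)."""
    return FeedingSchedule(Protocol.AD_LIBITUM,
                           (AccessWindow(start=0, duration=MINUTES_PER_DAY),),
                           dark_onset, dark_duration)


def lid_state(schedule: FeedingSchedule, clock: float,
              consumed_in_window: float = 0.0) -> LidState:
    """Lid state at a clock time given the mass already consumed in the current window.

    OPEN iff the time lies inside an access window and consumption has not
    reached the window allowance; reaching the allowance exactly closes the
    lid (consumed == allowance -> CLOSED).
    """
    if consumed_in_window < 0:
        raise ScheduleError("consumed_in_window must be >= 0")
    hit = schedule.window_at(clock)
    if hit is None:
        return LidState.CLOSED
    _, w = hit
    if w.unlimited or consumed_in_window < w.allowance:
        return LidState.OPEN
    return LidState.CLOSED


def update_allowance(policy: AllowancePolicy,
                     control_daily_intakes: Sequence[float]) -> AllowancePolicy:
    """Refresh a pair-fed policy from the control cohort's latest daily intakes.

    The control tdF/I is the arithmetic mean of the supplied values (typically
    the previous day's intakes of the ad libitum cohort, weighed 0900-1000);
    the new per-window allowance applies from the next dark onset.  A
    FIXED_MASS policy is returned unchanged with a warning.
    """
    if policy.mode is AllowanceMode.FIXED_MASS:
        warnings.warn("update_allowance is a no-op for FIXED_MASS policies",
                      stacklevel=2)
        return policy
    if len(control_daily_intakes) == 0:
        raise ScheduleError("need at least one control daily intake")
    mean = float(sum(control_daily_intakes)) / len(control_daily_intakes)
    if not mean > 0:
        raise ScheduleError("control intakes must average > 0 g")
    return replace(policy, control_tdfi=mean)
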