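"""Balance-scan time series: the primary raw-data object.

The feeding station weighs each under-cage food hopper every 90 s, so one
cage-day is 960 records.  A :class:`ScanSeries` holds the equally spaced
weight trace for one cage together with the lid state and per-record flags
(currently only ``REFILL`` — the daily positive weight step when the hopper
is topped up).  Analysis days are anchored at 0600 (lights on), so session
time 0 is 0600 of day 0 and a full dark phase is never split across days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

SCAN_INTERVAL_MIN = 1.5  # 90-s balance scans
SCANS_PER_DAY = 960
DAY_ANCHOR_CLOCK_MIN = 360  # session time 0 == 0600 (lights on)
REFILL_FLAG = "REFILL"


class Species(str, Enum):
    RAT = "RAT"
    MOUSE = "MOUSE"


class ScanFormatError(ValueError):
    """Malformed scan stream (spacing, columns, flags)."""


@dataclass
class ScanSeries:
    """Equally spaced (90 s) hopper-weight trace for one cage.

    ``times`` are minutes since session start (0600 of day 0); ``lid`` holds
    "OPEN"/"CLOSED" strings and ``flags`` empty strings or "REFILL".
    """

    times: np.ndarray
    weights: np.ndarray
    lid: np.ndarray
    flags: np.ndarray
    animal_id: str = ""
    species: Optional[Species] = None
    schedule: Optional[object] = None  # FeedingSchedule, kept loose to avoid a cycle

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.lid = np.asarray(self.lid, dtype=object)
        self.flags = np.asarray(self.flags, dtype=object)
        n = len(self.times)
        if not (len(self.weights) == len(self.lid) == len(self.flags) == n):
            raise ScanFormatError("times/weights/lid/flags length mismatch")
        if n >= 2:
            steps = np.diff(self.times)
            if not np.allclose(steps, SCAN_INTERVAL_MIN, atol=1e-9):
                raise ScanFormatError(
                    "scan times must be strictly increasing in 1.5-min (90-s) steps")
        if not np.all(np.isfinite(self.weights)):
            raise ScanFormatError("non-finite hopper weights")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_scans(self) -> int:
        return len(self.times)

    def clock(self) -> np.ndarray:
        """Clock time (minutes from midnight) of each scan."""
        return (self.times + DAY_ANCHOR_CLOCK_MIN) % 1440.0

    def day_index(self) -> np.ndarray:
        """0600-anchored analysis day of each scan (scan at t=1440 closes day 0)."""
        return np.ceil(self.times / 1440.0 - 1e-9).astype(int) - 1 + (self.times <= 0)

    def deltas(self) -> np.ndarray:
        """Per-scan consumption deltas w[i-1] - w[i]; element 0 is 0."""
        d = np.zeros_like(self.weights)
        d[1:] = self.weights[:-1] - self.weights[1:]
        return d

    def refill_mask(self) -> np.ndarray:
        return self.flags == REFILL_FLAG

    def copy(self, **updates) -> "ScanSeries":
        kw = dict(times=self.times.copy(), weights=self.weights.copy(),
                  lid=self.lid.copy(), flags=self.flags.copy(),
                  animal_id=self.animal_id, species=self.species,
                  schedule=self.schedule)
        kw.update(updates)
        return ScanSeries(**kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "weight_g": self.weights,
                             "lid": self.lid, "flag": self.flags})
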