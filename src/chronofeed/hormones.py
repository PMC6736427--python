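"""Corticosterone profile analytics.

Operates on 24-h single-animal concentration profiles sampled every 10 min
from 0600 (144 samples, minutes-after-0600 time base) and computes the four
standard descriptors of hypothalamo-pituitary-adrenal output:

* **AUC** — total secretory output, the trapezoidal area of the profile over
  the full 24 h (the profile is treated as 24-h periodic, so the trapezoid is
  closed with the first sample at t = 1440), reported in ug.mL^-1.min.
* **OC5** — "observed concentration 5", the nearest-rank 5th percentile of the
  ranked concentrations: an index of baseline secretion robust to pulses.
* **Circadian fit** — a fixed-24-h-period sinusoid fitted by linear least
  squares; reports mesor, amplitude, the clock position of the fitted
  maximum, and the fitted peak/nadir values.
* **Ultradian pulses** — the cluster peak-detection algorithm: a sliding
  pooled-t comparison of candidate nadir clusters against candidate peak
  clusters; a significant rise followed by a significant fall delimits a
  statistically significant pulse.

Because each time point carries a single measurement, the cluster t-statistic
uses an assay-derived variance model by default: SD = cv x concentration
(intra-assay CV 3.25%) floored at 1 ng/mL near the assay sensitivity limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440.0


class HormoneError(ValueError):
    pass


@dataclass
class HormoneProfile:
    """One animal's 24-h concentration series on an equally spaced grid.

    ``times`` are minutes after 0600 (0..1430 for the standard 10-min grid);
    missing samples (catheter failures) are flagged in ``missing`` — they are
    never silently dropped, and analyses interpolate them explicitly.
    """

    times: np.ndarray
    conc: np.ndarray
    missing: Optional[np.ndarray] = None
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.conc.shape:
            raise HormoneError("times and conc must be matching 1-D arrays")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0]) or steps[0] <= 0:
                raise HormoneError("profile must be on an equally spaced time grid")
        if self.missing is None:
            self.missing = ~np.isfinite(self.conc)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        if np.any(self.conc[~self.missing] < 0):
            raise HormoneError("concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def interpolated(self, max_missing_frac: float = 0.10) -> "HormoneProfile":
        """Linearly interpolate flagged samples; reject profiles missing > 10%."""
        if not self.missing.any():
            return self
        frac = self.missing.mean()
        if frac > max_missing_frac:
            raise HormoneError(
                f"{frac:.0%} of samples missing exceeds the {max_missing_frac:.0%} cap")
        good = ~self.missing
        if good.sum() < 2:
            raise HormoneError("profile is entirely missing")
        conc = self.conc.copy()
        conc[self.missing] = np.interp(self.times[self.missing],
                                       self.times[good], self.conc[good])
        return HormoneProfile(times=self.times, conc=conc,
                              missing=np.zeros_like(self.missing),
                              animal_id=self.animal_id)


@dataclass(frozen=True)
class CircadianFit:
    mesor: float
    amplitude: float
    peak_time: Optional[float]  # minutes after 0600; None when amplitude ~ 0
    peak_value: float
    nadir_value: float
    rss: float


class VarianceModel(str, Enum):
    REPLICATE_SD = "REPLICATE_SD"
    CV_MODEL = "CV_MODEL"


@dataclass(frozen=True)
class ClusterConfig:
    """Cluster pulse-detection parameters.

    Defaults are the canonical single-series settings: nadir cluster of 2
    samples, peak cluster of 1, t = 2.0 for both the significant rise and the
    significant fall, and no minimum peak size.  ``cv`` is the assay
    coefficient of variation used by the CV variance model; ``sd_floor``
    keeps the modeled SD away from zero near the assay sensitivity limit.
    """

    nadir_cluster_size: int = 2
    peak_cluster_size: int = 1
    t_up: float = 2.0
    t_down: float = 2.0
    min_peak_size: float = 0.0  # ng/mL
    variance_model: VarianceModel = VarianceModel.CV_MODEL
    cv: float = 0.0325
    sd_floor: float = 1.0  # ng/mL, near the 0.98 ng/mL assay sensitivity

    def __post_init__(self) -> None:
        if self.nadir_cluster_size < 1 or self.peak_cluster_size < 1:
            raise HormoneError("cluster sizes must be >= 1")
        if self.t_up <= 0 or self.t_down <= 0:
            raise HormoneError("t statistics must be > 0")
        if self.cv < 0 or self.sd_floor < 0:
            raise HormoneError("cv and sd_floor must be >= 0")


@dataclass
class PulseSet:
    """Detected ultradian pulses of one profile."""

    pulses: pd.DataFrame  # columns peak_time, height, mass
    frequency: float  # pulses per 24 h of profile
    config: ClusterConfig

    def __len__(self) -> int:
        return len(self.pulses)


@dataclass(frozen=True)
class SecretionSummary:
    auc: float  # ug.mL^-1.min
    oc5: float  # ng/mL


# ---------------------------------------------------------------------------


def compute_auc(profile: HormoneProfile) -> float:
    """Total secretory output: trapezoidal AUC over 24 h, in ug.mL^-1.min.

    The 24-h profile is treated as periodic, so the integral runs over the
    full 1440 min by closing the trapezoid with the first sample; no baseline
    is subtracted.  Missing samples are interpolated first.
    """
    p = profile.interpolated() if profile.missing.any() else profile
    if len(p) < 2:
        raise HormoneError("AUC needs at least 2 samples")
    t = np.append(p.times, p.times[0] + MINUTES_PER_DAY)
    c = np.append(p.conc, p.conc[0])
    return float(np.trapezoid(c, t)) / 1000.0


def compute_oc5(profile: HormoneProfile, *, percent: float = 5.0,
                time_mask: Optional[np.ndarray] = None) -> float:
    """Nearest-rank baseline percentile ("observed concentration 5").

    Returns the ceil(percent/100 x n)-th smallest concentration — the cutoff
    below which 5% of the samples fall when ranked ascending.  ``time_mask``
    restricts the computation to a clock subwindow (e.g. 1200-1800).
    """
    conc = profile.conc[~profile.missing]
    times = profile.times[~profile.missing]
    if time_mask is not None:
        mask = np.asarray(time_mask, dtype=bool)
        if mask.shape != profile.times.shape:
            raise HormoneError("time_mask must match the profile grid")
        keep = mask[~profile.missing]
        conc = conc[keep]
    n = len(conc)
    if n < 20:
        raise HormoneError(
            f"OC5 needs >= 20 samples so the {percent:g}% rank is >= 1; got {n}. "
            "Use a longer profile or a wider time mask.")
    rank = math.ceil(percent / 100.0 * n)
    return float(np.sort(conc)[rank - 1])


def time_window_mask(profile: HormoneProfile, start: float, end: float) -> np.ndarray:
    """Boolean mask for times in [start, end) minutes after 0600, wrap-aware."""
    t = profile.times % MINUTES_PER_DAY
    span = (end - start) % MINUTES_PER_DAY or MINUTES_PER_DAY
    return (t - start) % MINUTES_PER_DAY < span


def fit_circadian_sine(profile: HormoneProfile) -> CircadianFit:
    """Least-squares fit of a fixed-24-h-period sinusoid.

    Fits ``m + a.sin(2 pi t/1440) + b.cos(2 pi t/1440)`` through the linear
    normal equations; the amplitude is sqrt(a^2 + b^2), the circadian peak is
    the clock position of the fitted maximum, and peak/nadir values are
    mesor +/- amplitude.  A constant profile yields amplitude 0 and an
    undefined (None) peak time.
    """
    p = profile.interpolated() if profile.missing.any() else profile
    t, y = p.times, p.conc
    if len(np.unique(t)) < 3:
        raise HormoneError("sine fit needs >= 3 distinct time points")
    w = 2.0 * np.pi * t / MINUTES_PER_DAY
    X = np.column_stack([np.ones_like(t), np.sin(w), np.cos(w)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, a, b = (float(v) for v in beta)
    amplitude = math.hypot(a, b)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if amplitude < 1e-12 * max(1.0, abs(m)):
        return CircadianFit(mesor=m, amplitude=0.0, peak_time=None,
                            peak_value=m, nadir_value=m, rss=rss)
    # a.sin(w) + b.cos(w) = A.sin(w + phi), maximal at w = pi/2 - phi
    phi = math.atan2(b, a)
    peak_time = ((math.pi / 2.0 - phi) * MINUTES_PER_DAY / (2.0 * np.pi)) \
        % MINUTES_PER_DAY
    return CircadianFit(mesor=m, amplitude=amplitude, peak_time=float(peak_time),
                        peak_value=m + amplitude, nadir_value=m - amplitude,
                        rss=rss)


def _sample_sd(conc: np.ndarray, config: ClusterConfig) -> np.ndarray:
    if config.variance_model is VarianceModel.REPLICATE_SD:
        raise HormoneError(
            "REPLICATE_SD needs replicate measurements per time point; "
            "single-measurement profiles must use CV_MODEL")
    return np.maximum(config.cv * conc, config.sd_floor)


def detect_pulses_cluster(profile: HormoneProfile,
                          config: ClusterConfig | None = None) -> PulseSet:
    """Cluster-algorithm pulse detection on a single 24-h profile.

    Slides a nadir cluster (``nadir_cluster_size`` samples) against the
    adjacent peak cluster (``peak_cluster_size`` samples) and computes a
    pooled t statistic from the per-sample assay SDs.  A boundary with
    t >= ``t_up`` marks a significant rise; the pulse extends until a
    boundary with t >= ``t_down`` marks the significant fall, and the region
    between the bounding nadir clusters is one pulse.  Pulse height is the
    maximum concentration inside the region; pulse mass is the trapezoidal
    area above the chord joining the bounding nadirs; pulses below
    ``min_peak_size`` are discarded.
    """
    config = config or ClusterConfig()
    p = profile.interpolated() if profile.missing.any() else profile
    y = p.conc
    t = p.times
    n = len(y)
    ns, ps = config.nadir_cluster_size, config.peak_cluster_size
    if n < ns + ps + 1:
        raise HormoneError("profile shorter than the cluster sizes allow")
    sd = _sample_sd(y, config)
    var = sd ** 2

    def cluster_stat(idx_a: slice, idx_b: slice) -> float:
        # t for mean(b) - mean(a) under the assay variance model
        ya, yb = y[idx_a], y[idx_b]
        se = math.sqrt(var[idx_a].sum() / len(ya) ** 2
                       + var[idx_b].sum() / len(yb) ** 2)
        return (yb.mean() - ya.mean()) / se

    # boundary i sits between samples i and i+1
    t_up = np.full(n, -np.inf)
    t_down = np.full(n, -np.inf)
    for i in range(n - 1):
        if i - ns + 1 >= 0 and i + ps < n:
            t_up[i] = cluster_stat(slice(i - ns + 1, i + 1),
                                   slice(i + 1, i + 1 + ps))
        if i - ps + 1 >= 0 and i + ns < n:
            t_down[i] = -cluster_stat(slice(i - ps + 1, i + 1),
                                      slice(i + 1, i + 1 + ns))

    regions: list[tuple[int, int]] = []
    start: Optional[int] = None
    for i in range(n - 1):
        if start is None:
            if t_up[i] >= config.t_up:
                start = max(i - ns + 1, 0)
        else:
            if t_down[i] >= config.t_down:
                regions.append((start, min(i + ns, n - 1)))
                start = None

    rows = []
    for a, b in regions:
        seg = y[a:b + 1]
        k = int(np.argmax(seg))
        height = float(seg[k])
        if height < config.min_peak_size:
            continue
        chord = np.interp(t[a:b + 1], [t[a], t[b]], [y[a], y[b]])
        excess = np.maximum(seg - chord, 0.0)
        mass = float(np.trapezoid(excess, t[a:b + 1]))
        rows.append((float(t[a + k]), height, mass))
    pulses = pd.DataFrame(rows, columns=["peak_time", "height", "mass"])
    span_days = (t[-1] - t[0] + p.dt) / MINUTES_PER_DAY
    return PulseSet(pulses=pulses, frequency=len(pulses) / span_days,
                    config=config)


def summarize_profile(profile: HormoneProfile,
                      config: ClusterConfig | None = None):
    """Bundle the per-animal secretion row: AUC + OC5, circadian fit, pulse set."""
    summary = SecretionSummary(auc=compute_auc(profile), oc5=compute_oc5(profile))
    fit = fit_circadian_sine(profile)
    pulses = detect_pulses_cluster(profile, config)
    return summary, fit, pulses


def summarize_profiles(profiles: Sequence[HormoneProfile],
                       config: ClusterConfig | None = None) -> pd.DataFrame:
    """One summary row per animal, mirroring the standard secretion table."""
    rows = []
    for p in profiles:
        s, fit, ps = summarize_profile(p, config)
        rows.append({
            "animal_id": p.animal_id,
            "auc_ug_ml_min": s.auc,
            "oc5_ng_ml": s.oc5,
            "circadian_peak_time_min": fit.peak_time,
            "circadian_peak_value_ng_ml": fit.peak_value,
            "circadian_nadir_value_ng_ml": fit.nadir_value,
            "pulse_count_per_24h": ps.frequency,
            "pulse_height_ng_ml": float(ps.pulses["height"].mean()) if len(ps) else np.nan,
            "pulse_mass_ng_ml_min": float(ps.pulses["mass"].mean()) if len(ps) else np.nan,
        })
    return pd.DataFrame(rows)
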