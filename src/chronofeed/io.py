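"""File formats: scan CSV, manual-weighing CSV, hormone CSV, JSON sidecars.

Everything is plain text.  The scan dialect has a header row and columns
``timestamp`` (ISO, timezone-naive facility-local time), ``weight_g``,
``lid`` (OPEN/CLOSED) and ``flag`` ('' or REFILL).  Timestamps are rendered
from a nominal session start of 0600 on 2019-01-01; reading converts back to
minutes since the first record and enforces the 90-s grid.  All floats are
written with fixed precision so identical runs produce identical bytes.
"""

from __future__ import annotations

import json
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .series import ScanSeries, ScanFormatError, Species, SCAN_INTERVAL_MIN
from .hormones import HormoneProfile

SESSION_EPOCH = datetime(2019, 1, 1, 6, 0, 0)  # nominal 0600, day 0
_WEIGHT_FMT = "%.5f"


def write_scan_csv(series: ScanSeries, path: str | Path) -> None:
    ts = [SESSION_EPOCH + timedelta(minutes=float(t)) for t in series.times]
    df = pd.DataFrame({
        "timestamp": [t.isoformat(sep=" ") for t in ts],
        "weight_g": series.weights,
        "lid": series.lid,
        "flag": series.flags,
    })
    df.to_csv(path, index=False, float_format=_WEIGHT_FMT)


def read_scan_csv(path: str | Path, *, animal_id: str = "",
                  species: Optional[Species] = None) -> ScanSeries:
    df = pd.read_csv(path, dtype={"flag": str}, keep_default_na=False)
    required = {"timestamp", "weight_g", "lid", "flag"}
    if not required.issubset(df.columns):
        raise ScanFormatError(f"scan CSV needs columns {sorted(required)}; "
                              f"got {list(df.columns)}")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ScanFormatError(f"malformed timestamp: {exc}") from exc
    times = (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 60.0
    steps = np.diff(times)
    if len(steps) and not np.allclose(steps, SCAN_INTERVAL_MIN, atol=1e-6):
        bad = int(np.argmin(np.isclose(steps, SCAN_INTERVAL_MIN, atol=1e-6))) + 2
        raise ScanFormatError(f"non-90-s scan spacing at line {bad}")
    try:
        weights = df["weight_g"].astype(float).to_numpy()
    except ValueError as exc:
        raise ScanFormatError(f"malformed weight: {exc}") from exc
    return ScanSeries(times=times, weights=weights,
                      lid=df["lid"].to_numpy(dtype=object),
                      flags=df["flag"].to_numpy(dtype=object),
                      animal_id=animal_id, species=species)


def write_manual_csv(manual: pd.DataFrame, path: str | Path) -> None:
    manual.loc[:, ["animal_id", "day", "grams"]].to_csv(
        path, index=False, float_format=_WEIGHT_FMT)


def read_manual_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"animal_id", "day", "grams"}
    if not required.issubset(df.columns):
        raise ScanFormatError(f"manual CSV needs columns {sorted(required)}")
    return df


def write_hormone_csv(profiles: list[HormoneProfile], path: str | Path) -> None:
    frames = [pd.DataFrame({"animal_id": p.animal_id,
                            "minutes_after_0600": p.times,
                            "conc_ng_per_ml": p.conc})
              for p in profiles]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.4f")


def read_hormone_csv(path: str | Path) -> list[HormoneProfile]:
    df = pd.read_csv(path)
    required = {"animal_id", "minutes_after_0600", "conc_ng_per_ml"}
    if not required.issubset(df.columns):
        raise ScanFormatError(f"hormone CSV needs columns {sorted(required)}")
    out = []
    for aid, grp in df.groupby("animal_id", sort=False):
        out.append(HormoneProfile(times=grp["minutes_after_0600"].to_numpy(),
                                  conc=grp["conc_ng_per_ml"].to_numpy(),
                                  animal_id=str(aid)))
    return out


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_manifest(path: str | Path, config: dict, seed: int) -> None:
    """Reproducibility manifest: full config, seed and library versions."""
    import chronofeed
    manifest = {
        "package": "chronofeed",
        "version": chronofeed.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": int(seed),
        "config": config,
    }
    write_json(manifest, path)
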