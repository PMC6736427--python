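"""End-of-run reporting: summary tables and optional figures for a run directory.

A "run" is the directory layout produced by the CLI: ``scans_<id>.csv``,
``manual.csv``, ``truth_<id>.json``, analysis outputs (``events_<id>.csv``,
``meals_<id>.csv``, ``accuracy.json``, ``hormone_summary.csv``) and a
``manifest.json``.  The report gathers what is present into deterministic
summary tables; missing inputs are named explicitly.  Figures (feeding-event
bars with the cumulative line, the accuracy scatter with the parity line,
hormone overlays) are optional and written as PNG.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .intake import cumulative_profile


class ReportError(FileNotFoundError):
    pass


def build_report(run_dir: str | Path, *, plots: bool = False) -> dict:
    """Summarize a completed run directory; returns {name: written path}."""
    run = Path(run_dir)
    if not run.is_dir():
        raise ReportError(f"run directory not found: {run}")
    out = run / "report"
    out.mkdir(exist_ok=True)
    written: dict[str, str] = {}

    event_files = sorted(run.glob("events_*.csv"))
    meal_files = sorted(run.glob("meals_*.csv"))
    if not event_files and not meal_files and not (run / "hormone_summary.csv").exists():
        raise ReportError(
            f"nothing to report in {run}: expected events_*.csv, meals_*.csv "
            "or hormone_summary.csv (run analyze-intake / analyze-hormone first)")

    if event_files:
        daily_rows = []
        for f in event_files:
            aid = f.stem.removeprefix("events_")
            ev = pd.read_csv(f)
            cp = cumulative_profile(ev)
            per_day = cp.groupby("day")["grams"].sum()
            for day, g in per_day.items():
                daily_rows.append({"animal_id": aid, "day": int(day),
                                   "grams": float(g)})
        daily = pd.DataFrame(daily_rows)
        p = out / "daily_intake.csv"
        daily.to_csv(p, index=False, float_format="%.5f")
        written["daily_intake"] = str(p)

    if meal_files:
        meals = pd.concat(
            [pd.read_csv(f).assign(animal_id=f.stem.removeprefix("meals_"))
             for f in meal_files], ignore_index=True)
        p = out / "meal_table.csv"
        meals.to_csv(p, index=False, float_format="%.5f")
        written["meal_table"] = str(p)

    hs = run / "hormone_summary.csv"
    if hs.exists():
        p = out / "hormone_summary.csv"
        p.write_text(hs.read_text())
        written["hormone_summary"] = str(p)

    if plots:
        written.update(_plots(run, out, event_files))
    return written


def _plots(run: Path, out: Path, event_files: list[Path]) -> dict[str, str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    for f in event_files[:4]:
        aid = f.stem.removeprefix("events_")
        ev = pd.read_csv(f)
        day0 = ev[ev["time_min"] <= 1440.0]
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.bar(day0["time_min"] / 60.0, day0["grams"], width=0.025,
               color="0.5", label="feeding events")
        ax2 = ax.twinx()
        ax2.plot(day0["time_min"] / 60.0, day0["grams"].cumsum(), "k-",
                 label="cumulative")
        ax.set_xlabel("hours from 0600")
        ax.set_ylabel("event (g)")
        ax2.set_ylabel("cumulative (g)")
        ax.set_title(f"day-0 feeding profile: {aid}")
        p = out / f"profile_{aid}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written[f"profile_{aid}"] = str(p)

    acc = run / "accuracy.json"
    if acc.exists():
        from .io import read_json
        daily_path = out / "daily_intake.csv"
        if daily_path.exists() and (run / "manual.csv").exists():
            daily = pd.read_csv(daily_path)
            manual = pd.read_csv(run / "manual.csv")
            m = daily.merge(manual, on=["animal_id", "day"],
                            suffixes=("_system", "_manual"))
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.scatter(m["grams_manual"], m["grams_system"], s=12)
            lo = min(m["grams_manual"].min(), m["grams_system"].min())
            hi = max(m["grams_manual"].max(), m["grams_system"].max())
            ax.plot([lo, hi], [lo, hi], "k--", label="parity")
            r2 = read_json(acc).get("r_squared", float("nan"))
            ax.set_xlabel("manual daily intake (g)")
            ax.set_ylabel("system daily intake (g)")
            ax.set_title(f"accuracy (R^2 = {r2:.2f})")
            ax.legend()
            p = out / "accuracy_scatter.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            written["accuracy_scatter"] = str(p)
    return written
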