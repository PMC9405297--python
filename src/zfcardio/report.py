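"""Batch pipeline runner and group-level descriptive summaries.

``run_analysis`` executes read -> likelihood filter -> axis geometry ->
beat detection -> cardiac panel -> Poincaré HRV for each input table and
writes, per fish: the per-frame axis series (CSV), the per-beat table
(CSV), the cardiac panel (JSON) and a Poincaré figure (PNG), plus a run
log capturing every parameter and flagged cycle.  Failures are isolated
per file: one corrupted table never aborts the batch.

``summarize_groups`` reduces labeled collections of panels to n / mean /
SD per parameter.  Inferential statistics are deliberately out of scope;
mean ± SD matches how such panels are conventionally presented.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import beats as _beats
from . import tracking_io as _tio
from .cardiac_metrics import CardiacPanel, compute_panel
from .errors import ParameterError, ZfcardioError
from .geometry import axis_lengths
from .hrv_poincare import DEFAULT_CONFIDENCE, plot_poincare, poincare
from .tracking_io import filter_by_likelihood, read_landmark_table

log = logging.getLogger("zfcardio")


@dataclass
class RunConfig:
    """Everything one analysis run depends on, in one declarative object."""

    inputs: Sequence[str | Path] = ()
    out_dir: str | Path = "results"
    dialect: str = "csv3header"
    fps: float = _tio.DEFAULT_FPS
    scale_um_per_px: float | None = None
    p_cutoff: float = _tio.DEFAULT_P_CUTOFF
    gap_policy: str = "interpolate"
    smooth_window: int = _beats.DEFAULT_SMOOTH_WINDOW
    min_prominence_frac: float = _beats.DEFAULT_MIN_PROMINENCE_FRAC
    hr_min_bpm: float = _beats.DEFAULT_HR_MIN_BPM
    hr_max_bpm: float = _beats.DEFAULT_HR_MAX_BPM
    sf_denominator: str = "systolic"
    normalization: float | None = None
    poincare_confidence: float = DEFAULT_CONFIDENCE
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides (CLI flags) win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = {k: v for k, v in raw.items() if k not in known}
        cfg = {k: v for k, v in raw.items() if k in known}
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        if unknown:
            cfg.setdefault("extra", {}).update(unknown)
        return cls(**cfg)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inputs"] = [str(p) for p in self.inputs]
        d["out_dir"] = str(self.out_dir)
        return d


def analyze_track(track: _tio.LandmarkTrack, config: RunConfig):
    """Run the in-memory pipeline on one track.

    Returns ``(panel, axes_series, beat_table, poincare_result)``.
    """
    filtered = filter_by_likelihood(track, config.p_cutoff, config.gap_policy)
    series = axis_lengths(filtered)
    table = _beats.detect_beats(
        series,
        min_prominence_frac=config.min_prominence_frac,
        hr_min_bpm=config.hr_min_bpm,
        hr_max_bpm=config.hr_max_bpm,
        smooth_window=config.smooth_window,
    )
    panel = compute_panel(
        table,
        normalization=config.normalization,
        sf_denominator=config.sf_denominator,
        volume_unit=f"{series.length_unit}^3",
    )
    hrv = poincare(table.ibi_s, config.poincare_confidence)
    return panel, series, table, hrv


def run_analysis(config: RunConfig) -> dict:
    """Analyze every input table and write the per-fish report bundle.

    Returns a report dict with per-file status; also written to
    ``out_dir/run_log.json``.  The batch continues past per-file
    failures, recording each one.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: list[dict] = []
    panel_rows: list[pd.DataFrame] = []

    for path in config.inputs:
        path = Path(path)
        stem = path.stem
        entry: dict = {"input": str(path)}
        try:
            track = read_landmark_table(
                path,
                dialect=config.dialect,  # type: ignore[arg-type]
                fps=config.fps,
                scale_um_per_px=config.scale_um_per_px,
            )
            panel, series, table, hrv = analyze_track(track, config)

            series.to_dataframe().to_csv(out_dir / f"{stem}_axes.csv", index=False)
            table.to_dataframe().to_csv(out_dir / f"{stem}_beats.csv", index=False)
            panel.to_json(out_dir / f"{stem}_panel.json")
            ax = plot_poincare(hrv)
            ax.figure.savefig(out_dir / f"{stem}_poincare.png", dpi=120)
            plt.close(ax.figure)

            flagged = [
                {"cycle": i, "reason": r}
                for i, r in enumerate(table.flags)
                if r
            ]
            entry.update(
                status="ok",
                panel=panel.to_dict(),
                hrv=hrv.to_dict(),
                n_replaced=dict(track.n_replaced),
                flagged_cycles=flagged,
            )
            row = panel.to_row()
            row.insert(0, "fish", stem)
            row["sd1_s"] = hrv.sd1
            row["sd2_s"] = hrv.sd2
            panel_rows.append(row)
            log.info("%s: ok (%d beats)", path, panel.n_beats)
        except (ZfcardioError, FileNotFoundError, OSError) as exc:
            entry.update(status="failed", error=f"{type(exc).__name__}: {exc}")
            log.error("%s: %s", path, exc)
        results.append(entry)

    if panel_rows:
        pd.concat(panel_rows, ignore_index=True).to_csv(
            out_dir / "panels_summary.csv", index=False
        )
    report = {
        "config": config.to_dict(),
        "files": results,
        "n_ok": sum(r["status"] == "ok" for r in results),
        "n_failed": sum(r["status"] == "failed" for r in results),
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


_SUMMARY_PARAMS = {
    "heart_rate_bpm": "heart_rate",
    "EDV": "edv",
    "ESV": "esv",
    "SV": "sv",
    "CO_per_min": "co",
    "EF_pct": "ef",
    "SF_pct": "sf",
}


def summarize_groups(groups: Mapping[str, Sequence[CardiacPanel]]) -> pd.DataFrame:
    """n / mean / SD per cardiac parameter per labeled group.

    SD uses the n-1 denominator and is reported as NaN (blank in CSV) for
    groups of one, never as a misleading zero.
    """
    if not groups:
        raise ParameterError("need at least one group")
    rows = []
    for label, panels in groups.items():
        if not panels:
            raise ParameterError(f"group {label!r} is empty")
        for col, attr in _SUMMARY_PARAMS.items():
            values = np.array([getattr(p, attr) for p in panels], dtype=float)
            rows.append(
                {
                    "group": label,
                    "parameter": col,
                    "n": values.size,
                    "mean": float(values.mean()),
                    "sd": float(values.std(ddof=1)) if values.size > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
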