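"""Aggregate per-beat measurements into the seven-parameter cardiac panel.

Per cycle *i*:

    SV_i = EDV_i - ESV_i                      stroke volume
    EF_i = SV_i / EDV_i * 100                 ejection fraction (%)
    SF_i = (Dsd_i - Dss_i) / Dss_i * 100      shortening fraction (%)

Panel values are per-cycle means; cardiac output is the panel-level
identity ``CO = mean(SV) * HR`` in volume per minute.  Note the
shortening-fraction denominator: this pipeline's source workflow divides
by the *systolic* diameter ``Dss`` (so SF can exceed 100%), whereas the
conventional echocardiographic definition divides by the diastolic
diameter ``Dsd``.  The systolic form is the default; the conventional
form is available via ``sf_denominator="diastolic"`` and the convention
used is recorded on the panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .beats import BeatTable, beat_intervals, heart_rate
from .errors import DomainError, InsufficientBeatsError, InvertedCycleError, ParameterError

SFDenominator = Literal["systolic", "diastolic"]

PANEL_FIELDS = ("heart_rate", "edv", "esv", "sv", "co", "ef", "sf")


@dataclass(frozen=True)
class CardiacPanel:
    """Record-level cardiac physiology summary.

    Volumes are in the cubed length unit of the upstream series (px^3 or
    um^3); ``co`` is volume per minute; ``ef`` and ``sf`` are percent.
    """

    heart_rate: float  # bpm
    edv: float
    esv: float
    sv: float
    co: float  # volume / min
    ef: float  # percent
    sf: float  # percent
    n_beats: int
    volume_unit: str = "px^3"
    sf_denominator: SFDenominator = "systolic"
    sv_normalized: float | None = None
    per_beat: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "heart_rate_bpm": self.heart_rate,
            "EDV": self.edv,
            "ESV": self.esv,
            "SV": self.sv,
            "CO_per_min": self.co,
            "EF_pct": self.ef,
            "SF_pct": self.sf,
            "n_beats": self.n_beats,
            "volume_unit": self.volume_unit,
            "sf_denominator": self.sf_denominator,
        }
        if self.sv_normalized is not None:
            out["SV_normalized"] = self.sv_normalized
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_row(self) -> pd.DataFrame:
        """One-row tidy table, for tabulation across fish."""
        return pd.DataFrame([self.to_dict()])


def compute_panel(
    table: BeatTable,
    hr: float | None = None,
    *,
    normalization: float | None = None,
    sf_denominator: SFDenominator = "systolic",
    volume_unit: str = "px^3",
) -> CardiacPanel:
    """Compute the cardiac panel from a beat table.

    ``hr`` defaults to the instantaneous-average heart rate of the
    table's own inter-beat intervals.  ``normalization`` optionally
    divides the stroke volume by a caller-supplied reference volume and
    reports the quotient alongside.
    """
    if table.n_cycles < 1:
        raise InsufficientBeatsError("need at least one complete cardiac cycle")
    if hr is None:
        hr = heart_rate(beat_intervals(table))
    if hr <= 0:
        raise ParameterError(f"heart rate must be positive, got {hr}")

    bad = np.nonzero(table.esv >= table.edv)[0]
    if bad.size:
        raise InvertedCycleError(
            f"ESV >= EDV in cycle(s) {bad.tolist()}; inspect the flagged beat table"
        )
    if np.any(table.dss <= 0) or np.any(table.dsd <= 0):
        raise DomainError("short-axis diameters must be positive")

    sv_i = table.edv - table.esv
    ef_i = sv_i / table.edv * 100.0
    if sf_denominator == "systolic":
        sf_i = (table.dsd - table.dss) / table.dss * 100.0
    elif sf_denominator == "diastolic":
        sf_i = (table.dsd - table.dss) / table.dsd * 100.0
    else:
        raise ParameterError(f"unknown sf_denominator {sf_denominator!r}")

    per_beat = pd.DataFrame(
        {
            "EDV": table.edv,
            "ESV": table.esv,
            "SV": sv_i,
            "EF_pct": ef_i,
            "SF_pct": sf_i,
            "IBI_s": table.ibi_s,
        }
    )
    sv = float(np.mean(sv_i))
    sv_norm = None
    if normalization is not None:
        if normalization <= 0:
            raise ParameterError("normalization reference must be positive")
        sv_norm = sv / normalization

    return CardiacPanel(
        heart_rate=float(hr),
        edv=float(np.mean(table.edv)),
        esv=float(np.mean(table.esv)),
        sv=sv,
        co=sv * float(hr),
        ef=float(np.mean(ef_i)),
        sf=float(np.mean(sf_i)),
        n_beats=table.n_cycles,
        volume_unit=volume_unit,
        sf_denominator=sf_denominator,
        sv_normalized=sv_norm,
        per_beat=per_beat,
    )
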