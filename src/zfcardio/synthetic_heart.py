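"""Synthetic beating-heart landmark generator with full ground truth.

Emulates a 1-minute, 30 fps recording of a pulsating zebrafish-embryo
ventricle as seen by a markerless tracker:

1. Inter-beat intervals follow an AR(1) Gaussian process around the mean
   period ``60 / hr_bpm`` (stationary SD ``rr_sd_s``, lag-1 correlation
   ``rr_ar1``), truncated away from zero.  AR(1) is the minimal process
   that separates short-term (sd1) from long-term (sd2) variability.
2. Within each beat the ventricular volume follows an asymmetric
   raised-cosine pulse from ``edv0`` down to ``esv0`` over
   ``systolic_fraction`` of the cycle and back — smooth, with flat
   extremes, like a real filling curve.
3. The volume is realized as a prolate spheroid of fixed aspect ratio
   ``Dl/Ds``: ``Ds = (6 V / (pi * ar))**(1/3)``, ``Dl = ar * Ds``, so
   recomputing the spheroid volume from the noiseless landmarks returns
   the generator's V exactly.
4. Eight landmarks sit at 45-degree parametric increments on the ellipse
   with semi-axes ``Ds/2`` (landmarks 1-5 direction) and ``Dl/2``
   (landmarks 3-7 direction), centered at ``center_xy`` plus accumulated
   slide drift and any sudden-displacement (jump) events.
5. Tracker imperfections: i.i.d. Gaussian jitter per landmark per frame,
   and a ``dropout_rate`` fraction of samples given a sub-cutoff
   likelihood together with a large positional excursion, mimicking a
   momentary mislabel.

Ground truth (true beat frames, IBIs, per-beat EDV/ESV, heart rate,
sd1/sd2 of the generated interval sequence, and the noiseless per-frame
geometry) is returned alongside the track, so every pipeline stage can be
validated without any video.

Presets mirror the study conditions the pipeline targets: a healthy
control, an ethanol-like edema phenotype (slower, smaller heart, reduced
pulse amplitude), and a ponatinib-like phenotype (the same reductions
plus depressed ejection and an irregular, arrhythmic rhythm).  Preset
magnitudes are the generator's own documented choices; only the effect
*directions* are treated as meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .hrv_poincare import poincare
from .tracking_io import POINT_NAMES, LandmarkTrack

#: Likelihood assigned to well-tracked samples.
_GOOD_LIKELIHOOD = 0.99
#: Positional excursion SD (px) for dropout samples, large vs. tracking jitter.
_DROPOUT_DISPLACEMENT_PX = 25.0
#: Fraction of the first IBI by which the first diastolic peak is delayed,
#: so the record never starts exactly on a peak (an undetectable edge case).
_START_PHASE = 0.35


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated recording.

    Volumes are px^3, lengths px, times seconds.  ``jump_events`` is a
    sequence of ``(frame, (dx, dy))`` sudden displacements that persist
    from that frame onward (the "fish suddenly moved" artifact);
    ``drift_px_per_frame`` is a constant slide-drift velocity vector.
    """

    duration_s: float = 60.0
    fps: float = 30.0
    hr_bpm: float = 150.0
    rr_sd_s: float = 0.010
    rr_ar1: float = 0.2
    edv0: float = 4.0e5
    esv0: float = 2.0e5
    aspect_ratio: float = 1.2
    systolic_fraction: float = 0.35
    center_xy: tuple[float, float] = (1920.0, 1080.0)
    jitter_px: float = 0.5
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    jump_events: tuple[tuple[int, tuple[float, float]], ...] = ()
    dropout_rate: float = 0.0
    seed: int = 0
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ParameterError("duration_s and fps must be positive")
        if not self.edv0 > self.esv0 > 0:
            raise ParameterError("need edv0 > esv0 > 0")
        if not 0 < self.systolic_fraction < 1:
            raise ParameterError("systolic_fraction must be in (0, 1)")
        if not -1 < self.rr_ar1 < 1:
            raise ParameterError("rr_ar1 must be in (-1, 1)")
        if self.rr_sd_s < 0 or self.jitter_px < 0:
            raise ParameterError("noise scales must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.aspect_ratio <= 0:
            raise ParameterError("aspect_ratio must be positive")
        if self.fps * 60.0 / self.hr_bpm < 6.0:
            raise ParameterError(
                f"unresolvable beat: {self.fps * 60.0 / self.hr_bpm:.1f} "
                "frames per beat (< 6); lower hr_bpm or raise fps"
            )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually produced, for validation.

    ``beat_frames`` are the frames nearest each diastolic peak that fall
    strictly inside the record (edge peaks cannot be local maxima of the
    sampled trace and are excluded).  ``sd1_s``/``sd2_s`` are computed
    from ``ibis_s`` with the same Poincaré formulas the analysis uses.
    """

    beat_frames: np.ndarray
    ibis_s: np.ndarray
    edv_per_beat: np.ndarray
    esv_per_beat: np.ndarray
    hr_bpm: float
    sd1_s: float
    sd2_s: float
    volume: np.ndarray  # noiseless per-frame V (px^3)
    ds: np.ndarray
    dl: np.ndarray
    centroid_xy: np.ndarray  # noiseless per-frame center, drift/jumps included
    dropout_mask: np.ndarray  # (n_frames, 8) True where likelihood was degraded

    @property
    def n_beats(self) -> int:
        return int(self.beat_frames.size)

    def to_json(self, path) -> None:
        out = {
            "beat_frames": self.beat_frames.tolist(),
            "ibis_s": self.ibis_s.tolist(),
            "edv_per_beat": self.edv_per_beat.tolist(),
            "esv_per_beat": self.esv_per_beat.tolist(),
            "hr_bpm": self.hr_bpm,
            "sd1_s": self.sd1_s,
            "sd2_s": self.sd2_s,
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2)
            fh.write("\n")


def _raised_cosine_volume(phase: np.ndarray, edv0: float, esv0: float, sf: float) -> np.ndarray:
    """Volume at cycle phase in [0, 1): EDV at 0, ESV at ``sf``, back to EDV."""
    amp = edv0 - esv0
    v = np.empty_like(phase)
    contracting = phase < sf
    v[contracting] = edv0 - amp * 0.5 * (1 - np.cos(np.pi * phase[contracting] / sf))
    rel = (phase[~contracting] - sf) / (1.0 - sf)
    v[~contracting] = esv0 + amp * 0.5 * (1 - np.cos(np.pi * rel))
    return v


def _draw_ibis(spec: SyntheticSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    mean = 60.0 / spec.hr_bpm
    if spec.rr_sd_s == 0:
        return np.full(n, mean)
    eps = np.empty(n)
    phi = spec.rr_ar1
    innov_sd = spec.rr_sd_s * np.sqrt(1.0 - phi**2)
    eps[0] = rng.normal(0.0, spec.rr_sd_s)
    for i in range(1, n):
        eps[i] = phi * eps[i - 1] + rng.normal(0.0, innov_sd)
    floor = max(6.0 / spec.fps, 0.25 * mean)  # keep every beat resolvable
    return np.maximum(mean + eps, floor)


def simulate_track(spec: SyntheticSpec) -> tuple[LandmarkTrack, GroundTruth]:
    """Generate one recording and its ground truth.

    Deterministic in ``spec.seed``: the same spec yields an identical
    track; changing only the seed changes the noise realizations.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration_s * spec.fps))
    t = np.arange(n_frames) / spec.fps

    # Beat grid: one lead-in beat so t=0 falls mid-cycle, then enough
    # beats to cover the record.
    mean_ibi = 60.0 / spec.hr_bpm
    n_beats_max = int(np.ceil(spec.duration_s / (0.25 * mean_ibi))) + 4
    ibis_all = _draw_ibis(spec, rng, n_beats_max)
    starts = _START_PHASE * ibis_all[0] + np.concatenate(
        [[0.0], np.cumsum(ibis_all[1:])]
    )
    starts = np.concatenate([[starts[0] - ibis_all[0]], starts])  # lead-in
    ibis_grid = ibis_all
    # truncate to beats that begin before the record ends (plus one spare)
    last = int(np.searchsorted(starts, spec.duration_s)) + 1
    starts, ibis_grid = starts[: last + 1], ibis_grid[: last + 1]

    beat_of_frame = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, None)
    phase = (t - starts[beat_of_frame]) / ibis_grid[beat_of_frame]
    phase = np.clip(phase, 0.0, np.nextafter(1.0, 0.0))
    volume = _raised_cosine_volume(phase, spec.edv0, spec.esv0, spec.systolic_fraction)

    ds = np.cbrt(6.0 * volume / (np.pi * spec.aspect_ratio))
    dl = spec.aspect_ratio * ds

    # center = nominal + drift + accumulated jumps
    center = np.tile(np.asarray(spec.center_xy, float), (n_frames, 1))
    center += np.outer(np.arange(n_frames), np.asarray(spec.drift_px_per_frame, float))
    for frame, (dx, dy) in spec.jump_events:
        if not 0 <= frame < n_frames:
            raise ParameterError(f"jump event frame {frame} outside record")
        center[frame:] += (dx, dy)

    # 8 landmarks on the ellipse; landmark 1 along +x (short axis),
    # landmark 3 along +y (long axis) -> |p1-p5| = Ds, |p3-p7| = Dl.
    theta = np.deg2rad(45.0 * np.arange(8))
    x = center[:, [0]] + 0.5 * ds[:, None] * np.cos(theta)[None, :]
    y = center[:, [1]] + 0.5 * dl[:, None] * np.sin(theta)[None, :]

    if spec.jitter_px > 0:
        x = x + rng.normal(0.0, spec.jitter_px, x.shape)
        y = y + rng.normal(0.0, spec.jitter_px, y.shape)

    likelihood = np.full((n_frames, 8), _GOOD_LIKELIHOOD)
    dropout = np.zeros((n_frames, 8), dtype=bool)
    if spec.dropout_rate > 0:
        dropout = rng.random((n_frames, 8)) < spec.dropout_rate
        likelihood[dropout] = rng.uniform(0.02, 0.4, int(dropout.sum()))
        x[dropout] += rng.normal(0.0, _DROPOUT_DISPLACEMENT_PX, int(dropout.sum()))
        y[dropout] += rng.normal(0.0, _DROPOUT_DISPLACEMENT_PX, int(dropout.sum()))

    track = LandmarkTrack(
        frame_index=np.arange(n_frames, dtype=np.int64),
        x=x,
        y=y,
        likelihood=likelihood,
        fps=spec.fps,
        points=POINT_NAMES,
    )

    # ground truth: diastolic peaks strictly inside the record; true IBIs
    # are the exact (un-rounded) intervals between consecutive such peaks,
    # matching what beat detection can observe
    peak_frames = np.rint(starts * spec.fps).astype(np.int64)
    inside = (peak_frames >= 1) & (peak_frames <= n_frames - 2)
    true_ibis = np.diff(starts[inside])
    n_cycles = true_ibis.size
    if n_cycles >= 3:
        pc = poincare(true_ibis)
        sd1, sd2 = pc.sd1, pc.sd2
    else:
        sd1 = sd2 = float("nan")
    truth = GroundTruth(
        beat_frames=peak_frames[inside],
        ibis_s=true_ibis,
        edv_per_beat=np.full(n_cycles, spec.edv0),
        esv_per_beat=np.full(n_cycles, spec.esv0),
        hr_bpm=float(np.mean(60.0 / true_ibis)) if n_cycles else float("nan"),
        sd1_s=sd1,
        sd2_s=sd2,
        volume=volume,
        ds=ds,
        dl=dl,
        centroid_xy=center,
        dropout_mask=dropout,
    )
    return track, truth


_PRESETS: dict[str, dict] = {
    # Healthy 2-3 dpf embryo: ~150 bpm, EF 50%, mild rhythm variability.
    "control": dict(
        hr_bpm=150.0, edv0=4.0e5, esv0=2.0e5, rr_sd_s=0.010, rr_ar1=0.2
    ),
    # Ethanol-like pericardial edema: slower, smaller heart, smaller pulse
    # amplitude, but contractility (EF) preserved.
    "ethanol_like": dict(
        hr_bpm=110.0, edv0=2.6e5, esv0=1.3e5, rr_sd_s=0.012, rr_ar1=0.2
    ),
    # Ponatinib-like cardiotoxicity: the same reductions plus depressed
    # ejection (EF ~35%) and a markedly irregular rhythm.
    "ponatinib_like": dict(
        hr_bpm=100.0, edv0=2.4e5, esv0=1.56e5, rr_sd_s=0.040, rr_ar1=0.5
    ),
}


def preset(name: str, *, seed: int = 0, **overrides) -> SyntheticSpec:
    """Named simulation scenario: ``control``, ``ethanol_like`` or
    ``ponatinib_like``.

    Keyword overrides replace individual fields (e.g. ``jitter_px=1.0``).
    """
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return SyntheticSpec(label=name, seed=seed, **{**base, **overrides})


def preset_names() -> Sequence[str]:
    return tuple(_PRESETS)
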