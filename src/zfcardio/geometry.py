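"""Per-frame ventricle geometry: axis lengths, centroid and spheroid volume.

The ventricle is approximated as a prolate spheroid whose long axis is the
distance between landmarks 3 and 7 (``Dl``) and whose two equal equatorial
diameters are the short-axis distance between landmarks 1 and 5 (``Ds``).
Under that model the chamber volume is

    V = (pi / 6) * Dl * Ds**2

which for ``Dl == Ds`` reduces to the volume of a sphere of that diameter.
No ellipse fitting is performed: the axis endpoints are exactly the named
landmark pairs, and the remaining landmarks contribute only to the
centroid used for drift/jump diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolation, DomainError
from .tracking_io import LandmarkTrack

_SHORT_AXIS = ("1", "5")
_LONG_AXIS = ("3", "7")


@dataclass(frozen=True)
class AxisSeries:
    """Per-frame short axis, long axis, spheroid volume and centroid.

    Lengths are in micrometers when the source track carries a pixel
    scale, otherwise in pixels; volumes are in the cubed length unit.
    """

    time_s: np.ndarray
    ds: np.ndarray
    dl: np.ndarray
    volume: np.ndarray
    centroid_xy: np.ndarray  # shape (n, 2), always in pixels
    fps: float
    length_unit: str = "px"

    def __post_init__(self) -> None:
        n = self.time_s.size
        if not (self.ds.size == self.dl.size == self.volume.size == n):
            raise ContractViolation("axis series arrays must be aligned")
        if self.centroid_xy.shape != (n, 2):
            raise ContractViolation("centroid_xy must have shape (n, 2)")

    @property
    def n_frames(self) -> int:
        return int(self.time_s.size)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-frame table: time_s, Ds, Dl, V, centroid_x, centroid_y."""
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "Ds": self.ds,
                "Dl": self.dl,
                "V": self.volume,
                "centroid_x": self.centroid_xy[:, 0],
                "centroid_y": self.centroid_xy[:, 1],
            }
        )


def spheroid_volume(dl, ds):
    """Volume of a prolate spheroid with polar diameter ``dl`` and
    equatorial diameter ``ds``: ``(pi/6) * dl * ds**2``.

    Accepts scalars or arrays; units are the cube of the input unit.
    """
    dl = np.asarray(dl, dtype=float)
    ds = np.asarray(ds, dtype=float)
    if np.any(dl <= 0) or np.any(ds <= 0):
        raise DomainError("axis lengths must be positive")
    out = (np.pi / 6.0) * dl * ds**2
    return float(out) if out.ndim == 0 else out


def centroid_trajectory(track: LandmarkTrack) -> np.ndarray:
    """Per-frame mean position of the 8 landmarks, shape ``(n, 2)`` in px.

    The centroid is the drift/jump diagnostic: slide drift appears as a
    linear trend, a sudden animal movement as a single large
    frame-to-frame displacement.
    """
    _require_finite(track)
    return np.column_stack([track.x.mean(axis=1), track.y.mean(axis=1)])


def axis_lengths(track: LandmarkTrack) -> AxisSeries:
    """Compute per-frame ``Ds`` (landmarks 1-5), ``Dl`` (landmarks 3-7),
    centroid, and spheroid volume.

    Expects a filtered track (all coordinates finite).  If a pixel scale
    is set on the track, lengths are converted to micrometers (volumes to
    um^3); the centroid stays in pixels for plotting against the frame.
    A warning is emitted when the "short" axis exceeds the "long" axis in
    more than half of the frames, which usually means the landmark ring
    was labeled in a rotated order.
    """
    _require_finite(track)
    i1, i5 = (track.point_index(p) for p in _SHORT_AXIS)
    i3, i7 = (track.point_index(p) for p in _LONG_AXIS)
    ds = np.hypot(track.x[:, i1] - track.x[:, i5], track.y[:, i1] - track.y[:, i5])
    dl = np.hypot(track.x[:, i3] - track.x[:, i7], track.y[:, i3] - track.y[:, i7])

    unit = "px"
    if track.scale_um_per_px is not None:
        ds = ds * track.scale_um_per_px
        dl = dl * track.scale_um_per_px
        unit = "um"

    if ds.size and np.mean(ds > dl) > 0.5:
        warnings.warn(
            "short axis (1-5) exceeds long axis (3-7) in most frames; "
            "check the landmark labeling order",
            stacklevel=2,
        )
    return AxisSeries(
        time_s=track.time_s,
        ds=ds,
        dl=dl,
        volume=spheroid_volume(dl, ds),
        centroid_xy=centroid_trajectory(track),
        fps=track.fps,
        length_unit=unit,
    )


def _require_finite(track: LandmarkTrack) -> None:
    bad = ~(np.isfinite(track.x) & np.isfinite(track.y))
    if bad.any():
        frame = int(np.asarray(track.frame_index)[bad.any(axis=1)][0])
        raise ContractViolation(
            f"non-finite coordinates at frame {frame}; filter the track first"
        )
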