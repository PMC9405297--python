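"""Read, write and clean landmark tracking tables.

The on-disk dialect is the one produced by markerless pose-estimation
tools for single-animal videos: a CSV with three header rows (scorer /
bodyparts / coords) and one leading frame-index column, where every body
part contributes an ``x``, ``y`` and ``likelihood`` column, or an
equivalent single-table HDF5 layout.  The ventricle is described by eight
boundary landmarks named ``"1"`` .. ``"8"``: points 1 and 5 span the short
axis of the chamber, points 3 and 7 the long axis, and the remaining
points complete the boundary ring.

The tables carry no timebase, so frames-per-second is caller-supplied
metadata (default 30, the acquisition rate of the 1-minute recordings the
pipeline is designed for).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    ParameterError,
    TableParseError,
    UnrecoverableTrackError,
)

#: Canonical landmark names, in boundary order.
POINT_NAMES: tuple[str, ...] = ("1", "2", "3", "4", "5", "6", "7", "8")

#: Default likelihood threshold below which a sample is treated as unreliable.
DEFAULT_P_CUTOFF: float = 0.6

#: Default frame rate (frames per second) when the caller supplies none.
DEFAULT_FPS: float = 30.0

_COORDS = ("x", "y", "likelihood")
_SCORER = "zfcardio"
_HDF_KEY = "tracks"

Dialect = Literal["csv3header", "hdf"]


@dataclass(frozen=True)
class LandmarkTrack:
    """Per-frame positions and confidences of the 8 ventricle landmarks.

    Arrays are aligned: ``x``, ``y`` and ``likelihood`` all have shape
    ``(n_frames, 8)`` with columns in ``points`` order.  ``frame_index``
    keeps the original (0-based) video frame numbers so that dropped
    frames leave visible gaps in the timeline.
    """

    frame_index: np.ndarray
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    fps: float = DEFAULT_FPS
    points: tuple[str, ...] = POINT_NAMES
    scale_um_per_px: float | None = None
    #: per-point count of samples replaced by gap filling (set by filtering)
    n_replaced: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.points) != 8 or len(set(self.points)) != 8:
            raise FormatError(
                f"expected exactly 8 unique point names, got {self.points!r}"
            )
        if self.fps <= 0:
            raise ParameterError(f"fps must be positive, got {self.fps}")
        fi = np.asarray(self.frame_index)
        if fi.ndim != 1 or (fi.size > 1 and not np.all(np.diff(fi) > 0)):
            raise FormatError("frame_index must be strictly increasing")
        n = fi.size
        for name in ("x", "y", "likelihood"):
            arr = getattr(self, name)
            if arr.shape != (n, 8):
                raise FormatError(
                    f"{name} has shape {arr.shape}, expected ({n}, 8)"
                )
        lk = self.likelihood
        if lk.size and (np.nanmin(lk) < 0 or np.nanmax(lk) > 1):
            raise FormatError("likelihood values must lie in [0, 1]")
        if self.scale_um_per_px is not None and self.scale_um_per_px <= 0:
            raise ParameterError("scale_um_per_px must be positive")

    @property
    def n_frames(self) -> int:
        return int(np.asarray(self.frame_index).size)

    @property
    def time_s(self) -> np.ndarray:
        """Timestamps in seconds, ``frame_index / fps``."""
        return np.asarray(self.frame_index, dtype=float) / self.fps

    def point_index(self, name: str) -> int:
        try:
            return self.points.index(name)
        except ValueError:
            raise KeyError(f"unknown landmark {name!r}") from None

    def to_dataframe(self, scorer: str = _SCORER) -> pd.DataFrame:
        """Assemble the standard 3-level-column table (scorer/bodyparts/coords)."""
        columns = pd.MultiIndex.from_product(
            [[scorer], list(self.points), list(_COORDS)],
            names=["scorer", "bodyparts", "coords"],
        )
        data = np.empty((self.n_frames, 24), dtype=float)
        data[:, 0::3] = self.x
        data[:, 1::3] = self.y
        data[:, 2::3] = self.likelihood
        return pd.DataFrame(data, index=np.asarray(self.frame_index), columns=columns)


def _track_from_dataframe(
    df: pd.DataFrame,
    fps: float,
    scale_um_per_px: float | None,
    source: str,
) -> LandmarkTrack:
    if df.columns.nlevels != 3:
        raise FormatError(
            f"{source}: expected 3 header rows (scorer/bodyparts/coords), "
            f"got {df.columns.nlevels} column levels"
        )
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    missing = [p for p in POINT_NAMES if p not in bodyparts]
    extra = [p for p in bodyparts if p not in POINT_NAMES]
    if missing or extra:
        raise FormatError(
            f"{source}: body parts do not match the 8-landmark scheme"
            + (f"; missing {missing}" if missing else "")
            + (f"; unexpected {extra}" if extra else "")
        )
    scorer = df.columns.get_level_values(0)[0]
    for part in POINT_NAMES:
        for coord in _COORDS:
            if (scorer, part, coord) not in df.columns:
                raise FormatError(
                    f"{source}: body part {part!r} lacks a {coord!r} column"
                )

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        row = bad.any(axis=1).idxmax()
        raise TableParseError(f"{source}: non-numeric cell in row {row!r}")
    if numeric.isna().to_numpy().any():
        row = numeric.isna().any(axis=1).idxmax()
        raise TableParseError(f"{source}: missing value in row {row!r}")

    x = np.column_stack(
        [numeric[(scorer, p, "x")].to_numpy(float) for p in POINT_NAMES]
    )
    y = np.column_stack(
        [numeric[(scorer, p, "y")].to_numpy(float) for p in POINT_NAMES]
    )
    lk = np.column_stack(
        [numeric[(scorer, p, "likelihood")].to_numpy(float) for p in POINT_NAMES]
    )
    frame_index = np.asarray(df.index, dtype=np.int64)
    return LandmarkTrack(
        frame_index=frame_index,
        x=x,
        y=y,
        likelihood=lk,
        fps=fps,
        scale_um_per_px=scale_um_per_px,
    )


def read_landmark_table(
    path: str | Path,
    dialect: Dialect = "csv3header",
    *,
    fps: float = DEFAULT_FPS,
    scale_um_per_px: float | None = None,
    hdf_key: str = _HDF_KEY,
) -> LandmarkTrack:
    """Read a tracking table into a :class:`LandmarkTrack`.

    ``fps`` and ``scale_um_per_px`` are acquisition metadata the file does
    not carry.  Column order follows the header's body-part order, which
    must be exactly the eight canonical landmark names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv3header":
        try:
            df = pd.read_csv(
                path, header=[0, 1, 2], index_col=0, float_precision="round_trip"
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise FormatError(f"{path}: cannot parse as a 3-header CSV: {exc}") from exc
        # a non-numeric frame-index column is a parse error, not a format error
        try:
            df.index = pd.to_numeric(df.index).astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise TableParseError(f"{path}: non-integer frame index") from exc
    elif dialect == "hdf":
        df = pd.read_hdf(path, key=hdf_key)
        if not isinstance(df, pd.DataFrame):
            raise FormatError(f"{path}: HDF key {hdf_key!r} is not a table")
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    return _track_from_dataframe(df, fps, scale_um_per_px, str(path))


def write_landmark_table(
    track: LandmarkTrack,
    path: str | Path,
    dialect: Dialect = "csv3header",
    *,
    hdf_key: str = _HDF_KEY,
) -> Path:
    """Write a track so that :func:`read_landmark_table` recovers it exactly."""
    if track.n_frames == 0:
        raise ParameterError("refusing to write a track with 0 frames")
    path = Path(path)
    df = track.to_dataframe()
    if dialect == "csv3header":
        df.to_csv(path, float_format="%.17g")  # round-trippable floats
    elif dialect == "hdf":
        df.to_hdf(path, key=hdf_key, mode="w")
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    return path


def filter_by_likelihood(
    track: LandmarkTrack,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    gap_policy: Literal["interpolate", "drop_frame"] = "interpolate",
) -> LandmarkTrack:
    """Replace or drop samples whose likelihood falls below ``p_cutoff``.

    With ``gap_policy="interpolate"`` every unreliable (frame, point)
    sample is rebuilt by linear interpolation between the nearest
    confident frames of the same point; leading/trailing gaps take the
    nearest confident value (no extrapolation).  With ``drop_frame`` any
    frame containing an unreliable sample is removed entirely, preserving
    the original frame numbering of the survivors.

    The per-point number of replaced (or below-cutoff) samples is recorded
    on the returned track.  The operation is idempotent: confident samples
    are never altered, so a second pass with the same cutoff finds the
    same gaps and fills them identically.
    """
    if not 0.0 <= p_cutoff <= 1.0:
        raise ParameterError(f"p_cutoff must be in [0, 1], got {p_cutoff}")
    if p_cutoff == 0.0:
        return replace(track, n_replaced={p: 0 for p in track.points})

    low = track.likelihood < p_cutoff
    counts = {p: int(low[:, j].sum()) for j, p in enumerate(track.points)}

    if gap_policy == "interpolate":
        fi = np.asarray(track.frame_index, dtype=float)
        x = track.x.copy()
        y = track.y.copy()
        for j, name in enumerate(track.points):
            good = ~low[:, j]
            if not good.any():
                raise UnrecoverableTrackError(
                    f"landmark {name!r} has no frame with likelihood >= {p_cutoff}"
                )
            if good.all():
                continue
            # np.interp clamps outside the confident range -> nearest-value
            # extension at the record edges
            x[low[:, j], j] = np.interp(fi[low[:, j]], fi[good], x[good, j])
            y[low[:, j], j] = np.interp(fi[low[:, j]], fi[good], y[good, j])
        return replace(track, x=x, y=y, n_replaced=counts)

    if gap_policy == "drop_frame":
        keep = ~low.any(axis=1)
        if not keep.any():
            raise UnrecoverableTrackError(
                f"no frame has all landmarks at likelihood >= {p_cutoff}"
            )
        return replace(
            track,
            frame_index=np.asarray(track.frame_index)[keep],
            x=track.x[keep],
            y=track.y[keep],
            likelihood=track.likelihood[keep],
            n_replaced=counts,
        )

    raise ParameterError(f"unknown gap_policy {gap_policy!r}")
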