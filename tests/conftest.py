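import numpy as np
import pytest

from zfcardio.geometry import AxisSeries
from zfcardio.tracking_io import POINT_NAMES, LandmarkTrack


@pytest.fixture
def ring_track_factory():
    """Build a LandmarkTrack by placing the 8 landmarks on an ellipse.

    Independent of the synthetic_heart generator: a plain parametric ring
    with landmark 1 on the +x short semi-axis and landmark 3 on the +y
    long semi-axis, so |p1 - p5| = ds and |p3 - p7| = dl by construction.
    """

    def make(
        ds,
        dl,
        center=(100.0, 100.0),
        fps=30.0,
        likelihood=None,
        scale_um_per_px=None,
    ):
        ds = np.atleast_1d(np.asarray(ds, dtype=float))
        dl = np.atleast_1d(np.asarray(dl, dtype=float))
        n = ds.size
        center = np.broadcast_to(np.asarray(center, dtype=float), (n, 2))
        theta = np.deg2rad(45.0 * np.arange(8))
        x = center[:, [0]] + 0.5 * ds[:, None] * np.cos(theta)
        y = center[:, [1]] + 0.5 * dl[:, None] * np.sin(theta)
        if likelihood is None:
            likelihood = np.full((n, 8), 0.99)
        return LandmarkTrack(
            frame_index=np.arange(n, dtype=np.int64),
            x=x,
            y=y,
            likelihood=np.asarray(likelihood, dtype=float),
            fps=fps,
            points=POINT_NAMES,
            scale_um_per_px=scale_um_per_px,
        )

    return make


@pytest.fixture
def sinusoid_series():
    """Noiseless sinusoidal volume trace rendered as a valid AxisSeries."""

    def make(freq_hz=2.0, duration_s=60.0, fps=30.0, v0=3.0e5, amp=1.0e5, ar=1.2):
        t = np.arange(int(round(duration_s * fps))) / fps
        v = v0 + amp * np.sin(2 * np.pi * freq_hz * t)
        ds = np.cbrt(6.0 * v / (np.pi * ar))
        return AxisSeries(
            time_s=t,
            ds=ds,
            dl=ar * ds,
            volume=v,
            centroid_xy=np.zeros((t.size, 2)),
            fps=fps,
        )

    return make
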