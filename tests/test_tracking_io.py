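"""Round-trip, validation and likelihood-filtering behavior of tracking IO."""

import numpy as np
import pandas as pd
import pytest

from zfcardio.errors import (
    FormatError,
    ParameterError,
    TableParseError,
    UnrecoverableTrackError,
)
from zfcardio.synthetic_heart import preset, simulate_track
from zfcardio.tracking_io import (
    LandmarkTrack,
    filter_by_likelihood,
    read_landmark_table,
    write_landmark_table,
)


@pytest.fixture
def small_track():
    track, _ = simulate_track(preset("control", seed=7, duration_s=4.0))
    return track


@pytest.mark.parametrize("dialect,ext", [("csv3header", "csv"), ("hdf", "h5")])
def test_write_read_round_trip(small_track, tmp_path, dialect, ext):
    path = tmp_path / f"track.{ext}"
    write_landmark_table(small_track, path, dialect)
    back = read_landmark_table(path, dialect, fps=small_track.fps)
    np.testing.assert_array_equal(back.frame_index, small_track.frame_index)
    np.testing.assert_allclose(back.x, small_track.x, rtol=0, atol=0)
    np.testing.assert_allclose(back.y, small_track.y, rtol=0, atol=0)
    np.testing.assert_allclose(back.likelihood, small_track.likelihood)
    assert back.points == small_track.points
    assert back.fps == small_track.fps


def test_csv_dialect_has_three_header_rows(small_track, tmp_path):
    path = tmp_path / "track.csv"
    write_landmark_table(small_track, path, "csv3header")
    lines = path.read_text().splitlines()
    assert lines[0].startswith("scorer,")
    assert lines[1].startswith("bodyparts,")
    assert lines[2].startswith("coords,")
    # each body part appears three times (x, y, likelihood)
    assert lines[1].split(",").count("3") == 3


def test_missing_bodypart_is_format_error(small_track, tmp_path):
    path = tmp_path / "bad.csv"
    df = small_track.to_dataframe()
    df = df.drop(columns=[c for c in df.columns if c[1] == "4"])
    df.to_csv(path)
    with pytest.raises(FormatError, match="4"):
        read_landmark_table(path, "csv3header")


def test_non_numeric_cell_is_parse_error_with_row(small_track, tmp_path):
    path = tmp_path / "bad.csv"
    lines = write_landmark_table(small_track, path).read_text().splitlines()
    cells = lines[5].split(",")
    cells[3] = "oops"
    lines[5] = ",".join(cells)
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(TableParseError, match=r"row"):
        read_landmark_table(path, "csv3header")


def test_write_empty_track_rejected(small_track, tmp_path):
    empty = LandmarkTrack(
        frame_index=np.array([], dtype=np.int64),
        x=np.empty((0, 8)),
        y=np.empty((0, 8)),
        likelihood=np.empty((0, 8)),
    )
    with pytest.raises(ParameterError):
        write_landmark_table(empty, tmp_path / "empty.csv")


def test_missing_file_raises(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_landmark_table(tmp_path / "nope.csv")


class TestFilterByLikelihood:
    def test_zero_cutoff_is_passthrough(self, small_track):
        out = filter_by_likelihood(small_track, p_cutoff=0.0)
        np.testing.assert_array_equal(out.x, small_track.x)
        assert all(v == 0 for v in out.n_replaced.values())

    def test_single_gap_linear_midpoint(self, small_track):
        x = small_track.x.copy()
        y = small_track.y.copy()
        lk = small_track.likelihood.copy()
        x[9:12, 2], y[9:12, 2] = (10.0, 11.0, 12.0), (10.0, 13.0, 14.0)
        lk[10, 2] = 0.1
        track = LandmarkTrack(
            frame_index=small_track.frame_index, x=x, y=y, likelihood=lk
        )
        out = filter_by_likelihood(track, p_cutoff=0.6)
        assert out.x[10, 2] == pytest.approx(11.0)  # midpoint of (10, 12)
        assert out.y[10, 2] == pytest.approx(12.0)  # midpoint of (10, 14)
        assert out.n_replaced["3"] == 1

    def test_edge_gaps_take_nearest_confident_value(self, small_track):
        lk = small_track.likelihood.copy()
        lk[:3, 0] = 0.1
        lk[-2:, 0] = 0.1
        track = LandmarkTrack(
            frame_index=small_track.frame_index,
            x=small_track.x,
            y=small_track.y,
            likelihood=lk,
        )
        out = filter_by_likelihood(track, p_cutoff=0.6)
        assert np.all(out.x[:3, 0] == out.x[3, 0])
        assert np.all(out.x[-2:, 0] == out.x[-3, 0])

    def test_idempotent(self, small_track):
        track, _ = simulate_track(
            preset("control", seed=3, duration_s=6.0, dropout_rate=0.05)
        )
        once = filter_by_likelihood(track, 0.6)
        twice = filter_by_likelihood(once, 0.6)
        np.testing.assert_array_equal(once.x, twice.x)
        np.testing.assert_array_equal(once.y, twice.y)

    @pytest.mark.parametrize("gap_policy", ["interpolate", "drop_frame"])
    def test_raising_cutoff_never_decreases_replacements(self, gap_policy):
        track, _ = simulate_track(
            preset("control", seed=5, duration_s=6.0, dropout_rate=0.08)
        )
        totals = []
        for cutoff in (0.0, 0.3, 0.6, 0.95):
            out = filter_by_likelihood(track, cutoff, gap_policy)
            totals.append(sum(out.n_replaced.values()))
        assert totals == sorted(totals)

    def test_drop_frame_removes_whole_frames_keeping_numbering(self, small_track):
        lk = small_track.likelihood.copy()
        lk[5, 3] = 0.1
        track = LandmarkTrack(
            frame_index=small_track.frame_index,
            x=small_track.x,
            y=small_track.y,
            likelihood=lk,
        )
        out = filter_by_likelihood(track, 0.6, gap_policy="drop_frame")
        assert out.n_frames == track.n_frames - 1
        assert 5 not in out.frame_index
        assert np.all(np.diff(out.frame_index) >= 1)

    def test_point_with_no_confident_frame_unrecoverable(self, small_track):
        lk = small_track.likelihood.copy()
        lk[:, 6] = 0.2
        track = LandmarkTrack(
            frame_index=small_track.frame_index,
            x=small_track.x,
            y=small_track.y,
            likelihood=lk,
        )
        with pytest.raises(UnrecoverableTrackError, match="7"):
            filter_by_likelihood(track, 0.6)

    def test_reconstruction_error_on_jitter_scale(self):
        # same seed with dropout disabled gives the uncorrupted positions,
        # because the landmark jitter stream is drawn before dropout
        spec = preset("control", seed=11, dropout_rate=0.03, jitter_px=0.5)
        track, truth = simulate_track(spec)
        ref, _ = simulate_track(
            preset("control", seed=11, dropout_rate=0.0, jitter_px=0.5)
        )
        clean = filter_by_likelihood(track, 0.6)
        mask = truth.dropout_mask
        assert mask.sum() > 100
        raw_err = np.abs(track.x[mask] - ref.x[mask]).mean()
        rec_err = np.abs(clean.x[mask] - ref.x[mask]).mean()
        assert raw_err > 10.0  # the corrupted samples really were far off
        assert rec_err < 3.0  # interpolation restores jitter-scale accuracy


def test_seven_bodyparts_header_rejected(tmp_path):
    cols = pd.MultiIndex.from_product(
        [["s"], [str(i) for i in range(1, 8)], ["x", "y", "likelihood"]]
    )
    df = pd.DataFrame(np.zeros((5, 21)), columns=cols)
    path = tmp_path / "seven.csv"
    df.to_csv(path)
    with pytest.raises(FormatError, match="missing"):
        read_landmark_table(path, "csv3header")
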