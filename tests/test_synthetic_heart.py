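"""Generator contracts: determinism, construction inverses, ground truth."""

import numpy as np
import pytest

from zfcardio.errors import ParameterError
from zfcardio.geometry import axis_lengths, spheroid_volume
from zfcardio.hrv_poincare import poincare
from zfcardio.report import RunConfig, analyze_track
from zfcardio.synthetic_heart import SyntheticSpec, preset, simulate_track


class TestSpecValidation:
    def test_unresolvable_beat_rejected(self):
        with pytest.raises(ParameterError, match="unresolvable"):
            SyntheticSpec(hr_bpm=400.0, fps=30.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(edv0=1e5, esv0=2e5),
            dict(systolic_fraction=1.2),
            dict(rr_ar1=1.0),
            dict(dropout_rate=-0.1),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SyntheticSpec(**kwargs)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ParameterError, match="unknown preset"):
            preset("caffeine_like")


class TestDeterminism:
    def test_same_seed_identical_different_seed_not(self):
        a, _ = simulate_track(preset("control", seed=42, duration_s=5.0))
        b, _ = simulate_track(preset("control", seed=42, duration_s=5.0))
        c, _ = simulate_track(preset("control", seed=43, duration_s=5.0))
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.likelihood, b.likelihood)
        assert not np.array_equal(a.x, c.x)


class TestConstructionInverses:
    def test_noiseless_ring_returns_generator_volume(self):
        spec = preset("control", seed=0, jitter_px=0.0, duration_s=5.0)
        track, truth = simulate_track(spec)
        series = axis_lengths(track)
        np.testing.assert_allclose(series.volume, truth.volume, rtol=1e-9)
        np.testing.assert_allclose(series.ds, truth.ds, rtol=1e-9)
        np.testing.assert_allclose(series.dl, truth.dl, rtol=1e-9)

    def test_volume_extremes_match_spec(self):
        spec = preset("control", seed=0, jitter_px=0.0, rr_sd_s=0.0)
        _, truth = simulate_track(spec)
        # sampled extremes sit within the frame-discretization error of the
        # continuous waveform extremes (the trough is the sharper feature)
        assert truth.volume.max() == pytest.approx(spec.edv0, rel=5e-3)
        assert truth.volume.min() == pytest.approx(spec.esv0, rel=2e-2)
        assert truth.volume.max() <= spec.edv0
        assert truth.volume.min() >= spec.esv0

    def test_aspect_ratio_is_constant(self):
        spec = preset("control", seed=0, jitter_px=0.0, duration_s=5.0)
        _, truth = simulate_track(spec)
        np.testing.assert_allclose(truth.dl / truth.ds, spec.aspect_ratio)

    def test_single_frame_geometry_identity(self):
        spec = preset("control", seed=0, jitter_px=0.0, duration_s=5.0)
        track, truth = simulate_track(spec)
        k = 37
        p = {name: (track.x[k, j], track.y[k, j]) for j, name in enumerate(track.points)}
        ds = np.hypot(p["1"][0] - p["5"][0], p["1"][1] - p["5"][1])
        dl = np.hypot(p["3"][0] - p["7"][0], p["3"][1] - p["7"][1])
        assert spheroid_volume(dl, ds) == pytest.approx(truth.volume[k], rel=1e-9)


class TestGroundTruth:
    def test_ibi_sd_and_autocorrelation_structure(self):
        spec = preset("control", seed=19, rr_sd_s=0.02, rr_ar1=0.5)
        _, truth = simulate_track(spec)
        assert truth.ibis_s.size >= 100
        assert np.std(truth.ibis_s, ddof=1) == pytest.approx(0.02, rel=0.3)
        r1 = np.corrcoef(truth.ibis_s[:-1], truth.ibis_s[1:])[0, 1]
        assert r1 > 0.2

    def test_sd_indices_consistent_with_poincare_formula(self):
        _, truth = simulate_track(preset("control", seed=23))
        r = poincare(truth.ibis_s)
        assert truth.sd1_s == pytest.approx(r.sd1)
        assert truth.sd2_s == pytest.approx(r.sd2)

    def test_dropout_rate_realized(self):
        spec = preset("control", seed=29, dropout_rate=0.05)
        track, truth = simulate_track(spec)
        frac = truth.dropout_mask.mean()
        assert frac == pytest.approx(0.05, rel=0.2)
        assert np.all(track.likelihood[truth.dropout_mask] < 0.6)
        assert np.all(track.likelihood[~truth.dropout_mask] >= 0.9)

    def test_json_sidecar_round_trip(self, tmp_path):
        import json

        _, truth = simulate_track(preset("control", seed=1, duration_s=5.0))
        path = tmp_path / "truth.json"
        truth.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["beat_frames"] == truth.beat_frames.tolist()
        assert loaded["hr_bpm"] == pytest.approx(truth.hr_bpm)


class TestDriftRobustness:
    def test_drift_leaves_cardiac_panel_within_seed_spread(self):
        cfg = RunConfig()
        base, drifted = [], []
        for seed in range(6):
            t0, _ = simulate_track(preset("control", seed=seed))
            t1, _ = simulate_track(
                preset("control", seed=seed, drift_px_per_frame=(0.5, -0.3))
            )
            base.append(analyze_track(t0, cfg)[0])
            drifted.append(analyze_track(t1, cfg)[0])
        for attr in ("heart_rate", "edv", "esv", "ef"):
            b = np.array([getattr(p, attr) for p in base])
            d = np.array([getattr(p, attr) for p in drifted])
            spread = np.ptp(b) + 1e-9
            assert abs(b.mean() - d.mean()) <= max(spread, 0.01 * abs(b.mean()))


@pytest.fixture(scope="module")
def panels():
    cfg = RunConfig()
    out = {}
    for name in ("control", "ethanol_like", "ponatinib_like"):
        ps, hs = [], []
        for seed in range(5):
            track, _ = simulate_track(preset(name, seed=seed))
            panel, *_, hrv = analyze_track(track, cfg)
            ps.append(panel)
            hs.append(hrv)
        out[name] = (ps, hs)
    return out


class TestPresetDirections:

    @pytest.mark.parametrize("treated", ["ethanol_like", "ponatinib_like"])
    def test_pump_parameters_reduced(self, panels, treated):
        for attr in ("heart_rate", "edv", "esv", "sv", "co"):
            t = np.mean([getattr(p, attr) for p in panels[treated][0]])
            c = np.mean([getattr(p, attr) for p in panels["control"][0]])
            assert t < c

    def test_only_ponatinib_like_depresses_contractility(self, panels):
        ef = {k: np.mean([p.ef for p in v[0]]) for k, v in panels.items()}
        sf = {k: np.mean([p.sf for p in v[0]]) for k, v in panels.items()}
        assert ef["ponatinib_like"] < ef["control"] - 5
        assert sf["ponatinib_like"] < sf["control"] - 3
        assert abs(ef["ethanol_like"] - ef["control"]) < 5

    def test_ponatinib_like_raises_hrv(self, panels):
        for i in (0, 1):  # sd1, sd2
            t = np.mean([(h.sd1, h.sd2)[i] for h in panels["ponatinib_like"][1]])
            c = np.mean([(h.sd1, h.sd2)[i] for h in panels["control"][1]])
            assert t > c
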