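"""KLT feature tracking, probe interpolation (vs a brute-force barycentric
oracle), twitch-series recovery and series comparison."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.spatial import Delaunay

from echotrace.containers import ImageSequence
from echotrace.errors import AnalysisError
from echotrace.feature_tracking import (
    ProbeGrid,
    align_and_compare,
    detect_features,
    interpolate_probe_displacement,
    track_features,
    track_probes,
    track_twitch,
    twitch_series,
)


def _seq(frames, rate=80.0):
    return ImageSequence(np.asarray(frames), rate, (0.05, 0.05))


class TestDetect:
    def test_constant_image_yields_empty_set(self):
        fs = detect_features(np.full((80, 80), 17, dtype=np.uint8))
        assert fs.n == 0

    def test_single_bright_point_found(self):
        img = np.zeros((80, 80))
        img[40, 55] = 255.0
        img = gaussian_filter(img, 1.5)
        fs = detect_features(img, max_n=5)
        assert fs.n >= 1
        assert np.hypot(fs.positions[0, 0] - 40, fs.positions[0, 1] - 55) <= 0.5

    def test_min_spacing_enforced(self, speckle_frame):
        fs = detect_features(speckle_frame, max_n=200, min_spacing_px=8)
        assert fs.n > 20
        d = np.sqrt(
            ((fs.positions[:, None, :] - fs.positions[None, :, :]) ** 2).sum(-1)
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 8.0


class TestTrack:
    def test_static_sequence_all_survive_zero_motion(self, speckle_frame):
        seq = _seq(np.stack([speckle_frame] * 6))
        sets = track_features(seq, replenish=False)
        n0 = sets[0].n
        for fs in sets[1:]:
            assert fs.n == n0
            np.testing.assert_allclose(fs.displacement, 0.0, atol=1e-6)
        assert np.all(sets[-1].ages == 5)

    def test_global_integer_shift_recovered(self, speckle_frame):
        shifted = np.roll(speckle_frame, 2, axis=0)
        seq = _seq([speckle_frame, shifted])
        sets = track_features(seq, replenish=False)
        d = sets[1].displacement
        keep = np.all(np.isfinite(d), axis=1)
        assert keep.sum() > 10
        np.testing.assert_allclose(d[keep, 0], 2.0, atol=0.1)
        np.testing.assert_allclose(d[keep, 1], 0.0, atol=0.1)

    def test_all_features_lost_names_frame(self, speckle_frame):
        frames = [speckle_frame, np.zeros_like(speckle_frame)]
        with pytest.raises(AnalysisError, match="frame 1"):
            track_features(_seq(frames), replenish=False)

    def test_features_persist_on_twitch_scene(self, twitch_short):
        _, seq, _, seg = twitch_short
        sub = ImageSequence(seq.frames[:30], seq.frame_rate_hz, seq.calib_mm_per_px)
        sets = track_features(sub, seg)
        fasc = sets[-1].labels == "fascicle"
        frac_old = np.mean(sets[-1].ages[fasc] >= 10)
        assert frac_old >= 0.8


class TestProbeInterpolation:
    @staticmethod
    def _random_cloud(rng, n=40):
        return rng.uniform(10, 90, size=(n, 2))

    def test_uniform_displacement_passed_through(self):
        rng = np.random.default_rng(0)
        fp = self._random_cloud(rng)
        fd = np.tile([1.5, -0.5], (len(fp), 1))
        labels = np.full(len(fp), "fascicle", dtype=object)
        probes = rng.uniform(20, 80, size=(5, 5, 2))
        out = interpolate_probe_displacement(
            fp, fd, labels, probes, np.full((5, 5), "fascicle", dtype=object)
        )
        np.testing.assert_allclose(out[..., 0], 1.5, atol=1e-9)
        np.testing.assert_allclose(out[..., 1], -0.5, atol=1e-9)

    def test_affine_field_exact_inside_hull(self):
        """Linear interpolation reproduces an affine field exactly."""
        rng = np.random.default_rng(1)
        fp = self._random_cloud(rng, 60)
        A = np.array([[0.02, -0.01], [0.005, 0.03]])
        b = np.array([0.7, -0.2])
        fd = fp @ A.T + b
        labels = np.full(len(fp), "fascicle", dtype=object)
        probes = rng.uniform(30, 70, size=(4, 6, 2))
        out = interpolate_probe_displacement(
            fp, fd, labels, probes, np.full((4, 6), "fascicle", dtype=object)
        )
        expected = probes @ A.T + b
        tri = Delaunay(fp)
        inside = tri.find_simplex(probes.reshape(-1, 2)).reshape(4, 6) >= 0
        np.testing.assert_allclose(out[inside], expected[inside], atol=1e-6)

    def test_matches_brute_force_barycentric_oracle(self):
        """Independent oracle: explicit point-in-triangle search plus
        hand-computed barycentric weights for a smooth nonlinear field."""
        rng = np.random.default_rng(2)
        fp = self._random_cloud(rng, 50)
        fd = np.column_stack(
            [np.sin(fp[:, 0] / 15.0), np.cos(fp[:, 1] / 20.0)]
        )
        labels = np.full(len(fp), "fascicle", dtype=object)
        probes = rng.uniform(25, 75, size=(30, 2))
        out = interpolate_probe_displacement(
            fp, fd, labels, probes[None], np.full((1, 30), "fascicle", dtype=object)
        )[0]
        tri = Delaunay(fp)
        for k, p in enumerate(probes):
            found = None
            for simplex in tri.simplices:
                v = fp[simplex]
                mat = np.column_stack([v[0] - v[2], v[1] - v[2]])
                try:
                    w01 = np.linalg.solve(mat, p - v[2])
                except np.linalg.LinAlgError:
                    continue
                w = np.array([w01[0], w01[1], 1 - w01.sum()])
                if np.all(w >= -1e-9):
                    found = w @ fd[simplex]
                    break
            if found is not None:
                np.testing.assert_allclose(out[k], found, atol=1e-8)

    def test_too_few_features_yields_missing(self):
        fp = np.array([[10.0, 10.0], [20.0, 20.0]])
        fd = np.ones((2, 2))
        labels = np.full(2, "fascicle", dtype=object)
        probes = np.array([[[15.0, 15.0]]])
        out = interpolate_probe_displacement(
            fp, fd, labels, probes, np.array([["fascicle"]], dtype=object)
        )
        assert np.all(np.isnan(out))

    def test_dropping_30_percent_of_features_is_benign(self):
        """Probe estimates from a thinned feature cloud stay within 5%."""
        rng = np.random.default_rng(3)
        fp = self._random_cloud(rng, 120)
        fd = np.column_stack(
            [0.5 + 0.01 * fp[:, 0], -0.3 + 0.005 * fp[:, 1]]
        )
        labels = np.full(len(fp), "fascicle", dtype=object)
        probes = rng.uniform(30, 70, size=(6, 6, 2))
        plabels = np.full((6, 6), "fascicle", dtype=object)
        full = interpolate_probe_displacement(fp, fd, labels, probes, plabels)
        keep = rng.random(len(fp)) > 0.3
        thin = interpolate_probe_displacement(
            fp[keep], fd[keep], labels[keep], probes, plabels
        )
        scale = np.abs(full).mean()
        assert np.nanmax(np.abs(thin - full)) <= 0.05 * scale + 1e-9


class TestProbeGrid:
    def test_rows_on_aponeuroses_and_equal_spacing(self, twitch_short):
        _, _, _, seg = twitch_short
        grid = ProbeGrid.from_segmentation(seg)
        assert grid.shape == (8, 10)
        cols = grid.positions[0, :, 1]
        sup = seg.depth_at(cols, "superficial")
        deep = seg.depth_at(cols, "deep")
        np.testing.assert_allclose(grid.positions[0, :, 0], sup, atol=1e-9)
        np.testing.assert_allclose(grid.positions[-1, :, 0], deep, atol=1e-9)
        gaps = np.diff(grid.positions[:, 0, 0])
        np.testing.assert_allclose(gaps, gaps[0], atol=1e-9)
        assert list(np.unique(grid.labels[1:-1])) == ["fascicle"]


class TestTwitchSeries:
    def test_zero_displacement_keeps_initial_values(self, twitch_short):
        _, _, _, seg = twitch_short
        grid = ProbeGrid.from_segmentation(seg)
        traj = np.tile(grid.positions[None], (5, 1, 1, 1))
        ts = twitch_series(traj, (0.05, 0.05), 80.0)
        assert np.all(ts.length_mm == ts.length_mm[0])
        assert np.all(ts.thickness_mm == ts.thickness_mm[0])

    def test_twitch_amplitude_recovered_within_10_percent(self, twitch_short):
        params, seq, gt, seg = twitch_short
        ts = track_twitch(seq, seg)
        rec_short = ts.length_mm[0] - ts.length_mm.min()
        true_short = gt.length_mm[0] - gt.length_mm.min()
        assert rec_short == pytest.approx(true_short, rel=0.10)
        rec_thick = ts.thickness_mm.max() - ts.thickness_mm[0]
        true_thick = gt.thickness_mm.max() - gt.thickness_mm[0]
        assert rec_thick == pytest.approx(true_thick, rel=0.10)
        # resting thickness matches the scene within 0.1 mm
        assert ts.thickness_mm[0] == pytest.approx(
            params.resting_thickness_mm, abs=0.1
        )
        r = np.corrcoef(ts.length_mm, gt.length_mm)[0, 1]
        assert r * r >= 0.95


class TestAlignAndCompare:
    def test_identical_series(self):
        rng = np.random.default_rng(4)
        a = np.sin(np.linspace(0, 8 * np.pi, 300)) + 0.05 * rng.normal(size=300)
        res = align_and_compare(a, a, max_lag=20)
        assert res.lag == 0
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [3, 11])
    def test_constructed_delay_recovered(self, k):
        rng = np.random.default_rng(5)
        base = np.sin(np.linspace(0, 6 * np.pi, 400)) + 0.02 * rng.normal(size=400)
        b = np.roll(base, k)
        res = align_and_compare(base, b, max_lag=30)
        assert res.lag == k

    def test_scaled_series_slope(self):
        a = np.sin(np.linspace(0, 4 * np.pi, 200))
        res = align_and_compare(a, 0.8 * a + 3.0, max_lag=10)
        assert res.slope == pytest.approx(0.8)
        assert res.r2 == pytest.approx(1.0)

    def test_constant_series_rejected(self):
        with pytest.raises(AnalysisError):
            align_and_compare(np.ones(100), np.arange(100.0), max_lag=5)


def test_probe_tracking_static_features(speckle_frame, twitch_short):
    """Probes hold position when every interpolated displacement is zero."""
    _, _, _, seg = twitch_short
    from echotrace.feature_tracking import FeatureSet

    grid = ProbeGrid.from_segmentation(seg)
    rng = np.random.default_rng(6)
    n = 60
    pos = rng.uniform(100, 300, size=(n, 2))
    labels = np.full(n, "fascicle", dtype=object)
    f0 = FeatureSet(pos, np.ones(n), np.zeros(n, int), labels, np.full((n, 2), np.nan))
    f1 = FeatureSet(pos, np.ones(n), np.ones(n, int), labels, np.zeros((n, 2)))
    traj = track_probes([f0, f1], grid)
    np.testing.assert_allclose(traj[1], traj[0], atol=1e-12)
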