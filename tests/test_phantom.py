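"""Phantom generator: volume-true cell profiles, fringe synthesis, sampling."""

import numpy as np
import pytest
from scipy import stats

import rbcqpi as rq
from rbcqpi.phantom import PLATELET_VOLUME_LIMIT_FL


class TestCellProfiles:
    def test_flat_disc_is_a_cylinder(self, cfg):
        spec = rq.CellSpec("flat_disc", 60.0, 3.0, center_xy_um=(20.0, 20.0))
        h = rq.make_rbc_height(spec, (320, 320), cfg.pixel_pitch_um)
        vol = h.sum() * cfg.pixel_pitch_um**2
        assert vol == pytest.approx(60.0, rel=1e-12)  # discrete normalization
        # uniform height = V / (pi r^2) within the rasterized footprint
        inner = h[h > 0]
        assert inner.std() < 1e-12
        assert inner[0] == pytest.approx(60.0 / (np.pi * 3.0**2), rel=0.05)

    @pytest.mark.parametrize("shape,radius", [
        ("biconcave", 3.9), ("spherocyte", 3.71), ("flat_disc", 3.5),
    ])
    def test_volume_recovered_through_optics(self, cfg, shape, radius):
        spec = rq.CellSpec(shape, 90.0, radius, center_xy_um=(25.0, 25.0))
        phi = rq.make_rbc_phase(spec, (400, 400), cfg)
        assert phi.min() >= 0
        h = rq.phase_to_height(phi, cfg)
        vol = h.sum() * cfg.pixel_pitch_um**2
        assert vol == pytest.approx(90.0, rel=0.01)

    def test_rotation_invariance_of_symmetric_shape(self, cfg):
        kw = dict(shape="biconcave", target_volume_fl=90.0, radius_um=3.9,
                  center_xy_um=(25.0, 25.0))
        a = rq.make_rbc_height(rq.CellSpec(**kw), (400, 400), cfg.pixel_pitch_um)
        b = rq.make_rbc_height(
            rq.CellSpec(rotation_rad=1.1, **kw), (400, 400), cfg.pixel_pitch_um
        )
        assert np.abs(a - b).max() < 1e-9

    def test_cell_outside_grid_rejected(self, cfg):
        spec = rq.CellSpec("biconcave", 90.0, 3.9, center_xy_um=(1.0, 25.0))
        with pytest.raises(rq.PlacementError):
            rq.make_rbc_height(spec, (400, 400), cfg.pixel_pitch_um)

    def test_coarse_grid_rejected(self, cfg):
        spec = rq.CellSpec("biconcave", 90.0, 3.9, center_xy_um=(25.0, 25.0))
        with pytest.raises(rq.PlacementError):
            rq.make_rbc_height(spec, (50, 50), 1.0)  # < 10 px across

    def test_platelet_volume_cap_enforced(self):
        with pytest.raises(rq.ParameterError):
            rq.CellSpec("platelet", 25.0, 1.8)


class TestInterferogram:
    def test_pure_carrier_spectrum_peak(self, cfg, noiseless_model):
        scene = rq.build_scene([], (256, 256), cfg, aberration_peak_rad=0.0,
                               n_dirt=0, seed=0)
        img = rq.synthesize_interferogram(scene, noiseless_model, seed=0)
        # rows identical (straight fringes)
        assert np.abs(np.diff(img.astype(int), axis=0)).max() <= 1  # quantization
        spec = np.abs(np.fft.fft2(img.astype(float) - img.mean()))
        iy, ix = np.unravel_index(np.argmax(spec), spec.shape)
        u = np.fft.fftfreq(256)[ix]
        assert abs(abs(u) - noiseless_model.carrier_cpp) < 1e-6
        assert iy == 0

    def test_spectral_lobes_separated(self, single_cell_scene, noiseless_model):
        img = rq.synthesize_interferogram(single_cell_scene, noiseless_model, seed=0)
        f = np.abs(np.fft.fft2(img.astype(float)))
        u = np.fft.fftfreq(512)
        # energy near u = carrier/2 (between lobes) is far below the lobe peaks
        mid = np.argmin(np.abs(u - noiseless_model.carrier_cpp / 2))
        lobe = np.argmin(np.abs(u - noiseless_model.carrier_cpp))
        assert f[0, lobe] > 100 * np.abs(f[:, mid]).max()

    def test_same_seed_bit_identical(self, single_cell_scene):
        model = rq.InterferogramModel()  # with noise
        a = rq.synthesize_interferogram(single_cell_scene, model, seed=5)
        b = rq.synthesize_interferogram(single_cell_scene, model, seed=5)
        assert a.dtype == np.uint16
        assert np.array_equal(a, b)

    def test_background_shares_dirt_not_cells(self, dirty_scene, noiseless_model):
        np.testing.assert_allclose(
            dirty_scene.background_phase,
            dirty_scene.true_phase - dirty_scene.cell_phase,
            atol=1e-12,
        )
        bg1 = rq.make_background_frame(dirty_scene, noiseless_model, seed=2)
        bg2 = rq.make_background_frame(dirty_scene, noiseless_model, seed=2)
        assert np.array_equal(bg1, bg2)

    def test_three_pixel_rule_enforced(self):
        with pytest.raises(rq.FringeSamplingError):
            rq.InterferogramModel(carrier_cpp=0.4)


class TestSamplePopulation:
    def test_zero_rdw_gives_constant_volumes(self):
        specs = rq.sample_population(50, 90.0, 0.0, seed=0)
        assert all(s.target_volume_fl == 90.0 for s in specs)

    def test_large_sample_hits_mean_and_cv(self):
        specs = rq.sample_population(10_000, 90.0, 15.0, seed=1)
        v = np.array([s.target_volume_fl for s in specs])
        assert v.mean() == pytest.approx(90.0, rel=0.01)
        cv = 100 * v.std(ddof=1) / v.mean()
        assert abs(cv - 15.0) < 0.5

    def test_platelet_fraction_binomial(self):
        n, p = 4000, 0.1
        specs = rq.sample_population(
            n, 90.0, 15.0, {"biconcave": 0.9, "platelet": 0.1}, seed=2
        )
        k = sum(1 for s in specs if s.shape == "platelet")
        # within 4 binomial sd of n*p
        assert abs(k - n * p) < 4 * np.sqrt(n * p * (1 - p))
        assert all(
            s.target_volume_fl < PLATELET_VOLUME_LIMIT_FL
            for s in specs if s.shape == "platelet"
        )
        assert all(
            s.target_volume_fl > PLATELET_VOLUME_LIMIT_FL
            for s in specs if s.shape != "platelet"
        )

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(rq.ParameterError):
            rq.sample_population(10, 10.0, 5.0, seed=0)

    def test_determinism(self):
        a = rq.sample_population(100, 90.0, 15.0, seed=9)
        b = rq.sample_population(100, 90.0, 15.0, seed=9)
        assert [(s.shape, s.target_volume_fl) for s in a] == [
            (s.shape, s.target_volume_fl) for s in b
        ]


class TestSceneTruth:
    def test_truth_volume_and_centroid(self, single_cell_scene, cfg):
        t = single_cell_scene.truths[0]
        assert t.volume_fl == pytest.approx(90.0)
        # centroid at (32 um, 32 um) -> 255.5 px
        assert t.centroid_row_px == pytest.approx(32.0 / cfg.pixel_pitch_um - 0.5)
        assert t.surface_area_um2 > 2 * np.pi * 3.9**2 * 0.5  # sanity: positive, O(footprint)

    def test_placement_rejects_overlap(self, cfg):
        rng = np.random.default_rng(0)
        specs = [rq.CellSpec("biconcave", 90.0, 3.9) for _ in range(60)]
        placed, unplaced = rq.place_cells(specs, (256, 256), cfg.pixel_pitch_um, rng)
        assert len(placed) + len(unplaced) == 60
        centers = [s.center_xy_um for s in placed]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = np.hypot(
                    centers[i][0] - centers[j][0], centers[i][1] - centers[j][1]
                )
                assert d > 2 * 3.9  # edge-to-edge separation
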