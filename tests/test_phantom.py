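"""Phantom generators: geometry oracles, determinism, noise-free limits."""

import numpy as np
import pytest

import octscreen as oc
from octscreen.errors import ParameterError


class TestWellImage:
    def test_empty_well_by_construction(self):
        spec = oc.PhantomSpec(occupancy=0.0)
        img, gt = oc.make_well_image(spec, seed=1)
        assert not gt.has_tissue
        assert gt.bbox_px is None and gt.centroid_mm is None

    def test_ellipse_geometry_oracle(self):
        # 600x600 px over 30 mm -> 20 px/mm; radii (4, 3) mm span 8 x 6 mm.
        spec = oc.PhantomSpec(occupancy=1.0, image_size_px=(600, 600),
                              tissue_center_mm=(15.0, 15.0),
                              tissue_radii_mm=(4.0, 3.0))
        img, gt = oc.make_well_image(spec, seed=2)
        assert gt.centroid_mm == (15.0, 15.0)
        x0, y0, x1, y1 = gt.bbox_px
        assert abs((x1 - x0) - 160) <= 2  # 8 mm at 20 px/mm
        assert abs((y1 - y0) - 120) <= 2  # 6 mm at 20 px/mm
        # bbox must tightly bound the rasterized footprint
        rr, cc = np.nonzero(gt.mask)
        assert (cc.min(), rr.min(), cc.max() + 1, rr.max() + 1) == gt.bbox_px

    def test_determinism_bit_identical(self):
        spec = oc.PhantomSpec()
        img1, _ = oc.make_well_image(spec, seed=7)
        img2, _ = oc.make_well_image(spec, seed=7)
        assert np.array_equal(img1, img2)

    def test_invalid_size_rejected(self):
        with pytest.raises(ParameterError):
            oc.make_well_image(oc.PhantomSpec(image_size_px=(0, 100)), seed=0)


class TestOCTVolume:
    def test_uniform_profile_voxel_count_oracle(self, noise_free_spec):
        # uniform 180 um at dz=2 um -> exactly 90 tissue voxels per column
        vol, gt = oc.make_oct_volume(noise_free_spec, seed=0)
        counts = gt.mask.sum(axis=1)
        in_footprint = gt.thickness_map_um > 0
        assert in_footprint.any()
        assert np.all(counts[in_footprint] == 90)
        assert np.all(counts[~in_footprint] == 0)

    def test_noise_free_limit_single_tissue_intensity(self, noise_free_spec):
        vol, gt = oc.make_oct_volume(noise_free_spec, seed=0)
        tissue_vals = np.unique(vol[gt.mask.astype(bool)])
        assert tissue_vals.size == 1

    def test_dome_volume_matches_quadrature_oracle(self):
        spec = oc.PhantomSpec(
            n_alines=200, n_bscans=200, axial_px=256, dz_um=2.0,
            tissue_radii_mm=(2.0, 2.0), thickness_profile="dome",
            profile_params={"peak_um": 200.0, "edge_um": 100.0},
        )
        gt = oc.make_ground_truth(spec)
        # independent oracle: numeric quadrature of the dome at 10x resolution
        n = 2000
        h = spec.oct_fov_mm / n
        x = (np.arange(n) + 0.5) * h - spec.oct_fov_mm / 2
        rho2 = (x[None, :] ** 2 + x[:, None] ** 2) / 4.0
        t = np.where(rho2 <= 1.0, 100.0 + 100.0 * (1.0 - rho2), 0.0)
        vol_oracle_mm3 = t.sum() * h * h * 1e-3
        assert gt.volume_mm3 == pytest.approx(vol_oracle_mm3, rel=0.01)
        # and the discrete map agrees with the analytic ground truth to 1%
        dx = dy = spec.oct_fov_mm * 1000 / 200
        map_vol = gt.thickness_map_um.sum() * dx * dy * 1e-9
        assert map_vol == pytest.approx(gt.volume_mm3, rel=0.01)

    def test_mask_never_touches_membrane(self, small_volume_spec):
        vol, gt = oc.make_oct_volume(small_volume_spec, seed=4)
        mem_top = small_volume_spec.membrane_top_px()
        # membrane rows and everything below them are tissue-free
        assert gt.mask[:, mem_top:, :].sum() == 0
        # membrane itself is bright in the noise-free sense: rendered rows exist
        assert vol[:, mem_top, :].mean() > vol[:, 0, :].mean()

    def test_determinism_and_seed_sensitivity(self, small_volume_spec):
        v1, _ = oc.make_oct_volume(small_volume_spec, seed=5)
        v2, _ = oc.make_oct_volume(small_volume_spec, seed=5)
        v3, _ = oc.make_oct_volume(small_volume_spec, seed=6)
        assert np.array_equal(v1, v2)
        assert not np.array_equal(v1, v3)

    def test_profile_exceeding_axial_range_rejected(self):
        spec = oc.PhantomSpec(n_alines=32, n_bscans=4, axial_px=64, dz_um=2.0,
                              profile_params={"thickness_um": 500.0})
        with pytest.raises(ParameterError):
            oc.make_oct_volume(spec, seed=0)


class TestDepthStack:
    def test_single_frame_stack(self, noise_free_spec):
        stack, gt = oc.make_depth_stack(noise_free_spec, 1, 0, seed=0)
        assert len(stack.frames) == 1 and gt.optimal_z_index == 0

    def test_noise_free_means_strictly_unimodal(self, noise_free_spec):
        stack, _ = oc.make_depth_stack(noise_free_spec, 11, 7, seed=0)
        means = np.array([oc.mean_frame_intensity(f) for f in stack.frames])
        assert np.all(np.diff(means[:8]) > 0)
        assert np.all(np.diff(means[7:]) < 0)

    def test_invalid_optimal_index_rejected(self, noise_free_spec):
        with pytest.raises(ParameterError):
            oc.make_depth_stack(noise_free_spec, 5, 5, seed=0)


class TestScreenDataset:
    def test_zero_repeat_noise_gives_identical_repetitions(self):
        df = oc.make_screen_dataset(3, 3, repeat_sd=0.0, area_repeat_sd=0.0,
                                    volume_repeat_sd=0.0, seed=1)
        spread = df.groupby(["sample_id", "timepoint"])["thickness_um"].std()
        assert np.allclose(spread, 0.0)

    def test_negative_day10_mean_recovers_configured_value(self):
        # 191.8 um baseline with -30.3% change -> expected day-10 mean 133.7
        df = oc.make_screen_dataset(400, 2, seed=3)
        sub = df[(df.group == "negative") & (df.timepoint == "day10")]
        means = sub.groupby("sample_id")["thickness_um"].mean()
        se = 11.5 / np.sqrt(len(means))
        assert abs(means.mean() - 133.7) < 4 * se

    def test_day10_sd_converges_to_configured_sd(self):
        # law-of-large-numbers check on the between-sample SD
        df = oc.make_screen_dataset(10000, 2, repeat_sd=0.0, n_repeats=1,
                                    seed=5)
        sub = df[(df.group == "negative") & (df.timepoint == "day10")]
        assert sub["thickness_um"].std(ddof=1) == pytest.approx(11.5,
                                                                rel=0.03)

    def test_nonpositive_group_size_rejected(self):
        with pytest.raises(ParameterError):
            oc.make_screen_dataset(0, 4)


def test_self_consistency_mask_vs_analytic():
    """Morphometry on a noise-free phantom mask reproduces the analytic
    ground-truth readouts within 1% (area, volume) and 1 dz (thickness)."""
    spec = oc.PhantomSpec(
        n_alines=160, n_bscans=160, axial_px=256, dz_um=2.0,
        tissue_radii_mm=(2.0, 2.0),
        speckle_sd=0.0, reflectance_drift=0.0, specular_column_rate=0.0,
    )
    vol, gt = oc.make_oct_volume(spec, seed=0)
    seg = oc.SegVolume(masks=gt.mask, dx_um=6000 / 160, dy_um=6000 / 160,
                       dz_um=spec.dz_um)
    m = oc.thickness_map(seg)
    assert oc.tissue_area(m) == pytest.approx(gt.area_mm2, rel=0.01)
    assert oc.tissue_volume(m) == pytest.approx(gt.volume_mm3, rel=0.01)
    assert abs(oc.central_mean_thickness(m) - gt.central_thickness_um) \
        <= spec.dz_um
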