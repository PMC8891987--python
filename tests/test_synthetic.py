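"""The generators must deliver exactly what their ground-truth tables claim."""

import numpy as np
import pytest

from cellmech.errors import OutOfFrameError, OverlapError, PlacementError
from cellmech.migration import compute_msd
from cellmech.synthetic import (
    BEAD_MEAN_DIAMETER_UM,
    BEAD_SD_DIAMETER_UM,
    Disk,
    Ellipse,
    Star,
    bead_field,
    elliptical_cell_mask,
    furth_msd,
    generate_fa_image,
    generate_hertz_curve,
    generate_prw_ensemble,
    generate_prw_trajectory,
    generate_particle_image,
)
from cellmech.afm import hertz_force


class TestParticleImages:
    def test_empty_spec_list_gives_blank_image_and_empty_truth(self):
        img, truth = generate_particle_image([], (64, 64), 0.5)
        assert np.ptp(img.data) == 0
        assert truth.empty

    def test_disk_truth_matches_analytic_geometry(self):
        img, truth = generate_particle_image([Disk((40, 40), 20.0)], (80, 80), 0.5)
        row = truth.iloc[0]
        assert row.equiv_diameter_um == pytest.approx(20.0)  # 2*20 px * 0.5 µm/px
        assert row.circularity == 1.0
        assert row.solidity == 1.0
        assert row.area_um2 == pytest.approx(np.pi * 20**2 * 0.25)

    def test_rendered_pixel_count_tracks_analytic_area(self):
        # pixel-center rasterization: discretization error is O(perimeter)
        img, truth = generate_particle_image([Disk((40, 40), 15.0)], (80, 80), 0.5)
        assert truth.pixel_count[0] == pytest.approx(truth.area_px2[0], rel=0.02)

    def test_overlapping_shapes_rejected(self):
        with pytest.raises(OverlapError):
            generate_particle_image(
                [Disk((40, 40), 15.0), Disk((60, 40), 15.0)], (100, 100), 0.5
            )

    def test_out_of_frame_shape_rejected(self):
        with pytest.raises(OutOfFrameError):
            generate_particle_image([Disk((5, 40), 15.0)], (80, 80), 0.5)

    def test_ellipse_and_star_truth_descriptors(self):
        ell = Ellipse((0, 0), 40.0, 20.0)
        assert ell.inverse_aspect_ratio() == 0.5
        assert ell.solidity() == 1.0
        star = Star((0, 0), 40.0, n_spikes=5, depth=0.5)
        assert 0 < star.solidity() < 1
        # k-fold symmetric star has an isotropic moment ellipse
        assert star.inverse_aspect_ratio() == pytest.approx(1.0, abs=1e-9)

    def test_bead_field_seed_determinism(self):
        img1, t1 = bead_field(20, seed=9)
        img2, t2 = bead_field(20, seed=9)
        assert np.array_equal(img1.data, img2.data)
        assert t1.equals(t2)

    def test_bead_sample_mean_within_3_sem_of_manufacturer_mean(self):
        _, truth = bead_field(300, seed=4)
        sem = BEAD_SD_DIAMETER_UM / np.sqrt(300)
        assert abs(truth.equiv_diameter_um.mean() - BEAD_MEAN_DIAMETER_UM) < 3 * sem


class TestPRWTrajectories:
    def test_zero_diffusion_means_no_motion(self):
        tr = generate_prw_trajectory(0.0, 5.0, 5.0, 20, seed=0)
        assert np.all(tr.x == tr.x[0]) and np.all(tr.y == tr.y[0])

    def test_same_seed_reproduces_trajectory(self):
        a = generate_prw_trajectory(10.0, 5.0, 5.0, 50, seed=3)
        b = generate_prw_trajectory(10.0, 5.0, 5.0, 50, seed=3)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    @pytest.mark.parametrize("bad", [{"tau": 0.0}, {"dt": -1.0}, {"D": -1.0}])
    def test_invalid_parameters_rejected(self, bad):
        kw = {"D": 1.0, "tau": 5.0, "dt": 5.0, "n_steps": 10, **bad}
        with pytest.raises(ValueError):
            generate_prw_trajectory(**kw)

    def test_ensemble_msd_converges_to_furth_form(self):
        # Monte-Carlo vs closed form at every lag up to 20*tau
        D, tau, dt = 10.0, 5.0, 5.0
        trajs = generate_prw_ensemble(500, D, tau, dt, 100, seed=11)
        curves = np.array([compute_msd(tr, max_lag_fraction=0.2).msd for tr in trajs])
        lags = compute_msd(trajs[0], max_lag_fraction=0.2).lags
        keep = lags <= 20 * tau
        mean = curves.mean(axis=0)[keep]
        se = curves.std(axis=0, ddof=1)[keep] / np.sqrt(len(trajs))
        expected = furth_msd(lags[keep], D, tau)
        assert np.all(np.abs(mean - expected) < 3 * se)


class TestHertzCurves:
    def test_precontact_force_is_exactly_zero(self):
        z = np.linspace(0, 2e-6, 200)
        c = generate_hertz_curve(1000.0, 0.45, 30e-9, 1.0e-6, z)
        assert np.all(c.force[z < 1.0e-6] == 0.0)

    def test_generator_matches_hertz_force_closed_form(self):
        cp = 0.5e-6
        z = np.linspace(0, 2e-6, 401)  # grid hits cp + 500 nm exactly
        c = generate_hertz_curve(1000.0, 0.45, 30e-9, cp, z)
        i = np.argmin(np.abs(z - (cp + 500e-9)))
        assert c.force[i] == pytest.approx(hertz_force(1000.0, 0.45, 30e-9, 500e-9))

    def test_noise_sd_calibrated(self):
        # all-baseline curve: sample sd of 1000 points within 10% of 10 pN
        z = np.linspace(0, 2e-6, 1000)
        c = generate_hertz_curve(1000.0, 0.45, 30e-9, 5e-6, z, noise_sd=1e-11, seed=2)
        assert np.std(c.force, ddof=1) == pytest.approx(1e-11, rel=0.10)

    def test_nonmonotonic_z_grid_rejected(self):
        z = np.array([0.0, 1e-7, 5e-8] + list(np.linspace(2e-7, 2e-6, 30)))
        with pytest.raises(ValueError):
            generate_hertz_curve(1000.0, 0.45, 30e-9, 1e-6, z)


class TestFAImages:
    def test_zero_adhesions_blank_marker_inside_mask(self, cell_mask):
        marker, actin, truth = generate_fa_image(cell_mask, 0, seed=1)
        assert truth.empty
        assert np.ptp(marker.data[cell_mask.data]) == 0

    def test_truth_count_bookkeeping(self, cell_mask):
        _, _, truth = generate_fa_image(cell_mask, 10, fa_area_dist=6.0, seed=2)
        assert len(truth) == 10
        assert not truth.below_min_area.any()

    def test_cutoff_straddling_blobs_flagged_from_pixel_areas(self, cell_mask):
        areas = [2.0, 3.5, 4.0, 4.5, 6.0, 9.0]
        _, _, truth = generate_fa_image(cell_mask, len(areas), fa_area_dist=areas, seed=3)
        expected = truth.area_um2 < 4.14  # realized (rasterized) area decides
        assert (truth.below_min_area == expected).all()

    def test_mask_too_small_raises(self):
        tiny = elliptical_cell_mask((40, 40), 0.2, semi_axes_px=(8, 8))
        with pytest.raises(PlacementError):
            generate_fa_image(tiny, 30, fa_area_dist=8.0, seed=1, max_tries=200)
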