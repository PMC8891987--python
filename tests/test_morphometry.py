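"""Segmentation and shape descriptors against analytic oracles."""

import numpy as np
import pytest

from conftest import shoelace_area
from cellmech.errors import ThresholdError
from cellmech.images import IntensityImage, LabeledMask
from cellmech.morphometry import (
    ShapeRecord,
    filter_particles,
    measure_particles,
    segment_particles,
    shape_descriptors,
)
from cellmech.synthetic import Disk, Ellipse, PolygonShape, Star, generate_particle_image


def _descriptors_of(shape, image_shape=(160, 160), pixel_size=0.5):
    img, _ = generate_particle_image([shape], image_shape, pixel_size)
    mask = segment_particles(img, exclude_border=False)
    return shape_descriptors(mask)[0]


class TestSegmentation:
    def test_constant_image_has_no_threshold(self):
        with pytest.raises(ThresholdError):
            segment_particles(IntensityImage(np.full((32, 32), 7.0), 0.5))

    def test_border_touching_particles_removed(self):
        img = np.full((60, 60), 100.0)
        img[0:20, 25:35] = 1000.0  # touches the top edge
        mask = segment_particles(IntensityImage(img, 0.5), exclude_border=True)
        assert mask.n_particles == 0

    def test_disk_pixel_count_within_2pc_of_analytic_area(self):
        img, _ = generate_particle_image([Disk((50, 50), 20.0)], (100, 100), 0.5)
        mask = segment_particles(img, exclude_border=False)
        assert mask.n_particles == 1
        assert (mask.data == 1).sum() == pytest.approx(np.pi * 400, rel=0.02)

    def test_fill_holes_restores_full_disk_area(self):
        img = np.full((100, 100), 100.0)
        yy, xx = np.mgrid[0:100, 0:100]
        r2 = (xx - 50.0) ** 2 + (yy - 50.0) ** 2
        img[(r2 <= 400) & (r2 > 100)] = 1000.0  # annulus: disk with a hole
        filled = segment_particles(IntensityImage(img, 0.5), fill_holes=True)
        annulus = segment_particles(IntensityImage(img, 0.5), fill_holes=False)
        full_disk = (r2 <= 400).sum()
        assert (filled.data == 1).sum() == full_disk
        assert (annulus.data == 1).sum() < full_disk


class TestShapeDescriptors:
    def test_disk_symmetry(self, disk_image):
        img, _ = disk_image
        rec = shape_descriptors(segment_particles(img, exclude_border=False))[0]
        assert 0.95 <= rec.circularity <= 1.0
        assert rec.inverse_aspect_ratio == pytest.approx(1.0, abs=0.02)
        assert rec.solidity == pytest.approx(1.0, abs=0.02)
        assert rec.equiv_diameter_um == pytest.approx(40.0, rel=0.01)  # 2*40 px * 0.5

    def test_two_to_one_ellipse_inverse_aspect_ratio(self):
        rec = _descriptors_of(Ellipse((80, 80), 40.0, 20.0, orientation=0.3))
        assert rec.inverse_aspect_ratio == pytest.approx(0.5, abs=0.03)

    def test_star_solidity_matches_shoelace_oracle(self):
        star = Star((80, 80), 40.0, n_spikes=5, depth=0.5)
        rec = _descriptors_of(star)
        verts = star.vertices + np.asarray(star.center)
        hull_verts = verts[::2]  # outer pentagon is the convex hull of a star
        expected = shoelace_area(verts) / shoelace_area(hull_verts)
        assert rec.solidity == pytest.approx(expected, abs=0.05)

    def test_convex_hull_polygon_is_solid(self):
        star = Star((80, 80), 40.0, n_spikes=5, depth=0.5)
        hull = PolygonShape((80, 80), vertices=star.vertices[::2])
        rec = _descriptors_of(hull)
        assert rec.solidity == pytest.approx(1.0, abs=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_descriptors(LabeledMask(np.zeros((10, 10), dtype=int), 0.5))

    def test_scale_equivariance(self, disk_image):
        img, _ = disk_image
        double = IntensityImage(img.data, img.pixel_size * 2)
        r1 = shape_descriptors(segment_particles(img, exclude_border=False))[0]
        r2 = shape_descriptors(segment_particles(double, exclude_border=False))[0]
        assert r2.area_um2 == pytest.approx(4 * r1.area_um2)
        for attr in ("circularity", "inverse_aspect_ratio", "solidity"):
            assert getattr(r2, attr) == getattr(r1, attr)

    def test_rotation_robustness_of_descriptors(self):
        vals = {"circularity": [], "inverse_aspect_ratio": [], "solidity": []}
        for k in range(8):
            rec = _descriptors_of(Ellipse((80, 80), 40.0, 20.0, orientation=k * np.pi / 8))
            for attr in vals:
                vals[attr].append(getattr(rec, attr))
        for attr, v in vals.items():
            assert np.ptp(v) < 0.05, attr


class TestParticleFilter:
    @staticmethod
    def _rec(area_px2, circ):
        return ShapeRecord(
            label=1, area_px2=area_px2, area_um2=area_px2 * 0.25,
            perimeter_um=1.0, circularity=circ, inverse_aspect_ratio=1.0,
            solidity=1.0, equiv_diameter_um=1.0,
        )

    def test_area_window_applied_mechanically(self):
        recs = [self._rec(a, 0.9) for a in (100, 500, 2000)]
        kept = filter_particles(recs)
        assert [r.area_px2 for r in kept] == [500]

    def test_circularity_floor_excludes(self):
        assert filter_particles([self._rec(500, 0.5)]) == []

    def test_empty_input_empty_output(self):
        assert filter_particles([]) == []

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            filter_particles([], area_range_px2=(1250, 300))

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        recs = [self._rec(rng.uniform(100, 2000), rng.uniform(0.3, 1.0)) for _ in range(50)]
        n_prev = len(filter_particles(recs, (0, 1e9), (0.0, 1.0)))
        for floor in (0.3, 0.5, 0.65, 0.9):
            n = len(filter_particles(recs, (0, 1e9), (floor, 1.0)))
            assert n <= n_prev
            n_prev = n


def test_measure_particles_end_to_end_keeps_beads_only():
    specs = [Disk((40, 40), 17.0), Disk((120, 40), 5.0), Disk((80, 120), 35.0)]
    img, _ = generate_particle_image(specs, (170, 170), 0.3)
    recs = measure_particles(img)  # 300-1250 px² window keeps only the 17 px disk
    assert len(recs) == 1
    assert recs[0].area_px2 == pytest.approx(np.pi * 17**2, rel=0.02)
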