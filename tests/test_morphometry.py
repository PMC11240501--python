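"""Nuclear morphometry against closed-form shapes and analytic oracles."""

import numpy as np
import pytest
from skimage import draw

from astromorph.morphometry import (
    NucleusFeatureExtractor,
    area,
    axis_ratio,
    cellularity,
    circularity,
    entropy,
    irregularity,
    moment_summary,
    perimeter,
)

from .conftest import disk_mask, ellipse_mask, instance_from_mask


class TestCellularity:
    def test_all_background(self):
        assert cellularity(np.zeros((64, 64), dtype=np.uint16)).cellularity == 0.0

    def test_all_foreground(self):
        assert cellularity(np.ones((64, 64), dtype=np.uint16)).cellularity == 1.0

    def test_exact_pixel_count(self):
        mask = np.zeros((512, 512), dtype=np.uint16)
        mask.flat[:13_107] = 1
        rec = cellularity(mask, mpp=0.5)
        assert rec.cellularity == pytest.approx(13_107 / 262_144)
        assert rec.cell_area == pytest.approx(13_107 * 0.25)
        assert rec.total_area == pytest.approx(262_144 * 0.25)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cellularity(np.zeros((0, 0), dtype=np.uint16))


class TestAxisRatio:
    def test_disk_is_symmetric(self):
        assert axis_ratio(instance_from_mask(disk_mask(20))) == pytest.approx(1.0, abs=0.02)

    def test_two_to_one_ellipse(self):
        inst = instance_from_mask(ellipse_mask(40, 20))
        assert axis_ratio(inst) == pytest.approx(2.0, abs=0.05)

    @pytest.mark.parametrize("rotation", [np.pi / 6, np.pi / 4, 1.1])
    def test_rotation_invariance(self, rotation):
        inst = instance_from_mask(ellipse_mask(40, 20, rotation=rotation))
        assert axis_ratio(inst) == pytest.approx(2.0, abs=0.05)

    def test_collinear_pixels_flagged(self):
        mask = np.zeros((12, 12), dtype=np.uint16)
        mask[5, 2:9] = 1
        assert np.isnan(axis_ratio(instance_from_mask(mask)))


class TestCircularity:
    def test_disk_overlaps_itself(self):
        assert circularity(instance_from_mask(disk_mask(20))) >= 0.98

    def test_monotone_in_elongation(self):
        c2 = circularity(instance_from_mask(ellipse_mask(28, 14)))
        c4 = circularity(instance_from_mask(ellipse_mask(40, 10)))
        assert c4 < c2 < 1.0

    def test_elongation_matches_pixel_oracle(self):
        # brute-force pixel intersection with the equal-area centroid disk
        inst = instance_from_mask(ellipse_mask(40, 10))
        r = np.sqrt(inst.n_pixels / np.pi)
        d2 = (inst.rows - inst.centroid[0]) ** 2 + (inst.cols - inst.centroid[1]) ** 2
        assert circularity(inst) == pytest.approx((d2 <= r**2).sum() / inst.n_pixels)

    def test_thin_l_shape_scores_low(self):
        mask = np.zeros((80, 80), dtype=np.uint16)
        mask[10:70, 10:16] = 1
        mask[64:70, 10:70] = 1
        assert circularity(instance_from_mask(mask)) < 0.7


class TestEntropy:
    def test_constant_intensity(self):
        mask = disk_mask(15)
        intensity = np.full(mask.shape, 100, dtype=np.uint8)
        assert entropy(instance_from_mask(mask, intensity)) == 0.0

    def test_two_equal_levels_is_one_bit(self):
        mask = np.ones((20, 20), dtype=np.uint16)
        intensity = np.zeros((20, 20), dtype=np.uint8)
        intensity[:, ::2] = 200
        assert entropy(instance_from_mask(mask, intensity)) == pytest.approx(1.0)

    def test_sixteen_equiprobable_levels(self, rng):
        mask = np.ones((40, 40), dtype=np.uint16)  # 1600 px >= 1000
        levels = np.linspace(0, 240, 16).astype(np.uint8)
        intensity = rng.choice(levels, size=mask.shape)
        assert entropy(instance_from_mask(mask, intensity)) == pytest.approx(4.0, abs=0.1)

    def test_missing_intensities_flagged_not_zero(self):
        assert np.isnan(entropy(instance_from_mask(disk_mask(10))))


class TestArea:
    def test_closed_form(self):
        mask = np.zeros((20, 20), dtype=np.uint16)
        mask[5:15, 5:15] = 1  # 100 px
        assert area(instance_from_mask(mask, mpp=0.5)) == pytest.approx(25.0)

    def test_disk_matches_pi_r_squared(self):
        assert area(instance_from_mask(disk_mask(10))) == pytest.approx(np.pi * 100, abs=7)

    def test_area_scales_with_mpp_squared(self):
        mask = disk_mask(12)
        assert area(instance_from_mask(mask, mpp=2.0)) == pytest.approx(
            4 * area(instance_from_mask(mask, mpp=1.0))
        )


def ellipse_radial_variance(a: float, b: float) -> float:
    """Arc-length-weighted variance of centroid-to-boundary distance."""
    t = np.linspace(0, 2 * np.pi, 200_000, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    d = np.hypot(x, y)
    w = np.hypot(-a * np.sin(t), b * np.cos(t))  # |dp/dt|, arc-length weight
    mean = np.sum(w * d) / np.sum(w)
    return float(np.sum(w * (d - mean) ** 2) / np.sum(w))


class TestIrregularity:
    def test_circle_is_nearly_zero(self):
        inst = instance_from_mask(disk_mask(25))
        mean_r2 = (np.sqrt(inst.n_pixels / np.pi)) ** 2
        assert irregularity(inst) < 0.05 * mean_r2

    def test_ellipse_matches_dense_sampling_oracle(self):
        inst = instance_from_mask(ellipse_mask(40, 20))
        assert irregularity(inst) == pytest.approx(
            ellipse_radial_variance(40, 20), rel=0.05
        )

    def test_sinusoidal_perturbation_closed_form(self):
        # r(phi) = r0 (1 + eps sin k phi) has radial variance eps^2 r0^2 / 2
        r0, eps, k = 40.0, 0.15, 5
        phi = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        r = r0 * (1 + eps * np.sin(k * phi))
        mask = np.zeros((120, 120), dtype=np.uint16)
        rr, cc = draw.polygon(60 + r * np.sin(phi), 60 + r * np.cos(phi), mask.shape)
        mask[rr, cc] = 1
        assert irregularity(instance_from_mask(mask)) == pytest.approx(
            eps**2 * r0**2 / 2, rel=0.1
        )

    def test_few_vertices_flagged(self):
        mask = np.zeros((8, 8), dtype=np.uint16)
        mask[3, 3] = 1
        inst = instance_from_mask(mask)
        assert np.isnan(irregularity(inst)) or inst.boundary.shape[0] >= 8


class TestPerimeter:
    def test_square(self):
        mask = np.zeros((110, 110), dtype=np.uint16)
        mask[5:105, 5:105] = 1
        assert perimeter(instance_from_mask(mask)) == pytest.approx(400, rel=0.02)

    def test_disk_circumference(self):
        assert perimeter(instance_from_mask(disk_mask(50))) == pytest.approx(
            2 * np.pi * 50, rel=0.03
        )

    def test_perimeter_scales_linearly(self):
        p1 = perimeter(instance_from_mask(disk_mask(25)))
        p2 = perimeter(instance_from_mask(disk_mask(50)))
        assert p2 == pytest.approx(2 * p1, rel=0.01)


class TestMomentSummary:
    def test_constant_list_flags_higher_moments(self):
        s = moment_summary([3.0] * 10)
        assert s.variance == 0.0
        assert not s.higher_moments_defined
        assert np.isnan(s.skewness) and np.isnan(s.kurtosis)

    def test_hand_computed_example(self):
        s = moment_summary([1, 2, 3, 4, 5])
        assert s.mean == 3.0
        assert s.variance == 2.5
        assert s.skewness == pytest.approx(0.0, abs=1e-12)

    def test_small_sample_flags_higher_moments(self):
        s = moment_summary([1.0, 2.0, 4.0])
        assert s.n == 3
        assert np.isfinite(s.mean) and np.isfinite(s.variance)
        assert not s.higher_moments_defined

    def test_normal_draws_have_zero_skew_and_excess_kurtosis(self, rng):
        v = rng.standard_normal(100_000)
        s = moment_summary(v)
        assert s.skewness == pytest.approx(0.0, abs=0.03)
        assert s.kurtosis == pytest.approx(0.0, abs=0.06)


class TestExtractor:
    def test_translation_invariance_of_shape_features(self):
        base = np.zeros((120, 120), dtype=np.uint16)
        rr, cc = draw.ellipse(40, 40, 22, 11)
        base[rr, cc] = 1
        shifted = np.roll(np.roll(base, 30, axis=0), 25, axis=1)
        a = instance_from_mask(base)
        b = instance_from_mask(shifted)
        assert axis_ratio(a) == pytest.approx(axis_ratio(b))
        assert circularity(a) == pytest.approx(circularity(b))
        assert area(a) == pytest.approx(area(b))
        assert perimeter(a) == pytest.approx(perimeter(b))
        assert irregularity(a) == pytest.approx(irregularity(b))

    def test_border_touching_nuclei_excluded_from_shape_but_not_cellularity(self):
        mask = np.zeros((64, 64), dtype=np.uint16)
        rr, cc = draw.disk((32, 32), 8)
        mask[rr, cc] = 1
        rr, cc = draw.disk((0, 0), 10, shape=mask.shape)
        mask[rr, cc] = 2  # clipped at the corner
        ext = NucleusFeatureExtractor(mpp=1.0)
        per_nucleus = ext.transform([("u", mask, None)])
        assert per_nucleus["instance_id"].tolist() == [1]
        cell = ext.cellularity_table([("u", mask, None)])
        assert cell.loc[0, "cellularity"] == np.count_nonzero(mask) / mask.size

    def test_summarize_has_one_row_per_unit_feature(self):
        mask = np.zeros((100, 100), dtype=np.uint16)
        for i, c in enumerate([20, 45, 70], start=1):
            rr, cc = draw.disk((c, c), 8)
            mask[rr, cc] = i
        intensity = np.full(mask.shape, 128, dtype=np.uint8)
        ext = NucleusFeatureExtractor(mpp=1.0)
        per_nucleus = ext.transform([("u", mask, intensity)])
        summary = ext.summarize(per_nucleus)
        assert len(summary) == 6
        assert (summary["n"] == 3).all()
        assert not summary["higher_moments_defined"].any()  # n = 3 < 4
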