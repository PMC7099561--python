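"""Synthetic cohort generator: geometry, rendering, B/C remap, cohort structure."""

import numpy as np
import pytest

from conftest import count_holes, flood_components
from fazseg.datatypes import BCSetting, SubjectSpec
from fazseg.synthetic import (
    BC_SETTINGS,
    apply_bc_transform,
    generate_cohort,
    generate_faz_mask,
    generate_vessel_image,
)


def _spec(**kw):
    base = dict(
        subject_id="S1",
        myopia_class="low",
        faz_center=(0.5, 0.5),
        faz_radius_mm=0.3,
        boundary_harmonics=[(2, 0.06, 0.4), (3, 0.04, 1.1)],
        vessel_density=0.7,
        rng_seed=5,
    )
    base.update(kw)
    return SubjectSpec(**base)


class TestFazMask:
    def test_unperturbed_circle_area(self, circle_spec):
        mask = generate_faz_mask(circle_spec, (128, 128), scan_mm=3.0)
        expected = np.pi * (0.3 * 128 / 3.0) ** 2
        assert mask.n_foreground == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_single_component_no_holes(self, seed):
        rng = np.random.default_rng(seed)
        harmonics = [
            (int(k), rng.uniform(0, 0.07), rng.uniform(0, 2 * np.pi)) for k in (2, 3, 5)
        ]
        mask = generate_faz_mask(_spec(boundary_harmonics=harmonics, rng_seed=seed), (96, 96))
        n, _ = flood_components(mask.pixels, connectivity=8)
        assert n == 1
        assert count_holes(mask.pixels) == 0

    def test_seed_does_not_affect_deterministic_geometry(self, circle_spec):
        a = generate_faz_mask(circle_spec, (128, 128))
        spec_b = _spec(boundary_harmonics=[], rng_seed=circle_spec.rng_seed + 99)
        b = generate_faz_mask(spec_b, (128, 128))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_pixel_area_tracks_radius(self):
        for r in (0.2, 0.35, 0.5):
            mask = generate_faz_mask(_spec(faz_radius_mm=r, boundary_harmonics=[]), (128, 128))
            expected = np.pi * (r * 128 / 3.0) ** 2
            assert mask.n_foreground == pytest.approx(expected, rel=0.15)

    def test_boundary_exiting_image_rejected(self):
        spec = _spec(faz_center=(0.02, 0.5), boundary_harmonics=[])
        with pytest.raises(ValueError, match="exits"):
            generate_faz_mask(spec, (128, 128))

    def test_small_size_rejected(self, circle_spec):
        with pytest.raises(ValueError):
            generate_faz_mask(circle_spec, (32, 32))


class TestVesselImage:
    def test_faz_interior_darker_than_surround(self, circle_spec):
        mask = generate_faz_mask(circle_spec, (128, 128))
        img = generate_vessel_image(circle_spec, mask, (128, 128))
        inside = img.pixels[mask.pixels > 0].mean()
        outside = img.pixels[mask.pixels == 0].mean()
        assert outside - inside >= 30

    def test_deterministic_under_seed(self, circle_spec):
        mask = generate_faz_mask(circle_spec, (128, 128))
        a = generate_vessel_image(circle_spec, mask, (128, 128))
        b = generate_vessel_image(circle_spec, mask, (128, 128))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_zero_density_gives_background_only(self, circle_spec):
        spec = _spec(vessel_density=0.0)
        mask = generate_faz_mask(spec, (128, 128))
        img = generate_vessel_image(spec, mask, (128, 128))
        # background is ~28 +/- 6 gray levels of noise, no bright strokes
        assert img.pixels.max() < 80

    def test_size_mismatch_rejected(self, circle_spec):
        mask = generate_faz_mask(circle_spec, (128, 128))
        with pytest.raises(ValueError):
            generate_vessel_image(circle_spec, mask, (96, 96))


class TestBCTransform:
    def test_settings_table(self):
        pairs = {(s.brightness, s.contrast) for s in BC_SETTINGS.values()}
        assert pairs == {
            (130, 20), (90, 20), (110, 20), (150, 20), (170, 20),
            (130, 0), (130, 10), (130, 30), (130, 40),
        }
        assert sorted(BC_SETTINGS) == list(range(1, 10))

    def test_default_setting_is_identity(self, circle_spec):
        mask = generate_faz_mask(circle_spec, (128, 128))
        img = generate_vessel_image(circle_spec, mask, (128, 128))
        out = apply_bc_transform(img, BC_SETTINGS[1])
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_mean_monotone_in_brightness_and_contrast(self, circle_spec):
        mask = generate_faz_mask(circle_spec, (128, 128))
        img = generate_vessel_image(circle_spec, mask, (128, 128))
        by_brightness = [
            apply_bc_transform(img, BC_SETTINGS[g]).pixels.mean() for g in (2, 3, 1, 4, 5)
        ]
        assert all(a >= b for a, b in zip(by_brightness, by_brightness[1:]))
        by_contrast = [
            apply_bc_transform(img, BC_SETTINGS[g]).pixels.mean() for g in (6, 7, 1, 8, 9)
        ]
        assert all(a >= b for a, b in zip(by_contrast, by_contrast[1:]))

    def test_lower_contrast_reveals_faint_vessels(self, circle_spec):
        mask = generate_faz_mask(circle_spec, (128, 128))
        img = generate_vessel_image(circle_spec, mask, (128, 128))
        faint_threshold = 60
        visible = {
            g: (apply_bc_transform(img, BC_SETTINGS[g]).pixels > faint_threshold).sum()
            for g in (6, 7, 1)
        }
        assert visible[6] >= visible[7] >= visible[1]

    def test_constant_image_stays_constant(self):
        from fazseg.datatypes import ImageRecord

        img = ImageRecord(np.full((128, 128), 77, dtype=np.uint8))
        for g in BC_SETTINGS:
            out = apply_bc_transform(img, BC_SETTINGS[g])
            assert len(np.unique(out.pixels)) == 1

    def test_unknown_group_rejected(self, circle_spec):
        mask = generate_faz_mask(circle_spec, (128, 128))
        img = generate_vessel_image(circle_spec, mask, (128, 128))
        with pytest.raises(ValueError, match="group"):
            apply_bc_transform(img, BCSetting(10, 130, 20))


class TestCohort:
    def test_single_subject_shares_one_gt(self):
        samples = generate_cohort(1, 0, seed=3)
        assert len(samples) == 9
        for s in samples[1:]:
            np.testing.assert_array_equal(s.gt.pixels, samples[0].gt.pixels)
        assert sorted(s.bc.group_id for s in samples) == list(range(1, 10))

    def test_cohort_size_and_strata(self, small_cohort):
        assert len(small_cohort) == 54
        subjects = {(s.subject_id, s.myopia_class) for s in small_cohort}
        assert len(subjects) == 6
        assert sum(1 for _, c in subjects if c == "high") == 2

    def test_gt_identical_across_renderings(self, small_cohort):
        by_subject = {}
        for s in small_cohort:
            by_subject.setdefault(s.subject_id, []).append(s)
        for group in by_subject.values():
            assert len(group) == 9
            for s in group[1:]:
                np.testing.assert_array_equal(s.gt.pixels, group[0].gt.pixels)

    def test_deterministic_under_seed(self):
        a = generate_cohort(2, 1, seed=9)
        b = generate_cohort(2, 1, seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.image.pixels, sb.image.pixels)
            np.testing.assert_array_equal(sa.gt.pixels, sb.gt.pixels)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 0, seed=1)
        with pytest.raises(ValueError):
            generate_cohort(3, 4, seed=1)
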