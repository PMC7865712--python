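"""Phantom generator: geometry, determinism, drug effects, analytic shapes."""

from dataclasses import replace

import numpy as np
import pytest

from pavessel import (
    DrugEffectSpec,
    PhantomSpec,
    apply_drug_effect,
    carfilzomib_like_effect,
    generate_series,
    generate_tree_phantom,
    make_analytic_shape,
    null_effect,
)


class TestTreePhantom:
    def test_straight_bar_area_fraction_is_rectangle_area(self, bar_phantom):
        # width-9 trunk across all 256 columns: 9*256 white pixels
        _, truth = bar_phantom
        assert truth.area_fraction == pytest.approx(9 * 256 / (64 * 256), abs=0)
        assert truth.mask.sum() == 9 * 256

    def test_same_spec_and_seed_is_bit_identical(self, bar_spec):
        img1, t1 = generate_tree_phantom(bar_spec)
        img2, t2 = generate_tree_phantom(bar_spec)
        assert np.array_equal(img1, img2)
        assert np.array_equal(t1.mask, t2.mask)
        assert np.array_equal(t1.skeleton, t2.skeleton)

    def test_branch_widths_follow_geometric_decay(self):
        spec = PhantomSpec(seed=5, branch_levels=3, width_decay=0.6, trunk_width_px=12.0)
        _, truth = generate_tree_phantom(spec)
        level3 = [v for v in truth.per_vessel if v.level == 3]
        assert level3, "expected at least one level-3 vessel"
        for v in level3:
            assert v.width_px == pytest.approx(12.0 * 0.6 ** 3)

    def test_truth_consistency(self, default_phantom):
        img, truth = default_phantom
        assert truth.area_fraction == truth.mask.mean()
        assert truth.skeleton_fraction == truth.skeleton.mean()
        assert not np.any(truth.skeleton & ~truth.mask)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_image_too_small_for_trunks_raises(self):
        spec = PhantomSpec(image_size=(20, 20), n_trunks=3, trunk_width_px=12.0)
        with pytest.raises(ValueError, match="too small"):
            generate_tree_phantom(spec)

    @pytest.mark.parametrize("field,value", [
        ("width_decay", 0.0),
        ("vessel_peak_intensity", 0.0),
        ("background_level", 0.9),  # above default peak 0.8
        ("noise_sigma", -0.1),
        ("trunk_width_px", 0.5),
    ])
    def test_invalid_spec_rejected(self, field, value):
        with pytest.raises(ValueError):
            replace(PhantomSpec(), **{field: value}).validate()


class TestDrugEffect:
    def test_zero_effect_reproduces_baseline_exactly(self):
        spec = PhantomSpec(seed=5)
        base_img, base_truth = generate_tree_phantom(spec)
        img, truth = apply_drug_effect(spec, carfilzomib_like_effect(), 0)
        assert np.array_equal(img, base_img)
        assert np.array_equal(truth.mask, base_truth.mask)

    def test_full_dilation_scales_every_width(self):
        spec = PhantomSpec(seed=5)
        _, base = generate_tree_phantom(spec)
        effect = replace(carfilzomib_like_effect(),
                         effect_curve=(0.0, 1.0) + (0.0,) * 8)
        _, truth = apply_drug_effect(spec, effect, 1)
        base_w = {v.vessel_id: v.width_px for v in base.per_vessel}
        scaled = [v for v in truth.per_vessel if v.vessel_id in base_w]
        assert scaled
        for v in scaled:
            assert v.width_px == pytest.approx(1.2 * base_w[v.vessel_id])

    def test_recruitment_adds_expected_terminal_count(self):
        spec = PhantomSpec(seed=5)
        _, base = generate_tree_phantom(spec)
        effect = DrugEffectSpec(dilation_factor=1.0, intensity_factor=1.0,
                                recruit_fraction=0.5, bleed_spots=0,
                                effect_curve=(0.0, 1.0))
        _, truth = apply_drug_effect(spec, effect, 1)
        expected_new = round(0.5 * base.n_terminal)
        assert len(truth.per_vessel) == len(base.per_vessel) + expected_new

    def test_area_fraction_monotone_in_dilation(self):
        spec = PhantomSpec(seed=6, noise_sigma=0.0)
        fracs = []
        for dil in (1.0, 1.1, 1.25, 1.4):
            effect = DrugEffectSpec(dilation_factor=dil, intensity_factor=1.0,
                                    recruit_fraction=0.0, bleed_spots=0,
                                    effect_curve=(0.0, 1.0))
            _, truth = apply_drug_effect(spec, effect, 1)
            fracs.append(truth.area_fraction)
        assert fracs == sorted(fracs)
        assert fracs[-1] > fracs[0]

    def test_bleed_spots_not_in_vessel_mask(self):
        spec = PhantomSpec(seed=7, noise_sigma=0.0)
        effect = DrugEffectSpec(dilation_factor=1.0, intensity_factor=1.0,
                                recruit_fraction=0.0, bleed_spots=6,
                                effect_curve=(0.0, 1.0))
        base_img, base = generate_tree_phantom(spec)
        img, truth = apply_drug_effect(spec, effect, 1)
        # same vessel truth, but extra bright pixels outside the mask
        assert np.array_equal(truth.mask, base.mask)
        assert (img[~truth.mask] > base_img[~truth.mask] + 0.3).any()

    def test_timepoint_outside_curve_raises(self):
        with pytest.raises(IndexError):
            apply_drug_effect(PhantomSpec(), carfilzomib_like_effect(), 10)


class TestSeries:
    def test_first_element_is_unmodified_baseline(self):
        spec = PhantomSpec(seed=8)
        base_img, _ = generate_tree_phantom(spec)
        series = generate_series(spec, carfilzomib_like_effect(), 10)
        assert series[0][0] == "control"
        assert np.array_equal(series[0][1], base_img)

    def test_zero_effect_series_has_identical_truth_distinct_noise(self):
        spec = PhantomSpec(seed=8)
        series = generate_series(spec, null_effect(), 10)
        masks = [t.mask for _, _, t in series]
        for m in masks[1:]:
            assert np.array_equal(m, masks[0])
        assert not np.array_equal(series[0][1], series[1][1])  # noise differs

    def test_effect_peak_maximizes_truth_area(self):
        spec = PhantomSpec(seed=9, noise_sigma=0.0)
        series = generate_series(spec, carfilzomib_like_effect(), 10)
        fracs = [t.area_fraction for _, _, t in series]
        assert int(np.argmax(fracs)) == 2  # the 30-min index

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            generate_series(PhantomSpec(), carfilzomib_like_effect(), 1)


class TestAnalyticShapes:
    def test_filled_square_pixel_count(self):
        assert make_analytic_shape("filled_square", side=81).sum() == 81 ** 2

    def test_straight_line_pixel_count(self):
        line = make_analytic_shape("straight_line", length=100)
        assert line.shape == (100, 100)
        assert line.sum() == 100

    def test_sierpinski_carpet_matches_digit_oracle(self):
        # independent construction: pixel (i, j) is white iff no base-3
        # digit position has digit 1 in both coordinates
        depth = 4
        carpet = make_analytic_shape("sierpinski_carpet", depth=depth)
        assert carpet.shape == (81, 81)
        assert carpet.sum() == 8 ** depth

        def white(i, j):
            for _ in range(depth):
                if i % 3 == 1 and j % 3 == 1:
                    return False
                i //= 3
                j //= 3
            return True

        oracle = np.array([[white(i, j) for j in range(81)] for i in range(81)])
        assert np.array_equal(carpet, oracle)

    def test_carpet_side_must_be_power_of_three(self):
        with pytest.raises(ValueError, match="power of 3"):
            make_analytic_shape("sierpinski_carpet", side=80)

    def test_bar_dimensions(self):
        bar = make_analytic_shape("bar", width=9, length=100, size=(63, 120))
        assert bar.sum() == 900
        rows = np.unique(np.where(bar)[0])
        assert len(rows) == 9

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            make_analytic_shape("circle", radius=3)
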