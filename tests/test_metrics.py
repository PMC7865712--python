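"""The five vascular parameters against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pavessel import (
    compute_all,
    density,
    fractal_dimension,
    length_fraction,
    make_analytic_shape,
    mean_diameter,
    pa_signal,
    pa_signal_vessel,
    skeletonize,
)
from pavessel.metrics import box_counts, box_sizes


def brute_force_box_count(mask: np.ndarray, r: int) -> int:
    """Grid count by explicit double loop over origin-anchored boxes."""
    m, n = mask.shape
    count = 0
    for i0 in range(0, m, r):
        for j0 in range(0, n, r):
            if mask[i0:i0 + r, j0:j0 + r].any():
                count += 1
    return count


class TestBoxCounting:
    def test_counts_match_brute_force_on_random_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            mask = rng.random((64, 64)) < rng.uniform(0.02, 0.4)
            sizes, counts = box_counts(mask)
            for r, nr in zip(sizes, counts):
                assert nr == brute_force_box_count(mask, r)

    def test_counts_non_increasing_in_box_size(self):
        rng = np.random.default_rng(7)
        mask = rng.random((64, 64)) < 0.1
        _, counts = box_counts(mask)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_ladder_has_at_least_three_sizes(self):
        assert len(box_sizes((64, 64))) >= 3
        assert len(box_sizes((81, 81))) >= 3
        assert box_sizes((81, 81)) == [1, 3, 9, 27, 81]


class TestFractalDimension:
    def test_sierpinski_carpet_dimension(self):
        carpet = make_analytic_shape("sierpinski_carpet", depth=4)
        fd, curve = fractal_dimension(carpet)
        assert fd == pytest.approx(math.log(8) / math.log(3), abs=0.05)
        # self-similar counts are exact on the power-of-3 ladder
        assert curve.counts == tuple(8 ** (4 - k) for k in range(5))

    def test_filled_square_dimension_is_two(self):
        fd, _ = fractal_dimension(make_analytic_shape("filled_square", side=256))
        assert fd >= 1.98
        assert fd <= 2.0 + 1e-9

    def test_straight_line_dimension_is_one(self):
        fd, _ = fractal_dimension(make_analytic_shape("straight_line", length=100))
        assert fd == pytest.approx(1.0, abs=0.05)

    def test_empty_mask_is_zero_by_convention(self):
        fd, curve = fractal_dimension(np.zeros((64, 64), bool))
        assert fd == 0.0 and curve.sizes == ()

    @pytest.mark.parametrize("name,kwargs,factor", [
        ("straight_line", {"length": 100}, 2),
        ("filled_square", {"side": 128}, 2),
        # the carpet's scaling group is powers of 3; a dyadic grid on a
        # base-3 fractal shows log-periodic bias, so upscale by 3
        ("sierpinski_carpet", {"depth": 4}, 3),
    ])
    def test_invariant_under_upscaling(self, name, kwargs, factor):
        shape = make_analytic_shape(name, **kwargs)
        fd, _ = fractal_dimension(shape)
        up = np.kron(shape, np.ones((factor, factor), dtype=bool))
        fd_up, _ = fractal_dimension(up)
        assert fd_up == pytest.approx(fd, abs=0.05)


class TestDiameter:
    def test_bar_diameter_from_centerline(self, bar_phantom):
        _, truth = bar_phantom
        diam, edt_mean = mean_diameter(truth.mask, truth.skeleton)
        assert 9 <= diam <= 11
        assert edt_mean == pytest.approx(diam / 2)

    def test_disc_center_gives_full_width(self):
        # disc of radius R (strict interior), single center-pixel skeleton
        R = 10
        yy, xx = np.mgrid[:41, :41]
        disc = np.hypot(yy - 20, xx - 20) < R
        skel = np.zeros_like(disc)
        skel[20, 20] = True
        diam, _ = mean_diameter(disc, skel)
        assert diam == pytest.approx(2 * R)

    def test_empty_skeleton_is_zero(self):
        assert mean_diameter(np.ones((8, 8), bool), np.zeros((8, 8), bool)) == (0.0, 0.0)

    def test_skeleton_outside_mask_rejected(self):
        mask = np.zeros((8, 8), bool)
        skel = np.zeros((8, 8), bool)
        skel[4, 4] = True
        with pytest.raises(ValueError, match="outside"):
            mean_diameter(mask, skel)


class TestScalarMetrics:
    def test_density_against_loop_oracle(self):
        rng = np.random.default_rng(5)
        mask = rng.random((32, 48)) < 0.3
        count = sum(1 for i in range(32) for j in range(48) if mask[i, j])
        assert density(mask) == count / (32 * 48)

    def test_bar_density_is_exact(self, bar_phantom):
        _, truth = bar_phantom
        assert density(truth.mask) == 9 / 64

    def test_length_fraction_of_line(self):
        line = make_analytic_shape("straight_line", length=100)
        assert length_fraction(line) == pytest.approx(0.01)

    def test_pa_signal_of_constant_and_half_images(self):
        assert pa_signal(np.full((10, 10), 0.37)) == pytest.approx(0.37)
        half = np.zeros((10, 10))
        half[:5] = 1.0
        assert pa_signal(half) == 0.5

    def test_pa_signal_vessel_restricted_to_mask(self):
        img = np.zeros((4, 4))
        img[0, 0] = 1.0
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        assert pa_signal_vessel(img, mask) == 1.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_density_and_pa_signal_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((16, 16))
        mask = img > 0.5
        perm = rng.permutation(256)
        img_p = img.ravel()[perm].reshape(16, 16)
        mask_p = mask.ravel()[perm].reshape(16, 16)
        assert pa_signal(img_p) == pytest.approx(pa_signal(img))
        assert density(mask_p) == density(mask)


class TestComputeAll:
    def test_empty_inputs_give_all_zero_metrics(self):
        z = np.zeros((64, 64))
        m = compute_all(z, z.astype(bool), z.astype(bool))
        assert (m.pa_signal, m.diameter_px, m.density,
                m.length_fraction, m.fractal_dimension) == (0, 0, 0, 0, 0)

    def test_matches_individual_operations_on_bar(self, bar_phantom):
        img, truth = bar_phantom
        m = compute_all(img, truth.mask, truth.skeleton)
        assert m.pa_signal == pa_signal(img)
        assert m.density == density(truth.mask)
        assert m.length_fraction == length_fraction(truth.skeleton)
        assert (m.diameter_px, m.edt_mean_px) == mean_diameter(truth.mask, truth.skeleton)
        assert m.fractal_dimension == fractal_dimension(truth.mask)[0]

    def test_length_fraction_bounded_by_density(self, default_phantom):
        img, truth = default_phantom
        m = compute_all(img, truth.mask, truth.skeleton)
        assert m.length_fraction <= m.density
        assert 0 <= m.fractal_dimension <= 2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_all(np.zeros((8, 8)), np.zeros((8, 9), bool), np.zeros((8, 9), bool))


def test_dilation_raises_density_and_diameter_but_not_length_fraction(default_phantom):
    """Thickening vessels changes area and caliber, not centerline length."""
    from skimage.morphology import dilation, disk
    _, truth = default_phantom
    dil = dilation(truth.mask, disk(1))
    sk0, sk1 = skeletonize(truth.mask), skeletonize(dil)
    assert density(dil) > density(truth.mask)
    assert mean_diameter(dil, sk1)[0] > mean_diameter(truth.mask, sk0)[0]
    lf0, lf1 = length_fraction(sk0), length_fraction(sk1)
    assert abs(lf1 - lf0) / lf0 <= 0.02
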