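import numpy as np
import pytest

from vesselrad import dice, skeletonize
from vesselrad import synth
from vesselrad.synth import (
    PhantomSpec,
    Segment,
    add_background_gradient,
    add_columnwise_noise,
    degrade_resize_erode,
    generate_phantom,
    generate_tree,
    rasterize,
    render_intensity,
)


class TestGenerateTree:
    def test_single_branch_is_straight_segment(self):
        spec = PhantomSpec(n_branch_target=1, seed=3)
        segments = generate_tree(spec)
        assert len(segments) == 1
        assert segments[0].radius == spec.root_radius

    def test_deterministic_given_seed(self):
        spec = PhantomSpec(n_branch_target=30, seed=7)
        assert generate_tree(spec) == generate_tree(spec)

    def test_branch_count_and_radius_bounds(self):
        spec = PhantomSpec(n_branch_target=40, seed=7)
        segments = generate_tree(spec)
        assert 32 <= len(segments) <= 48  # within 20% of the target
        radii = [s.radius for s in segments]
        assert min(radii) >= spec.min_radius
        assert max(radii) <= spec.root_radius

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(image_size=32)
        with pytest.raises(ValueError):
            PhantomSpec(radius_decay=1.5)
        with pytest.raises(ValueError):
            PhantomSpec(min_radius=7.0, root_radius=6.0)


class TestRasterize:
    def test_horizontal_segment_geometry(self):
        seg = Segment(p0=(32.0, 10.0), p1=(32.0, 50.0), radius=2.0)
        mask, centerline, radii, n_bif = rasterize([seg], 64)
        assert n_bif == 0
        assert mask[30:35, 30].all()  # rows 30-34 on the span
        assert not mask[29, 30] and not mask[35, 30]
        assert centerline[32, 10:51].all()
        assert radii[32, 30] == 2.0

    def test_crossing_segments_union(self):
        a = Segment((32.0, 5.0), (32.0, 59.0), 2.0)
        b = Segment((5.0, 32.0), (59.0, 32.0), 2.0)
        mask_u, cl_u, _, _ = rasterize([a, b], 64)
        mask_a, cl_a, _, _ = rasterize([a], 64)
        mask_b, cl_b, _, _ = rasterize([b], 64)
        np.testing.assert_array_equal(mask_u, mask_a | mask_b)
        np.testing.assert_array_equal(cl_u, cl_a | cl_b)

    def test_area_close_to_analytic(self):
        # half-integer radii: pixel-centre coverage then matches 2 r L closely
        segs = [
            Segment((20.0, 10.0), (20.0, 110.0), 3.5),
            Segment((60.0, 10.0), (60.0, 110.0), 5.5),
        ]
        mask, _, _, _ = rasterize(segs, 128)
        expected = sum(2 * s.radius * s.length + np.pi * s.radius**2 for s in segs)
        assert abs(mask.sum() - expected) / expected < 0.10

    def test_split_points_counted(self):
        parent = Segment((60.0, 30.0), (40.0, 30.0), 3.0)
        kids = [Segment((40.0, 30.0), (20.0, 20.0), 2.0), Segment((40.0, 30.0), (20.0, 40.0), 2.0)]
        _, _, _, n_bif = rasterize([parent] + kids, 64)
        assert n_bif == 1


class TestRenderIntensity:
    def test_uniform_profile_binary(self):
        seg = Segment((16.0, 4.0), (16.0, 28.0), 2.0)
        mask, _, _, _ = rasterize([seg], 32)
        img = render_intensity(mask, [seg], "uniform")
        assert set(np.unique(img)) <= {0.0, 1.0}
        np.testing.assert_array_equal(img > 0, mask)

    def test_gaussian_profile_values(self):
        seg = Segment((16.0, 4.0), (16.0, 28.0), 4.0)
        mask, _, _, _ = rasterize([seg], 32)
        img = render_intensity(mask, [seg], "gaussian-cross-section")
        assert img[16, 16] == pytest.approx(1.0)  # on-axis
        assert img[20, 16] == pytest.approx(np.exp(-2.0), rel=1e-6)  # d = r
        assert img[22, 16] == 0.0  # outside the mask


class TestDegrade:
    def test_identity_when_disabled(self, rng):
        img = rng.uniform(size=(32, 32))
        np.testing.assert_array_equal(degrade_resize_erode(img, factor=1, erode=False), img)

    def test_support_growth_bounded_and_faint(self):
        from scipy import ndimage

        seg = Segment((32.0, 8.0), (32.0, 52.0), 3.0)  # clear of the borders
        mask, _, _, _ = rasterize([seg], 64)
        img = mask.astype(float)
        out = degrade_resize_erode(img, factor=2)
        outside = img == 0
        # resize blur may leak a faint skirt a few pixels out, never more
        assert out[outside].max() < 0.3
        dist = ndimage.distance_transform_edt(outside)
        assert not np.any((out > 0) & (dist > 3.5))

    def test_thin_tube_attenuates_thick_survives(self):
        thin = Segment((16.0, 4.0), (16.0, 124.0), 1.0)
        thick = Segment((80.0, 4.0), (80.0, 124.0), 5.0)
        mask, _, _, _ = rasterize([thin, thick], 128)
        out = degrade_resize_erode(mask.astype(float), factor=2)
        assert out[16, 20:100].max() < 0.7  # 1 px tube loses contrast
        assert out[80, 20:100].max() > 0.9  # thick tube survives intact

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            degrade_resize_erode(np.ones((8, 8)), factor=0)


class TestNoise:
    def test_level_zero_identity(self, rng):
        img = rng.uniform(size=(16, 16))
        np.testing.assert_array_equal(add_columnwise_noise(img, 0, seed=1), img)

    def test_deterministic_given_seed(self):
        img = np.zeros((64, 64))
        a = add_columnwise_noise(img, 100, seed=5)
        b = add_columnwise_noise(img, 100, seed=5)
        np.testing.assert_array_equal(a, b)
        c = add_columnwise_noise(img, 100, seed=6)
        assert not np.array_equal(a, c)

    def test_per_column_mean_shift(self):
        img = np.full((512, 8), 0.5)
        out = add_columnwise_noise(img, 100, seed=2)
        expected = 100 / synth.GRAY_SCALE_MAX
        se = expected / np.sqrt(512)
        shifts = out.mean(axis=0) - 0.5
        assert np.all(np.abs(shifts - expected) < 3 * se + 1e-9)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            add_columnwise_noise(np.zeros((4, 4)), 123)

    def test_output_clipped(self):
        out = add_columnwise_noise(np.ones((32, 32)), 200, seed=0)
        assert out.max() <= 1.0 and out.min() >= 0.0


class TestGradient:
    def test_zero_fraction_identity(self, rng):
        img = rng.uniform(size=(8, 8))
        np.testing.assert_array_equal(add_background_gradient(img, 0.0), img)

    def test_ramp_endpoints(self):
        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        out = add_background_gradient(img, 0.75)
        np.testing.assert_array_equal(out[:, 0], img[:, 0])  # left edge unchanged
        assert out[0, -1] == pytest.approx(0.75)

    def test_contrast_reduced_at_right_edge(self):
        seg_l = Segment((8.0, 2.0), (8.0, 14.0), 1.0)
        seg_r = Segment((24.0, 50.0), (24.0, 62.0), 1.0)
        mask, _, _, _ = rasterize([seg_l, seg_r], 64)
        out = add_background_gradient(mask.astype(float), 0.75)
        contrast_left = out[8, 8] - out[2, 8]
        contrast_right = out[24, 56] - out[2, 56]
        assert contrast_right < contrast_left

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            add_background_gradient(np.ones((4, 4)), 1.5)


class TestPhantom:
    def test_byte_for_byte_determinism(self):
        spec = PhantomSpec(image_size=128, n_branch_target=8, root_radius=4.0, seed=21)
        p1 = generate_phantom(spec)
        p2 = generate_phantom(spec)
        np.testing.assert_array_equal(p1.image, p2.image)
        np.testing.assert_array_equal(p1.truth_mask, p2.truth_mask)
        np.testing.assert_array_equal(p1.truth_radii, p2.truth_radii)
        assert p1.truth_bifurcations == p2.truth_bifurcations

    def test_truth_invariants(self, degraded_phantom):
        ph = degraded_phantom
        assert np.all(ph.truth_mask[ph.truth_centerline])
        assert np.all(ph.truth_radii[ph.truth_centerline] > 0)
        assert np.all(ph.truth_radii[~ph.truth_centerline] == 0)
        background = ~ph.truth_mask
        assert ph.image[ph.truth_mask].mean() > ph.image[background].mean()

    def test_thinning_agrees_with_analytic_centerline(self):
        # tubes of radius >= 2 px: topological skeleton tracks the true axes
        spec = PhantomSpec(image_size=256, n_branch_target=10, root_radius=5.0,
                           min_radius=2.0, seed=5)
        ph = generate_phantom(spec, resize_erode_factor=1, erode=False)
        skel = skeletonize(ph.truth_mask)
        from scipy import ndimage

        near_axis = ndimage.binary_dilation(ph.truth_centerline, iterations=1)
        assert dice(skel & near_axis, skel) >= 0.8

    def test_undegraded_truth_equals_rasterization(self):
        spec = PhantomSpec(image_size=128, n_branch_target=6, root_radius=4.0, seed=2)
        ph = generate_phantom(spec, resize_erode_factor=1, erode=False)
        mask, centerline, radii, n_bif = rasterize(ph.segments, 128)
        np.testing.assert_array_equal(ph.truth_mask, mask)
        np.testing.assert_array_equal(ph.truth_centerline, centerline)
        np.testing.assert_array_equal(ph.truth_radii, radii)
        assert ph.truth_bifurcations == n_bif
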