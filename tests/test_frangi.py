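import numpy as np
import pytest

from vesselrad import frangi
from vesselrad.frangi import (
    FrangiParams,
    HessianEigen,
    SigmaPlan,
    adaptive_multiscale,
    build_sigma_plan,
    coarse_mask,
    edt,
    fast_march_binarize,
    hessian_at_scale,
    plain_multiscale,
    sigma_ladder,
    vesselness2d,
)
from conftest import make_tube_image


def brute_force_edt(mask):
    """Nearest-background search by exhaustive enumeration (border = background)."""
    padded = np.pad(np.asarray(mask, dtype=bool), 1)
    bg = np.argwhere(~padded)
    out = np.zeros(padded.shape)
    for r, c in np.argwhere(padded):
        out[r, c] = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1)).min()
    return out[1:-1, 1:-1]


class TestCoarseMask:
    def test_threshold_fraction_rule(self):
        img = np.zeros((8, 8))
        img[0, :3] = [0.2, 0.6, 0.9]
        mask = coarse_mask(img, threshold_fraction=0.5, min_speck_px=1)
        assert set(map(tuple, np.argwhere(mask))) == {(0, 1), (0, 2)}

    def test_uniform_image_degenerate_full_mask(self):
        with pytest.warns(UserWarning, match="entire image"):
            mask = coarse_mask(np.ones((8, 8)))
        assert mask.all()

    def test_phantom_mask_within_dilated_truth(self, small_phantom):
        from scipy import ndimage

        mask = coarse_mask(small_phantom.image)
        dilated = ndimage.binary_dilation(small_phantom.truth_mask, iterations=1)
        assert np.all(dilated[mask])

    def test_blank_image_raises(self):
        with pytest.raises(ValueError, match="no vessels"):
            coarse_mask(np.zeros((8, 8)))


class TestEdt:
    def test_single_pixel_distance_one(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert edt(mask)[2, 2] == 1.0

    def test_disk_max_matches_radius(self):
        rows, cols = np.mgrid[0:41, 0:41]
        disk = (rows - 20) ** 2 + (cols - 20) ** 2 <= 10**2
        m = edt(disk).max()
        assert 10 <= m <= 11

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(20, 20)) < 0.6
        np.testing.assert_allclose(edt(mask), brute_force_edt(mask))

    def test_full_foreground_measures_to_border(self):
        mask = np.ones((9, 9), dtype=bool)
        np.testing.assert_allclose(edt(mask), brute_force_edt(mask))

    def test_empty_mask_all_zero(self):
        assert edt(np.zeros((4, 4), dtype=bool)).sum() == 0


class TestSigmaLadder:
    @pytest.mark.parametrize(
        "radii_max,expected",
        [
            (4.0, (0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0)),
            (1.0, (0.8, 1.0)),
            (0.5, (0.8,)),  # sqrt(0.5) < sigma_min: clamped to the smallest scale
        ],
    )
    def test_ladder_endpoints(self, radii_max, expected):
        assert sigma_ladder(radii_max) == expected

    def test_ladder_ascending_and_snaps_up(self):
        ladder = sigma_ladder(3.0)  # sqrt(3) = 1.732 -> snaps up to 1.8
        assert ladder[-1] == 1.8
        assert all(b > a for a, b in zip(ladder, ladder[1:]))


class TestHessian:
    def test_constant_image_zero_eigenvalues(self):
        eig = hessian_at_scale(np.full((32, 32), 0.7), 1.0)
        np.testing.assert_allclose(eig.lambda1, 0.0, atol=1e-12)
        np.testing.assert_allclose(eig.lambda2, 0.0, atol=1e-12)

    def test_bright_ridge_has_negative_lambda2(self):
        img = make_tube_image(64, radius=2.0, orientation="h", profile="gaussian")
        eig = hessian_at_scale(img, 1.0)
        crest = eig.lambda2[32, 20:44]
        along = eig.lambda1[32, 20:44]
        assert np.all(crest < 0)
        assert np.all(np.abs(along) < 0.1 * np.abs(crest))

    def test_ordering_invariant(self, rng):
        eig = hessian_at_scale(rng.uniform(size=(24, 24)), 1.2)
        assert np.all(np.abs(eig.lambda1) <= np.abs(eig.lambda2) + 1e-15)

    def test_rotation_equivariance(self, rng):
        img = rng.uniform(size=(24, 24))
        e = hessian_at_scale(img, 1.0)
        er = hessian_at_scale(np.rot90(img), 1.0)
        np.testing.assert_allclose(er.lambda2, np.rot90(e.lambda2), atol=1e-10)
        np.testing.assert_allclose(er.lambda1, np.rot90(e.lambda1), atol=1e-10)

    def test_oversized_sigma_raises(self):
        with pytest.raises(ValueError, match="too large"):
            hessian_at_scale(np.ones((16, 16)), 10.0)


class TestVesselness:
    def test_direct_formula_value(self):
        eig = HessianEigen(lambda1=np.zeros((1, 1)), lambda2=np.full((1, 1), -10.0), sigma=1.0)
        v = vesselness2d(eig, FrangiParams(beta=0.5, c=5.0))
        np.testing.assert_allclose(v[0, 0], 1.0 - np.exp(-2.0), rtol=1e-12)

    def test_zero_where_lambda2_positive(self, rng):
        l2 = rng.normal(size=(16, 16))
        eig = HessianEigen(lambda1=np.zeros_like(l2) + 0.1 * l2, lambda2=l2, sigma=1.0)
        v = vesselness2d(eig, FrangiParams(c=1.0))
        assert np.all(v[l2 > 0] == 0)

    def test_blob_suppressed_relative_to_ridge(self):
        s = 10.0 / np.sqrt(2)  # blob with same Frobenius norm as the ridge
        ridge = HessianEigen(np.zeros((1, 1)), np.full((1, 1), -10.0), 1.0)
        blob = HessianEigen(np.full((1, 1), -s), np.full((1, 1), -s), 1.0)
        params = FrangiParams(beta=0.5, c=5.0)
        assert vesselness2d(blob, params)[0, 0] < vesselness2d(ridge, params)[0, 0]

    def test_matches_reference_formula_on_random_fields(self, rng):
        l2 = -np.abs(rng.normal(size=(16, 16))) - 0.1
        l1 = l2 * rng.uniform(0, 1, size=(16, 16))
        beta, c = 0.5, 0.7
        expected = np.exp(-((l1 / l2) ** 2) / (2 * beta**2)) * (
            1.0 - np.exp(-(l1**2 + l2**2) / (2 * c**2))
        )
        v = vesselness2d(HessianEigen(l1, l2, 1.0), FrangiParams(beta=beta, c=c))
        np.testing.assert_allclose(v, expected, rtol=1e-12)

    def test_constant_image_zero_everywhere(self):
        vmap = plain_multiscale(np.full((32, 32), 0.4), (0.8, 1.0))
        assert vmap.data.sum() == 0


class TestAdaptive:
    def test_global_plan_reduces_to_plain_frangi(self, small_phantom):
        img = small_phantom.image
        ladder = (0.8, 1.0, 1.2, 1.4)
        plan = SigmaPlan(
            labels=np.ones(img.shape, dtype=int),
            radii_max_per_region={1: 1.96},
            sigma_set_per_region={1: ladder},
            global_fallback_set=ladder,
            sigma_max_map=np.full(img.shape, ladder[-1]),
            sigma_min=0.8,
            sigma_step=0.2,
        )
        vmap = adaptive_multiscale(img, plan)
        ref = plain_multiscale(img, ladder)
        np.testing.assert_array_equal(vmap.data, ref.data)
        np.testing.assert_array_equal(vmap.sigma_argmax, ref.sigma_argmax)

    def test_sigma_argmax_monotone_in_tube_radius(self):
        winners = []
        for r in (1.0, 2.0, 3.0, 4.0, 6.0):
            img = make_tube_image(96, radius=r, profile="gaussian")
            mask_c = coarse_mask(img)
            plan = build_sigma_plan(edt(mask_c), mask_c)
            vmap = adaptive_multiscale(img, plan)
            winners.append(np.median(vmap.sigma_argmax[48, 30:66]))
        assert all(b >= a for a, b in zip(winners, winners[1:]))
        assert winners[-1] > winners[0]

    def test_thin_tube_selects_smaller_scale_than_thick(self):
        img = make_tube_image(128, radius=1.5, orientation="h")  # thin tube at row 64
        img[94:107, :] = 1.0  # thick tube (radius 6) at row 100
        mask_c = coarse_mask(img)
        plan = build_sigma_plan(edt(mask_c), mask_c)
        vmap = adaptive_multiscale(img, plan)
        thin_sigma = np.median(vmap.sigma_argmax[64, 20:108])
        thick_sigma = np.median(vmap.sigma_argmax[100, 20:108])
        assert thin_sigma < thick_sigma


class TestBinarize:
    def test_unit_tube_recovered_exactly(self):
        v = np.zeros((32, 32))
        v[10:13, 4:28] = 1.0
        mask = fast_march_binarize(v)
        np.testing.assert_array_equal(mask, v > 0)

    def test_isolated_subthreshold_structure_excluded(self):
        v = np.zeros((32, 32))
        v[5:8, 4:28] = 1.0
        v[20:23, 4:28] = 0.0005  # below the acceptance threshold
        mask = fast_march_binarize(v, threshold=0.001)
        assert mask[6, 10]
        assert not mask[21, 10]

    def test_threshold_nesting(self, rng):
        v = rng.uniform(size=(16, 16))
        lo = fast_march_binarize(v, threshold=0.2)
        hi = fast_march_binarize(v, threshold=0.6)
        assert np.all(lo[hi])  # mask(t_high) is a subset of mask(t_low)

    def test_zero_map_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no seeds"):
            mask = fast_march_binarize(np.zeros((8, 8)))
        assert not mask.any()


class TestSegmentPipeline:
    def test_rotation_equivariance_full_pipeline(self, small_phantom):
        img = small_phantom.image
        mask, _, _ = frangi.segment(img)
        mask_rot, _, _ = frangi.segment(np.rot90(img))
        np.testing.assert_array_equal(mask_rot, np.rot90(mask))

    def test_deterministic(self, small_phantom):
        m1, v1, _ = frangi.segment(small_phantom.image)
        m2, v2, _ = frangi.segment(small_phantom.image)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(v1.data, v2.data)
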