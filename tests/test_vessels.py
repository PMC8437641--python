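import math

import numpy as np
import pytest
from scipy import ndimage

from cscrseg import (PhantomSpec, VesselMask, build_log_kernel,
                     generate_phantom, inpaint_vessels, log_filter,
                     preprocess_fundus, vessel_mask_from_response)


def _direct_log(r, c, sigma):
    rho2 = r * r + c * c
    return (-(1.0 / (math.pi * sigma ** 4))
            * (1.0 - rho2 / (2.0 * sigma ** 2))
            * math.exp(-rho2 / (2.0 * sigma ** 2)))


class TestLoGKernel:
    def test_formula_pointwise(self):
        k = build_log_kernel(3.0, 3, 3)
        for r in range(-3, 4):
            for c in range(-3, 4):
                assert k.weights[r + 3, c + 3] == pytest.approx(
                    _direct_log(r, c, 3.0), abs=1e-15)

    def test_center_value_sigma3(self):
        k = build_log_kernel(3.0, 3, 3)
        assert abs(k.weights[3, 3] - (-1.0 / (81.0 * math.pi))) < 1e-12

    def test_zero_contour_at_two_sigma_squared(self):
        # corners of the 7x7 support: r^2 + c^2 = 18 = 2 sigma^2 exactly
        k = build_log_kernel(3.0, 3, 3)
        for r, c in ((0, 0), (0, 6), (6, 0), (6, 6)):
            assert abs(k.weights[r, c]) < 1e-12

    def test_four_fold_symmetry(self):
        k = build_log_kernel(2.2, 3, 3).weights
        np.testing.assert_allclose(k, k[::-1, :])
        np.testing.assert_allclose(k, k[:, ::-1])
        np.testing.assert_allclose(k, k.T)

    def test_truncated_sum_is_far_from_zero(self):
        # the 7x7, sigma=3 support holds only the central negative lobe, so
        # unlike the infinite LoG the truncated weights do NOT sum to ~0
        k = build_log_kernel(3.0, 3, 3)
        direct = sum(_direct_log(r, c, 3.0)
                     for r in range(-3, 4) for c in range(-3, 4))
        assert k.weights.sum() == pytest.approx(direct, rel=1e-12)
        assert abs(direct) > 10 * abs(k.weights[3, 3])
        assert (k.weights <= 0).all()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            build_log_kernel(0.0)
        with pytest.raises(ValueError):
            build_log_kernel(3.0, -1, 3)


class TestLoGFilter:
    def test_impulse_response_reproduces_kernel(self):
        k = build_log_kernel(3.0, 3, 3)
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        resp = log_filter(img, k)
        np.testing.assert_allclose(resp[4:11, 4:11], k.weights, atol=1e-14)

    def test_constant_block_gives_sum_times_constant(self):
        k = build_log_kernel(3.0, 3, 3)
        resp = log_filter(np.full((20, 20), 0.6), k)
        np.testing.assert_allclose(resp, 0.6 * k.weights.sum(), atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        k = build_log_kernel(3.0, 3, 3)
        X, Y = rng.random((30, 30)), rng.random((30, 30))
        np.testing.assert_allclose(
            log_filter(2.0 * X + 0.5 * Y, k),
            2.0 * log_filter(X, k) + 0.5 * log_filter(Y, k), atol=1e-12)

    def test_block_smaller_than_kernel_rejected(self):
        with pytest.raises(ValueError):
            log_filter(np.zeros((5, 5)), build_log_kernel(3.0, 3, 3))


class TestVesselMask:
    def test_constant_response_empty_mask(self):
        vm = vessel_mask_from_response(np.full((40, 40), 0.3))
        assert not vm.mask.any()

    def test_small_area_removal(self):
        resp = np.zeros((60, 60))
        resp[5:7, 5:10] = 1.0            # 10 px component
        resp[20:30, 20:30] = 1.0         # 100 px component
        vm = vessel_mask_from_response(resp, min_area=30)
        assert vm.mask[20:30, 20:30].all()
        assert not vm.mask[5:7, 5:10].any()

    def test_nonfinite_rejected(self):
        bad = np.zeros((10, 10))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            vessel_mask_from_response(bad)

    def test_phantom_stroke_recall(self):
        # one 5-px-wide stroke; the detected mask must cover >= 70% of it
        spec = PhantomSpec(rng_seed=3, n_vessels=1, vessel_width_px=(5, 5),
                           n_blobs=0, noise_sigma=0.01)
        pair, truth = generate_phantom(spec)
        I_c = preprocess_fundus(pair.color_fundus)
        resp = log_filter(I_c, build_log_kernel())
        vm = vessel_mask_from_response(resp)
        recall = (vm.mask & truth.vessel_mask).sum() / truth.vessel_mask.sum()
        assert recall >= 0.70


class TestInpaint:
    def test_empty_mask_is_identity(self):
        rng = np.random.default_rng(1)
        I = rng.random((40, 40))
        vm = VesselMask(mask=np.zeros((40, 40), bool), min_area_used=30)
        np.testing.assert_array_equal(inpaint_vessels(I, vm), I)

    def test_constant_block_fills_constant(self):
        I = np.full((30, 30), 0.42)
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        out = inpaint_vessels(I, VesselMask(mask, 30), dilate_radius=0)
        np.testing.assert_allclose(out, 0.42, atol=1e-10)

    def test_single_pixel_within_neighbor_range(self):
        rng = np.random.default_rng(2)
        I = rng.random((9, 9))
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        out = inpaint_vessels(I, VesselMask(mask, 30), dilate_radius=0)
        nbrs = [I[4 + dr, 4 + dc] for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
        assert min(nbrs) - 1e-12 <= out[4, 4] <= max(nbrs) + 1e-12

    def test_unmasked_pixels_bit_exact(self):
        rng = np.random.default_rng(3)
        I = rng.random((50, 50))
        mask = rng.random((50, 50)) < 0.1
        out = inpaint_vessels(I, VesselMask(mask, 30), dilate_radius=2)
        dil = ndimage.binary_dilation(mask, iterations=2)
        np.testing.assert_array_equal(out[~dil], I[~dil])

    def test_full_mask_rejected(self):
        with pytest.raises(ValueError):
            inpaint_vessels(np.zeros((10, 10)),
                            VesselMask(np.ones((10, 10), bool), 30))

    def test_vessel_suppression_on_phantom(self, default_phantom):
        # the multimodal step exists to weaken the bright vessels
        from cscrseg import extract_roi, roi_covering_blobs, \
            segment_and_inpaint
        pair, truth = default_phantom
        box = roi_covering_blobs(truth, pair.shape)
        I_a, fb = extract_roi(pair, box)
        G_P, vm = segment_and_inpaint(I_a, preprocess_fundus(fb))
        tm = truth.vessel_mask[box.r0:box.r1, box.c0:box.c1]
        assert tm.any()
        assert G_P[tm].max() < I_a[tm].max()
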