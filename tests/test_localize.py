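import numpy as np
import pytest

from discgabor.gabor import GaborBankParams, apply_bank, build_bank
from discgabor.localize import (DISC_U1, DISC_U2, Priors, candidate_cols,
                                candidate_rows, compute_boxes,
                                compute_disc_gfi, elliptical_footprint,
                                elliptical_median, estimate_angle,
                                refine_centers, row_profile)
from discgabor.phantom import PhantomSpec, generate
from discgabor.spine import DetectionFailure, SpinalCurves


def make_curves(M, left, right):
    return SpinalCurves(left=np.full(M, left, dtype=int),
                        right=np.full(M, right, dtype=int),
                        valid_rows=(0, M - 1))


class TestPriors:
    def test_defaults(self):
        p = Priors()
        assert (p.min_dy, p.max_dy) == (25.0, 60.0)
        assert p.x_alignment_tol == 15.0
        assert p.angle_range == 30.0

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            Priors(min_dy=30, max_dy=20)

    def test_mm_window_converted_through_spacing(self):
        p = Priors.from_spacing(0.5)  # 0.5 mm/px -> 20mm = 40px, 50mm = 100px
        assert p.min_dy == pytest.approx(40.0)
        assert p.max_dy == pytest.approx(100.0)

    def test_no_spacing_keeps_pixel_defaults(self):
        p = Priors.from_spacing(None)
        assert (p.min_dy, p.max_dy) == (25.0, 60.0)


class TestComputeDiscGfi:
    def test_reference_direction_subsets(self):
        assert DISC_U1 == (7, 8, 9, 10, 11)
        assert DISC_U2 == (1, 2, 3, 4, 5)

    def test_nonnegative(self, phantom_stack):
        assert np.all(compute_disc_gfi(phantom_stack) >= 0)

    def test_disc_contrast_on_phantom(self, phantom_stack, phantom_truth):
        g = compute_disc_gfi(phantom_stack)
        disc_mask = np.zeros(g.shape, dtype=bool)
        for m in phantom_truth.disc_masks:
            disc_mask |= m
        band = np.zeros(g.shape, dtype=bool)
        cols = np.arange(g.shape[1])
        for r in range(g.shape[0]):
            band[r] = ((cols >= phantom_truth.spine_left[r]) &
                       (cols <= phantom_truth.spine_right[r]))
        inside = g[disc_mask].mean()
        outside = g[band & ~disc_mask].mean()
        assert inside > 2 * outside

    def test_requires_16_directions(self):
        params = GaborBankParams(S=8, K=2, window=11)
        stack = apply_bank(np.random.default_rng(0).random((40, 40)),
                           build_bank(params), params)
        with pytest.raises(ValueError):
            compute_disc_gfi(stack)


class TestEllipticalMedian:
    def test_default_template_shape(self):
        fp = elliptical_footprint(44, 17)
        assert fp.shape == (17, 45)
        assert fp[8, 0] and fp[8, -1]  # long axis spans the template
        assert fp[0, 22] and fp[-1, 22]

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            elliptical_footprint(10, 20)
        with pytest.raises(ValueError):
            elliptical_footprint(0, 0)

    def test_constant_image_unchanged(self):
        img = np.full((40, 40), 3.5)
        np.testing.assert_allclose(elliptical_median(img, 15, 7), img)

    def test_matches_brute_force_median(self):
        rng = np.random.default_rng(5)
        img = rng.random((32, 32))
        long_axis, minor_axis = 9, 5
        got = elliptical_median(img, long_axis, minor_axis)
        fp = elliptical_footprint(long_axis, minor_axis)
        hr, hc = fp.shape[0] // 2, fp.shape[1] // 2
        padded = np.pad(img, ((hr, hr), (hc, hc)), mode="symmetric")
        expected = np.empty_like(img)
        for r in range(32):
            for c in range(32):
                patch = padded[r:r + fp.shape[0], c:c + fp.shape[1]]
                expected[r, c] = np.median(patch[fp])
        np.testing.assert_array_equal(got, expected)


class TestRowProfile:
    def test_all_ones_gives_band_width(self):
        g = np.ones((6, 10))
        curves = make_curves(6, 2, 7)
        gh = row_profile(g, curves)
        np.testing.assert_allclose(gh, np.full(6, 6.0))  # cols 2..7 inclusive

    def test_zero_grid_zero_profile(self):
        curves = make_curves(5, 1, 3)
        assert np.all(row_profile(np.zeros((5, 6)), curves) == 0)

    def test_hand_computed_toy_grid(self):
        g = np.arange(24, dtype=float).reshape(4, 6)
        curves = make_curves(4, 1, 3)
        expected = [g[r, 1:4].sum() for r in range(4)]
        np.testing.assert_allclose(row_profile(g, curves), expected)

    def test_rows_outside_valid_range_zero(self):
        g = np.ones((8, 6))
        curves = SpinalCurves(left=np.full(8, 1), right=np.full(8, 4),
                              valid_rows=(2, 5))
        gh = row_profile(g, curves)
        assert np.all(gh[:2] == 0) and np.all(gh[6:] == 0)
        assert np.all(gh[2:6] > 0)


def gaussian_bumps(M, centers, sigma=4.0, amps=None):
    rows = np.arange(M, dtype=float)
    out = np.zeros(M)
    amps = amps or [1.0] * len(centers)
    for c, a in zip(centers, amps):
        out += a * np.exp(-0.5 * ((rows - c) / sigma) ** 2)
    return out


class TestCandidateRows:
    def test_five_bumps_spaced_40(self):
        centers = [60, 100, 140, 180, 220]
        gh = gaussian_bumps(300, centers)
        got = candidate_rows(gh, Priors())
        assert len(got) == 5
        for c, g in zip(centers, got):
            assert abs(g - c) <= 1

    def test_close_bumps_merge_to_weighted_mean(self):
        gh = gaussian_bumps(120, [50, 60], amps=[1.0, 3.0])
        got = candidate_rows(gh, Priors())
        assert len(got) == 1
        # merged position is pulled toward the stronger bump
        assert 55 <= got[0] <= 60

    def test_single_bump(self):
        gh = gaussian_bumps(80, [37])
        got = candidate_rows(gh, Priors())
        assert list(got) == [37]

    def test_zero_profile_raises(self):
        with pytest.raises(DetectionFailure):
            candidate_rows(np.zeros(100), Priors())

    def test_negative_profile_rejected(self):
        with pytest.raises(ValueError):
            candidate_rows(np.full(50, -1.0), Priors())

    def test_chained_twin_peaks_split_per_disc(self):
        # twin edge-response peaks 14 px apart per disc, discs 45 px apart:
        # chained gaps are all < min_dy yet the group must split per disc
        centers = []
        for disc in [100, 145, 190]:
            centers += [disc - 7, disc + 7]
        gh = gaussian_bumps(300, centers, sigma=3.0)
        got = candidate_rows(gh, Priors(min_dy=25, max_dy=60))
        assert len(got) == 3
        for disc, g in zip([100, 145, 190], got):
            assert abs(g - disc) <= 2


class TestCandidateCols:
    def _feature(self, M=200, N=80, col=40, rows=(50, 100, 150)):
        g = np.zeros((M, N))
        for r in rows:
            g[r - 4:r + 5, col - 10:col + 11] = 1.0
        return g

    def test_phantom_aligned_columns(self, phantom_stack, phantom_truth,
                                     phantom_curves, phantom_detections):
        detections, _ = phantom_detections
        true_col = phantom_truth.centers[0][1]
        for det in detections:
            assert abs(det.coarse_center[1] - true_col) <= 3

    def test_single_disc_argmax(self):
        g = self._feature(rows=(100,))
        curves = make_curves(200, 10, 70)
        x, gv = candidate_cols(g, np.array([100]), curves, Priors())
        assert x[0] == 30  # argmax tie broken toward the lowest index
        assert len(gv) == 1

    def test_hand_built_band_profile(self):
        g = np.zeros((60, 40))
        g[28:33, 20] = 2.0
        g[28:33, 25] = 1.0
        curves = make_curves(60, 5, 35)
        x, gv = candidate_cols(g, np.array([30]), curves, Priors())
        assert x[0] == 20
        assert gv[0][20] == pytest.approx(10.0)
        assert gv[0][25] == pytest.approx(5.0)

    def test_outlier_snapped_to_median_line(self):
        rows = (40, 80, 120, 160, 200)
        g = self._feature(M=260, rows=rows)
        g[118:123, 8:19] = 3.0  # stronger off-axis blob at disc 3
        g[116:125, 30:51] = 0.0
        curves = make_curves(260, 5, 75)
        x, _ = candidate_cols(g, np.array(rows), curves, Priors())
        med = np.median(x)
        assert abs(x[2] - med) <= Priors().x_alignment_tol


class TestComputeBoxes:
    def test_unimodal_bump_with_zero_flanks(self):
        gh = np.zeros(100)
        gh[40:61] = gaussian_bumps(21, [10], sigma=3.0)
        gv = np.zeros(50)
        gv[20:31] = gaussian_bumps(11, [5], sigma=2.0)
        boxes, kept = compute_boxes(gh, [gv], np.array([50]), np.array([25]))
        assert kept == [0]
        top, bottom, left, right = boxes[0]
        assert abs(top - 40) <= 3 and abs(bottom - 60) <= 3
        assert abs(left - 20) <= 3 and abs(right - 30) <= 3

    def test_box_contains_candidate_center(self, phantom_detections):
        detections, _ = phantom_detections
        for det in detections:
            top, bottom, left, right = det.box
            r, c = det.coarse_center
            assert top <= r <= bottom
            assert left <= c <= right

    def test_boxes_cover_true_disc_masks(self, phantom_detections,
                                         phantom_truth):
        from discgabor.metrics import match_centers
        detections, _ = phantom_detections
        pairs, _, _ = match_centers([d.center for d in detections],
                                    phantom_truth.centers)
        for i, j, _ in pairs:
            top, bottom, left, right = detections[i].box
            box = np.zeros(phantom_truth.image.shape, dtype=bool)
            box[top:bottom + 1, left:right + 1] = True
            m = phantom_truth.disc_masks[j]
            assert (box & m).sum() >= 0.9 * m.sum()

    def test_degenerate_box_dropped(self):
        gh = np.zeros(50)
        gv = np.zeros(30)
        boxes, kept = compute_boxes(gh, [gv], np.array([25]), np.array([15]))
        assert boxes == [] and kept == []


def single_disc_stack(angle_deg, default_bank, default_params):
    truth = generate(PhantomSpec(seed=2, n_discs=1, image_size=(160, 160),
                                 angle_deg=(angle_deg, angle_deg),
                                 disc_width=(32, 32),
                                 endplate_thickness=0.0))
    stack = apply_bank(truth.image, default_bank, default_params)
    r, c = truth.centers[0]
    box = (int(r) - 15, int(r) + 15, int(c) - 22, int(c) + 22)
    return stack, box


class TestEstimateAngle:
    BIN = 180.0 / 16

    @pytest.mark.parametrize("angle", [0.0, 15.0, -30.0])
    def test_phantom_disc_angle_within_one_bin(self, angle, default_bank,
                                               default_params):
        stack, box = single_disc_stack(angle, default_bank, default_params)
        est = estimate_angle(stack, box)
        assert abs(est - angle) <= self.BIN + 1e-9

    def test_clamped_to_45(self, phantom_stack):
        est = estimate_angle(phantom_stack, (0, 50, 0, 50))
        assert -45.0 <= est <= 45.0


class TestRefineCenters:
    def test_symmetric_ellipse_centroid(self):
        g = np.zeros((60, 60))
        rr, cc = np.mgrid[:60, :60]
        ellipse = ((cc - 30) / 12.0) ** 2 + ((rr - 28) / 6.0) ** 2 <= 1
        g[ellipse] = 10.0
        centers = refine_centers(g, [(18, 38, 14, 46)], [(28, 30)])
        assert centers[0][0] == pytest.approx(28, abs=0.1)
        assert centers[0][1] == pytest.approx(30, abs=0.1)

    def test_centroid_matches_brute_force(self):
        rng = np.random.default_rng(9)
        g = rng.random((40, 40)) * 100
        box = (5, 30, 8, 33)
        centers = refine_centers(g, [box], [(17, 20)])
        from discgabor.segment import otsu_threshold
        top, bottom, left, right = box
        sub = g[top:bottom + 1, left:right + 1]
        thr = otsu_threshold(sub)
        rs, cs = [], []
        for r in range(sub.shape[0]):
            for c in range(sub.shape[1]):
                if sub[r, c] > thr:
                    rs.append(r + top)
                    cs.append(c + left)
        assert centers[0][0] == pytest.approx(np.mean(rs))
        assert centers[0][1] == pytest.approx(np.mean(cs))

    def test_empty_foreground_falls_back_to_coarse(self):
        g = np.zeros((20, 20))
        centers = refine_centers(g, [(2, 10, 2, 10)], [(6, 7)])
        assert centers[0] == (6.0, 7.0)

    def test_refinement_not_worse_on_phantom(self, phantom_detections,
                                             phantom_truth):
        from discgabor.metrics import match_centers
        detections, _ = phantom_detections
        pairs, _, _ = match_centers([d.center for d in detections],
                                    phantom_truth.centers)
        refined_err, coarse_err = [], []
        for i, j, dist in pairs:
            ref = np.array(phantom_truth.centers[j])
            refined_err.append(dist)
            coarse_err.append(float(np.hypot(
                *(np.array(detections[i].coarse_center, dtype=float) - ref))))
        assert np.mean(refined_err) <= np.mean(coarse_err) + 1e-9
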