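"""Image-quantification suite: gradients, regions, ratios, survival curves."""

import numpy as np
import pytest

from lumiplan import (
    DetectorImage,
    RegionMask,
    compare_survival,
    flat_field_correct,
    gradient_magnitude_map,
    linearity_fit,
    normalized_histogram,
    power_ratio,
    probe_contrast_survival,
    sbr,
    uniform_region,
)


def stencil_gradient_oracle(arr):
    """Explicit central-difference stencil, one-sided at borders."""
    ny, nx = arr.shape
    gx = np.zeros_like(arr)
    gy = np.zeros_like(arr)
    for i in range(ny):
        for j in range(nx):
            if 0 < j < nx - 1:
                gx[i, j] = (arr[i, j + 1] - arr[i, j - 1]) / 2
            elif j == 0:
                gx[i, j] = arr[i, 1] - arr[i, 0]
            else:
                gx[i, j] = arr[i, -1] - arr[i, -2]
            if 0 < i < ny - 1:
                gy[i, j] = (arr[i + 1, j] - arr[i - 1, j]) / 2
            elif i == 0:
                gy[i, j] = arr[1, j] - arr[0, j]
            else:
                gy[i, j] = arr[-1, j] - arr[-2, j]
    return np.sqrt(gx**2 + gy**2)


def region_oracle(arr, threshold=0.9):
    """Brute-force candidate scan + flood fill, 8-connectivity."""
    cand = arr >= threshold * arr.max()
    seen = np.zeros_like(cand)
    comps = []
    for i, j in zip(*np.nonzero(cand)):
        if seen[i, j]:
            continue
        stack, pixels = [(i, j)], []
        seen[i, j] = True
        while stack:
            a, b = stack.pop()
            pixels.append((a, b))
            for da in (-1, 0, 1):
                for db in (-1, 0, 1):
                    na, nb = a + da, b + db
                    if (
                        0 <= na < arr.shape[0]
                        and 0 <= nb < arr.shape[1]
                        and cand[na, nb]
                        and not seen[na, nb]
                    ):
                        seen[na, nb] = True
                        stack.append((na, nb))
        comps.append(pixels)
    comps.sort(key=len, reverse=True)
    rows = [p[0] for p in comps[0]]
    cols = [p[1] for p in comps[0]]
    return min(rows), min(cols), max(rows) + 1, max(cols) + 1


class TestGradient:
    def test_constant_image_has_zero_gradient(self):
        assert gradient_magnitude_map(np.full((8, 8), 9.0)).max() == 0.0

    def test_linear_ramp_has_unit_gradient(self):
        x = np.tile(np.arange(16, dtype=float), (10, 1))
        grad = gradient_magnitude_map(x)
        np.testing.assert_allclose(grad, 1.0)

    def test_matches_stencil_oracle(self, rng):
        arr = rng.random((24, 31))
        np.testing.assert_array_equal(
            gradient_magnitude_map(arr), stencil_gradient_oracle(arr)
        )

    def test_smoothing_reduces_noise_gradient(self, rng):
        arr = 100 + 10 * rng.standard_normal((64, 64))
        rough = gradient_magnitude_map(arr).mean()
        smooth = gradient_magnitude_map(arr, smooth_window=12).mean()
        assert smooth < rough / 3

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            gradient_magnitude_map(np.ones((2, 5)))


class TestUniformRegion:
    def test_constant_image_gives_full_frame(self):
        box = uniform_region(np.full((6, 9), 5.0))
        assert box.bbox() == (0, 0, 6, 9)
        assert box.n_pixels == 54

    def test_gaussian_spot_box_grows_with_width(self, rng):
        def box_area(sigma):
            y, x = np.mgrid[:49, :49] - 24.0
            img = np.exp(-(x**2 + y**2) / (2 * sigma**2))
            r0, c0, r1, c1 = uniform_region(img).bbox()
            assert r0 <= 24 < r1 and c0 <= 24 < c1  # centered on the peak
            return (r1 - r0) * (c1 - c0)

        areas = [box_area(s) for s in (3.0, 6.0, 10.0)]
        assert areas[0] < areas[1] < areas[2]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            img = rng.random((20, 20))
            img[rng.integers(0, 20, 5), rng.integers(0, 20, 5)] = 1.0
            assert uniform_region(img).bbox() == region_oracle(img)

    def test_two_plateaus_picks_larger(self):
        img = np.zeros((12, 20))
        img[2:4, 2:4] = 1.0       # 4 pixels
        img[7:10, 12:16] = 1.0    # 12 pixels
        assert uniform_region(img).bbox() == (7, 12, 10, 16)

    def test_equal_plateaus_pick_component_of_argmax(self):
        img = np.zeros((10, 10))
        img[1:3, 1:3] = 0.99
        img[6:8, 6:8] = 0.99
        img[7, 7] = 1.0  # strict argmax in the second plateau
        assert uniform_region(img).bbox() == (6, 6, 8, 8)

    def test_zero_image_rejected(self):
        with pytest.raises(ValueError):
            uniform_region(np.zeros((5, 5)))


class TestHistogramAndPower:
    def test_constant_image_occupies_single_bin(self):
        img = np.full((10, 10), 40.0)
        edges, density = normalized_histogram(img, None, ref_max=80.0, bins=10)
        assert (density > 0).sum() == 1
        occupied = int(np.flatnonzero(density > 0)[0])
        assert edges[occupied] <= 0.5 <= edges[occupied + 1]

    def test_density_integrates_to_one(self, rng):
        img = rng.random((30, 30)) * 200
        edges, density = normalized_histogram(img, None, ref_max=200.0)
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0)

    def test_self_reference_support_in_unit_interval(self, rng):
        img = rng.random((20, 20)) * 131
        edges, density = normalized_histogram(img, None, ref_max=img.max())
        assert edges[-1] == pytest.approx(1.0)

    def test_matches_counting_oracle(self, rng):
        img = rng.random((16, 16))
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        edges, density = normalized_histogram(img, mask, ref_max=2.0, bins=8)
        counts, _ = np.histogram(img[mask] / 2.0, bins=edges)
        oracle = counts / counts.sum() / np.diff(edges)
        np.testing.assert_allclose(density, oracle)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            normalized_histogram(rng.random((5, 5)), np.zeros((5, 5), bool), 1.0)

    def test_power_ratio_identity_and_linearity(self, rng):
        img = rng.random((12, 12)) + 0.2
        mask = np.ones((12, 12), bool)
        assert power_ratio(img, mask, img, mask) == pytest.approx(1.0)
        assert power_ratio(2 * img, mask, img, mask) == pytest.approx(2.0)

    def test_power_ratio_scale_free(self, rng):
        a, b = rng.random((8, 8)) + 0.1, rng.random((8, 8)) + 0.1
        mask = np.ones((8, 8), bool)
        r1 = power_ratio(a, mask, b, mask)
        r2 = power_ratio(13.7 * a, mask, 13.7 * b, mask)
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestFlatField:
    def test_sample_equal_to_standard_flattens(self, rng):
        vals = (rng.random((16, 16)) * 150 + 50).round()
        sample = DetectorImage(vals)
        standard = DetectorImage(vals)
        corrected, valid = flat_field_correct(sample, standard)
        inner = corrected.pixels[valid.mask]
        assert inner.std() / inner.mean() < 1e-6

    def test_proportional_sample_flattens_to_constant(self, rng):
        vals = rng.random((16, 16)) * 100 + 40
        sample = DetectorImage((0.5 * vals).round())
        standard = DetectorImage(vals.round())
        corrected, valid = flat_field_correct(sample, standard)
        inner = corrected.pixels[valid.mask]
        assert inner.std() / inner.mean() < 0.02  # quantization only

    def test_vignetted_scene_recovers_reflectance(self, rng):
        # known scene under a strong radial illumination falloff
        y, x = np.mgrid[:48, :48] - 23.5
        illum = np.exp(-(x**2 + y**2) / (2 * 18.0**2))
        scene = 0.4 + 0.3 * (x > 0)  # two-level "reflectance"
        sample = DetectorImage(np.round(200 * illum * scene))
        standard = DetectorImage(np.round(250 * illum))
        corrected, valid = flat_field_correct(sample, standard, floor=0.05)
        ratio_map = corrected.pixels
        left = ratio_map[valid.mask & (x < -1)].mean()
        right = ratio_map[valid.mask & (x > 1)].mean()
        assert right / left == pytest.approx(0.7 / 0.4, rel=0.03)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            flat_field_correct(
                DetectorImage(np.ones((4, 4))), DetectorImage(np.ones((5, 5)))
            )


class TestSBR:
    def test_doubled_uptake_gives_two(self, rng):
        pre = rng.random((10, 10)) * 80 + 20
        mask = np.ones((10, 10), bool)
        assert sbr(pre, 2 * pre, mask) == pytest.approx(2.0)
        assert sbr(pre, pre, mask) == pytest.approx(1.0)

    def test_region_mean_oracle(self, rng):
        pre = rng.random((20, 20)) * 50 + 10
        post = rng.random((20, 20)) * 120 + 30
        mask = np.zeros((20, 20), bool)
        mask[5:15, 8:17] = True
        assert sbr(pre, post, mask) == pytest.approx(
            post[mask].mean() / pre[mask].mean(), rel=1e-12
        )

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            sbr(np.zeros((4, 4)), np.ones((4, 4)), np.ones((4, 4), bool))


class TestSurvival:
    def test_equal_constant_cohorts_step_at_one(self):
        spec = [np.full((8, 8), 7.0)] * 3
        nonspec = [np.full((8, 8), 7.0)] * 3
        curves = probe_contrast_survival(spec, nonspec)
        assert curves.mean[0] == 1.0
        assert curves.mean[-1] == 0.0
        below = curves.grid < 1.0 - 1e-9
        above = curves.grid > 1.0 + 1e-9
        assert np.all(curves.mean[below] == 1.0)
        assert np.all(curves.mean[above] == 0.0)

    def test_twofold_contrast_steps_at_two(self):
        spec = [np.full((8, 8), 10.0)]
        nonspec = [np.full((8, 8), 5.0)]
        curves = probe_contrast_survival(spec, nonspec)
        assert np.all(curves.mean[curves.grid < 2.0 - 1e-9] == 1.0)

    def test_curves_are_monotone_from_one_to_zero(self, rng):
        spec = [rng.lognormal(1.0, 0.4, (16, 16)) for _ in range(5)]
        nonspec = [rng.lognormal(0.0, 0.4, (16, 16)) for _ in range(5)]
        curves = probe_contrast_survival(spec, nonspec)
        for row in curves.per_image:
            assert row[0] == 1.0
            assert row[-1] == pytest.approx(0.0, abs=1e-12)
            assert np.all(np.diff(row) <= 1e-12)

    def test_separated_cohorts_and_ks_oracle(self, rng):
        fold = 2.5
        base = [rng.lognormal(0.0, 0.3, (16, 16)) for _ in range(5)]
        spec = [fold * rng.lognormal(0.0, 0.3, (16, 16)) for _ in range(5)]
        curves_hi = probe_contrast_survival(spec, base)
        curves_lo = probe_contrast_survival(base, base)
        # survival of the boosted cohort dominates
        mid = len(curves_hi.grid) // 4
        assert curves_hi.mean[mid] > curves_lo.mean[mid]
        stat, p = compare_survival(curves_hi, curves_lo)
        # direct ECDF-difference oracle on the pooled ratios
        a = np.sort(curves_hi.pooled_ratios)
        b = np.sort(curves_lo.pooled_ratios)
        support = np.concatenate([a, b])
        ecdf_a = np.searchsorted(a, support, side="right") / a.size
        ecdf_b = np.searchsorted(b, support, side="right") / b.size
        assert stat == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)), abs=1e-12)
        assert p < 1e-6

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            probe_contrast_survival([], [np.ones((4, 4))])


class TestLinearity:
    def test_exact_line_recovered(self):
        x = np.arange(6, dtype=float)
        slope, intercept, r2 = linearity_fit(x, 3 * x + 1)
        assert (slope, intercept) == (pytest.approx(3.0), pytest.approx(1.0))
        assert r2 == pytest.approx(1.0)

    def test_noisy_series_slope_within_two_se(self, rng):
        x = np.linspace(0, 25, 6)
        truth = 8.0
        y = truth * x + rng.normal(0, 4.0, x.size)
        slope, _, _ = linearity_fit(x, y)
        from scipy.stats import linregress

        se = linregress(x, y).stderr
        assert abs(slope - truth) < 2 * se + 1e-9

    def test_degenerate_levels_rejected(self):
        with pytest.raises(ValueError):
            linearity_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDetectorImage:
    def test_rgb_reduces_to_green_channel(self, rng):
        rgb = (rng.random((6, 6, 3)) * 255).round()
        img = DetectorImage(rgb)
        np.testing.assert_array_equal(img.pixels, rgb[..., 1])

    def test_range_enforced(self):
        with pytest.raises(ValueError):
            DetectorImage(np.full((4, 4), 300.0), bit_depth=8)

    def test_region_mask_bbox(self):
        m = np.zeros((7, 7), bool)
        m[2:5, 3:6] = True
        assert RegionMask(m).bbox() == (2, 3, 5, 6)

    def test_region_mask_rle_roundtrip(self, rng):
        m = rng.random((9, 13)) > 0.6
        m[0, 0] = True  # exercise the leading-True edge case
        back = RegionMask.from_rle(RegionMask(m).to_rle())
        np.testing.assert_array_equal(back.mask, m)
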