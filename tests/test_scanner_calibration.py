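"""Device calibration: patch extraction, gamma fit, WPPLS, dE* maps."""

import numpy as np
import pytest

from ihccal.colorimetry import ChartColors
from ihccal.errors import (
    CalibrationError,
    EncodingError,
    IhccalError,
    InsufficientDataError,
    LayoutError,
)
from ihccal.scanner_calibration import (
    GammaEstimate,
    ImagePatch,
    IncidentLight,
    PolynomialColorMap,
    apply_color_map,
    calibrate_scanner,
    compute_de_map,
    estimate_gamma,
    extract_patch_colors,
    fit_wppls,
    linearize,
    mean_patch_delta_e,
    normalize_by_incident,
)
from ihccal.synthetic import default_chart_layout, render_color_chart, scanner_preset


def uniform_chart_image(colors: ChartColors, layout) -> ImagePatch:
    img = np.ones((200, 210, 3)) * colors.column("BG")
    for pid, (r0, c0, h, w) in layout.items():
        img[r0 : r0 + h, c0 : c0 + w] = colors.column(pid)
    return ImagePatch(img, "device_gamma")


class TestExtractPatchColors:
    def test_uniform_patches_recovered_exactly(self, chart_reference):
        layout = default_chart_layout()
        img = uniform_chart_image(chart_reference, layout)
        got = extract_patch_colors(img, layout)
        np.testing.assert_allclose(got.values, chart_reference.values, atol=1e-12)
        assert got.values.shape == (3, 13)

    def test_noise_averages_within_standard_error(self):
        rng = np.random.default_rng(0)
        truth = np.array([0.4, 0.6, 0.2])
        img = np.ones((100, 100, 3)) * truth
        img += rng.normal(0, 0.01, img.shape)
        layout = {pid: (0, 0, 100, 100) for pid in default_chart_layout()}
        got = extract_patch_colors(ImagePatch(img, "device_gamma"), layout)
        # central region is 50x50; 3-sigma bound on the mean of 2500 samples
        assert np.all(np.abs(got.column("A1") - truth) < 3 * 0.01 / 50)

    def test_out_of_bounds_rectangle_rejected(self, chart_reference):
        layout = default_chart_layout()
        img = uniform_chart_image(chart_reference, layout)
        layout["A1"] = (190, 0, 40, 40)
        with pytest.raises(LayoutError):
            extract_patch_colors(img, layout)

    def test_missing_patch_rejected(self, chart_reference):
        layout = default_chart_layout()
        img = uniform_chart_image(chart_reference, layout)
        del layout["C4"]
        with pytest.raises(LayoutError):
            extract_patch_colors(img, layout)


class TestNormalizeByIncident:
    def test_incident_pixel_maps_to_white_and_zero_stays(self):
        inc = IncidentLight([0.9, 0.95, 0.85])
        px = np.broadcast_to(inc.I0, (2, 2, 3)).copy()
        px[0, 0] = 0.0
        out = normalize_by_incident(ImagePatch(px), inc)
        np.testing.assert_allclose(out.pixels[0, 0], 0.0)
        np.testing.assert_allclose(out.pixels[1, 1], 1.0)
        assert out.encoding == "device_gamma"

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(3)
        px = rng.uniform(0, 1, (5, 4, 3))
        inc = IncidentLight([0.8, 0.9, 0.7])
        out = normalize_by_incident(ImagePatch(px), inc).pixels
        for i in range(5):
            for j in range(4):
                for ch in range(3):
                    assert out[i, j, ch] == px[i, j, ch] / inc.I0[ch]

    def test_nonpositive_incident_rejected(self):
        with pytest.raises(IhccalError):
            IncidentLight([1.0, 0.0, 1.0])


class TestGammaEstimation:
    def test_linear_scan_gives_unit_gamma(self, chart_reference, C):
        scanned = ChartColors(chart_reference.values.copy(), role="scanned")
        est = estimate_gamma(scanned, chart_reference, C)
        assert est.gamma == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("gamma", [1.8, 2.2])
    def test_recovers_display_gamma_noiseless(self, chart_reference, C, gamma):
        scanned = ChartColors(chart_reference.values ** (1 / gamma), role="scanned")
        est = estimate_gamma(scanned, chart_reference, C)
        assert est.gamma == pytest.approx(gamma, abs=0.01)

    def test_noisy_fit_matches_grid_search_oracle(self, chart_reference, C):
        rng = np.random.default_rng(5)
        gamma = 2.2
        vals = np.clip(
            chart_reference.values ** (1 / gamma) + rng.normal(0, 0.005, (3, 13)),
            0.0,
            1.0,
        )
        scanned = ChartColors(vals, role="scanned")
        est = estimate_gamma(scanned, chart_reference, C)
        # independent oracle: dense grid search over [0.2, 5.0] step 0.001
        from ihccal.colorimetry import GRAYSCALE_IDS

        y_row = C.C[1]
        ys = np.array([y_row @ scanned.column(p) for p in GRAYSCALE_IDS])
        yr = np.array([y_row @ chart_reference.column(p) for p in GRAYSCALE_IDS])
        keep = (ys > 0) & (ys < 1)
        grid = np.arange(0.2, 5.0, 0.001)
        losses = [np.sum((ys[keep] ** g - yr[keep]) ** 2) for g in grid]
        assert est.gamma == pytest.approx(grid[int(np.argmin(losses))], abs=0.002)

    def test_saturated_chart_rejected(self, chart_reference, C):
        scanned = ChartColors(np.ones((3, 13)), role="scanned")
        with pytest.raises(InsufficientDataError):
            estimate_gamma(scanned, chart_reference, C)


class TestLinearize:
    def test_unit_gamma_is_identity_and_endpoints_fixed(self):
        px = np.random.default_rng(0).uniform(0, 1, (4, 4, 3))
        px[0, 0] = 0.0
        px[0, 1] = 1.0
        out = linearize(ImagePatch(px), GammaEstimate(1.0))
        np.testing.assert_array_equal(out.pixels, px)
        out22 = linearize(ImagePatch(px), GammaEstimate(2.2))
        assert out22.pixels[0, 0, 0] == 0.0 and out22.pixels[0, 1, 0] == 1.0
        assert out22.encoding == "device_linear"

    def test_midgray_power_law(self):
        img = ImagePatch(np.full((1, 1, 3), 0.5))
        out = linearize(img, GammaEstimate(2.2))
        assert out.pixels[0, 0, 0] == pytest.approx(0.5 ** 2.2, rel=1e-12)

    def test_wrong_encoding_rejected(self):
        img = ImagePatch(np.full((1, 1, 3), 0.5), "device_linear")
        with pytest.raises(EncodingError):
            linearize(img, GammaEstimate(2.0))


def constrained_lsq_oracle(reference: np.ndarray, scanned: np.ndarray) -> np.ndarray:
    """Independent route: eliminate the constraint by null-space substitution."""
    r, g, b = scanned
    phi = np.vstack([r, g, b, r * g * b, np.ones_like(r)])  # 5 x N
    phi_u = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
    coeffs = np.empty((3, 5))
    # particular solution + null-space basis of the constraint m . phi_u = 1
    m0 = phi_u / (phi_u @ phi_u)
    _, _, vt = np.linalg.svd(phi_u[None, :])
    N = vt[1:].T  # 5 x 4 null-space basis
    for ch in range(3):
        resid = reference[ch] - m0 @ phi
        z, *_ = np.linalg.lstsq((N.T @ phi).T, resid, rcond=None)
        coeffs[ch] = m0 + N @ z
    return coeffs


class TestWPPLS:
    def test_identity_when_scanned_equals_reference(self, chart_reference):
        cmap = fit_wppls(chart_reference, ChartColors(chart_reference.values, role="scanned"))
        out = cmap(chart_reference.values.T).T
        np.testing.assert_allclose(out, chart_reference.values, atol=1e-9)

    def test_white_point_always_preserved(self, chart_reference):
        rng = np.random.default_rng(11)
        for _ in range(10):
            vals = np.clip(
                chart_reference.values + rng.normal(0, 0.05, (3, 13)), 0, 1
            )
            cmap = fit_wppls(chart_reference, ChartColors(vals, role="scanned"))
            np.testing.assert_allclose(cmap(np.ones(3)), 1.0, atol=1e-9)

    def test_recovers_known_mixing_matrix(self, chart_reference):
        A = np.array([[0.9, 0.07, 0.03], [0.05, 0.9, 0.05], [0.02, 0.08, 0.9]])
        scanned = ChartColors(A @ chart_reference.values, role="scanned")
        cmap = fit_wppls(chart_reference, scanned)
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, (50, 3))
        np.testing.assert_allclose(
            cmap((A @ pts.T).T), pts, atol=1e-8
        )

    def test_matches_null_space_constrained_lsq_oracle(self, chart_reference):
        rng = np.random.default_rng(4)
        vals = np.clip(chart_reference.values + rng.normal(0, 0.03, (3, 13)), 0, 1)
        scanned = ChartColors(vals, role="scanned")
        cmap = fit_wppls(chart_reference, scanned)
        oracle = constrained_lsq_oracle(chart_reference.values, vals)
        np.testing.assert_allclose(cmap.coeffs, oracle, atol=1e-8)

    def test_degenerate_chart_rejected(self):
        same = np.tile(np.array([[0.5], [0.5], [0.5]]), (1, 13))
        with pytest.raises(CalibrationError):
            fit_wppls(
                ChartColors(same, role="reference"),
                ChartColors(same, role="scanned"),
            )


class TestApplyColorMap:
    def test_identity_map_and_white_invariance(self):
        cmap = PolynomialColorMap.identity()
        px = np.random.default_rng(0).uniform(0, 1, (5, 5, 3))
        out = apply_color_map(ImagePatch(px, "device_linear"), cmap)
        np.testing.assert_array_equal(out.pixels, px)
        assert out.encoding == "standard_linear"

    def test_matches_per_pixel_loop_oracle(self):
        rng = np.random.default_rng(9)
        coeffs = rng.normal(0, 0.3, (3, 5))
        # force white preservation: adjust constant column
        coeffs[:, 4] = 0.0
        phi_u = np.array([1, 1, 1, 1, 1.0])
        coeffs[:, 4] = np.array([1, 1, 1.0]) - coeffs @ phi_u
        cmap = PolynomialColorMap(coeffs)
        px = rng.uniform(0, 1, (6, 7, 3))
        out = apply_color_map(ImagePatch(px, "device_linear"), cmap).pixels
        for i in range(6):
            for j in range(7):
                r, g, b = px[i, j]
                basis = np.array([r, g, b, r * g * b, 1.0])
                np.testing.assert_allclose(out[i, j], coeffs @ basis, atol=1e-12)

    def test_wrong_encoding_rejected(self):
        with pytest.raises(EncodingError):
            apply_color_map(
                ImagePatch(np.zeros((1, 1, 3)), "device_gamma"),
                PolynomialColorMap.identity(),
            )


class TestDeltaEMap:
    def test_identical_images_zero(self, C):
        px = np.random.default_rng(0).uniform(0.1, 0.9, (8, 8, 3))
        a = ImagePatch(px, "standard_linear")
        de = compute_de_map(a, a, C)
        assert de.mean == 0.0 and de.sd == 0.0
        assert np.all(de.values == 0)

    def test_histogram_has_64_bins(self, C):
        rng = np.random.default_rng(1)
        a = ImagePatch(rng.uniform(0.1, 0.9, (8, 8, 3)), "standard_linear")
        b = ImagePatch(rng.uniform(0.1, 0.9, (8, 8, 3)), "standard_linear")
        de = compute_de_map(a, b, C)
        assert de.histogram.size == 64
        assert de.histogram.sum() == 64  # all 8x8 pixels counted

    def test_uniform_pair_equals_scalar_delta_e(self, C, white):
        from ihccal.colorimetry import LinearRGB, delta_e, linear_rgb_to_lab

        c1, c2 = np.array([0.3, 0.5, 0.2]), np.array([0.25, 0.55, 0.3])
        a = ImagePatch(np.ones((4, 4, 3)) * c1, "standard_linear")
        b = ImagePatch(np.ones((4, 4, 3)) * c2, "standard_linear")
        de = compute_de_map(a, b, C)
        expected = delta_e(
            linear_rgb_to_lab(LinearRGB(*c1), C, white),
            linear_rgb_to_lab(LinearRGB(*c2), C, white),
        )
        np.testing.assert_allclose(de.values, expected, atol=1e-9)

    def test_mask_restricts_summaries(self, C):
        a = ImagePatch(np.full((4, 4, 3), 0.5), "standard_linear")
        px = np.full((4, 4, 3), 0.5)
        px[0] = 0.1  # difference only in the masked-out row
        b = ImagePatch(px, "standard_linear")
        mask = np.ones((4, 4), bool)
        mask[0] = False
        de = compute_de_map(a, b, C, mask=mask)
        assert de.mean == 0.0
        assert de.histogram.sum() == mask.sum()

    def test_shape_mismatch_rejected(self, C):
        a = ImagePatch(np.zeros((4, 4, 3)), "standard_linear")
        b = ImagePatch(np.zeros((5, 4, 3)), "standard_linear")
        with pytest.raises(IhccalError):
            compute_de_map(a, b, C)


class TestEndToEndCalibration:
    def test_identity_scanner_calibrates_to_itself(self, chart_reference, C):
        cfg = scanner_preset("A", gamma=1.0, noise_sd=0.0)
        cfg = type(cfg)(np.eye(3), 1.0, IncidentLight(np.ones(3)), 0.0, 0)
        img, layout = render_color_chart(chart_reference, cfg)
        cal = calibrate_scanner(img, layout, chart_reference, C)
        out = extract_patch_colors(
            ImagePatch(cal.apply(img).pixels, "standard_linear"), layout
        )
        assert mean_patch_delta_e(out, chart_reference, C) < 1e-6

    @pytest.mark.parametrize("gamma", [1.0, 1.8, 2.2])
    def test_preset_scanner_recovery(self, chart_reference, C, gamma):
        cfg = scanner_preset("B", gamma=gamma, noise_sd=0.0)
        img, layout = render_color_chart(chart_reference, cfg)
        cal = calibrate_scanner(img, layout, chart_reference, C)
        assert cal.gamma.gamma == pytest.approx(gamma, abs=0.01)
        out = extract_patch_colors(
            ImagePatch(cal.apply(img).pixels, "standard_linear"), layout
        )
        assert mean_patch_delta_e(out, chart_reference, C) < 0.1
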