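"""Optical density, bead panels, unmixing and intensity transfer."""

import numpy as np
import pytest

from ihccal.errors import CalibrationError, EncodingError, MissingLevelError
from ihccal.scanner_calibration import ImagePatch, IncidentLight
from ihccal.stain_calibration import (
    IntensityTransferMap,
    RUIFROK_DAB,
    RUIFROK_HEMATOXYLIN,
    ThresholdSet,
    build_intensity_transfer,
    calibrate_thresholds_method1,
    compose,
    correct_image_method2,
    estimate_dab_vector,
    make_stain_model,
    measure_bead_panel,
    od_to_rgb,
    rgb_to_od,
    unmix,
)
from ihccal.synthetic import StainBatchConfig, render_calibrator, scanner_preset

UNIT = IncidentLight(np.ones(3))


def identity_scanner(noise_sd=0.0, seed=0):
    from ihccal.synthetic import ScannerSimConfig

    return ScannerSimConfig(np.eye(3), 1.0, UNIT, noise_sd, seed)


class TestOpticalDensity:
    def test_white_pixel_zero_od_and_log_identity(self):
        img = ImagePatch(np.full((1, 2, 3), 1.0), "standard_linear")
        img = ImagePatch(np.stack([np.ones(3), np.full(3, 0.1)])[None], "standard_linear")
        od = rgb_to_od(img, UNIT)
        np.testing.assert_allclose(od[0, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(od[0, 1], 1.0, atol=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        od = rng.uniform(0, 2, (5, 5, 3))
        img = od_to_rgb(od, UNIT)
        np.testing.assert_allclose(rgb_to_od(img, UNIT), od, atol=1e-10)

    def test_wrong_encoding_rejected(self):
        with pytest.raises(EncodingError):
            rgb_to_od(ImagePatch(np.ones((1, 1, 3)), "device_gamma"), UNIT)


class TestBeadPanel:
    def test_render_measure_round_trip_noiseless(self):
        batch = StainBatchConfig()
        img, geometry, truth = render_calibrator(batch, identity_scanner())
        panel = measure_bead_panel(img_std(img), UNIT, bead_layout=geometry)
        np.testing.assert_allclose(panel.mean_od, truth.mean_od, atol=1e-6)
        assert panel.mean_od.shape == (10, 3)

    def test_autodetect_matches_layout_measurement(self):
        batch = StainBatchConfig()
        img, geometry, truth = render_calibrator(batch, identity_scanner())
        # the faintest level's total OD (~0.03) sits below the default
        # detection threshold; lower it to resolve all 10 beads
        auto = measure_bead_panel(img_std(img), UNIT, od_threshold=0.02)
        np.testing.assert_allclose(
            auto.dab_od(batch.dab_vector), truth.dab_od(batch.dab_vector), atol=0.01
        )

    def test_blank_slide_raises_missing_level(self):
        img = ImagePatch(np.ones((64, 64, 3)), "standard_linear")
        with pytest.raises(MissingLevelError):
            measure_bead_panel(img, UNIT)


def img_std(img: ImagePatch) -> ImagePatch:
    """Rendered identity-scanner output is already standard linear; retag."""
    return ImagePatch(img.pixels, "standard_linear")


class TestDabVector:
    def test_collinear_levels_return_direction(self):
        from ihccal.stain_calibration import BeadPanel

        v = RUIFROK_DAB / np.linalg.norm(RUIFROK_DAB)
        ods = np.linspace(0.05, 0.5, 10)[:, None] * v
        panel = BeadPanel(10.0 ** (-ods), ods, np.full(10, 100))
        got = estimate_dab_vector(panel)
        np.testing.assert_allclose(got, v, atol=1e-12)
        assert np.linalg.norm(got) == pytest.approx(1.0)

    def test_noisy_levels_within_two_degrees(self):
        from ihccal.stain_calibration import BeadPanel

        rng = np.random.default_rng(1)
        v = RUIFROK_DAB / np.linalg.norm(RUIFROK_DAB)
        ods = np.linspace(0.05, 0.5, 10)[:, None] * v + rng.normal(0, 0.005, (10, 3))
        ods = np.abs(ods)
        panel = BeadPanel(10.0 ** (-ods), ods, np.full(10, 100))
        angle = np.degrees(np.arccos(np.clip(estimate_dab_vector(panel) @ v, -1, 1)))
        assert angle < 2.0

    def test_all_dark_levels_rejected(self):
        from ihccal.stain_calibration import BeadPanel

        v = RUIFROK_DAB / np.linalg.norm(RUIFROK_DAB)
        ods = np.linspace(0.8, 2.0, 10)[:, None] * v
        panel = BeadPanel(10.0 ** (-ods), ods, np.full(10, 100))
        with pytest.raises(CalibrationError):
            estimate_dab_vector(panel)


class TestUnmix:
    def test_pure_and_mixed_pixels(self):
        model = make_stain_model(RUIFROK_DAB)
        od = 0.4 * model.dab_vector
        dab, hem = unmix(od[None, None], model)
        assert dab[0, 0] == pytest.approx(0.4, abs=1e-10)
        assert hem[0, 0] == pytest.approx(0.0, abs=1e-10)
        mix = compose(np.array([[0.3]]), np.array([[0.2]]), model)
        dab, hem = unmix(mix, model)
        assert dab[0, 0] == pytest.approx(0.3, abs=1e-10)
        assert hem[0, 0] == pytest.approx(0.2, abs=1e-10)

    def test_zero_od_gives_zero_concentrations(self):
        model = make_stain_model(RUIFROK_DAB)
        dab, hem = unmix(np.zeros((2, 2, 3)), model)
        assert np.all(dab == 0) and np.all(hem == 0)

    def test_compose_unmix_closure_random_images(self):
        model = make_stain_model(RUIFROK_DAB)
        rng = np.random.default_rng(2)
        dab = rng.uniform(0, 1.5, (16, 16))
        hem = rng.uniform(0, 1.0, (16, 16))
        got_dab, got_hem = unmix(compose(dab, hem, model), model)
        np.testing.assert_allclose(got_dab, dab, atol=1e-10)
        np.testing.assert_allclose(got_hem, hem, atol=1e-10)

    def test_collinear_stains_rejected(self):
        with pytest.raises(CalibrationError):
            make_stain_model(RUIFROK_HEMATOXYLIN, RUIFROK_HEMATOXYLIN)


def make_panels(scale: float):
    from ihccal.stain_calibration import BeadPanel

    v = RUIFROK_DAB / np.linalg.norm(RUIFROK_DAB)
    ref_ods = np.geomspace(0.02, 1.2, 10)[:, None] * v
    tgt_ods = scale * ref_ods
    ref = BeadPanel(10.0 ** (-ref_ods), ref_ods, np.full(10, 100))
    tgt = BeadPanel(10.0 ** (-tgt_ods), tgt_ods, np.full(10, 100))
    return tgt, ref


class TestIntensityTransfer:
    def test_identity_panels_give_identity_map(self):
        tgt, ref = make_panels(1.0)
        model = make_stain_model(RUIFROK_DAB)
        tm = build_intensity_transfer(ref, ref, model, model)
        xs = np.linspace(0, 1.2, 50)
        np.testing.assert_allclose(tm(xs), xs, atol=1e-9)
        assert tm(0.0) == 0.0

    def test_scaled_panel_recovers_inverse_scale(self):
        tgt, ref = make_panels(0.7)
        model = make_stain_model(RUIFROK_DAB)
        tm = build_intensity_transfer(tgt, ref, model, model)
        xs = np.linspace(0.0, 0.7 * 1.2, 40)
        np.testing.assert_allclose(tm(xs), xs / 0.7, atol=1e-9)

    def test_monotone_and_anchored(self):
        tgt, ref = make_panels(1.3)
        model = make_stain_model(RUIFROK_DAB)
        tm = build_intensity_transfer(tgt, ref, model, model)
        xs = np.linspace(0, 2.0, 100)
        assert np.all(np.diff(tm(xs)) >= 0)
        assert tm(0.0) == 0.0


class TestMethod1:
    def test_identity_transfer_keeps_thresholds(self):
        thr = ThresholdSet(0.05, 0.15, 0.29)
        out = calibrate_thresholds_method1(thr, IntensityTransferMap.identity())
        assert out.as_tuple() == pytest.approx(thr.as_tuple())

    def test_doubling_transfer_halves_thresholds(self):
        tm = IntensityTransferMap(np.array([0.0, 1.0]), np.array([0.0, 2.0]))
        out = calibrate_thresholds_method1(ThresholdSet(0.05, 0.15, 0.29), tm)
        assert out.as_tuple() == pytest.approx((0.025, 0.075, 0.145))

    def test_piecewise_inverse_forward_check(self):
        x = np.array([0.0, 0.1, 0.3, 0.6, 1.0])
        y = np.array([0.0, 0.15, 0.35, 0.8, 1.1])
        tm = IntensityTransferMap(x, y)
        thr = ThresholdSet(0.05, 0.29, 0.9)
        out = calibrate_thresholds_method1(thr, tm)
        for t_target, t_ref in zip(out.as_tuple(), thr.as_tuple()):
            assert tm(t_target) == pytest.approx(t_ref, abs=1e-9)

    def test_flat_segment_midpoint_with_warning(self):
        tm = IntensityTransferMap(
            np.array([0.0, 0.1, 0.2, 0.4]), np.array([0.0, 0.15, 0.15, 0.5])
        )
        with pytest.warns(UserWarning):
            got = tm.inverse(0.15)
        assert got == pytest.approx(0.15)  # midpoint of the flat run [0.1, 0.2]


class TestMethod2:
    def test_identity_transfer_same_model_is_noop(self):
        model = make_stain_model(RUIFROK_DAB)
        rng = np.random.default_rng(3)
        dab = rng.uniform(0, 0.6, (8, 8))
        hem = rng.uniform(0, 0.5, (8, 8))
        img = od_to_rgb(compose(dab, hem, model), UNIT)
        out = correct_image_method2(
            img, IntensityTransferMap.identity(), model, model, UNIT
        )
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-9)

    def test_pure_dab_doubles_under_doubling_transfer(self):
        model = make_stain_model(RUIFROK_DAB)
        dab = np.full((4, 4), 0.2)
        img = od_to_rgb(compose(dab, np.zeros((4, 4)), model), UNIT)
        tm = IntensityTransferMap(np.array([0.0, 1.0]), np.array([0.0, 2.0]))
        out = correct_image_method2(img, tm, model, model, UNIT)
        got_dab, _ = unmix(rgb_to_od(out, UNIT), model)
        np.testing.assert_allclose(got_dab, 0.4, atol=1e-9)

    def test_hematoxylin_untouched_by_dab_transfer(self):
        model = make_stain_model(RUIFROK_DAB)
        hem = np.full((4, 4), 0.5)
        img = od_to_rgb(compose(np.zeros((4, 4)), hem, model), UNIT)
        tm = IntensityTransferMap(np.array([0.0, 1.0]), np.array([0.0, 3.0]))
        out = correct_image_method2(img, tm, model, model, UNIT)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-9)

    def test_corrected_bead_ods_match_reference_scale(self):
        # transfer-map recovery invariant on rendered calibrators
        model = make_stain_model(RUIFROK_DAB)
        for scale in (0.5, 1.5):
            batch = StainBatchConfig(dab_scale=scale)
            img, geometry, _ = render_calibrator(batch, identity_scanner())
            ref_img, _, ref_truth = render_calibrator(
                StainBatchConfig(dab_scale=1.0), identity_scanner()
            )
            panel_t = measure_bead_panel(img_std(img), UNIT, bead_layout=geometry)
            panel_r = measure_bead_panel(img_std(ref_img), UNIT, bead_layout=geometry)
            tm = build_intensity_transfer(panel_t, panel_r, model, model)
            corrected = tm(panel_t.dab_od(model.dab_vector))
            ref_ods = panel_r.dab_od(model.dab_vector)
            dyn = ref_ods.max() - ref_ods.min()
            assert np.max(np.abs(corrected - ref_ods)) < 0.01 * dyn
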