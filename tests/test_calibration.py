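"""Calibration chain: baseline, bleach, power, smoothing, masking, AUC."""

import numpy as np
import pytest

import filmspec as fs
from filmspec.calibration import (
    CalibrationConfig,
    calibrate,
    correct_baseline,
    correct_photobleach,
    exclude_band,
    masked_auc,
    normalize_auc,
    normalize_power,
    smooth_spectrum,
)
from filmspec.datatypes import Spectrum, extract_spectrum
from filmspec.errors import ConfigError, NormalizationError
from filmspec.synthetic import AcquisitionSpec, ir_power_profile, photobleach_curve, render_stack


def _spectrum(values, axis=None):
    values = np.asarray(values, dtype=float)
    axis = axis or fs.make_axis(1000, 1000 + 10 * (values.size - 1), values.size)
    return Spectrum(values, axis)


class TestBaseline:
    def test_ir_off_constant_subtraction(self):
        signal = np.linspace(0, 1, 10)
        spec = _spectrum(signal + 5.0)
        config = CalibrationConfig(baseline_mode="ir_off_frames", ir_off_frames=(0,))
        out = correct_baseline(spec.with_intensities(np.r_[5.0, signal[1:] + 5.0]), config)
        np.testing.assert_allclose(out.intensities[1:], signal[1:])
        assert out.mask[0]  # IR-off frame masked afterwards

    def test_all_zero_stays_zero(self):
        config = CalibrationConfig(baseline_mode="ir_off_frames", ir_off_frames=(0, 1))
        out = correct_baseline(_spectrum(np.zeros(8)), config)
        np.testing.assert_array_equal(out.intensities, 0.0)

    def test_power_dip_proxy_recovers_injected_offset(self, axis64, refs64):
        # deep dip -> lowest-power frames carry almost pure baseline
        power = ir_power_profile(axis64, dip_depth=0.98, dip_fwhm=40)
        scene = fs.synthetic.random_scene(shape=(32, 32), n_organelles=4, seed=2)
        offset = 0.05
        acq = AcquisitionSpec(axis=axis64, ir_power=power, baseline_offset=offset, seed=0)
        stack, truth = render_stack(scene, refs64, acq)
        spec = extract_spectrum(stack, truth.masks > 0)
        config = CalibrationConfig(baseline_mode="power_dip_proxy", ir_power=power)
        bins = np.argsort(power)[:3]
        estimated = spec.intensities[bins].mean()
        assert estimated == pytest.approx(offset, rel=0.02)
        out = correct_baseline(spec, config)
        assert out.intensities[bins].mean() == pytest.approx(0.0, abs=offset * 0.02)

    def test_missing_baseline_bins_config_error(self):
        with pytest.raises(ConfigError):
            correct_baseline(_spectrum(np.ones(5)), CalibrationConfig(baseline_mode="ir_off_frames"))


class TestBleachAndPower:
    def test_identity_curves(self):
        spec = _spectrum(np.arange(1.0, 6.0))
        np.testing.assert_array_equal(
            correct_photobleach(spec, np.ones(5)).intensities, spec.intensities
        )
        np.testing.assert_array_equal(
            normalize_power(spec, np.ones(5)).intensities, spec.intensities
        )

    def test_bleach_division_recovers_clean_spectrum(self, noiseless_scene, axis64):
        _, acq, stack, truth = noiseless_scene
        mask = truth.masks == 1
        raw = extract_spectrum(stack, mask)
        corrected = correct_photobleach(
            raw.with_intensities(raw.intensities - acq.baseline_offset),
            photobleach_curve(axis64.n_frames, acq.bleach_rate),
        )
        bleach_free = extract_spectrum(truth.noiseless_stack, mask).intensities
        bleach_free = (bleach_free - acq.baseline_offset) / photobleach_curve(
            axis64.n_frames, acq.bleach_rate
        )
        np.testing.assert_allclose(corrected.intensities, bleach_free, rtol=1e-6)

    def test_zero_multiplier_division_error(self):
        spec = _spectrum(np.ones(4))
        with pytest.raises(ZeroDivisionError):
            correct_photobleach(spec, np.array([1.0, 0.0, 1.0, 1.0]))
        with pytest.raises(ZeroDivisionError):
            normalize_power(spec, np.array([1.0, -1.0, 1.0, 1.0]))

    def test_pure_power_artifact_flattens(self):
        power = np.linspace(0.5, 1.5, 6)
        spec = _spectrum(power)
        np.testing.assert_allclose(normalize_power(spec, power).intensities, 1.0)

    def test_dip_artifact_removed_for_flat_sigma(self, axis64, refs64):
        # uniform-composition scene: sigma is spatially flat, so after power
        # division the spectrum must be proportional to sigma within 1e-6
        power = ir_power_profile(axis64, dip_depth=0.4)
        comp = np.full(8, 1 / 8)
        scene = fs.SceneSpec(
            shape=(16, 16),
            organelles=(fs.OrganelleSpec((8.0, 8.0), 4.0, comp, 1.0),),
            background_dye=0.0,
            feather_px=0.0,
        )
        acq = AcquisitionSpec(axis=axis64, ir_power=power)
        stack, truth = render_stack(scene, refs64, acq)
        spec = extract_spectrum(stack, truth.masks == 1)
        corrected = normalize_power(spec, power)
        sigma = comp @ refs64.spectra
        ratio = corrected.intensities / sigma
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-6)


class TestSmoothing:
    def test_constant_unchanged(self):
        spec = _spectrum(np.full(7, 3.3))
        np.testing.assert_allclose(smooth_spectrum(spec, 3).intensities, 3.3)

    def test_impulse_moving_average(self):
        spec = _spectrum([0, 0, 1, 0, 0])
        np.testing.assert_allclose(
            smooth_spectrum(spec, 3).intensities, [0, 1 / 3, 1 / 3, 1 / 3, 0]
        )

    def test_even_window_rejected(self):
        with pytest.raises(ConfigError):
            smooth_spectrum(_spectrum(np.ones(5)), 4)

    def test_masked_bins_excluded_from_averages(self):
        spec = _spectrum([1, 1, 100, 1, 1]).with_mask([False, False, True, False, False])
        out = smooth_spectrum(spec, 3)
        np.testing.assert_allclose(out.intensities[[0, 1, 3, 4]], 1.0)
        assert out.intensities[2] == 100  # masked value retained

    def test_total_variation_contracts(self, rng):
        values = rng.uniform(0, 1, 41)
        spec = _spectrum(values)
        for window in (3, 5):
            smoothed = smooth_spectrum(spec, window).intensities
            tv = np.abs(np.diff(smoothed)).sum()
            assert tv <= np.abs(np.diff(values)).sum() + 1e-12


class TestExclusionAndAuc:
    def test_band_masking(self):
        axis = fs.make_axis(1000, 1800, 126)
        spec = Spectrum(np.ones(126), axis)
        out = exclude_band(spec, 1380, 1480)
        masked_wn = axis.values[out.mask]
        assert masked_wn.size > 0
        assert masked_wn.min() >= 1380 and masked_wn.max() <= 1480
        in_band = (axis.values >= 1380) & (axis.values <= 1480)
        np.testing.assert_array_equal(out.mask, in_band)

    def test_out_of_span_band_warns_no_op(self):
        spec = _spectrum(np.ones(10))
        with pytest.warns(UserWarning, match="no bins"):
            out = exclude_band(spec, 100, 200)
        assert not out.mask.any()

    def test_full_band_masks_everything_and_auc_fails(self):
        axis = fs.make_axis(1000, 1800, 20)
        out = exclude_band(Spectrum(np.ones(20), axis), 1000, 1800)
        assert out.mask.all()
        with pytest.raises(NormalizationError):
            normalize_auc(out)

    def test_auc_normalization_and_idempotence(self, rng):
        spec = _spectrum(rng.uniform(0.1, 1.0, 30))
        out = normalize_auc(spec)
        assert masked_auc(out) == pytest.approx(1.0, abs=1e-12)
        again = normalize_auc(out)
        np.testing.assert_allclose(again.intensities, out.intensities, atol=1e-12)

    def test_zero_spectrum_normalization_error(self):
        with pytest.raises(NormalizationError):
            normalize_auc(_spectrum(np.zeros(6)))


class TestFullChain:
    def test_noiseless_recovery_within_1e6(
        self, noiseless_scene, noiseless_calibration_config, refs64, axis64
    ):
        """End-to-end oracle: calibrate(render(scene)) equals the
        AUC-normalized absorption spectrum of each organelle."""
        scene, acq, stack, truth = noiseless_scene
        for i, org in enumerate(scene.organelles, start=1):
            mask = truth.masks == i
            cal = calibrate(extract_spectrum(stack, mask), noiseless_calibration_config)
            sigma = org.composition @ refs64.spectra
            expected = normalize_auc(Spectrum(sigma, axis64, cal.mask))
            keep = ~cal.mask
            np.testing.assert_allclose(
                cal.intensities[keep], expected.intensities[keep], atol=1e-6
            )
        assert [s["step"] for s in cal.provenance] == [
            "baseline", "photobleach", "power", "exclude", "normalize",
        ]

    def test_stack_calibration_matches_per_spectrum(
        self, noiseless_scene, noiseless_calibration_config
    ):
        _, _, stack, truth = noiseless_scene
        cal_stack = calibrate(stack, noiseless_calibration_config)
        mask1 = truth.masks == 1
        from_stack = np.nanmean(cal_stack.data[mask1], axis=0)
        per_spec = calibrate(extract_spectrum(stack, mask1), noiseless_calibration_config)
        keep = ~np.asarray(cal_stack.meta["excluded_frames"], dtype=bool)
        # stack path normalizes per pixel, spectrum path after averaging;
        # for a hard-disk organelle (uniform spectrum) both agree
        np.testing.assert_allclose(
            from_stack[keep], per_spec.intensities[keep], rtol=1e-5, atol=1e-12
        )

    def test_order_sensitivity_of_baseline_and_power(self, axis64):
        power = ir_power_profile(axis64, dip_depth=0.5)
        rng = np.random.default_rng(4)
        raw = Spectrum(rng.uniform(1.0, 2.0, 64) + 0.5, axis64)
        config = CalibrationConfig(
            ir_power=power, baseline_mode="power_dip_proxy", dip_window=3,
            smooth_window=1, exclude_bands=(), normalize="none",
        )
        chained = calibrate(raw, config)
        swapped = correct_baseline(normalize_power(raw, power), config)
        assert not np.allclose(chained.intensities, swapped.intensities)

    def test_fit_exponential_without_trace_is_config_error(self, axis64):
        config = CalibrationConfig(bleach_curve="fit-exponential", smooth_window=1)
        with pytest.raises(ConfigError):
            calibrate(Spectrum(np.ones(64), axis64), config)

    def test_fitted_bleach_matches_true_curve(self, axis64):
        curve = fs.synthetic.photobleach_curve(64, 0.02)
        config = CalibrationConfig(
            bleach_curve="fit-exponential", dc_trace=5.0 * curve,
            smooth_window=1, exclude_bands=(), normalize="none",
        )
        out = calibrate(Spectrum(curve.copy(), axis64), config)
        np.testing.assert_allclose(out.intensities, 1.0, rtol=1e-9)

    def test_smooth_window_one_disables_smoothing(self, rng, axis64):
        spec = Spectrum(rng.uniform(1, 2, 64), axis64)
        config = CalibrationConfig(smooth_window=1, exclude_bands=(), normalize="none")
        np.testing.assert_array_equal(calibrate(spec, config).intensities, spec.intensities)
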