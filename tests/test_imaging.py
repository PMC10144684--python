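"""ADC fitting, SER computation, and the diffusion forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coclin import (
    DiffusionSeries,
    DynamicSeries,
    InvalidInputError,
    ROIMask,
    compute_ser_map,
    fit_adc_map,
    predict_diffusion_signal,
)

B_PRECLINICAL = np.array([0.0, 150.0, 700.0])
B_CLINICAL = np.array([0.0, 100.0, 600.0, 800.0])


def _dwi(signal_rows, b):
    """Stack per-voxel signal rows into a 1-D-in-space series."""
    arr = np.asarray(signal_rows, dtype=float)
    return DiffusionSeries(arr.reshape(-1, 1, 1, len(b)), b, [1.0, 1.0, 1.0])


class TestForwardModel:
    def test_zero_decay(self):
        np.testing.assert_allclose(
            predict_diffusion_signal(1000, 0.0, [0, 150, 700]), [1000, 1000, 1000]
        )

    def test_b_zero_returns_s0(self):
        np.testing.assert_allclose(predict_diffusion_signal(1000, 1e-3, [0]), [1000])

    def test_scalar_exponential(self):
        np.testing.assert_allclose(
            predict_diffusion_signal(1000, 1e-3, [700]),
            [1000 * np.exp(-0.7)],
            rtol=1e-12,
        )

    @pytest.mark.parametrize("s0,adc", [(0.0, 1e-3), (-5.0, 1e-3), (100.0, -1e-4)])
    def test_rejects_invalid_parameters(self, s0, adc):
        with pytest.raises(InvalidInputError):
            predict_diffusion_signal(s0, adc, [0, 100])


class TestAdcFit:
    @pytest.mark.parametrize("b", [B_PRECLINICAL, B_CLINICAL], ids=["preclin", "clin"])
    @pytest.mark.parametrize("adc", [0.0, 2e-4, 1.0e-3, 3.0e-3])
    def test_noiseless_recovery(self, b, adc):
        series = _dwi([predict_diffusion_signal(1000, adc, b)], b)
        fitted = fit_adc_map(series).values.ravel()[0]
        if adc == 0:
            assert abs(fitted) < 1e-12
        else:
            assert abs(fitted - adc) / adc < 1e-9

    def test_constant_signal_gives_zero_adc(self):
        series = _dwi([[250.0] * 3], B_PRECLINICAL)
        assert fit_adc_map(series).values.ravel()[0] == pytest.approx(0.0, abs=1e-15)

    def test_nonpositive_signal_masks_voxel(self):
        series = _dwi([[1000.0, 0.0, 100.0], [1000.0, 500.0, -3.0]], B_PRECLINICAL)
        assert np.all(np.isnan(fit_adc_map(series).values.ravel()))

    def test_requires_two_distinct_b_values(self):
        single = DiffusionSeries(np.ones((1, 1, 1, 1)), [0.0], [1, 1, 1])
        with pytest.raises(InvalidInputError):
            fit_adc_map(single)
        series = _dwi([[1000.0, 500.0]], np.array([0.0, 500.0]))
        series.b_values = np.array([100.0, 100.0])  # bypass ctor to hit the fit check
        with pytest.raises(InvalidInputError):
            fit_adc_map(series)

    def test_mask_shape_mismatch_rejected(self):
        series = _dwi([[1000, 800, 500]], B_PRECLINICAL)
        mask = ROIMask(np.ones((2, 2, 2), bool), [1, 1, 1])
        with pytest.raises(InvalidInputError):
            fit_adc_map(series, mask)

    def test_mask_nan_pattern_and_geometry_preserved(self):
        rng = np.random.default_rng(0)
        vox = rng.uniform(500, 1000, size=(4, 3, 2, 3))
        series = DiffusionSeries(vox, B_PRECLINICAL, [0.5, 0.5, 2.0])
        mask = ROIMask(rng.random((4, 3, 2)) > 0.5, [0.5, 0.5, 2.0])
        out = fit_adc_map(series, mask)
        assert out.values.shape == (4, 3, 2)
        np.testing.assert_array_equal(out.voxel_spacing, [0.5, 0.5, 2.0])
        assert np.all(np.isnan(out.values[~mask.mask]))
        assert np.all(np.isfinite(out.values[mask.mask]))
        assert np.all(out.values[mask.mask] >= 0)

    def test_matches_scipy_bounded_least_squares_on_noisy_voxels(self):
        from scipy.optimize import least_squares

        rng = np.random.default_rng(7)
        b = B_CLINICAL
        clean = predict_diffusion_signal(1000, 1.2e-3, b)
        noisy = clean[None, :] + rng.normal(0, 20, size=(30, len(b)))
        noisy = np.clip(noisy, 1.0, None)
        ours = fit_adc_map(_dwi(noisy, b)).values.ravel()
        for row, fitted in zip(noisy, ours):
            ref = least_squares(
                lambda p: p[0] * np.exp(-p[1] * b) - row,
                x0=[row[0], 1e-3],
                bounds=([1e-9, 0.0], [1e9, 1e-2]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            ).x[1]
            assert fitted == pytest.approx(ref, abs=5e-9)

    def test_noise_recovery_snr50(self):
        rng = np.random.default_rng(99)
        b = B_PRECLINICAL
        true_adc = 1.0e-3
        clean = predict_diffusion_signal(1000, true_adc, b)
        noisy = clean[None, :] + rng.normal(0, 1000 / 50, size=(500, len(b)))
        fitted = fit_adc_map(_dwi(noisy, b)).values.ravel()
        rel = np.abs(fitted - true_adc) / true_adc
        assert np.nanmedian(rel) < 0.05


def _dce(curve_rows, times=None):
    arr = np.asarray(curve_rows, dtype=float)
    if times is None:
        times = 30.0 * np.arange(arr.shape[-1])
    return DynamicSeries(arr.reshape(-1, 1, 1, arr.shape[-1]), times, [1, 1, 1])


def _standard_curve(baseline=100.0, peak=300.0, late=200.0, n=25):
    """10 baseline frames, rise, peak at frame 11, linear washout to `late` at +360 s."""
    times = 30.0 * np.arange(n)
    curve = np.full(n, baseline)
    curve[10] = baseline + 0.6 * (peak - baseline)
    post = times >= times[11]
    curve[post] = peak + (late - peak) * (times[post] - times[11]) / 360.0
    return curve


class TestSer:
    def test_worked_example(self):
        # baseline 100, peak 300, 200 at the frame 6 min post-peak -> SER 2.0
        ser = compute_ser_map(_dce([_standard_curve()])).values.ravel()[0]
        assert ser == pytest.approx(2.0, rel=1e-12)

    def test_plateau_gives_unity(self):
        ser = compute_ser_map(_dce([_standard_curve(late=300.0)])).values.ravel()[0]
        assert ser == pytest.approx(1.0, rel=1e-12)

    def test_never_enhancing_voxel_is_nan(self):
        ser = compute_ser_map(_dce([np.full(25, 100.0)])).values.ravel()[0]
        assert np.isnan(ser)

    def test_too_few_frames_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_ser_map(_dce([np.full(10, 100.0)]))

    def test_nonpositive_late_offset_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_ser_map(_dce([_standard_curve()]), late_offset=0.0)

    def test_peak_tie_breaks_to_earliest_frame(self):
        # two equal maxima; washout measured from the first one
        curve = _standard_curve()
        curve[12] = curve[11]
        ser = compute_ser_map(_dce([curve])).values.ravel()[0]
        # late frame still the one nearest t(11) + 360
        expected = (curve[11] - 100.0) / (curve[23] - 100.0)
        assert ser == pytest.approx(expected, rel=1e-12)

    def test_late_frame_clamped_and_flagged(self):
        curve = _standard_curve(n=25)
        # truncate so peak + 360 s exceeds the acquisition
        short = curve[:15]
        out = compute_ser_map(_dce([short]))
        assert out.quality.ravel()[0]
        expected = (short[11] - 100.0) / (short[14] - 100.0)
        assert out.values.ravel()[0] == pytest.approx(expected, rel=1e-12)

    def test_roi_peak_mode_matches_voxel_mode_on_uniform_tumor(self):
        curve = _standard_curve()
        vox = np.tile(curve, (2, 2, 1, 1))
        series = DynamicSeries(vox, 30.0 * np.arange(25), [1, 1, 1])
        mask = ROIMask(np.ones((2, 2, 1), bool), [1, 1, 1])
        a = compute_ser_map(series, mask, peak_mode="voxel").values
        b = compute_ser_map(series, mask, peak_mode="roi").values
        np.testing.assert_allclose(a, b)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 50.0),
        offset=st.floats(-50.0, 200.0),
    )
    def test_affine_rescale_invariance(self, scale, offset):
        """SER is unchanged under S -> a*S + c with a > 0."""
        curve = _standard_curve()
        base = compute_ser_map(_dce([curve])).values.ravel()[0]
        rescaled = compute_ser_map(_dce([scale * curve + offset])).values.ravel()[0]
        assert rescaled == pytest.approx(base, rel=1e-9)
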