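"""Background subtraction, k-resampling and phase-domain corrected FFT."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aooct import (
    CorrectionParams,
    SpectralVolume,
    correction_phase,
    phase_matrix,
    reconstruct_volume,
    resample_to_k,
    simulate_spectra,
    subtract_background,
)
from aooct.reconstruction import PipelineStateError

from .conftest import (
    amplitude_fwhm_px,
    reconstruct_chain,
    single_layer_phantom,
    small_config,
)


def crossing_fwhm(profile: np.ndarray) -> float:
    """FWHM in samples from linear interpolation of the half-max crossings."""
    i = int(np.argmax(profile))
    half = profile[i] / 2.0
    lo = i
    while lo > 0 and profile[lo] > half:
        lo -= 1
    hi = i
    while hi < len(profile) - 1 and profile[hi] > half:
        hi += 1
    left = lo + (half - profile[lo]) / (profile[lo + 1] - profile[lo])
    right = hi - 1 + (profile[hi - 1] - half) / (profile[hi - 1] - profile[hi])
    return right - left


class TestSubtractBackground:
    def test_identical_alines_cancel_completely(self):
        cfg = small_config(n_fast=8)
        fr = np.tile(np.sin(np.linspace(0, 20, cfg.n_spectral_px)), (2, 8, 1))
        out = subtract_background(SpectralVolume(fr, cfg))
        assert np.allclose(out.fringes, 0.0)

    def test_analytically_zero_mean_fringes_unchanged(self):
        cfg = small_config(n_fast=16)
        x = np.arange(16)[None, :, None]
        j = np.arange(cfg.n_spectral_px)[None, None, :]
        fr = np.cos(2 * np.pi * 3 * x / 16 + 0.1 * j) * np.ones((2, 1, 1))
        out = subtract_background(SpectralVolume(fr, cfg))
        assert np.max(np.abs(out.fringes - fr)) < 1e-9 * np.max(np.abs(fr))

    def test_zero_delay_peak_suppressed_at_least_30_db(self):
        cfg = small_config()
        ph = single_layer_phantom(cfg, 150.0, tilt_slope_um_per_col=0.05)
        vol = simulate_spectra(ph, cfg, noise_sd=0.0, seed=0, dc_level=1.0)
        sub = subtract_background(vol)
        # the z=0 bin of the transform is the plain spectral sum
        raw_dc = np.abs(vol.fringes.sum(axis=-1)).mean()
        sub_dc = np.abs(sub.fringes.sum(axis=-1)).mean()
        assert 20 * np.log10(raw_dc / sub_dc) >= 30.0

    def test_mean_spectrum_is_removed(self):
        cfg = small_config(n_fast=32)
        rng = np.random.default_rng(0)
        fr = rng.normal(1.0, 0.5, (cfg.n_slow, 32, cfg.n_spectral_px))
        for scope in ("per_bscan", "per_volume"):
            out = subtract_background(SpectralVolume(fr, cfg), scope)
            axes = 1 if scope == "per_bscan" else (0, 1)
            assert np.max(np.abs(out.fringes.mean(axis=axes))) < 1e-9

    def test_unknown_scope_rejected(self):
        cfg = small_config(n_fast=4)
        vol = SpectralVolume(np.ones((2, 4, cfg.n_spectral_px)), cfg)
        with pytest.raises(ValueError):
            subtract_background(vol, "per_aline")


class TestResampleToK:
    def test_uniform_wavenumber_input_passes_through(self, cfg_k):
        fr = np.random.default_rng(1).normal(size=(2, cfg_k.n_fast, cfg_k.n_spectral_px))
        vol = SpectralVolume(fr, cfg_k)
        out = resample_to_k(vol)
        np.testing.assert_array_equal(out.fringes, fr)
        assert any("identity" in p for p in out.provenance)

    def test_resampling_restores_transform_limited_peak_at_deep_depth(self, cfg_wl):
        # uniform-wavelength sampling chirps deep fringes; at 3/4 of the
        # depth range the unresampled peak is badly broadened
        depth = 0.75 * cfg_wl.depth_range_um
        ph = single_layer_phantom(cfg_wl, depth, tilt_slope_um_per_col=0.02)
        vol = simulate_spectra(ph, cfg_wl, noise_sd=0.0, seed=0, dc_level=0.0)
        sub = subtract_background(vol)
        resampled = resample_to_k(sub)
        rec = reconstruct_volume(resampled, CorrectionParams())
        fwhm = crossing_fwhm(np.abs(rec.data[0, 32])) * rec.axial_pitch_um
        assert fwhm == pytest.approx(6.23, rel=0.10)

        # oracle for the broken path: same FFT without the k-resampling
        n = cfg_wl.n_spectral_px
        raw = np.abs(np.fft.fft(sub.fringes[0, 32], n=2 * n))[:n]
        raw_fwhm = crossing_fwhm(raw) * rec.axial_pitch_um
        assert raw_fwhm >= 2.0 * fwhm

    def test_linear_and_cubic_agree_on_peak_position(self, cfg_wl):
        ph = single_layer_phantom(cfg_wl, 150.0, tilt_slope_um_per_col=0.02)
        vol = subtract_background(simulate_spectra(ph, cfg_wl, noise_sd=0.0, seed=0))
        peaks = []
        for method in ("linear", "cubic_spline"):
            rec = reconstruct_volume(resample_to_k(vol, method), CorrectionParams())
            a = np.abs(rec.data[0, 32])
            i = a.argmax()
            # parabolic sub-pixel peak position
            num = 0.5 * (a[i - 1] - a[i + 1])
            den = a[i - 1] - 2 * a[i] + a[i + 1]
            peaks.append(i + num / den)
        assert abs(peaks[0] - peaks[1]) < 0.1


class TestCorrectionPhase:
    def test_all_zero_coefficients_give_zero_phase(self):
        p = CorrectionParams()
        phi = phase_matrix(p, n_fast=16, n_k=64)
        assert np.all(phi == 0.0)

    def test_curvature_is_even_about_center(self):
        p = CorrectionParams(curvature_coeff=0.3, fast_axis_center=10.0)
        for d in (1.0, 3.5, 7.0):
            assert p.delta_z(10.0 + d, 0) == pytest.approx(p.delta_z(10.0 - d, 0))

    def test_integer_ramp_equals_circular_shift(self, cfg_k):
        ph = single_layer_phantom(cfg_k, 150.0, tilt_slope_um_per_col=0.05)
        vol = simulate_spectra(ph, cfg_k, noise_sd=0.0, seed=0)
        spec = vol.fringes[0]
        n = cfg_k.n_spectral_px
        p = CorrectionParams(rotation_slope=1.0, fast_axis_center=0.0)
        a0 = np.fft.fft(spec, n=2 * n, axis=-1)
        a1 = np.fft.fft(spec * np.exp(1j * phase_matrix(p, cfg_k.n_fast, n)), n=2 * n, axis=-1)
        for col, shift in [(3, 3), (10, 10)]:
            np.testing.assert_allclose(
                a1[col], np.roll(a0[col], shift), rtol=0, atol=1e-10 * np.abs(a0[col]).max()
            )

    def test_half_pixel_ramp_matches_bandlimited_interpolation(self):
        # Dirichlet (sinc) interpolation oracle via direct DFT evaluation
        n = 128
        rng = np.random.default_rng(2)
        spec = rng.normal(size=n) + 1j * rng.normal(size=n)
        dz = 0.5
        j = np.arange(n)
        ramp = np.exp(2j * np.pi * j * dz / (2 * n))
        shifted = np.fft.fft(spec * ramp, n=2 * n)
        m = np.arange(2 * n)
        oracle = (spec[None, :] * np.exp(-2j * np.pi * np.outer(m - dz, j) / (2 * n))).sum(axis=1)
        assert np.max(np.abs(shifted - oracle)) < 1e-6 * np.max(np.abs(oracle))

    def test_phase_multiplication_conserves_energy(self, cfg_k):
        ph = single_layer_phantom(cfg_k, 150.0, tilt_slope_um_per_col=0.05)
        vol = simulate_spectra(ph, cfg_k, noise_sd=0.1, seed=0)
        p = CorrectionParams(dispersion_a2=5.0, rotation_slope=0.02, curvature_coeff=1e-4)
        carrier = np.exp(1j * phase_matrix(p, cfg_k.n_fast, cfg_k.n_spectral_px))
        before = np.sum(np.abs(vol.fringes[0]) ** 2)
        after = np.sum(np.abs(vol.fringes[0] * carrier) ** 2)
        assert after / before == pytest.approx(1.0, abs=1e-10)

    def test_opposite_ramps_cancel(self, cfg_k):
        rng = np.random.default_rng(3)
        spec = rng.normal(size=(cfg_k.n_fast, cfg_k.n_spectral_px))
        plus = CorrectionParams(rotation_slope=0.7, fast_axis_center=5.0)
        minus = CorrectionParams(rotation_slope=-0.7, fast_axis_center=5.0)
        n = cfg_k.n_spectral_px
        out = (
            spec
            * np.exp(1j * phase_matrix(plus, cfg_k.n_fast, n))
            * np.exp(1j * phase_matrix(minus, cfg_k.n_fast, n))
        )
        assert np.max(np.abs(out - spec)) < 1e-9 * np.max(np.abs(spec))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(shift=st.integers(-20, 20), col=st.integers(0, 31))
    def test_integer_shift_property(self, shift, col):
        # phase ramps with integer dz reproduce circular shifts for any column
        n = 64
        rng = np.random.default_rng(42)
        spec = rng.normal(size=(32, n))
        p = CorrectionParams(rotation_slope=float(shift), fast_axis_center=float(col) - 1.0)
        a0 = np.fft.fft(spec[col], n=2 * n)
        a1 = np.fft.fft(
            spec[col] * np.exp(1j * correction_phase(p, col, np.arange(n), n, 32)), n=2 * n
        )
        np.testing.assert_allclose(a1, np.roll(a0, shift), atol=1e-9 * np.abs(a0).max())


class TestReconstructVolume:
    def test_out_of_order_pipeline_refused(self, cfg_k, cfg_wl):
        ph = single_layer_phantom(cfg_k, 150.0)
        vol = simulate_spectra(ph, cfg_k, noise_sd=0.0, seed=0)
        with pytest.raises(PipelineStateError):
            reconstruct_volume(vol, CorrectionParams())  # no background subtraction
        ph2 = single_layer_phantom(cfg_wl, 150.0)
        vol2 = subtract_background(simulate_spectra(ph2, cfg_wl, noise_sd=0.0, seed=0))
        with pytest.raises(PipelineStateError):
            reconstruct_volume(vol2, CorrectionParams())  # still wavelength-sampled

    def test_curvature_round_trip_flattens_layer(self, cfg_wl):
        cfg = small_config(n_fast=128, spectral_sampling="uniform_wavelength")
        c_um = 20.0 / (cfg.n_fast / 2.0) ** 2
        ph = single_layer_phantom(cfg, 150.0, curvature_um_per_col2=c_um)
        vol = simulate_spectra(ph, cfg, noise_sd=0.0, seed=0)
        pitch = cfg.axial_pitch_um
        rec = reconstruct_chain(vol, CorrectionParams(curvature_coeff=-c_um / pitch))
        depths = np.abs(rec.data[0]).argmax(axis=-1)
        assert depths.max() - depths.min() <= 0.5

    def test_dispersion_compensation_restores_peak_width(self, cfg_wl):
        a2 = 30.0
        ph = single_layer_phantom(cfg_wl, 150.0, tilt_slope_um_per_col=0.02)
        free = simulate_spectra(ph, cfg_wl, noise_sd=0.0, seed=0)
        mismatched = simulate_spectra(ph, cfg_wl, noise_sd=0.0, seed=0, dispersion_a2=a2)
        f_free = amplitude_fwhm_px(np.abs(reconstruct_chain(free).data[0, 32]))
        f_comp = amplitude_fwhm_px(
            np.abs(reconstruct_chain(mismatched, CorrectionParams(dispersion_a2=-a2)).data[0, 32])
        )
        assert f_comp == pytest.approx(f_free, rel=0.05)
        # negative control: without compensation the peak is grossly broadened
        f_raw = crossing_fwhm(np.abs(reconstruct_chain(mismatched).data[0, 32]))
        assert f_raw > 2.0 * f_free

    def test_wrapping_corrections_refused(self, cfg_k):
        ph = single_layer_phantom(cfg_k, 150.0, tilt_slope_um_per_col=0.05)
        vol = resample_to_k(subtract_background(simulate_spectra(ph, cfg_k, seed=0)))
        with pytest.raises(ValueError):
            reconstruct_volume(vol, CorrectionParams(rotation_slope=10.0))

    def test_axial_pitch_and_halfspace_shape(self, cfg_k):
        ph = single_layer_phantom(cfg_k, 150.0, tilt_slope_um_per_col=0.05)
        rec = reconstruct_chain(simulate_spectra(ph, cfg_k, seed=0))
        assert rec.n_z == cfg_k.n_spectral_px
        assert rec.axial_pitch_um == pytest.approx(cfg_k.axial_pitch_um)

    def test_hann_window_broadens_but_reconstructs(self, cfg_k):
        ph = single_layer_phantom(cfg_k, 150.0, tilt_slope_um_per_col=0.05)
        vol = simulate_spectra(ph, cfg_k, noise_sd=0.0, seed=0)
        rec = reconstruct_chain(vol, window="hann")
        assert abs(np.abs(rec.data[0, 32]).argmax() - 150.0 / rec.axial_pitch_um) <= 1.0
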