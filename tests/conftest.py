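"""Shared fixtures: small acquisition geometries and pre-built phantom volumes.

Everything is generated programmatically with fixed seeds; expensive
simulations are session-scoped so multiple tests share one volume.
"""

from __future__ import annotations

import numpy as np
import pytest

from aooct import (
    AcquisitionConfig,
    CorrectionParams,
    LayerSpec,
    MotionTrace,
    RetinaPhantom,
    default_phantom,
    reconstruct_volume,
    resample_to_k,
    simulate_spectra,
    subtract_background,
)


def small_config(**kw) -> AcquisitionConfig:
    base = dict(
        n_spectral_px=256,
        n_fast=64,
        n_slow=2,
        fov_deg=64 * 1.6 / 300.0,
        spectral_sampling="uniform_wavenumber",
    )
    base.update(kw)
    return AcquisitionConfig(**base)


def single_layer_phantom(cfg: AcquisitionConfig, depth_um: float = 150.0, **kw) -> RetinaPhantom:
    return RetinaPhantom(
        [LayerSpec("RPE", depth_um, 1.0)], field_size_um=cfg.field_size_um, **kw
    )


def reconstruct_chain(vol, params=None, **kw):
    """Run the standard pre-FFT chain on a raw spectral volume."""
    return reconstruct_volume(
        resample_to_k(subtract_background(vol)), params or CorrectionParams(), **kw
    )


def compensating_params(phantom: RetinaPhantom, cfg: AcquisitionConfig, dispersion_a2=0.0):
    pitch = cfg.axial_pitch_um
    return CorrectionParams(
        dispersion_a2=-dispersion_a2,
        rotation_slope=-phantom.tilt_slope_um_per_col / pitch,
        curvature_coeff=-phantom.curvature_um_per_col2 / pitch,
    )


def amplitude_fwhm_px(profile: np.ndarray, halfspan: int = 4) -> float:
    """FWHM (pixels) of a peak via log-parabola fit around the maximum."""
    i = int(np.argmax(profile))
    x = np.arange(i - halfspan, i + halfspan + 1)
    y = np.log(profile[i - halfspan : i + halfspan + 1])
    c = np.polyfit(x, y, 2)
    sigma = np.sqrt(-1.0 / (2.0 * c[0]))
    return 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma


@pytest.fixture(scope="session")
def cfg_k() -> AcquisitionConfig:
    """Small k-uniform geometry for reconstruction unit tests."""
    return small_config()


@pytest.fixture(scope="session")
def cfg_wl() -> AcquisitionConfig:
    """Small wavelength-uniform geometry (resampling non-trivial)."""
    return small_config(spectral_sampling="uniform_wavelength")


@pytest.fixture(scope="session")
def motion_scene():
    """A 160x160 phantom volume with combined axial+lateral motion and noise.

    Reconstructed with the geometry-compensating phase corrections; shared
    by the motion-correction and en-face test modules.
    """
    acq = AcquisitionConfig(
        n_spectral_px=256, n_fast=160, n_slow=160, fov_deg=160 * 1.6 / 300.0
    )
    seed = 3
    phantom = default_phantom(acq, seed=seed, tilt_total_um=4.0, curvature_sagitta_um=6.0)
    motion = MotionTrace.random_walk(acq.n_slow, axial_step_um=0.8, lateral_step_px=1, seed=seed + 1)
    vol = simulate_spectra(phantom, acq, motion, noise_sd=0.2, seed=seed)
    rec = reconstruct_chain(vol, compensating_params(phantom, acq))
    return {"acq": acq, "phantom": phantom, "motion": motion, "recon": rec, "seed": seed}


@pytest.fixture(scope="session")
def corrected_scene(motion_scene):
    """The motion scene after both motion corrections, with its RPE trace."""
    from aooct import correct_axial, correct_lateral, detect_rpe_trace, estimate_lateral_trace

    rec = motion_scene["recon"]
    trace = detect_rpe_trace(rec)
    rec = correct_axial(rec, trace)
    lateral = estimate_lateral_trace(rec)
    rec = correct_lateral(rec, lateral)
    post = detect_rpe_trace(rec)
    return {**motion_scene, "corrected": rec, "trace": post, "lateral": lateral}
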