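"""Spectral-domain reconstruction with pre-FFT phase-domain geometry correction.

The chain mirrors standard spectral-domain OCT processing: the laterally
averaged spectrum is subtracted from every A-line, spectra are resampled
onto a uniform wavenumber grid, a per-A-scan phase is added that combines
second-order dispersion compensation with a linear phase ramp whose slope
varies linearly (B-scan rotation) and quadratically (retinal curvature)
with the A-scan column, the data are zero-padded exactly once to double the
axial pixel count, and the FFT's positive-depth half is kept.  Applying the
rotation/curvature correction as a spectral phase ramp gives sub-pixel
axial shifts without extra zero-padding or image-domain interpolation.

Sign convention: the phase ramp ``+2*pi*j*dz/(2*n_k)`` on spectral sample
``j`` moves structure *posterior* (to larger depth index) by ``dz`` output
pixels under the unnormalised forward FFT used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import CubicSpline

from .phantom import SpectralVolume

__all__ = [
    "CorrectionParams",
    "ReconVolume",
    "PipelineStateError",
    "subtract_background",
    "resample_to_k",
    "correction_phase",
    "phase_matrix",
    "reconstruct_volume",
]


class PipelineStateError(RuntimeError):
    """An operation was applied out of order in the processing chain."""


@dataclass
class CorrectionParams:
    """Dispersion / rotation / curvature phase coefficients.

    ``dispersion_a2`` is the quadratic phase (rad) added at the band edge
    (centred normalised wavenumber kappa = +/-1); to cancel a simulated
    mismatch ``d2`` pass ``-d2``.  ``rotation_slope`` and ``curvature_coeff``
    are the axial shift each column receives, in *output* (zero-padded)
    pixels per column and per column squared, about ``fast_axis_center``
    (default: the fast-axis centre).  Positive shifts move structure
    posterior (``shift_posterior_positive``).
    """

    dispersion_a2: float = 0.0
    rotation_slope: float = 0.0
    curvature_coeff: float = 0.0
    fast_axis_center: float | None = None
    sign_convention: Literal["shift_posterior_positive"] = "shift_posterior_positive"

    def __post_init__(self) -> None:
        for name in ("dispersion_a2", "rotation_slope", "curvature_coeff"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.sign_convention != "shift_posterior_positive":
            raise ValueError(f"unknown sign convention {self.sign_convention!r}")

    def center(self, n_fast: int) -> float:
        return (n_fast - 1) / 2.0 if self.fast_axis_center is None else self.fast_axis_center

    def delta_z(self, columns: np.ndarray | float, n_fast: int) -> np.ndarray:
        """Axial shift (output pixels) applied to the given columns."""
        d = np.asarray(columns, dtype=float) - self.center(n_fast)
        return self.rotation_slope * d + self.curvature_coeff * d**2

    def validate_against(self, n_fast: int, n_z: int) -> None:
        """Refuse shifts that would wrap around the axial range."""
        if abs(self.rotation_slope * n_fast) >= n_z / 2:
            raise ValueError("rotation_slope implies an axial shift beyond half the range")
        if abs(self.curvature_coeff * (n_fast / 2.0) ** 2) >= n_z / 2:
            raise ValueError("curvature_coeff implies an axial shift beyond half the range")


@dataclass
class ReconVolume:
    """Reconstructed complex volume, slow x fast x depth.

    ``n_z`` equals the spectral pixel count (the positive-depth half of the
    x2 zero-padded transform); ``axial_pitch_um`` converts depth index to
    single-pass optical path.  Axial index 0 is the zero-delay (anterior).
    """

    data: np.ndarray
    axial_pitch_um: float
    lateral_pitch_um: float
    orientation: str = "anterior_at_index_0"
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.axial_pitch_um <= 0:
            raise ValueError("axial_pitch_um must be > 0")

    @property
    def n_slow(self) -> int:
        return self.data.shape[0]

    @property
    def n_fast(self) -> int:
        return self.data.shape[1]

    @property
    def n_z(self) -> int:
        return self.data.shape[2]

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.data) ** 2

    def with_data(self, data: np.ndarray, note: str) -> "ReconVolume":
        return ReconVolume(
            data,
            self.axial_pitch_um,
            self.lateral_pitch_um,
            self.orientation,
            self.log + [note],
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def subtract_background(
    vol: SpectralVolume, scope: Literal["per_bscan", "per_volume"] = "per_bscan"
) -> SpectralVolume:
    """Subtract the laterally averaged spectrum from every A-line.

    ``per_bscan`` averages over the fast axis within each B-scan (robust to
    slow drifts of the reference spectrum); ``per_volume`` averages over the
    whole volume.  Removes the DC / autocorrelation pedestal near zero delay.
    """
    if scope == "per_bscan":
        if vol.config.n_fast < 2:
            raise ValueError("per-B-scan background needs >= 2 A-scans per B-scan")
        mean = vol.fringes.mean(axis=1, keepdims=True)
    elif scope == "per_volume":
        if vol.config.n_fast * vol.config.n_slow < 2:
            raise ValueError("per-volume background needs >= 2 A-scans")
        mean = vol.fringes.mean(axis=(0, 1), keepdims=True)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return vol.with_(vol.fringes - mean, f"background_subtracted:{scope}")


def resample_to_k(
    vol: SpectralVolume, method: Literal["linear", "cubic_spline"] = "cubic_spline"
) -> SpectralVolume:
    """Interpolate spectra onto a uniform wavenumber grid spanning the band.

    A volume already sampled uniformly in k passes through unchanged (with a
    provenance note).  Uniform-wavelength spectra are interpolated from
    their non-uniform wavenumbers onto ``config.uniform_k()``.
    """
    cfg = vol.config
    if cfg.spectral_sampling == "uniform_wavenumber":
        return vol.with_(vol.fringes, "resampled_to_k:identity")
    k_src = cfg.sample_k()
    k_dst = cfg.uniform_k()
    flat = vol.fringes.reshape(-1, cfg.n_spectral_px)
    if method == "linear":
        out = np.empty_like(flat)
        for i, row in enumerate(flat):
            out[i] = np.interp(k_dst, k_src, row)
    elif method == "cubic_spline":
        out = CubicSpline(k_src, flat, axis=1)(k_dst)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return vol.with_(
        out.reshape(vol.fringes.shape),
        f"resampled_to_k:{method}",
        spectral_sampling="uniform_wavenumber",
    )


def correction_phase(
    params: CorrectionParams,
    column: np.ndarray | int,
    k_index: np.ndarray | int,
    n_k: int,
    n_fast: int | None = None,
) -> np.ndarray:
    """Pre-FFT correction phase (rad) for a column / spectral-sample pair.

    ``phi = a2*kappa**2 + 2*pi*(k_index / (2*n_k)) * dz(column)`` with
    ``kappa`` the centred wavenumber normalised to [-1, 1] over the uniform
    grid and ``dz`` in output (zero-padded) pixels.  Pure function;
    broadcasts over array arguments.
    """
    if n_fast is None:
        if params.fast_axis_center is None:
            raise ValueError("n_fast required when fast_axis_center is not set")
        n_fast = 0  # unused: centre is explicit
    j = np.asarray(k_index, dtype=float)
    kappa = 2.0 * (j - (n_k - 1) / 2.0) / (n_k - 1)
    dz = params.delta_z(column, n_fast)
    return params.dispersion_a2 * kappa**2 + 2.0 * math.pi * (j / (2.0 * n_k)) * dz


def phase_matrix(params: CorrectionParams, n_fast: int, n_k: int) -> np.ndarray:
    """Correction phase for every (column, spectral sample): shape (n_fast, n_k)."""
    cols = np.arange(n_fast, dtype=float)[:, None]
    j = np.arange(n_k, dtype=float)[None, :]
    return correction_phase(params, cols, j, n_k, n_fast)


def reconstruct_volume(
    vol: SpectralVolume,
    params: CorrectionParams,
    window: Literal["none", "hann"] = "none",
    dtype: np.dtype | type = np.complex128,
) -> ReconVolume:
    """FFT-reconstruct a background-subtracted, k-uniform spectral volume.

    Per A-line: multiply by ``exp(1j * correction_phase)``, apply the
    optional spectral window, zero-pad once to ``2 * n_spectral_px``,
    forward-FFT (unnormalised) and keep the positive-depth half.  Refuses
    volumes whose provenance does not show background subtraction and
    k-resampling, so the chain cannot silently run out of order.
    """
    cfg = vol.config
    if not any(p.startswith("background_subtracted") for p in vol.provenance):
        raise PipelineStateError("volume is not background-subtracted; run subtract_background first")
    if cfg.spectral_sampling != "uniform_wavenumber" or not any(
        p.startswith("resampled_to_k") for p in vol.provenance
    ):
        raise PipelineStateError("volume is not uniform in wavenumber; run resample_to_k first")
    n_k = cfg.n_spectral_px
    params.validate_against(cfg.n_fast, n_k)

    carrier = np.exp(1j * phase_matrix(params, cfg.n_fast, n_k))
    if window == "hann":
        carrier = carrier * np.hanning(n_k)[None, :]
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")

    out = np.empty((cfg.n_slow, cfg.n_fast, n_k), dtype=dtype)
    for t in range(cfg.n_slow):  # per B-scan keeps the padded buffer small
        spec = vol.fringes[t] * carrier
        a = np.fft.fft(spec, n=2 * n_k, axis=-1)
        out[t] = a[:, :n_k]

    log = list(vol.provenance) + [
        "reconstructed:"
        f"a2={params.dispersion_a2} rot={params.rotation_slope} "
        f"curv={params.curvature_coeff} x0={params.center(cfg.n_fast)} window={window}",
        "sign_convention:shift_posterior_positive",
    ]
    return ReconVolume(
        out,
        axial_pitch_um=cfg.axial_pitch_um,
        lateral_pitch_um=cfg.px_size_um,
        log=log,
    )
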