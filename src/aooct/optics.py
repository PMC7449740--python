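"""Closed-form instrument arithmetic for validation and config sanity checks."""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SourceSpec",
    "axial_resolution",
    "marechal_rms_limit",
    "lateral_sampling",
    "frames_per_exposure",
]


@dataclass
class SourceSpec:
    """Broadband source spectrum and the refractive index of the sample."""

    center_wavelength_nm: float = 840.0
    fwhm_bandwidth_nm: float = 50.0
    tissue_index: float = 1.38  # standard average retinal value

    def __post_init__(self) -> None:
        if self.center_wavelength_nm <= 0 or self.tissue_index <= 0:
            raise ValueError("wavelength and tissue index must be positive")
        if not 0 <= self.fwhm_bandwidth_nm < self.center_wavelength_nm:
            raise ValueError("bandwidth must be non-negative and below the center wavelength")


def axial_resolution(src: SourceSpec) -> float:
    """Coherence-length axial resolution in tissue, micrometres.

    ``(2 ln 2 / pi) * lambda0**2 / delta_lambda / n``: 840 nm with 50 nm
    FWHM gives 6.2 um in air and 4.5 um at n = 1.38.
    """
    if src.fwhm_bandwidth_nm == 0:
        raise ValueError("zero bandwidth: axial resolution undefined")
    lc_nm = (2.0 * math.log(2.0) / math.pi) * src.center_wavelength_nm**2 / src.fwhm_bandwidth_nm
    return lc_nm / src.tissue_index * 1e-3


def marechal_rms_limit(wavelength_nm: float) -> float:
    """Marechal criterion: diffraction-limited below an RMS error of lambda/14 (nm)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return wavelength_nm / 14.0


def lateral_sampling(fov_deg: float, n_px: int, um_per_deg: float = 300.0) -> float:
    """Lateral pixel pitch in micrometres for a scan of ``n_px`` over ``fov_deg``."""
    if fov_deg <= 0 or n_px <= 0 or um_per_deg <= 0:
        raise ValueError("all arguments must be positive")
    return fov_deg * um_per_deg / n_px


def frames_per_exposure(exposure_s: float, b_scan_rate_hz: float) -> float:
    """Number of B-scans spanned by a wavefront-sensor exposure."""
    if exposure_s < 0 or b_scan_rate_hz <= 0:
        raise ValueError("exposure must be >= 0 and rate > 0")
    return exposure_s * b_scan_rate_hz
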