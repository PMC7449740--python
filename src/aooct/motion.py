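"""Inter-B-scan motion correction referenced to the RPE.

Axial motion is estimated per B-scan by laterally averaging all A-scans
and walking the averaged depth profile from the choroid toward the
anterior retina until the first strong peak — the RPE, the brightest
posterior band once the weaker choriocapillaris and Bruch's membrane are
skipped by the threshold.  Lateral (fast-axis) motion is estimated from
the peak of the 2D cross-correlation between successive B-scans.  Both
corrections move whole B-scans by integer pixels and zero-fill vacated
rows/columns; sub-pixel geometry is already handled by the pre-FFT phase
correction, and slow-axis motion is not corrected (the correlation is
between successive B-scans only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal

from .reconstruction import ReconVolume

__all__ = [
    "AxialTraceEstimate",
    "LateralTraceEstimate",
    "detect_rpe_trace",
    "correct_axial",
    "estimate_lateral_trace",
    "correct_lateral",
]


@dataclass
class AxialTraceEstimate:
    """Detected RPE depth (pixels) for every B-scan."""

    rpe_depth: np.ndarray
    detection_threshold: float
    search_direction: Literal["posterior_to_anterior"] = "posterior_to_anterior"
    flagged: np.ndarray = field(default=None)  # B-scans filled by interpolation

    def __post_init__(self) -> None:
        self.rpe_depth = np.asarray(self.rpe_depth, dtype=float)
        if self.flagged is None:
            self.flagged = np.zeros(len(self.rpe_depth), dtype=bool)
        if not 0 < self.detection_threshold < 1:
            raise ValueError("detection threshold must be in (0, 1)")


@dataclass
class LateralTraceEstimate:
    """Cumulative fast-axis shift (pixels) for every B-scan; shift[0] = 0."""

    shift: np.ndarray
    subpixel: bool = False

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        if len(self.shift) and self.shift[0] != 0.0:
            raise ValueError("lateral trace must start at 0 (reference frame)")


def _shift_zero_fill(arr: np.ndarray, shift: int, axis: int) -> np.ndarray:
    """Shift along an axis by an integer, zero-filling vacated entries."""
    out = np.zeros_like(arr)
    n = arr.shape[axis]
    if abs(shift) >= n:
        return out
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    if shift >= 0:
        dst[axis] = slice(shift, n)
        src[axis] = slice(0, n - shift)
    else:
        dst[axis] = slice(0, n + shift)
        src[axis] = slice(-shift, n)
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# axial
# ---------------------------------------------------------------------------


def detect_rpe_trace(
    vol: ReconVolume, threshold: float = 0.5, min_prominence: float = 0.05
) -> AxialTraceEstimate:
    """Detect the RPE depth per B-scan from the laterally averaged profile.

    For each B-scan the intensity is averaged over the fast axis and the
    profile is searched from the deepest index toward the anterior; the
    first local maximum exceeding ``threshold`` times the profile maximum
    with prominence at least ``min_prominence`` times the maximum is
    reported.  B-scans without such a peak are flagged and filled by linear
    interpolation from their neighbours, never silently zeroed.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    profiles = vol.intensity.mean(axis=1)  # (n_slow, n_z)
    n_slow = profiles.shape[0]
    depths = np.full(n_slow, np.nan)
    for t in range(n_slow):
        p = profiles[t]
        pmax = p.max()
        if pmax <= 0:
            continue
        peaks, _ = signal.find_peaks(
            p, height=threshold * pmax, prominence=min_prominence * pmax
        )
        if len(peaks):
            depths[t] = peaks[-1]  # deepest qualifying peak = first from the choroid
    flagged = ~np.isfinite(depths)
    if flagged.all():
        raise ValueError("no B-scan shows a peak above threshold; cannot build an RPE trace")
    if flagged.any():
        good = np.flatnonzero(~flagged)
        depths[flagged] = np.interp(np.flatnonzero(flagged), good, depths[good])
    return AxialTraceEstimate(depths, detection_threshold=threshold, flagged=flagged)


def correct_axial(
    vol: ReconVolume,
    trace: AxialTraceEstimate,
    reference: Literal["median", "first"] = "median",
) -> ReconVolume:
    """Align every B-scan's detected RPE to a common reference depth.

    Shifts are integer pixels; rows shifted out of range are zero-filled.
    A requested shift beyond half the axial range indicates a detection
    failure and is refused.
    """
    if len(trace.rpe_depth) != vol.n_slow:
        raise ValueError("trace length must equal the number of B-scans")
    ref = float(np.median(trace.rpe_depth)) if reference == "median" else float(trace.rpe_depth[0])
    shifts = np.rint(ref - trace.rpe_depth).astype(int)
    if np.any(np.abs(shifts) > vol.n_z / 2):
        raise ValueError("axial shift exceeds half the depth range: RPE detection failed")
    data = np.empty_like(vol.data)
    for t in range(vol.n_slow):
        data[t] = _shift_zero_fill(vol.data[t], shifts[t], axis=-1)
    return vol.with_data(
        data, f"axial_corrected:reference={reference} ref_px={ref:.1f}"
    )


# ---------------------------------------------------------------------------
# lateral
# ---------------------------------------------------------------------------


def estimate_lateral_trace(
    vol: ReconVolume,
    subpixel: bool = False,
    corr_floor: float = 0.1,
    max_step: int = 8,
) -> LateralTraceEstimate:
    """Fast-axis shift between successive B-scans by 2D cross-correlation.

    B-scan intensity images are restricted to the retina band (depths whose
    volume-mean intensity exceeds 5% of the maximum — signal-free depths
    would dilute the peak), log-scaled to tame bright-layer dominance, and
    stripped of their per-depth lateral mean (horizontal layer stripes are
    translation-invariant along the fast axis and would pin the peak at
    zero lag).  The full 2D cross-correlation of each successive pair,
    normalised by the overlap length to undo the triangular windowing bias,
    is searched within ``+/-max_step`` fast-axis pixels — at hundreds of
    B-scans per second, per-frame eye motion is small even during
    microsaccades.  The fast-axis component of the peak gives the pairwise
    shift; shifts accumulate into a trace with ``shift[0] = 0`` describing
    the displacement of each B-scan image relative to the first frame.
    Pairs whose normalised peak correlation falls below ``corr_floor``
    (featureless frames) carry the previous pairwise shift forward.
    Optional parabolic interpolation around the peak refines to sub-pixel.
    """
    if vol.n_slow < 2:
        raise ValueError("need at least 2 B-scans to estimate lateral motion")
    n_fast = vol.n_fast
    max_step = min(max_step, n_fast - 1)
    intensity = vol.intensity
    profile = intensity.mean(axis=(0, 1))
    band = profile > 0.05 * profile.max()
    if band.sum() >= 4:
        intensity = intensity[:, :, band]
    imgs = np.log1p(intensity)
    imgs = imgs - imgs.mean(axis=1, keepdims=True)
    # fixed-pattern removal: any scan-frame-static texture (it does not move
    # with the retina) would bias the correlation peak toward zero lag
    imgs = imgs - imgs.mean(axis=0)

    lags = np.arange(-(n_fast - 1), n_fast)
    keep = np.abs(lags) <= max_step
    kept_idx = np.flatnonzero(keep)
    overlap = (n_fast - np.abs(lags[keep])).astype(float)

    shifts = np.zeros(vol.n_slow)
    prev_pair = 0.0
    for t in range(1, vol.n_slow):
        a, b = imgs[t], imgs[t - 1]  # (n_fast, n_z_band)
        corr = signal.fftconvolve(a, b[::-1, ::-1], mode="full")
        sub = corr[keep, :] / overlap[:, None]
        peak = np.unravel_index(np.argmax(sub), sub.shape)
        norm = np.linalg.norm(a) * np.linalg.norm(b)
        coef = corr[keep, :][peak] / norm if norm > 0 else 0.0
        if coef < corr_floor:
            pair = prev_pair
        else:
            pair = float(lags[keep][peak[0]])
            if subpixel:
                i = kept_idx[peak[0]]
                if 0 < i < corr.shape[0] - 1:
                    y0, y1, y2 = corr[i - 1, peak[1]], corr[i, peak[1]], corr[i + 1, peak[1]]
                    denom = y0 - 2 * y1 + y2
                    if denom != 0:
                        pair += 0.5 * (y0 - y2) / denom
        shifts[t] = shifts[t - 1] + pair
        prev_pair = pair
    return LateralTraceEstimate(shifts, subpixel=subpixel)


def correct_lateral(vol: ReconVolume, trace: LateralTraceEstimate) -> ReconVolume:
    """Shift every B-scan along the fast axis by minus its cumulative shift.

    Vacated columns are zero-filled; the usable fast-axis field (columns
    populated in every B-scan) is recorded in the provenance log — this is
    why a motion-corrected 4 deg scan yields a slightly narrower usable
    field.  Shifts beyond a quarter of the fast axis indicate gross failure
    and are refused.
    """
    if len(trace.shift) != vol.n_slow:
        raise ValueError("trace length must equal the number of B-scans")
    shifts = np.rint(trace.shift).astype(int)
    if np.any(np.abs(shifts) > vol.n_fast / 4):
        raise ValueError("lateral shift exceeds a quarter of the fast axis: estimation failed")
    data = np.empty_like(vol.data)
    for t in range(vol.n_slow):
        data[t] = _shift_zero_fill(vol.data[t], -shifts[t], axis=0)
    usable = vol.n_fast - int(shifts.max() - shifts.min())
    return vol.with_data(
        data, f"lateral_corrected:usable_fast_px={usable}"
    )
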