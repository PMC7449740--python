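"""RPE-referenced layer segmentation and depth-integrated en-face images.

Once the volume is motion-corrected and flattened, every posterior layer
sits at a fixed depth offset from the RPE reference, so layers are
segmented as fixed windows (offset +/- half-width, in micrometres)
relative to the median detected RPE depth rather than re-segmented
per layer.  En-face images are formed by reducing the intensity over the
window's depth range at each (slow, fast) position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .motion import AxialTraceEstimate
from .reconstruction import PipelineStateError, ReconVolume

__all__ = [
    "LayerWindow",
    "EnFaceImage",
    "default_layer_windows",
    "segment_layers",
    "extract_enface",
]


@dataclass
class LayerWindow:
    """Depth window relative to the RPE reference (negative offset = anterior)."""

    name: str
    offset_um: float
    half_width_um: float

    def __post_init__(self) -> None:
        if self.half_width_um <= 0:
            raise ValueError(f"window {self.name!r}: half_width must be > 0")


@dataclass
class EnFaceImage:
    """Depth-integrated transverse image (slow x fast) with its pixel size."""

    pixels: np.ndarray
    px_size_um: float
    source_layer: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.px_size_um <= 0:
            raise ValueError("px_size_um must be > 0")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("en-face pixels must be finite")


def default_layer_windows(half_width_um: float = 5.0) -> list[LayerWindow]:
    """Named default windows for the posterior layers of the default phantom."""
    offsets = {
        "IS/OS": -40.0,
        "COST": -20.0,
        "ROST": -12.0,
        "RPE": 0.0,
        "BM": 12.0,
        "CC": 30.0,
    }
    return [LayerWindow(name, off, half_width_um) for name, off in offsets.items()]


def segment_layers(
    vol: ReconVolume,
    rpe_trace: AxialTraceEstimate,
    windows: list[LayerWindow],
    reference: Literal["median", "first"] = "median",
) -> dict[str, tuple[int, int]]:
    """Absolute pixel depth range [lo, hi) of each layer window.

    The reference depth is the median (or first) detected RPE depth; each
    window's range is ``reference + offset +/- half_width`` converted to
    pixels.  Ranges partially outside the axial extent are clipped (and the
    clipping noted in the volume log); a window entirely outside raises an
    error naming the layer.  Overlapping windows are all returned; overlap
    is the caller's information, not merged away.
    """
    if not any(entry.startswith("axial_corrected") for entry in vol.log):
        raise PipelineStateError("volume is not motion-corrected; run correct_axial first")
    ref = float(np.median(rpe_trace.rpe_depth)) if reference == "median" else float(
        rpe_trace.rpe_depth[0]
    )
    pitch = vol.axial_pitch_um
    ranges: dict[str, tuple[int, int]] = {}
    for w in windows:
        center = ref + w.offset_um / pitch
        lo = int(np.floor(center - w.half_width_um / pitch))
        hi = int(np.ceil(center + w.half_width_um / pitch)) + 1
        lo_c, hi_c = max(lo, 0), min(hi, vol.n_z)
        if lo_c >= hi_c:
            raise ValueError(
                f"layer window {w.name!r} ([{lo}, {hi}) px) lies outside the axial range"
            )
        if (lo_c, hi_c) != (lo, hi):
            vol.log.append(f"segment_layers:clipped {w.name} [{lo},{hi})->[{lo_c},{hi_c})")
        ranges[w.name] = (lo_c, hi_c)
    return ranges


def extract_enface(
    vol: ReconVolume,
    layer_range: tuple[int, int],
    reducer: Literal["mean", "sum", "max"] = "mean",
    source_layer: str = "",
) -> EnFaceImage:
    """Reduce intensity over a depth window into a transverse image."""
    lo, hi = layer_range
    if not (0 <= lo < hi <= vol.n_z):
        raise ValueError(f"empty or out-of-range depth window [{lo}, {hi})")
    block = vol.intensity[:, :, lo:hi]
    if reducer == "mean":
        pixels = block.mean(axis=2)
    elif reducer == "sum":
        pixels = block.sum(axis=2)
    elif reducer == "max":
        pixels = block.max(axis=2)
    else:
        raise ValueError(f"unknown reducer {reducer!r}")
    return EnFaceImage(pixels, px_size_um=vol.lateral_pitch_um, source_layer=source_layer)
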