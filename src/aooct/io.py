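"""Readers and writers for volumes, images, traces and ground truth.

Spectral volumes are stored as raw little-endian float32 binary plus a
JSON sidecar carrying shape, acquisition config, provenance and (when
simulated) a reference to the ground-truth phantom file.  Reconstructed
intensity volumes and en-face images go to 32-bit float TIFF with JSON
metadata; traces and radial profiles to CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .enface import EnFaceImage
from .mosaic import RadialProfile
from .motion import AxialTraceEstimate, LateralTraceEstimate
from .phantom import AcquisitionConfig, RetinaPhantom, SpectralVolume
from .reconstruction import ReconVolume

__all__ = [
    "write_spectral_volume",
    "read_spectral_volume",
    "write_recon_volume",
    "write_enface",
    "write_traces_csv",
    "write_radial_profile_csv",
    "write_phantom_json",
    "sha256_of",
]

_RAW_NAME = "fringes.raw"
_SIDECAR_NAME = "volume.json"


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_spectral_volume(vol: SpectralVolume, out_dir: str | Path, extra: dict | None = None) -> Path:
    """Write raw float32 fringes plus a JSON sidecar; returns the sidecar path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = out_dir / _RAW_NAME
    vol.fringes.astype("<f4").tofile(raw)
    sidecar = {
        "format": "aooct.spectral_volume.v1",
        "raw_file": _RAW_NAME,
        "dtype": "<f4",
        "order": "C",
        "axes": ["slow", "fast", "spectral"],
        "shape": list(vol.shape),
        "config": _jsonable(vol.config),
        "provenance": list(vol.provenance),
    }
    if extra:
        sidecar.update(_jsonable(extra))
    path = out_dir / _SIDECAR_NAME
    path.write_text(json.dumps(sidecar, indent=1))
    return path


def read_spectral_volume(in_dir: str | Path) -> SpectralVolume:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / _SIDECAR_NAME).read_text())
    if meta.get("format") != "aooct.spectral_volume.v1":
        raise ValueError(f"{in_dir}: not an aooct spectral volume")
    cfg = AcquisitionConfig(**meta["config"])
    fringes = np.fromfile(in_dir / meta["raw_file"], dtype=meta["dtype"]).reshape(meta["shape"])
    return SpectralVolume(fringes.astype(float), cfg, list(meta.get("provenance", [])))


def write_recon_volume(vol: ReconVolume, out_dir: str | Path, stem: str = "recon") -> list[Path]:
    """Write the intensity volume as a multi-page float32 TIFF plus metadata JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = out_dir / f"{stem}_intensity.tiff"
    tifffile.imwrite(tif, vol.intensity.astype(np.float32), photometric="minisblack")
    meta = out_dir / f"{stem}_meta.json"
    meta.write_text(
        json.dumps(
            {
                "axial_pitch_um": vol.axial_pitch_um,
                "lateral_pitch_um": vol.lateral_pitch_um,
                "orientation": vol.orientation,
                "shape": list(vol.data.shape),
                "log": vol.log,
            },
            indent=1,
        )
    )
    return [tif, meta]


def write_enface(
    img: EnFaceImage, path: str | Path, preview_png: str | Path | None = None
) -> list[Path]:
    """Write an en-face image as float32 TIFF, optionally an 8-bit PNG preview."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, img.pixels.astype(np.float32), photometric="minisblack")
    written = [path]
    if preview_png is not None:
        from PIL import Image

        lo, hi = np.percentile(img.pixels, [1, 99])
        scaled = np.clip((img.pixels - lo) / max(hi - lo, 1e-30), 0, 1)
        Image.fromarray((scaled * 255).astype(np.uint8)).save(preview_png)
        written.append(Path(preview_png))
    return written


def write_traces_csv(
    axial: AxialTraceEstimate | None, lateral: LateralTraceEstimate | None, path: str | Path
) -> Path:
    """Write per-B-scan motion traces: index, axial px, lateral px."""
    n = len(axial.rpe_depth) if axial is not None else len(lateral.shift)
    ax = axial.rpe_depth if axial is not None else np.full(n, np.nan)
    lat = lateral.shift if lateral is not None else np.full(n, np.nan)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = np.column_stack([np.arange(n), ax, lat])
    np.savetxt(
        path,
        rows,
        delimiter=",",
        header="bscan,rpe_depth_px,lateral_shift_px",
        comments="",
        fmt=["%d", "%.3f", "%.3f"],
    )
    return path


def write_radial_profile_csv(profile: RadialProfile, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(
        path,
        np.column_stack([profile.radii, profile.magnitude]),
        delimiter=",",
        header="spatial_frequency_cyc_per_um,mean_fft_magnitude",
        comments="",
    )
    return path


def write_phantom_json(phantom: RetinaPhantom, path: str | Path) -> Path:
    """Ground-truth phantom (layer surfaces, mosaics, geometry) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(phantom), indent=1))
    return path
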