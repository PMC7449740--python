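"""Synthetic retina phantoms and raw spectral-domain OCT interferograms.

The simulator is the package's ground-truth source: it builds a layered
retina (ELM through choriocapillaris) with jittered hexagonal cone and RPE
mosaics, applies B-scan tilt, retinal curvature, dispersion mismatch and
per-B-scan axial/lateral motion, and renders the raw spectral fringes that
a spectrometer-based OCT system would record.  Everything downstream of the
spectrometer — and nothing upstream of it — is modelled.

Conventions
-----------
* Depths ``z`` are single-pass optical path lengths in micrometres;
  axial index 0 is the zero-delay line (anterior) and depth increases
  toward the choroid.
* The interferometric fringe phase is ``2 * k * z`` with ``k = 2*pi/lambda``
  in rad/um, i.e. the double pass is folded into the factor 2.
* Lateral field coordinates are in micrometres with the origin at the
  corner of the scanned field; A-scan ``i`` samples ``x = (i + 0.5) * px``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "AcquisitionConfig",
    "LayerSpec",
    "RetinaPhantom",
    "PointSet",
    "MotionTrace",
    "SpectralVolume",
    "DepthRangeError",
    "make_hex_mosaic",
    "render_mosaic_image",
    "simulate_spectra",
    "default_phantom",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

CANONICAL_LAYER_ORDER = ("NFL", "ELM", "IS/OS", "COST", "ROST", "RPE", "BM", "CC")


class DepthRangeError(ValueError):
    """A phantom layer falls outside the unambiguous imaging depth range."""


@dataclass
class AcquisitionConfig:
    """Acquisition geometry and spectrometer sampling.

    Defaults mirror an 840 nm / 50 nm FWHM spectral-domain system scanning
    750 x 750 A-scans over a 4 deg x 4 deg field (1.6 um lateral pitch) at a
    250 kHz A-scan rate (~300 B-scans/s).  ``spectral_span_nm`` is the total
    wavelength range captured by the ``n_spectral_px`` spectrometer pixels;
    the 120 nm default keeps truncation of the Gaussian source envelope
    negligible so the reconstructed axial point spread matches the
    coherence-length formula.
    """

    center_wavelength_nm: float = 840.0
    fwhm_bandwidth_nm: float = 50.0
    n_spectral_px: int = 800
    n_fast: int = 750
    n_slow: int = 750
    fov_deg: float = 4.0
    um_per_deg: float = 300.0
    a_scan_rate_hz: float = 250e3
    b_scan_rate_hz: float = 300.0
    spectral_sampling: Literal["uniform_wavelength", "uniform_wavenumber"] = (
        "uniform_wavelength"
    )
    spectral_span_nm: float = 120.0

    def __post_init__(self) -> None:
        for name in ("n_spectral_px", "n_fast", "n_slow"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2, got {getattr(self, name)}")
        if not 0 < self.fwhm_bandwidth_nm < self.center_wavelength_nm:
            raise ValueError("FWHM bandwidth must be positive and below the center wavelength")
        if not 0 < self.spectral_span_nm < 2 * self.center_wavelength_nm:
            raise ValueError("spectral span must be positive and physical")
        if self.spectral_sampling not in ("uniform_wavelength", "uniform_wavenumber"):
            raise ValueError(f"unknown spectral sampling dialect {self.spectral_sampling!r}")

    # -- lateral geometry ---------------------------------------------------

    @property
    def px_size_um(self) -> float:
        """Lateral sampling pitch along the fast axis (um per A-scan)."""
        return self.fov_deg * self.um_per_deg / self.n_fast

    @property
    def field_size_um(self) -> tuple[float, float]:
        """(fast, slow) extent of the scanned field in micrometres."""
        return (self.n_fast * self.px_size_um, self.n_slow * self.px_size_um)

    # -- spectral geometry --------------------------------------------------

    @property
    def k_center(self) -> float:
        """Center wavenumber in rad/um."""
        return 2.0 * math.pi / (self.center_wavelength_nm * 1e-3)

    @property
    def k_bounds(self) -> tuple[float, float]:
        """(k_min, k_max) of the sampled band in rad/um."""
        lam0 = self.center_wavelength_nm * 1e-3
        half = 0.5 * self.spectral_span_nm * 1e-3
        return (2.0 * math.pi / (lam0 + half), 2.0 * math.pi / (lam0 - half))

    def sample_k(self) -> np.ndarray:
        """Wavenumber of each spectral sample, ascending in k (rad/um).

        For the ``uniform_wavelength`` dialect the samples are equispaced in
        wavelength, hence non-uniform in k; for ``uniform_wavenumber`` they
        are equispaced in k.  Both span the same band.
        """
        k_min, k_max = self.k_bounds
        n = self.n_spectral_px
        if self.spectral_sampling == "uniform_wavenumber":
            return np.linspace(k_min, k_max, n)
        lam0 = self.center_wavelength_nm * 1e-3
        half = 0.5 * self.spectral_span_nm * 1e-3
        lam = np.linspace(lam0 + half, lam0 - half, n)  # descending => k ascending
        return 2.0 * math.pi / lam

    def uniform_k(self) -> np.ndarray:
        """The uniform wavenumber grid targeted by k-resampling."""
        k_min, k_max = self.k_bounds
        return np.linspace(k_min, k_max, self.n_spectral_px)

    @property
    def axial_pitch_um(self) -> float:
        """Depth per output pixel after the single x2 zero-pad (um)."""
        k = self.uniform_k()
        dk = (k[-1] - k[0]) / (len(k) - 1)
        return math.pi / (2.0 * self.n_spectral_px * dk)

    @property
    def depth_range_um(self) -> float:
        """Unambiguous (positive-half) imaging depth in micrometres."""
        return self.n_spectral_px * self.axial_pitch_um

    def source_envelope(self, k: np.ndarray) -> np.ndarray:
        """Gaussian source spectrum evaluated at wavenumbers ``k``."""
        lam0 = self.center_wavelength_nm * 1e-3
        dk_fwhm = 2.0 * math.pi * (self.fwhm_bandwidth_nm * 1e-3) / lam0**2
        return np.exp(-4.0 * math.log(2.0) * ((k - self.k_center) / dk_fwhm) ** 2)


@dataclass
class PointSet:
    """A planar point pattern (cell centres) in field coordinates (um)."""

    coordinates: np.ndarray  # (n, 2) array of (x, y)
    nominal_center_spacing: float
    jitter_sigma: float
    seed: int

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.coordinates)


@dataclass
class LayerSpec:
    """One retinal layer: a reflective surface at a nominal depth.

    ``mosaic`` laterally modulates the reflectivity multiplicatively: the
    factor is 1 at cell centres and ``mosaic_floor`` between cells.
    """

    name: str
    base_depth_um: float
    reflectivity: float
    mosaic: PointSet | None = None
    axial_jitter_sigma_um: float = 0.0
    mosaic_floor: float = 0.3
    mosaic_spot_fwhm_um: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.reflectivity) or self.reflectivity < 0:
            raise ValueError(f"layer {self.name!r}: reflectivity must be finite and >= 0")
        if self.axial_jitter_sigma_um < 0:
            raise ValueError(f"layer {self.name!r}: axial jitter sigma must be >= 0")

    @property
    def spot_fwhm_um(self) -> float:
        if self.mosaic_spot_fwhm_um is not None:
            return self.mosaic_spot_fwhm_um
        if self.mosaic is not None:
            return 0.3 * self.mosaic.nominal_center_spacing
        return 0.0


@dataclass
class RetinaPhantom:
    """Ground-truth layered retina with tilt and curvature.

    The evaluated surface of every layer is
    ``z(x) = base_depth + tilt_slope*(x - x0) + curvature_coeff*(x - x0)**2``
    with ``x`` the fast-axis column index and ``x0`` the fast-axis centre;
    tilt emulates B-scan rotation from decentred pupil illumination and the
    quadratic term the residual retinal curvature over the field.
    """

    layers: list[LayerSpec]
    tilt_slope_um_per_col: float = 0.0
    curvature_um_per_col2: float = 0.0
    field_size_um: tuple[float, float] = (1200.0, 1200.0)

    def __post_init__(self) -> None:
        order = {name: i for i, name in enumerate(CANONICAL_LAYER_ORDER)}
        ranked = [(order.get(l.name), l) for l in self.layers]
        known = [(r, l) for r, l in ranked if r is not None]
        depths = [l.base_depth_um for _, l in sorted(known, key=lambda t: t[0])]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("layer depths must be strictly ordered anterior to posterior")

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def surface_depth(self, layer: LayerSpec, columns: np.ndarray, n_fast: int) -> np.ndarray:
        """Evaluate the layer surface z (um) at the given fast-axis columns."""
        x0 = (n_fast - 1) / 2.0
        d = np.asarray(columns, dtype=float) - x0
        return layer.base_depth_um + self.tilt_slope_um_per_col * d + self.curvature_um_per_col2 * d**2


@dataclass
class MotionTrace:
    """Per-B-scan bulk motion: axial shift in um, lateral shift in fast px."""

    axial_shift_um: np.ndarray
    lateral_shift_px: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.axial_shift_um = np.asarray(self.axial_shift_um, dtype=float)
        self.lateral_shift_px = np.asarray(self.lateral_shift_px, dtype=float)
        if self.axial_shift_um.shape != self.lateral_shift_px.shape:
            raise ValueError("axial and lateral traces must have equal length")
        if len(self.axial_shift_um) and (
            self.axial_shift_um[0] != 0.0 or self.lateral_shift_px[0] != 0.0
        ):
            raise ValueError("first B-scan is the reference frame: motion must start at 0")

    @classmethod
    def none(cls, n_slow: int) -> "MotionTrace":
        return cls(np.zeros(n_slow), np.zeros(n_slow), seed=0)

    @classmethod
    def random_walk(
        cls,
        n_slow: int,
        axial_step_um: float,
        lateral_step_px: int,
        seed: int,
    ) -> "MotionTrace":
        """Integer-lateral random-walk motion, zero at the reference frame."""
        rng = np.random.default_rng(seed)
        ax = np.cumsum(rng.normal(0.0, axial_step_um, n_slow))
        lat = np.cumsum(rng.integers(-lateral_step_px, lateral_step_px + 1, n_slow))
        ax -= ax[0]
        lat = (lat - lat[0]).astype(float)
        return cls(ax, lat, seed=seed)

    @classmethod
    def sawtooth(cls, n_slow: int, amplitude_um: float, period: int) -> "MotionTrace":
        """Deterministic sawtooth axial drift (lateral zero); test fixture."""
        t = np.arange(n_slow)
        ax = amplitude_um * ((t % period) / max(period - 1, 1))
        ax -= ax[0]
        return cls(ax, np.zeros(n_slow), seed=0)


@dataclass
class SpectralVolume:
    """Raw (or partially processed) spectral fringes, slow x fast x spectral."""

    fringes: np.ndarray
    config: AcquisitionConfig
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fringes = np.asarray(self.fringes)
        expected = (self.config.n_slow, self.config.n_fast, self.config.n_spectral_px)
        if self.fringes.shape != expected:
            raise ValueError(
                f"fringe array shape {self.fringes.shape} inconsistent with config {expected}"
            )
        if not np.all(np.isfinite(self.fringes)):
            raise ValueError("fringes must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fringes.shape

    def with_(self, fringes: np.ndarray, note: str, **config_updates) -> "SpectralVolume":
        """Derived volume with a provenance note appended."""
        cfg = replace(self.config, **config_updates) if config_updates else self.config
        return SpectralVolume(fringes, cfg, self.provenance + [note])


# ---------------------------------------------------------------------------
# mosaic generation and rendering
# ---------------------------------------------------------------------------


def make_hex_mosaic(
    center_spacing: float,
    jitter_sigma: float,
    field_size: tuple[float, float],
    seed: int,
) -> PointSet:
    """Jittered hexagonally packed point mosaic filling a rectangular field.

    Points sit on a triangular lattice with the given centre-to-centre
    spacing ``a`` (row pitch ``a*sqrt(3)/2``), each displaced by an isotropic
    Gaussian of standard deviation ``jitter_sigma`` and clipped to the field.
    Point density is ~``2 / (sqrt(3) * a**2)``.

    Parameters are in micrometres; ``field_size`` is (width, height).
    """
    if center_spacing <= 0:
        raise ValueError(f"center_spacing must be > 0, got {center_spacing}")
    w, h = field_size
    if w <= 0 or h <= 0:
        raise ValueError(f"field_size dimensions must be > 0, got {field_size}")
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")

    a = center_spacing
    dy = a * math.sqrt(3.0) / 2.0
    rows = int(math.floor(h / dy)) + 1
    xs, ys = [], []
    for r in range(rows):
        off = 0.5 * a if (r % 2) else 0.0
        ncol = int(math.floor((w - off) / a)) + 1 if w >= off else 0
        x = off + a * np.arange(ncol)
        xs.append(x)
        ys.append(np.full(ncol, r * dy))
    coords = np.column_stack([np.concatenate(xs), np.concatenate(ys)]) if xs else np.empty((0, 2))

    if jitter_sigma > 0 and len(coords):
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, jitter_sigma, coords.shape)
        coords[:, 0] = np.clip(coords[:, 0], 0.0, w)
        coords[:, 1] = np.clip(coords[:, 1], 0.0, h)
    return PointSet(coords, nominal_center_spacing=a, jitter_sigma=jitter_sigma, seed=seed)


def render_mosaic_image(
    points: PointSet,
    spot_fwhm: float,
    px_size: float,
    image_size: tuple[int, int] | int,
) -> np.ndarray:
    """Render a point set as unit-amplitude Gaussian spots on a dark field.

    ``image_size`` is (rows, cols) = (slow, fast); pixel (r, c) is centred at
    field position ``x = (c + 0.5) * px_size``, ``y = (r + 0.5) * px_size``.
    An empty point set yields an all-zero image.
    """
    if px_size <= 0:
        raise ValueError("px_size must be > 0")
    if spot_fwhm <= 0:
        raise ValueError("spot_fwhm must be > 0")
    if isinstance(image_size, int):
        image_size = (image_size, image_size)
    ny, nx = image_size
    img = np.zeros((ny, nx), dtype=float)
    if len(points) == 0:
        return img

    sigma_px = spot_fwhm * _FWHM_TO_SIGMA / px_size
    halo = max(int(math.ceil(4.0 * sigma_px)), 1)
    # per-point Gaussian stamps keep sub-pixel positions exact
    for x_um, y_um in points.coordinates:
        cx = x_um / px_size - 0.5
        cy = y_um / px_size - 0.5
        c0 = max(int(math.floor(cx)) - halo, 0)
        c1 = min(int(math.floor(cx)) + halo + 2, nx)
        r0 = max(int(math.floor(cy)) - halo, 0)
        r1 = min(int(math.floor(cy)) + halo + 2, ny)
        if c0 >= c1 or r0 >= r1:
            continue
        cc = np.arange(c0, c1) - cx
        rr = np.arange(r0, r1) - cy
        img[r0:r1, c0:c1] += np.exp(
            -0.5 * (rr[:, None] ** 2 + cc[None, :] ** 2) / sigma_px**2
        )
    return img


# ---------------------------------------------------------------------------
# spectral simulation
# ---------------------------------------------------------------------------


def _modulation_image(
    layer: LayerSpec, px_size: float, shape: tuple[int, int]
) -> np.ndarray:
    """Lateral reflectivity modulation of a mosaic-bearing layer on the field grid."""
    spots = render_mosaic_image(layer.mosaic, layer.spot_fwhm_um, px_size, shape)
    return layer.mosaic_floor + (1.0 - layer.mosaic_floor) * np.clip(spots, 0.0, 1.0)


def simulate_spectra(
    phantom: RetinaPhantom,
    config: AcquisitionConfig,
    motion: MotionTrace | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dc_level: float = 1.0,
    dispersion_a2: float = 0.0,
) -> SpectralVolume:
    """Render the raw spectral interferogram volume for a phantom.

    Each A-scan records
    ``E(k) * (dc + sum_l r_l(x, y) * cos(2*k*z_l(x) + a2*kappa(k)**2))``
    plus additive Gaussian noise, with ``E`` the Gaussian source envelope,
    ``z_l`` the layer surface including tilt, curvature, per-layer axial
    jitter and the axial motion trace, ``r_l`` the (mosaic-modulated)
    reflectivity sampled at the motion-displaced lateral position, and
    ``kappa`` the centred wavenumber normalised to [-1, 1] across the band
    (``dispersion_a2`` is the unbalanced second-order dispersion in rad at
    the band edge).  Spectral samples follow the config's sampling dialect.

    Raises :class:`DepthRangeError` if any layer surface (including motion)
    leaves the unambiguous depth range.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n_slow, n_fast, n_k = config.n_slow, config.n_fast, config.n_spectral_px
    if motion is None:
        motion = MotionTrace.none(n_slow)
    if len(motion.axial_shift_um) != n_slow:
        raise ValueError("motion trace length must equal n_slow")

    rng = np.random.default_rng(seed)
    k = config.sample_k()
    env = config.source_envelope(k)
    k_min, k_max = config.k_bounds
    kappa = (k - 0.5 * (k_min + k_max)) / (0.5 * (k_max - k_min))
    disp_phase = dispersion_a2 * kappa**2

    cols = np.arange(n_fast, dtype=float)
    px = config.px_size_um
    z_max = config.depth_range_um
    ax_lo, ax_hi = motion.axial_shift_um.min(), motion.axial_shift_um.max()

    # the scan sits centred in the (possibly larger) phantom field, so that
    # lateral motion samples real structure instead of a replicated edge
    field_w, field_h = phantom.field_size_um
    nx_field = max(int(round(field_w / px)), n_fast)
    ny_field = max(int(round(field_h / px)), n_slow)
    off_x = (nx_field - n_fast) / 2.0
    off_y = (ny_field - n_slow) / 2.0

    # precompute per-layer surfaces, jitter fields and modulation images
    surfaces, modulations = [], []
    for layer in phantom.layers:
        z = phantom.surface_depth(layer, cols, n_fast)
        if layer.axial_jitter_sigma_um > 0:
            # retina-fixed surface roughness, correlated over ~a cell diameter
            # (3 um), emulating the axial irregularity of photoreceptor tips
            corr_px = 3.0 / px
            raw = rng.normal(0.0, 1.0, (ny_field, nx_field))
            sm = ndimage.gaussian_filter(raw, corr_px, mode="wrap")
            sm *= layer.axial_jitter_sigma_um / max(sm.std(), 1e-12)
            jitter = sm
        else:
            jitter = None
        j_lo = jitter.min() if jitter is not None else 0.0
        j_hi = jitter.max() if jitter is not None else 0.0
        if z.min() + ax_lo + j_lo <= 0 or z.max() + ax_hi + j_hi >= z_max:
            raise DepthRangeError(
                f"layer {layer.name!r} leaves the depth range (0, {z_max:.1f} um): "
                f"z in [{z.min() + ax_lo + j_lo:.1f}, {z.max() + ax_hi + j_hi:.1f}] um"
            )
        surfaces.append((z, jitter))
        if layer.mosaic is not None:
            modulations.append(_modulation_image(layer, px, (ny_field, nx_field)))
        else:
            modulations.append(None)

    fringes = np.empty((n_slow, n_fast, n_k), dtype=float)
    row = np.arange(n_fast, dtype=float)
    for t in range(n_slow):
        total = np.full((n_fast, n_k), float(dc_level))
        lat = motion.lateral_shift_px[t]
        # retina-fixed fields are sampled at the motion-displaced position
        coords = np.vstack([np.full(n_fast, t + off_y), row + off_x + lat])
        for layer, (z, jitter), mod in zip(phantom.layers, surfaces, modulations):
            zt = z + motion.axial_shift_um[t]
            if jitter is not None:
                zt = zt + ndimage.map_coordinates(jitter, coords, order=1, mode="nearest")
            r = layer.reflectivity
            if mod is not None:
                m = ndimage.map_coordinates(mod, coords, order=1, mode="nearest")
                amp = r * m
            else:
                amp = np.full(n_fast, r)
            total += amp[:, None] * np.cos(2.0 * zt[:, None] * k[None, :] + disp_phase[None, :])
        fringes[t] = env[None, :] * total
    if noise_sd > 0:
        fringes += rng.normal(0.0, noise_sd, fringes.shape)

    prov = [
        f"simulated seed={seed} noise_sd={noise_sd} dc={dc_level} dispersion_a2={dispersion_a2}"
    ]
    return SpectralVolume(fringes, config, prov)


# ---------------------------------------------------------------------------
# default phantom
# ---------------------------------------------------------------------------


def default_phantom(
    config: AcquisitionConfig,
    seed: int = 0,
    rpe_depth_frac: float = 0.45,
    tilt_total_um: float = 10.0,
    curvature_sagitta_um: float = 15.0,
    rpe_spacing_um: float = 16.05,
    rpe_jitter_um: float = 1.0,
    cone_spacing_um: float = 8.0,
    cone_jitter_um: float = 0.7,
    field_margin_um: float = 50.0,
) -> RetinaPhantom:
    """Fovea-like seven-layer phantom scaled to the acquisition geometry.

    The RPE sits at ``rpe_depth_frac`` of the unambiguous depth range and
    carries a jittered hexagonal cell mosaic (16.05 um centre spacing at the
    default, i.e. ~4480 cells/mm^2 and a 13.9 um row pitch); IS/OS and COST
    share a finer cone mosaic.  ``tilt_total_um`` is the depth ramp across
    the full fast axis (B-scan rotation) and ``curvature_sagitta_um`` the
    parabolic sag between field centre and edge.
    """
    w, h = config.field_size_um
    # mosaics extend beyond the scanned area so lateral motion stays on-retina
    w, h = w + 2 * field_margin_um, h + 2 * field_margin_um
    rpe_z = rpe_depth_frac * config.depth_range_um
    rpe_mosaic = make_hex_mosaic(rpe_spacing_um, rpe_jitter_um, (w, h), seed=seed)
    cone_mosaic = make_hex_mosaic(cone_spacing_um, cone_jitter_um, (w, h), seed=seed + 1)
    # photoreceptor-tip layers carry axial roughness: the tips of individual
    # cells sit at slightly irregular depths, most visibly at COST
    layers = [
        LayerSpec("ELM", rpe_z - 65.0, 0.3),
        LayerSpec("IS/OS", rpe_z - 40.0, 0.9, mosaic=cone_mosaic, axial_jitter_sigma_um=0.5),
        LayerSpec("COST", rpe_z - 20.0, 0.8, mosaic=cone_mosaic, axial_jitter_sigma_um=1.2),
        LayerSpec("ROST", rpe_z - 12.0, 0.35, axial_jitter_sigma_um=0.8),
        LayerSpec("RPE", rpe_z, 1.3, mosaic=rpe_mosaic, mosaic_spot_fwhm_um=6.0),
        LayerSpec("BM", rpe_z + 12.0, 0.25),
        LayerSpec("CC", rpe_z + 30.0, 0.15),
    ]
    return RetinaPhantom(
        layers=layers,
        tilt_slope_um_per_col=tilt_total_um / config.n_fast,
        curvature_um_per_col2=curvature_sagitta_um / (config.n_fast / 2.0) ** 2,
        field_size_um=(w, h),
    )
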