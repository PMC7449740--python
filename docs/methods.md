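# Methods

This note documents the models, conventions and numerical choices behind
`aooct`: a spectral-domain AO-OCT post-processing chain (reconstruction
with pre-FFT phase-domain geometry correction, RPE-referenced motion
correction, en-face extraction, ring-based mosaic-spacing quantification)
validated against a built-in spectral-interferogram phantom.

## Signal model and conventions

A spectrometer-based OCT system records, per A-scan, the interference
spectrum

    S(k) = E(k) · [ DC + Σ_l r_l(x, y) · cos(2 k z_l(x) + a2·κ(k)²) ] + n(k)

with `k = 2π/λ` (rad/µm), `E(k)` a Gaussian source envelope (840 nm centre,
50 nm FWHM by default), `r_l` the reflectivity of layer `l`, `z_l` its
single-pass optical-path depth in µm, `κ` the centred wavenumber normalised
to [−1, 1] over the sampled band, `a2` the unbalanced second-order
dispersion (rad at the band edge), and `n` additive Gaussian noise.  The
double pass is folded into the factor 2 of the fringe phase.  Axial index 0
is the zero-delay line (anterior); depth increases toward the choroid, so
"the first strong signal from the choroid" is a high-to-low index scan.

The spectrometer samples either uniformly in wavelength (the realistic
default, making wavenumber resampling a real operation) or uniformly in
wavenumber (for test isolation).  The default sampled span is 120 nm: wide
enough that truncating the 50 nm FWHM Gaussian at the band edges (±2.8 σ)
is negligible, so the reconstructed axial point spread matches the
coherence-length formula `(2 ln2/π)·λ₀²/Δλ` = 6.2 µm in air / 4.5 µm at a
tissue index of 1.38.  A narrower span (~60 nm) would reproduce the class
of instrument's ~2.4 mm depth range instead, at the price of a truncated
source spectrum; resolution fidelity was preferred since the axial PSF is
a validated quantity and the depth range is not.

With `N` spectral pixels spanning `Δk` and a single ×2 zero-pad, the axial
pitch is `π/(2 N δk)` per output pixel (`δk` the uniform grid step), ~1.46
µm at the defaults; the positive-depth half (N pixels) is kept.

## Reconstruction

Processing order (enforced through a provenance log; out-of-order calls
are refused):

1. **Background subtraction** — the laterally averaged spectrum (per
   B-scan by default; the averaging scope is configurable) is subtracted
   from every A-line, removing the DC/autocorrelation pedestal near zero
   delay (≥30 dB suppression of the z=0 peak in the validation suite).
   Note a physically real corollary reproduced by the phantom: a perfectly
   flat, laterally uniform reflector is cancelled by this step; real (and
   simulated) retinas survive because tilt, curvature and cellular texture
   decorrelate the fringes laterally.
2. **Wavenumber resampling** — cubic-spline (or linear) interpolation onto
   a uniform k grid spanning the same band.
3. **Phase-domain geometry correction** — each A-line is multiplied by
   `exp(i·φ)` with

       φ(x, j) = a2·κ_j² + 2π · (j / 2N) · Δz(x),
       Δz(x) = s·(x − x₀) + c·(x − x₀)²,

   i.e. second-order dispersion compensation plus a linear phase ramp
   whose slope varies linearly (B-scan rotation, `s`) and quadratically
   (retinal curvature, `c`) with the A-scan column about the fast-axis
   centre `x₀`.  `s` and `c` are parameterised directly as *output pixels
   of axial shift* per column (and per column²), because the raw rad/sample
   slope is meaningful only through the shift it induces; the conversion to
   the spectral ramp is internal.  The sign convention
   (`shift_posterior_positive`) is recorded in the provenance: positive Δz
   moves structure deeper.  Integer Δz reproduces circular shifts exactly
   and fractional Δz equals band-limited (Dirichlet) interpolation to
   1e-6, which is the point of correcting before the FFT: sub-pixel
   geometry without extra zero-padding.
4. **FFT** — unnormalised forward FFT after one ×2 zero-pad; no spectral
   window by default (a Hann option exists for sidelobe studies).

Correction parameters mirror the manual workflow of tuning on a displayed
B-scan: the CLI offers a `--preview` mode rendering the first corrected
B-scan, and the pipeline's manifest reports a within-B-scan RPE flatness
diagnostic so an uncompensated rotation/curvature is flagged rather than
silently propagated.

## Motion correction

**Axial.** Per B-scan, intensity is averaged over the fast axis and the
profile is searched from the deepest index anteriorly; the first local
maximum above `threshold` × (profile max) with a prominence guard is the
RPE.  The default threshold of 0.5 skips the weaker choriocapillaris and
Bruch's-membrane bands; it presumes the RPE dominates its posterior
neighbours, which holds for this instrument class because the focus and
wavefront correction are referenced to the RPE.  B-scans without a
qualifying peak are flagged and interpolated from neighbours, never
zeroed.  Correction shifts whole B-scans by integer pixels (sub-pixel
geometry is already handled pre-FFT) and zero-fills vacated rows.

**Lateral.** The shift between successive B-scans is the fast-axis
component of the peak of their 2D intensity cross-correlation, accumulated
into a trace with the first frame as reference; correcting shifts each
B-scan by minus its cumulative shift, and the usable fast-axis field
(columns populated in every frame) is reported — this is why a corrected
4° scan yields a slightly narrower usable field.  Four preprocessing steps
make the bare recipe robust on a cell-mosaic scene:

* restriction to the retina band (depths above 5% of the volume-mean
  profile maximum) — signal-free depths dilute the peak;
* log scaling, taming bright-layer dominance;
* removal of each B-scan's mean A-scan profile — horizontal layer stripes
  are translation-invariant along the fast axis and would pin the peak at
  zero lag;
* removal of the across-frame mean image (fixed-pattern removal) — any
  scan-frame-static texture biases the peak toward zero lag;

plus a ±8 px pairwise search range (at hundreds of B-scans per second,
per-frame eye motion is small even during microsaccades; the quarter-width
sanity bound applies to the cumulative trace).  Optional parabolic
sub-pixel refinement is off by default.  Slow-axis (y) motion is *not*
corrected — the correlation is strictly between successive B-scans — and
is a known limitation.

Pairwise chaining accumulates scene-induced bias on a periodic mosaic;
with the full 750-column B-scans of the default geometry the recovered
trace stays within ±1 px of truth, while on small (≲400-column) test
volumes occasional 2 px drift remains.  The validation suite therefore
exercises this property at the full B-scan width.

## Layers and en-face images

After flattening, every posterior layer sits at a fixed offset from the
RPE, so layers are windows (`offset ± half-width`, µm) relative to the
median detected RPE depth rather than independently re-segmented; the
defaults (IS/OS −40, COST −20, ROST −12, RPE 0, BM +12, CC +30 µm, half
width 5 µm) match the default phantom anatomy.  Out-of-model curvature
(e.g. near the papilla in real data) is reported by the flatness
diagnostic, not fixed.  En-face images reduce intensity over the window
(mean by default; sum and max available; `mean × window length = sum`
exactly).

## Mosaic-spacing estimation

The 2D FFT magnitude of an en-face mosaic image shows an annulus whose
radius is the mosaic's dominant spatial frequency.  The estimator averages
the centred FFT magnitude over annular bins of equal radial width
(anisotropy is averaged away by construction), masks frequencies below a
DC exclusion (default 1/100 µm⁻¹), lightly smooths (3-bin moving average),
takes the argmax (ties toward lower frequency, parabolic sub-bin
refinement), and reports its reciprocal.  **The reported spacing is
row-to-row**: for a triangular lattice the first-order ring sits at
`1/row_spacing` with `row_spacing = (√3/2) × centre-to-centre spacing` —
this conversion is the single most error-prone convention in the field.
A peak/median prominence below 3.0 flags the estimate invalid (spacing
NaN), never a silent guess.  The profile uses FFT magnitude; a power
option would only square the contrast and does not move the argmax.

Two display filters accompany the estimator: a Fourier band-pass keyed to
structure size in pixels (fourth-order super-Gaussian band edges with
half-power points at the `low`/`high` structure sizes, zero DC — matching
the behaviour, not the bits, of the common 1–50 px band-pass used for
mosaic display) and a disc mean filter (radius in px, reflective edges).

A note on field size: with radial averaging, the ring's peak/median ratio
is nearly field-size invariant (the lattice's Bragg spots are diluted by
the annulus average in proportion to the field), but the ring's height
above the *background fluctuation* of the profile grows with field size,
which is what makes the larger field genuinely more reliable when noise
limits mosaic visibility.  The test suite asserts the latter property.

## The phantom

`default_phantom` builds a fovea-like seven-layer stack (ELM, IS/OS, COST,
ROST, RPE, BM, CC) with the RPE at 45% of the depth range and fixed
offsets for the rest.  Reflectivities (0.3, 0.9, 0.8, 0.35, 1.3, 0.25,
0.15) are a stand-in — no reflectance model is claimed — chosen so the
laterally averaged profile has the RPE as the dominant posterior band, as
the RPE-referenced detection presumes.  Features:

* **Mosaics** — jittered hexagonal point sets; RPE at 16.05 µm centre
  spacing (≈4,482 cells/mm², 13.9 µm row pitch) with 1 µm jitter, cones at
  8 µm with 0.7 µm jitter.  Mosaic contrast is multiplicative on the layer
  reflectivity: factor 1 at cell centres, 0.3 between cells — chosen so
  the ring is detectable at the default noise level.
* **Geometry** — a linear depth ramp across the fast axis (B-scan
  rotation; default 10 µm across the field) and a parabolic sag (retinal
  curvature; default 15 µm at the field edge), both scanner-frame, so the
  pre-FFT corrections can invert them exactly.
* **Axial roughness** — photoreceptor-tip layers carry retina-fixed
  surface roughness (Gaussian, σ 0.5/1.2/0.8 µm for IS/OS/COST/ROST,
  laterally correlated over ~3 µm), reflecting the observed axial
  irregularity of cone tips.  This matters beyond realism: a strictly
  periodic lattice makes inter-B-scan registration ambiguous.
* **Field margin** — mosaics extend 50 µm beyond the scanned area with the
  scan centred, so lateral motion samples real structure rather than a
  replicated edge.
* **Motion** — per-B-scan axial shifts (µm, continuous) and lateral shifts
  (integer fast-axis pixels), first frame zero; default random walk with
  0.8 µm axial steps and ±1 px lateral steps.
* **Noise** — additive Gaussian on the spectral samples (default sd 0.2,
  ~27 dB peak image SNR at the RPE).

What the phantom does **not** model: speckle (Gaussian spectral noise plus
jittered mosaics stand in; the ring estimator is a spatial-frequency
method robust to the noise family), polarisation and depolarisation,
eye-aberration PSFs across the field, vignetting, slow-axis motion within
a B-scan, and rod/cone outer-segment dynamics.  Passing tests therefore
demonstrate the correctness of the *processing chain* under controlled
geometry, motion and noise — not performance on in-vivo data, where
speckle and aberration-limited mosaic visibility are the dominant
difficulties.

## Problem sizes used in validation

Unit and property tests run on reduced geometries (64–256 A-scans per
B-scan, 96–256 B-scans, 128–256 spectral pixels) that preserve the axial
pitch and lateral sampling of the full 750×750×800 default; the
lateral-motion recovery property runs at the full 750-column B-scan width
with a reduced B-scan count, and the headline mosaic-spacing recovery runs
at the full 750×750 en-face size.  The acceptance script regenerates the
mosaic-spacing experiment (ten 750×750 renders) from scratch in a few
seconds.

## Numerical details

* FFT normalisation: unnormalised forward transform throughout, so dB
  comparisons are internally consistent.
* Correction-parameter safety: rotation/curvature implying shifts beyond
  half the axial range are refused (no wrap-around); axial-correction
  shifts beyond half the depth range and lateral shifts beyond a quarter
  of the fast axis indicate estimation failure and are refused.
* Degenerate inputs: empty point sets render as all-zero images (logged);
  featureless B-scan pairs carry the previous lateral shift forward;
  profiles with no unmasked bins raise.
* Determinism: every stochastic component takes an explicit seed;
  identical seeds give bit-identical volumes and byte-identical pipeline
  outputs.
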