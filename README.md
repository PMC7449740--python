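# aooct

Post-processing for spectral-domain adaptive-optics OCT (AO-OCT) of the
posterior retina: from raw spectral fringes to motion-corrected volumes,
en-face layer images, and quantitative photoreceptor / retinal pigment
epithelium (RPE) mosaic spacing — with a built-in phantom simulator that
generates raw interferogram volumes with known ground truth, so every
stage of the chain can be validated end to end.

It is written for people building or studying AO-OCT processing pipelines:
the in-vivo data such instruments produce is rarely public, so
the package ships the forward model (a layered retina with jittered
hexagonal cone and RPE cell mosaics, B-scan tilt, retinal curvature,
dispersion mismatch, eye motion and noise) alongside the inverse chain
that undoes it.

## The processing chain

For each A-scan the spectrometer records
`S(k) = E(k)[DC + Σ_l r_l cos(2 k z_l + a₂κ²)] + n(k)`.
Reconstruction follows standard spectral-domain OCT practice with one
distinctive step — geometry correction applied as a *phase* in the
spectral domain, before the FFT:

1. subtract the laterally averaged spectrum from each A-line;
2. resample onto a uniform wavenumber grid;
3. multiply each A-line by `exp i[a₂κ² + 2π(j/2N)·Δz(x)]` where
   `Δz(x) = s(x−x₀) + c(x−x₀)²` — dispersion compensation (`a₂`) plus an
   axial shift per column that is linear in the column for B-scan
   rotation (`s`) and quadratic for retinal curvature (`c`), in units of
   output pixels; by the Fourier shift theorem this realises sub-pixel
   shape correction with no image-domain interpolation;
4. zero-pad once to double the axial pixel count, FFT, keep the
   positive-depth half.

Motion is then corrected between B-scans: axially by detecting the RPE as
the first strong peak of the laterally averaged A-scan walking from the
choroid anteriorly, and aligning it across B-scans; laterally from the
peak of the cross-correlation between successive B-scans.  Layers are
segmented as fixed depth windows relative to the RPE reference and
reduced to en-face images.

Mosaic regularity is quantified from the en-face image by the ring in its
2D Fourier magnitude: the spectrum is converted to polar coordinates,
averaged per radius, and the peak frequency `f` of the resulting radial
profile gives the **row-to-row** spacing `1/f` — for a triangular mosaic
of centre-to-centre spacing `a`, the row spacing is `a·√3/2`, and a
density of 4,482 cells/mm² corresponds to a 13.9 µm row spacing.

## Worked example

Run the full chain on a simulated 256×256 A-scan volume (1.6 µm lateral
pitch, default retina with an RPE mosaic at 16.05 µm centre spacing):

```
$ cat example.yaml
acquisition:
  n_spectral_px: 256
  n_fast: 256
  n_slow: 256
  fov_deg: 1.3653333333333333
phantom:
  tilt_total_um: 5.0
  curvature_sagitta_um: 8.0
mosaic:
  n_bins: 128

$ aooct run --config example.yaml --out run1 --seed 5
{
 "rpe_residual_range_px": 1.0,
 "rpe_flat": true,
 "rpe_bscan_range_px": 0.6425985939958707,
 "bscan_flat": true,
 "lateral_log": "lateral_corrected:usable_fast_px=230",
 "row_spacing_um": 13.776557789556618,
 "peak_frequency_cyc_per_um": 0.07258707256743441,
 "peak_prominence": 8.321698331299958,
 "spacing_valid": true
}
```

Reading the diagnostics: after correction the detected RPE depth varies by
at most 1 pixel between B-scans (`rpe_flat`) and by 0.64 pixels across the
central B-scan (`bscan_flat` — tilt and curvature were compensated by the
pre-FFT phase terms); lateral motion correction left 230 of 256 columns
usable; and the ring estimator recovered a 13.78 µm row spacing from the
RPE en-face image — the simulated lattice's true row pitch is
16.05·√3/2 = 13.90 µm.  The run directory contains the raw volume and
ground truth, reconstructed intensity TIFF, motion traces (CSV), per-layer
en-face TIFFs, the radial profile (CSV), and a JSON manifest with every
stage's parameters and output checksums.

The library mirrors the CLI one-to-one, e.g.:

```python
from aooct import (AcquisitionConfig, default_phantom, simulate_spectra,
                   subtract_background, resample_to_k, reconstruct_volume,
                   CorrectionParams)

acq = AcquisitionConfig(n_spectral_px=256, n_fast=256, n_slow=256,
                        fov_deg=256 * 1.6 / 300)
phantom = default_phantom(acq, seed=5)
raw = simulate_spectra(phantom, acq, noise_sd=0.2, seed=5)
vol = reconstruct_volume(resample_to_k(subtract_background(raw)),
                         CorrectionParams())
```

Instrument arithmetic used for sanity checks is available as
`aooct metrics axial-res|marechal|sampling|frames` (840 nm / 50 nm FWHM →
4.5 µm axial resolution in tissue; 840/14 = 60 nm diffraction-limit RMS
budget; 4° × 300 µm/° / 750 px = 1.6 µm sampling; 50 ms × 300 B-scans/s =
15 B-scans per wavefront-sensor exposure).

## Layout

| module | contents |
| --- | --- |
| `aooct.phantom` | acquisition config, layered retina, hex mosaics, motion traces, interferogram simulator |
| `aooct.reconstruction` | background subtraction, k-resampling, correction phase, FFT reconstruction |
| `aooct.motion` | RPE-trace detection, axial and lateral correction |
| `aooct.enface` | RPE-referenced layer windows, depth-integrated en-face images |
| `aooct.mosaic` | radial FFT profile, row-spacing estimator, band-pass and mean display filters |
| `aooct.optics` | closed-form instrument arithmetic |
| `aooct.io`, `aooct.pipeline`, `aooct.cli` | file formats, validated config, end-to-end runner, CLI |

See `docs/methods.md` for the model conventions, parameter defaults and
what the phantom does and does not emulate.
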