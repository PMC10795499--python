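# Methods

## Optical model

The instrument is modeled entirely in Mueller calculus. Unpolarized
halogen light passes a **generator** polarizer (transmission axis 45°),
the sample, and an **analyzer** made of LCVR 1 (fast axis 0°, retardance
δ₁), LCVR 2 (fast axis 45°, retardance δ₂) and a horizontal polarizer.
The detected intensity for sample-exit Stokes vector S is

I(δ₁, δ₂) = ½ (S0 + S1·cos δ₂ + S2·sin δ₁ sin δ₂ − S3·cos δ₁ sin δ₂).

The four analyzer states are H = (0, 0), V = (0, π), P45 = (π/2, π/2)
and RC = (0, **−π/2**), giving Iₕ = ½(S0+S1), Iᵥ = ½(S0−S1),
I₄₅ = ½(S0+S2), Iᵣ꜀ = ½(S0+S3), so the reconstruction

S0 = Iₕ+Iᵥ, S1 = Iₕ−Iᵥ, S2 = 2I₄₅−(Iₕ+Iᵥ), S3 = 2Iᵣ꜀−(Iₕ+Iᵥ)

is exactly the identity on noiseless data.

**Sign convention.** Retarders use the standard textbook matrix (S3 row
`[0, s·sinδ, −c·sinδ, cosδ]`, c = cos 2θ, s = sin 2θ). Under it a
quarter-wave plate at fast axis θ turns the 45° generator light into
(1, sin2θ cos2θ, sin²2θ, −cos2θ), matching the analytic calibration
curves. Consistency then forces the circular state to δ₂ = −π/2: with
+π/2 the reconstructed S3 flips sign and the calibration sweep returns
+cos2θ. Which physical handedness "right circular" denotes (source vs.
receiver view) is not decidable from intensity data alone; only the
internal consistency above is claimed. Both the analyzer chain and the
canonical-state table in `phsi.polarization` document this.

Cubes are indexed (row, col, band), row 0 at the top, 0-based. The
instrument axis is 470–750 nm with 97 bands; all simulation defaults use
a 21-band axis over the same range (470–750 nm, 14 nm steps) so that the
full test suite and the acceptance script run in seconds on one CPU —
the full-resolution 1200 × 1200 × 97 geometry is available via
`SpectralAxis.default()` and the `shape` config key.

## Normalization and degenerate pixels

`normalize_stokes` divides S1–S3 by S0 where |S0| > ε,
ε = 10⁻⁹ · max|S0| by default. Pixels at or below ε become NaN and are
flagged in a validity mask that every downstream statistic respects;
they are never silently zeroed. Noise can push reconstructed vectors
outside the physical cone S1²+S2²+S3² ≤ S0²; such pixels are counted and
logged but retained unmodified.

Gaussian element-image noise of std σ propagates through the
reconstruction to std √2·σ on S0 and S1 and √6·σ on S2 and S3 (the
coefficient vectors are (1,1), (1,−1) and (2,−1,−1)); the tests assert
these exact factors within sampling tolerance.

## Scene simulator

A `Scene` is a per-pixel (optionally per-band) field of 4 × 4 Mueller
matrices; acquisition applies the generator spectrum, the scene matrix,
and each analyzer state, then detector noise. What the phantoms emulate
— and what they do not:

- **QWP target**: an ideal achromatic quarter-wave retarder, uniform
  over the field. Real LCVRs and wave plates are chromatic; an optional
  δ(λ) = δ₀·λ₀/λ dispersion can be attached via per-band scenes, but the
  default is achromatic because the calibration analysis normalizes per
  band anyway.
- **Fiber phantom** (collagen analog): anti-aliased capsule segments
  whose fast axis follows the fiber direction, drawn over a neutral
  absorbing background. Defaults: 12 fibers on 64 × 64, width 3 px,
  length ~40 px, peak retardance 0.6 rad (a collagen-scale tens-of-nm
  path difference at mid-visible wavelengths), background and fiber
  transmittance both 0.9 — *matched on purpose*, so the fibers carry no
  intensity signature and the polarization contrast claim is tested in
  its hardest setting. `density="sparse"` quarters the fiber count.
  These optical constants are illustrative, not tissue-calibrated.
- **Cell phantom** (H&E analog): cytoplasm/nucleus disks with
  wavelength-dependent absorbance (Gaussian lobe peaking at 550 nm,
  hematoxylin-like; nucleus 0.7, cytoplasm 0.3 peak absorbance), a small
  residual nuclear retardance (0.05 rad), optional multi-lobed
  fragmentation. `nucleus_orientation_deg` fixes the nuclear fast axis
  (default: random per cell); a fixed orientation models anisotropic
  tissue and is what makes group-level S3 differences detectable, since
  randomly oriented retarders average to zero circular signature.

Not modeled: scattering and depolarization, diffraction/defocus,
radiometrically accurate dye spectra, camera spatial response. Passing
phantom tests therefore demonstrates the correctness of the processing
chain and the *direction* of the contrast and spectral effects, not
quantitative agreement with any real slide.

**Noise.** Default `NoiseSpec` is Poisson shot noise at 10⁴ expected
counts per unit intensity plus Gaussian read noise of std 10⁻³ — a
well-exposed scientific camera; at these levels the simulated
calibration RMSE is ~10⁻³. All randomness flows through one explicit
integer seed per call (sweeps derive one child seed per angle via
`numpy.random.SeedSequence`); there is no hidden global state.

## Calibration

The quarter-wave-plate sweep uses fast-axis angles 0–180° in 10° steps
(N = 19). Per angle the Stokes cube is reconstructed, normalized, and
**averaged over valid pixels** — the target is spatially uniform, so the
field mean is the natural reduction. RMSE per parameter and wavelength
is the mean-normalized form √(Σ(exp−theory)²/N). Reporting wavelengths
snap to the nearest band center with a logged warning (on the 21-band
axis, 525 → 526 nm and 626 → 624 nm).

## Synthetic RGB

Channels are convex band combinations: each response curve is
nonnegative and normalized to unit sum. Defaults are raised-cosine lobes
peaking at 610/540/470 nm (half-width 90 nm) — qualitative, fully
overridable via CSV; no colorimetric fidelity is claimed, and the S0
rendering is only an H&E-like analog. Signed cubes are mapped to [0, 1]
first: `symmetric` ([−a, a] → [0, 1], a = max|value|; the default for
S1–S3, with zero at mid-gray), `minmax`, or `identity` (default for S0
after division by its maximum). Per-parameter scaling is the default;
the mode and scale are recorded in each image's provenance. Because
`symmetric`/`minmax` scales are data-dependent, rendering commutes with
cropping only when an explicit `scale` is supplied — the API accepts one
for exactly that use.

## Quantification

**GLCM contrast** quantizes a [0, 1] image into `n_levels` = 8 uniform
bins over the fixed [0, 1] range (not the image range), pools
co-occurrence counts over the four standard neighbor offsets
(0, 1), (1, 0), (1, 1), (1, −1) — "adjacent" is direction-ambiguous, so
all four are used — symmetrically by default, and returns
Σ((i−j)/(L−1))²·p(i, j). The level-difference normalization bounds the
score by 1 for full-range images; a constant image scores 0 and a
two-level checkerboard against a single horizontal offset scores 1.
Pooling counts before normalizing is exactly equivalent to a brute-force
double loop over all in-bounds pixel pairs, which the tests verify
literally. Contrast is computed on the luminance grayscale
(Rec. 709 weights) of the synthesized RGB by default; a single band can
be scored instead.

**ROI spectra** use population standard deviation (divide by n) and
exclude normalization-masked pixels band-wise. **Per-band comparison**
is Welch's unequal-variance two-sample t test by default (Student's
pooled variant selectable), one average spectrum per ROI as the sampling
unit; raw p values are reported, with an optional Benjamini–Hochberg
column. Bands where both groups have zero variance report t = 0, p = 1
with a log note. As with any per-cell design, ROIs from one slide are
not strictly independent samples; group-level p values should be read
accordingly.

## Problem sizes and numerical choices

Test and acceptance runs use 64 × 64 × 21 cubes (19-angle sweeps: ~6.5 M
intensities per sweep), 200-replicate null calibrations at 5 vs 5 ROIs
over 8 bands, and 10-seed phantom batteries — sizes chosen so the whole
battery completes in seconds while keeping sampling error well inside
the asserted tolerances. Noiseless roundtrip assertions use 10⁻¹⁰
(relative to the field maximum); matrix identities use 10⁻¹²–10⁻¹⁵.
ENVI I/O stores data in the array's own floating dtype so round trips
are bit-exact; unsorted wavelength lists are reordered ascending with a
warning.

## Known limitations

- No depolarization or Mueller-matrix (16-element) imaging; the scene
  model is deterministic per pixel.
- Phantom optics are illustrative; no claim of quantitative agreement
  with tissue measurements.
- The RC handedness is a convention pinned by internal consistency, not
  a physical determination.
- The CLI's `ttest` consumes per-ROI mean-spectrum CSVs; automated ROI
  segmentation is out of scope (masks are inputs).
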