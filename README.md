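# phsi — polarized hyperspectral microscopy toolkit

`phsi` simulates and processes **full-Stokes polarized hyperspectral
imaging (PHSI)** of histopathology slides. In a PHSI microscope a linear
polarizer at 45° illuminates the sample; behind it, two liquid-crystal
variable retarders (LCVR 1 at 0°, LCVR 2 at 45°) and a horizontal
polarizer form a switchable analyzer. Four analyzer states yield the
element-image cubes *I*ₕ, *I*ᵥ, *I*₄₅, *I*ᵣ꜀ (each rows × cols × bands over
470–750 nm), from which the Stokes parameters are reconstructed per pixel
and band:

```
S0 = Ih + Iv          S2 = 2·I45 − (Ih + Iv)
S1 = Ih − Iv          S3 = 2·Irc − (Ih + Iv)
```

Birefringent structures such as fibrillar collagen barely register in the
intensity image S0 but imprint strongly on S1–S3 — the basis for
enhanced-contrast visualization of collagen and cell morphology on H&E
slides. The toolkit provides:

- **Mueller/Stokes core** — polarizer and retarder matrices, the four
  analyzer states, Stokes reconstruction and S0-normalization
  (`phsi.polarization`);
- **scene simulator** — per-pixel Mueller-matrix phantoms
  (quarter-wave-plate target, birefringent fiber fields, absorbing cell
  fields) and virtual acquisition with seeded Poisson + Gaussian detector
  noise (`phsi.simulate`);
- **calibration** — the rotating quarter-wave-plate protocol: sweep the
  plate fast axis 0–180° in 10° steps, compare the reconstructed
  normalized parameters with the analytic curves
  s1 = sin 2θ cos 2θ, s2 = sin²2θ, s3 = −cos 2θ, and report the RMSE
  per parameter at chosen wavelengths (`phsi.calibrate`);
- **synthetic RGB** — band-weighted three-channel renderings of any
  Stokes cube with configurable spectral response curves
  (`phsi.visualize`);
- **quantification** — gray-level co-occurrence (GLCM) contrast,
  masked-ROI mean ± std spectra, and per-band two-sample t tests between
  ROI groups (`phsi.quantify`);
- **I/O + CLI** — ENVI and multi-page TIFF cubes, PNG masks, YAML run
  configs with reproducibility snapshots, and the `phsi` command
  (`phsi.io`, `phsi.cli`).

## Worked example

Simulate a collagen-like fiber phantom whose fibers have the *same*
transmittance as the background (invisible by intensity alone),
reconstruct the Stokes cubes, and render them:

```sh
phsi --seed 0 simulate --phantom fiber --shape 64 64 -o elems
phsi stokes elems --normalize -o stokes
phsi rgb --cube stokes --param S3 -o s3.png
phsi contrast --image s3.png
```

prints `0.019195`: the GLCM contrast of the S3 rendering. Doing the same
in Python for all four parameters:

```python
import phsi
from phsi.quantify import glcm_contrast, rgb_to_gray

axis = phsi.SpectralAxis.test_scale()
scene = phsi.make_fiber_scene(phsi.FiberPhantomParams(), (64, 64), axis, seed=0)
images = phsi.simulate_acquisition(scene, noise=phsi.NoiseSpec(seed=0))
cube = phsi.normalize_stokes(phsi.compute_stokes(images))
for name, rgb in phsi.render_stokes(cube).items():
    print(name, round(glcm_contrast(rgb_to_gray(rgb)), 4))
```

```
S0 0.0
S1 0.0137
S2 0.0014
S3 0.0192
```

S0 scores zero — the matched-transmittance fibers are invisible in
intensity — while every polarized parameter picks them up, S3 most
strongly. A noiseless calibration run,

```sh
phsi calibrate --no-noise -o cal
```

reports `max RMSE = 3.7e-14`: the reconstruction inverts the simulated
optics exactly; with the default detector noise the RMSE stays near
1e-3, far inside the 0.2 acceptance bound used for the physical
instrument.

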