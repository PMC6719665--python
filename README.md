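# cryomerge

Tools for merging cryo-EM single-particle datasets collected at different
magnifications.

When two datasets of the same specimen are collected on different microscopes
(or at different nominal magnifications), their pixel sizes rarely agree —
and the *nominal* pixel size reported by a facility can be off by several
percent.  Before the particles can be refined against one 3D reference, the
relative pixel size must be determined empirically and every piece of the
data — micrographs, particle images, picked coordinates, defocus values —
brought onto one common scale.  `cryomerge` implements that workflow for
RELION-style projects (MRC maps/stacks, `_rln` STAR metadata):

1. **Calibrate** the relative pixel size from two independent
   reconstructions: a coarse scan that rescales one map to a grid of
   candidate pixel sizes and ranks them by Fourier shell correlation (FSC)
   against the fixed reference, then a continuous golden-section refinement
   of the real-space correlation coefficient.
2. **Harmonize** either at the micrograph level (*rescale micrographs, then
   re-pick/re-extract* — Method 1) or at the particle level (*rescale
   particles during extraction with an even box pair, then crop* — Method 2).
3. **Join** the harmonized STAR tables, with a guard that refuses silently
   mismatched scales.

## The core quantities

* Reciprocal-space pad/crop rescaling can only change an even box of `N`
  pixels in steps of 2, so the achievable pixel size is quantized with step
  `Δa = 2·a/N` — 2% of the pixel size for a 100-pixel box, 1% for a
  200-pixel box.  The calibration scan therefore reports a *plateau* of
  equally scoring pixel sizes, and a continuous real-space refinement
  resolves below that step.
* FSC between maps with transforms `F₁, F₂`, per shell `s` of integer
  Fourier radius: `FSC(s) = Re Σ F₁·F₂* / √(Σ|F₁|²·Σ|F₂|²)`.
* Fitted defocus depends on the square of the assumed pixel size: correcting
  `0.900 → 0.880` Å/px multiplies defocus by `(0.880/0.900)² = 0.956049`.
  The spherical-aberration term is quartic: `Cs → Cs·(0.900/0.880)⁴`.
* Scaling straight to a target box is usually impossible with even boxes
  (`420 × 1.120/0.880 = 534.5`); the even-box-pair search finds the pair in
  range whose ratio best matches `start_apix/target_apix` — for the case
  above, extract 560 → scale 440 hits the ratio exactly.

## Worked example

Find the even box pair for rescaling 0.880 Å/px particles into a
1.120 Å/px frame, searching boxes 420–600:

```console
$ cryomerge boxscale --min 420 --max 600 --start-apix 0.880 --target-apix 1.120 -n 1
Start with a 560 pixel box, scale to a 440 pixel box
This will give a scaling factor of 0.78571, compared to a desired pixel size ratio of 0.78571, giving a 0.000 per cent error.
```

The ratio 440/560 = 11/14 equals 0.880/1.120 exactly, so particles extracted
at 560 px and rescaled to 440 px land at exactly 1.120 Å/px (then
`cryomerge window --box 420` crops them to the reference box).

Calibrate the relative pixel size of two synthetic reconstructions of the
same phantom — one at 1.40 Å/px, the other truly at 1.28 Å/px but declared
as 1.36 (a 6% error):

```console
$ cryomerge calibrate --ref-map map1.mrc --angpix-ref 1.40 \
      --map map2.mrc --angpix-nominal 1.36
BEST:1.275 range:1.275 - 1.275
REFINED:1.2750 cc:0.8858
```

The scan localizes the true pixel size to within its granularity step
(`2 × 1.28 / 64 ≈ 0.04` Å for these 64-pixel test maps; larger boxes scan
proportionally finer), recovering ≈1.28 despite the 6% misdeclaration.
Rescale CTF metadata for the corrected pixel size:

```console
$ cryomerge scale-ctf micrographs_ctf.star --old-apix 0.900 --new-apix 0.880 \
      --o micrographs_ctf_newapix.star
Acceleration voltage read as 300, will use electron wavelength of 0.0197 A
Defocus scaled by 0.956049
Wrote out micrographs_ctf_newapix.star
```

The library surface mirrors the CLI: `scan_relative_pixel_size`,
`refine_scale_realspace`, `fourier_rescale`, `scale_ctf_table`,
`find_box_pairs`, `extract_particles`, `merge_datasets`, and the end-to-end
`run_method1` / `run_method2` (see `docs/methods.md`).

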