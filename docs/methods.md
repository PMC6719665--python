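# Methods

This note records the models, conventions and design choices behind
`cryomerge`, and what the synthetic tests do and do not demonstrate.

## Problem setting

Two single-particle datasets of the same specimen are collected at different
(and imperfectly known) pixel sizes.  Merging them requires (a) estimating
the true pixel size of one dataset *relative* to the other, and (b)
rewriting images and metadata so both datasets live on one grid.  All
operations act on MRC volumes/stacks and RELION ≤3.0 STAR tables;
optics-group STAR files (RELION ≥3.1) are explicitly rejected rather than
half-supported.

## Rescaling by reciprocal-space pad/crop

`fourier_rescale` changes the pixel size of a map, micrograph or movie by
forward FFT, symmetric crop or zero-pad of the centered spectrum, inverse
FFT.  Conventions, all load-bearing:

* **Even boxes only.** Odd sizes raise; the one internal rounding (the new
  box of `fourier_rescale`) goes to the *nearest* even integer and the
  achieved pixel size `N·a/N'` is reported back.  Achievable pixel sizes are
  therefore quantized with step `granularity(N, a) = 2a/N`.
* **Centering.** After `fftshift` the DC term sits at index `N//2` in every
  dimension and pad/crop is symmetric about it.  This makes the identity
  rescale exact, makes up/down round trips exact for band-limited content,
  and keeps the image center fixed so a centered particle stays centered.
  The residual sub-pixel origin shift that rescaling introduces is handled
  by explicit translational registration, never assumed away.
* **Amplitudes.** The spectrum is renormalized by the voxel-count ratio so
  grey values (and the mean) are preserved.  Under pure zero-padding the
  pad/crop step conserves total spectral power exactly (Parseval), which the
  tests check to 1e−6 relative.
* **Stacks and movies** rescale frame by frame with the same spatial factor;
  frames are never mixed.

`fourier_rescale_to_box` is the extraction-time variant: exact factor
`scaled_box/extract_box`, achieved pixel size `a·extract/scaled`.
`crop_window`/`pad_window` are centered real-space windows that leave the
pixel size untouched; `resample_real_space` re-declares a map's pixel size
(keeping the center voxel in place) and interpolates it trilinearly onto a
reference grid, with zeros outside — the route used when two maps must share
a grid exactly.

## Map comparison

FSC uses shells one Fourier voxel wide (integer radius) up to Nyquist.  The
scalar score used for ranking candidate pixel sizes is the mean FSC over all
shells excluding DC: simple, monotone under uniform improvement, and stable
on phantoms.  It is *not* a resolution estimate; shells beyond the signal
band contribute near-zero terms that dilute but never reorder a uniform
improvement.  Real-space similarity is the Pearson correlation over voxels
(optionally inside a `>0.5` mask); it is affine-invariant, so brightness and
offset conventions cannot masquerade as agreement.  Translational
registration maximizes circular cross-correlation at integer shifts, then
refines each axis with a three-point parabola; sub-voxel shifts are applied
as Fourier phase ramps.

## Pixel-size calibration

The coarse scan declares the target map at each candidate pixel size (grid
centered on the nominal value, default halfwidth ±10%, step
`max(granularity, 0.002 Å)`), resamples it onto the reference grid,
*re-registers it per candidate* (rescaling shifts the origin), and scores by
mean FSC.  Candidates scoring within `plateau_tol` (default 1e−3) of the
best define the reported range — the FSC simply cannot distinguish pixel
sizes closer than the pad/crop step, so a plateau, not a peak, is the honest
output.  The dataset with the larger pixel size is the reference and is held
constant; the API warns (but does not refuse) when called the other way
around.

The continuous refinement maximizes the real-space correlation coefficient
over the plateau by golden-section search (default tolerance 1e−4 Å), with a
7-point pre-sample that both tightens the bracket and detects
multi-modality (warned, not fatal).  Trilinear resampling is continuous in
the pixel size, so this stage is not granularity-limited.

## CTF metadata scaling

Correcting an assumed pixel size from `old` to `new` maps every digital
frequency to a new physical frequency (`k → k·old/new`), so the fitted
defocus — quadratic in frequency — must be multiplied by `(new/old)²`, and a
fixed Cs — quartic — would need `(old/new)⁴`.  `scale_ctf_table` applies the
defocus factor and normalizes `_rlnMagnification`/`_rlnDetectorPixelSize` so
the implied pixel size equals the corrected one.  Defaults and choices:

* **Constant correction off by default.** The quadratic factor is exact for
  the defocus term; the residual is the Cs term's quartic mismatch.  The
  usual practice is to keep Cs fixed and let per-dataset CTF refinement
  absorb the residual.
* **`phase_match` mode** adds the constant
  `c = (Cs·λ²/2)·k_ref²·(s⁴−1)/s²`, `s = old/new`, `k_ref = 1/ref_resolution`
  in the original frame, derived by requiring equality of
  `χ(k) = πλΔz k² − (π/2)Cs λ³k⁴` at `k_ref`; the tests verify the phase
  match to 1e−6 rad against that oracle evaluated directly.  Under the
  opposite Cs sign convention the same magnitude applies with opposite sign.
* Cs is millimetres at the API surface and in STAR columns; conversions to Å
  (1 mm = 1e7 Å) are centralized.  The astigmatism angle is a pure rotation
  and is never rescaled.
* The electron wavelength uses the standard relativistic closed form
  `λ = 12.2639/√(V(1 + 0.97845e−6·V))` Å with `V` in volts.

## Particle operations

* **Coordinates are continuous** throughout; extraction rounds to the
  nearest pixel for windowing and stores the sub-pixel residual in
  `_rlnOriginX/Y`, preserving information for later refinement.  Edge
  particles are skipped and counted, never zero-padded.
* **Even-box-pair search**: exhaustive over even pairs with *both* boxes in
  the requested range.  The lower bound applies to the scaled box too
  because the workflow ends by cropping down to the final box — a scaled box
  below it would be useless.  (An unconstrained search would prefer
  420 → 330 over 560 → 440 for the 0.880/1.120 case; both are exact, but
  330 < 420 cannot be cropped to 420.)
* **Background normalization**: the background-circle diameter is specified
  in extraction-frame pixels (the frame in which
  `0.75·420·1.120/0.880 → 400` holds) but normalization is applied to the
  rescaled particle with the circle scaled by `scaled/extract`.  Normalizing
  before the rescale would bake the raw (full-band) noise SD into the
  particle scale, while the micrograph-rescaling route sees low-passed
  noise — the two methods would then disagree by the band-limiting factor.
  With normalization after the rescale, the two routes agree to <2% RMS on
  band-limited synthetic spots.
* **Guarded joins**: tables merge over the intersection of their columns in
  first-table order; `merge_datasets` additionally requires the implied
  pixel sizes to agree within a tolerance (default 1e−3 Å at the low-level
  API, 2e−3 in the workflow, which must accept deliberate near-misses such
  as 1.119 vs 1.120 from a fallback box pair).

## Synthetic ground truth

Phantoms are sums of spherical Gaussian blobs defined in physical
coordinates, renderable in closed form at any box and pixel size — two
renderings at different pixel sizes are consistent views of the same object,
which is what makes scale recovery well-posed and gives every rescaling
operator an interpolation-free oracle.  Generator defaults: blob centers in
a sphere of radius 0.35·extent (no clipping under ±20% rescales), sigmas
1.2–3% of the extent (≈2–4 Å at the default test scale — the detail scale of
a mid-resolution reconstruction, so percent-level scale errors visibly
decorrelate the periphery), amplitudes 0.5–1.5, reproducible for a fixed
seed.  SNR is defined as signal variance over noise variance; the default
test condition is box 128, 25 blobs, SNR 5.

The mis-scaling experiment renders a reference dataset at 1.120 Å/px and a
second at 0.880 Å/px, harmonizes the second under a deliberately wrong
declared pixel size, averages, and scores the average against the noiseless
truth by mean FSC.  Harmonization here uses real-space resampling rather
than spectral pad/crop: spectral cropping *removes* high-shell noise for
smaller declared pixel sizes, which would bias the mean-FSC comparison in
favour of slightly-too-small candidates for reasons unrelated to scale
accuracy.  At box 96 and SNR 5 the experiment reproduces the expected
tolerance ordering: the correct scale is best and beats the single dataset,
a 0.5% error is indistinguishable, ~2% errors are mildly worse, and a ~7%
error drags the merged map below the single dataset.

**What passing these tests does not show:** the phantoms have no CTF, no
detector MTF, no ice gradient, no orientation bias, and the "merge" is a
simple average rather than a refinement, so absolute scores and resolutions
do not transfer to real reconstructions — only the orderings and the
geometric/metadata bookkeeping do.  Problem sizes (boxes 64–128, three-digit
particle counts) were chosen so the whole suite runs in well under a minute
of FFT time per experiment; they are desk-scale stand-ins for the
cluster-scale originals.

## Known limitations

* Only the RELION ≤3.0 STAR dialect; no TIFF/EER movies; MRC modes are
  limited to real-valued ones.
* Rotational registration is out of scope: calibration assumes the two
  reconstructions are already approximately superposed (same handedness and
  orientation), as they are when refined against a common reference.
* Micrograph rescaling assumes square pixels; non-square micrographs get
  per-axis nearest-even boxes, which can make the per-axis achieved pixel
  sizes differ by a sub-granularity amount.
* CTF *estimation* is external by design: Method 1 re-estimates CTF on the
  rescaled micrographs with the user's preferred tool, and the Method 1
  output flags its CTF columns accordingly.
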