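# Methods

## The operator

All operators are flat (binary-SE) grayscale morphology. Erosion and
dilation are local min/max over the footprint; images are implicitly
extended by edge replication at the border, so a flat SE never invents
values outside the image's local range and the top-hat of a constant
image is identically zero, including at the frame edge. Internal
arithmetic is float64; results are quantized back to the input bit depth
(round half up) only at output boundaries.

The RMP opening rotates the image through `N` equiangular directions in
`[0, π)`, opens each rotation with a horizontal line SE of odd length
`L`, rotates back and takes the pixelwise maximum. Implementation
details that matter:

- **Rotation canvas.** Before rotating, the image is embedded in a
  square canvas of side `max(⌈√(H²+W²)⌉, max(H,W)+2L)` padded by edge
  replication, so corner content survives every rotation and the line
  opening near the original border sees replicated edge values only.
- **Lattice-exact directions.** Angles that are multiples of 90° are
  executed with `rot90` on the unpadded image — no resampling and
  exactly the replicate-border semantics of the plain opening. Hence
  `N=1` reduces identically to the horizontal line opening and `N=2` to
  the max of the horizontal and vertical openings, which the tests
  exploit as oracles.
- **Interpolation.** Default nearest-neighbour, which preserves flat
  morphology semantics (no invented intermediate gray levels); bilinear
  is available and gives smoother unions. With `N=36`, bilinear
  restoration of a bar phantom saturates (the 36→72 PSNR gain is ~1.3 dB
  against ~10.7 dB for 8→36), whereas nearest keeps gaining from extra
  directions because they repair resampling jaggies; the rotation-count
  experiment therefore uses bilinear.
- **Anti-extensivity clamp.** Resampling can push the union above the
  input by a few gray levels; by default the union is clamped to
  `min(f, union)` so the top-hat residual is provably non-negative. The
  clamp is a no-op for lattice-exact angle sets.
- **Reconstruction.** Grayscale geodesic reconstruction (used by the
  h-dome baseline) runs to the exact fixed point with 8-connectivity
  (configurable to 4). Note the definitional edge case: the h-dome of a
  constant image is `h` everywhere, because a constant image is a single
  plateau the marker cannot climb.

## The pipeline

`presmooth → denoise → extract → binarize → cleanup → label/measure`,
with defaults `se_noise=13`, `se_spot=21`, `N=36`, threshold 0,
no cleanup, no presmoothing (the benchmark configuration turns on the
3×3 Gaussian presmooth, σ=0.8, and the disk-13 cleanup). Stage outputs
are rounded to integer gray levels, emulating an 8-bit processing chain;
a threshold of 0 therefore means "any strictly positive integer
residual" and does not pick up sub-gray resampling crumbs. With bilinear
rotation a threshold of 1 is the sensible default.

Measurements: 8-connected labeling; centroid and area from the labeled
mask; integrated intensity summed over the **original** (pre-denoise)
image; averaged Feret diameter as the mean caliper width over 36
equally spaced directions, where each pixel contributes its full square
footprint (center projection span plus `|cos θ|+|sin θ|`). On planted
digital disks of diameter 7–15 px this measures the nominal diameter
within ±1 px. Physical units are metadata only (a resolution factor);
all morphology runs in pixels.

If a binarized residual leaves a 1-px bridge between two spots, the
8-connected labeling merges them (counted as a miss by the benchmark's
matching rule); the 1-px-wide SE makes this rare but it is a known
sensitivity.

## The synthetic benchmark

**Spot model.** Spots are 2-D Gaussian kernels truncated to a 17×17
support, scaled so the peak is 255 or 127 (alternating), placed
uniformly at random with a minimum center separation of 24 px (so the
planted truth is resolvable) and fully inside the 512×512 frame. The
default σ is 4 px, from the standard support rule `width = 4σ+1`; this
makes the spot *domain* 17 px wide, which is the geometry the pipeline's
SE choices (13 < 17 < 21, disk-13 cleanup) are designed around. A much
narrower profile (e.g. σ=2 px, FWHM 4.7 px) is destroyed by the 13-px
denoise opening — the residual falls to ~1% of the peak — and cannot be
detected reliably under noise with these SE lengths; σ is a config field
for exploring that regime.

**Noise model.** The clean source contains the spots only; the
observation is `Poisson(s·(f + b)) / s` quantized to 8 bits, with
photon scale `s` (photons per gray level) and background `b` either
uniform or a left→right linear ramp. PSNR `10·log10(255²/MSE)` is
measured between source and observation, so the (undetected) background
offset contributes to it. Calibration constants, chosen once and kept in
config: uniform `b=51` and ramp `0→120` at `s=1` put the two image sets
at ≈13.9 and ≈11.3 dB; the nine-level noise ladder uses a dimmer uniform
background (`b=30`, forced by its brightest rung at ≈17.7 dB) with nine
photon scales from 0.1525 down to 0.0031 solved for evenly spaced target
PSNRs. Because of 8-bit clipping, measured PSNR under this model cannot
fall much below ≈10 dB — at extreme noise the clipped image drifts back
toward the reference — so the darkest rungs saturate near that floor,
and PSNR is monotone in `s` only outside the clipping regime.

**Scoring.** Detected centroids are matched one-to-one to planted
centers greedily by distance within 4 px (≈2 spot σ). A single component
covering two centers yields one match; the other center counts as a
miss — merged spots are false negatives. Recall `TP/(TP+FN)`, precision
`TP/(TP+FP)`, F-measure their harmonic mean, in percent; with no
detections at all precision is undefined (NaN) and F is 0.

**Baselines.** All methods share the 3×3 presmooth, binarization and
disk-13 cleanup. The conventional top-hat baseline replaces only the
extraction step (disk-21 opening instead of the line union, after the
same RMP denoise); the h-dome baseline (`h=50`) is applied directly to
the presmoothed image. On the uniform-background set the disk top-hat
floods the residual with background structure (many false alarms, merged
spots) and the h-dome's caps — the region above `peak−h` — are narrower
than the cleanup disk and get erased (recall ≈0), while the RMP pipeline
is exact. These failure modes, not the exact counts, are the robust
comparison outcome.

**What the generator does not emulate.** Real micrographs have textured
backgrounds, aberrated and spatially varying point-spread functions,
read noise, and spots of irregular shape; the benchmark's Gaussian spots
on smooth backgrounds test the geometry of the operator (separation,
isotropy, background rejection under shot noise), not photometric
realism. Passing it shows the operator behaves as designed, not that any
particular real dataset will be detected perfectly.

## Problem sizes and runtime choices

The detector comparison runs 10 images of 512×512 px per background
type; the ladder uses one source image per seed across nine noise
levels and three seeds. One full pipeline run on a 512×512 image (two
RMP stages at N=36) takes ≈2.5 s on one CPU; the whole acceptance script
≈2 minutes. The rotation-count experiment uses a 256×256 phantom of six
5-px-wide bars (orientations 10°–160°, avoiding the lattice-exact angle
sets) plus twelve 9-px disks, restored by RMP opening with a 31-px line.

## Known limitations

- The noise ladder's detection break-point sits at ≈15 dB measured PSNR
  under this noise model, because mid-ladder rungs already carry very
  large shot noise (the PSNR is offset-dominated); robustness "to
  ≈10 dB" is not achievable here for any spot profile that also keeps
  the h-dome baseline's failure mode. Precision, by contrast, is 100%
  (zero false alarms) at every rung in every run — background structure
  that survives denoise + top-hat never assembles a disk-13-sized blob.
- Nearest-neighbour rotation leaves small direction-dependent residue on
  elongated structures; use bilinear (with threshold 1) when smooth
  unions matter more than exact gray-level semantics.
- 3-D stacks, non-flat (ball) SEs and color images are out of scope.
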