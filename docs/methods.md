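# Methods

## Model

`brightseg` segments the total area occupied by cells in a brightfield
micrograph — not individual cells — under one assumption: cell interiors
produce dense local edge contrast (organelles, membrane texture) while the
background varies smoothly. The pipeline is a fixed composition:

    to_8bit → equalize_histogram → canny → maximum_filter
            → binary_close → binary_open → [count_erode]

Every stage is deterministic, so a mask is a pure function of (image,
configuration); the configuration is serialized as flat `key=value` text
whose keys are the historical macro parameter names (`gaussian`, `low`,
`high`, `radius`, `close_iterations`, …) and recorded in a per-run manifest.

## Parameters

* **Pixel calibration (nm/pixel, required).** The two scale-dependent radii
  are looked up from the resolution table (see README). The bands are
  treated as half-open `[lo, hi)` with a shared boundary belonging to the
  upper band (the printed table is ambiguous at 180/270/360); inputs below
  90 nm/px clamp to the first band with a warning rather than failing.
* **Equalization.** `saturated_percent` (default 0) is accepted and logged
  but has no effect on the equalize mapping, mirroring the reference
  behaviour the macro line relies on. The default mapping weights histogram
  counts by their square roots; `classic=True` uses raw counts. The
  cumulative mapping is frozen as `floor(255·cum/total)` with an inclusive
  cumulative sum; a histogram with a single occupied bin short-circuits to
  the identity, so constant images pass through unchanged. (A worked
  two-value oracle: equal counts of {10, 200} map to {127, 255} in classic
  mode.)
* **Canny.** `gaussian_kernel_radius` is the σ of the smoothing Gaussian in
  pixels; `low_threshold`/`high_threshold` (defaults 0.1/8.0) apply to the
  gradient magnitude scaled by `MAGNITUDE_SCALE = 100/255`, a frozen
  calibration constant that puts the conventional threshold numbers on a
  meaningful scale for 8-bit input. The high threshold is the first
  parameter to adjust on difficult material (faint cell borders: lower it;
  noisy background: raise it).
* **Morphology.** `iterations`, `count` (1–8) and `pad` follow the
  count-based convention: erosion removes a foreground pixel iff ≥ `count`
  of its 8 neighbours are background, dilation adds a background pixel iff
  ≥ `count` are foreground. `pad=true` treats out-of-image neighbours as
  foreground during erosion (border-protected, used by the closing and the
  final erosion); dilation always treats out-of-image as background. The
  published protocol states the opening's iterations as 10 in prose but 20
  in its macro line; the default follows the prose and the macro value is
  shipped as `OPEN_ITERATIONS_MACRO`.
* **Circular kernels.** The maximum filter's neighbourhood is
  `{(dy,dx) : dy²+dx² ≤ r²+1}`, the rank-filter inclusion rule that
  reproduces the reference kernels for the fractional radii 1.25, 1.67 and
  2.5 (note it makes radius 1 a full 3×3). Borders use shrinking windows.

## Numerical choices

* Gaussian and derivative kernels are truncated at half-width ⌈4σ⌉; the
  smoothing kernel is renormalized to unit sum, the derivative kernel is
  −x/σ² times it. Image borders are edge-replicated.
* Non-maximum suppression interpolates the two magnitude samples one pixel
  away along ± the gradient direction and keeps a pixel iff it is strictly
  greater than the forward sample and ≥ the backward one. The asymmetric
  tie-break is deliberate: an ideal integer step produces an exact two-pixel
  magnitude tie, and this rule thins it to a single-pixel curve (on the
  bright side) while still keeping isolated maxima. Hysteresis links
  8-connected components.
* 16-bit inputs are converted to 8 bit by min–max display-range scaling; a
  constant 16-bit image maps to 0. RGB inputs are converted with ITU-R 601
  luminance weights, rounded to integer.
* Mean fluorescence over an empty mask is NaN, never 0; the integrated
  density is an exact integer sum, so `integrated = mean × area` holds to
  rounding by construction.
* Degenerate inputs: empty edge maps stay empty through all morphology;
  `area_difference_percent` refuses an empty reference instead of silently
  dividing by zero; two empty masks have Dice and IoU 1.

## Synthetic scenes

`generate_scene` emulates a high-magnification brightfield field: a 512×512
frame at 110 nm/px holding 5 elliptical cells of 40–80 px radius (9–18 µm
diameter, typical adherent lines), placed with centres at least 60% of their
combined radii apart. Interiors carry zero-mean texture — Gaussian noise
low-pass filtered at 2 px, about the organelle granularity at this
resolution, rescaled to SD = `interior_texture_amp`/2 (default amplitude
45 counts) — because uncorrelated noise would be annihilated by the σ=1.75
smoothing, which no real intracellular texture is. Rims are 12% of the
ellipse radius and darker than background by `border_contrast` (60 counts).
The background is level 150 plus a diagonal illumination gradient
(10 counts) and Gaussian noise (SD 2). Debris blobs (default 3, radius
2–5 px, high contrast) are rendered outside the ground truth, mirroring the
observation that contrasting impurities are the main source of the method's
positive area bias. Randomness uses numpy's PCG64 (`default_rng`) with
explicit seeding; cells, debris and noise draw from independent seed-derived
streams so adding debris leaves the rest of a scene bit-identical.

What the scenes do **not** model: point-spread-function blur, specific cell
morphologies or lines, out-of-focus acquisition, scale bars, and severely
uneven illumination. Passing the synthetic recovery checks therefore shows
the pipeline implements its stages correctly and is well-behaved under the
modeled image structure; it does not certify accuracy on any particular real
acquisition, which still requires the overlay check (step 7 of the classic
workflow: inspect `overlay_outline` and adjust the high threshold first).

On these default scenes the high-magnification pipeline recovers the ground
truth with median Dice ≈ 0.93 and a mean signed area difference of about
+14% (regression-guarded at median Dice ≥ 0.8 and |mean| ≤ 20%): the mask is
systematically slightly larger than the truth, the same lenient direction
the method shows against human annotation, because the maximum filter's
dilation is only partly undone by the final 2-iteration erosion. A
published-style comparison against *manual* annotation is not reproducible
offline (no annotated images are distributed), which is why validation here
is property-based: exhaustive oracle agreement for the morphology (all
65,536 4×4 masks, counts 1/3/8, pad=false — the convention under which
erode/dilate duality holds on interior pixels), kernel-enumeration agreement
for the maximum filter, single-pixel step-edge behaviour and threshold
monotonicity for the detector, and scene recovery plus bit-exact determinism
for the whole pipeline. Problem sizes in the acceptance script (20 scenes of
512², 250 random 32² rasters) were chosen so the whole validation runs in
seconds on one CPU.

## Known limitations

* Poor-quality inputs — underexposed or out-of-focus images, or blank fields
  with contrasting impurities — are segmented without complaint and can be
  nonsensical; there is deliberately no automatic image-quality gate, and
  users are expected to inspect the outline overlay.
* Cells with faint borders (e.g. fibroblasts) may need a lower high
  threshold and re-tuned morphology.
* Touching cells are fused: the output is total area, not instances.
* Scale bars or burned-in annotations will be detected as edges; crop them
  first.
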