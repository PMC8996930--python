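# Methods

## The measurement problem

Top-view cameras over a broiler pen produce video from which two per-frame
statistics summarise what the flock is doing without tracking individual
birds:

* the **cluster index** measures crowding — how much the birds have gathered
  into few, large, close groups;
* the **unrest index** measures movement — how far the flock's image content
  shifts from one second to the next, in centimetres.

Both indices are computed frame by frame at 1 fps (native recordings are
typically 30 fps; decimation selects every 30th frame, no averaging, because
a blended frame would smear moving birds into ghosts). A 7-hour session at
1 fps yields 25,200 frames per condition; with the 2 × 2 design
(temperature × enrichment) that is 100,800 frames, grouped into 14
thirty-minute blocks of 1,800 frames each for the statistical comparison.

## Segmentation

Birds are compact blobs against litter. The default route is:

1. Gaussian low-pass filter (`lowpass_sigma`, default 1 px) to suppress
   litter texture (feathers, shavings);
2. pixel-wise **median background** across the sequence, then Otsu
   thresholding of `|frame − background|`. The absolute difference makes the
   method polarity-free: it works whether birds image darker or lighter than
   litter. A global fixed threshold is available for controlled fixtures,
   with a `dark_birds` polarity flag.
3. morphological cleanup: hole filling (background complement taken
   4-connected when foreground is 8-connected) and removal of components
   with area < `min_blob_area_px` (default 25 px — a few square centimetres
   at a typical ceiling-camera scale; exposed because the right value is a
   per-deployment decision).

Foreground components are 8-connected by default: birds touching diagonally
merge into one blob, and that merging *is* the crowding signal — no attempt
is made to split merged birds.

**Perimeter estimator.** Blob perimeters use Moore boundary tracing with
orthogonal steps counted 1 and diagonal steps √2. A blob whose traced chain
is empty (an isolated pixel) is assigned its pixel-boundary length 4.0 so
perimeters are always positive. The same function is the oracle in the test
suite; the cluster index needs internal consistency, not sub-pixel accuracy.

## The indices

**Cluster index**, per frame:

    CI(i) = 2 · Ā · √(h² + w²) / (P̄ · D̄ · (n_A − 1))

with Ā, P̄ the mean blob area and perimeter (px), D̄ the mean pairwise
distance between blob centroids (px, over all n_A(n_A−1)/2 unordered
pairs), n_A the blob count, and h, w the (possibly cropped) frame
dimensions. Fewer, larger, closer blobs give a higher value. Two published
typesettings of the formula are ambiguous and both readings are exposed:

* the denominator factor is `(n_A − 1)` by default, with `variant="nA_inverse"`
  selecting `n_A`;
* the numerator radical is the image diagonal √(h²+w²) by default
  (dimensionally consistent: px·px² over px·px gives px, cancelled by the
  diagonal's px), with `diagonal=False` selecting (h²+w²).

Frames with n_A < 2 have no D̄ and are **flagged invalid**, never given a
value; block averages use valid frames only and record the valid count.
The index scales linearly under consistent pixel rescaling (Ā→s²Ā, P̄→sP̄,
D̄→sD̄, h,w→s·h,w multiplies CI by s), which the suite tests.

**Unrest index**, per consecutive frame pair:

    UI(i, i−1) = k · max{ d_H(F(i), F(i−1)), d_H(F(i−1), F(i)) }

the symmetric Hausdorff distance between the bird point sets of two frames
one second apart, scaled to cm by the camera factor

    k = 2 · H · tan(α/2) / w_sensor

(H mount height in cm, α lens opening angle, w_sensor the pixel length of
the frame's largest dimension). The point sets default to **all foreground
pixels** of the cleaned masks — the most literal reading of "the birds" —
with a centroid mode for speed. A frame with empty foreground makes the
pair a flagged missing value, never zero movement.

**Numerics of the Hausdorff distance.** Point-set distances are computed on
squared distances with one final square root (monotone, hence bit-identical
to the naive double loop; note that squaring must use `x*x` — a libm
`pow(x, 2)` can differ in the last ulp). Mask-to-mask distances use the
exact Euclidean distance transform: `d_H(A→B) = max over A of EDT(¬B)`,
exact on integer pixel grids; the pipeline computes one EDT per frame and
reuses it for both adjacent pairs. Both paths are tested for exact equality
against the exhaustive oracle.

## Block analysis

Per-frame series are averaged into the design's time blocks and compared
with a split-plot-in-time ANOVA: temperature is the whole-plot factor,
enrichment the subplot factor, time blocks the repeated measures. The model

    y ~ temperature * enrichment + block + temperature:block

is fitted by OLS; the temperature main effect is tested against the
temperature × block mean square (whole-plot error, 13 denominator df in the
full design) and enrichment and the interaction against the residual
(subplot error, 26 df). This standard layout is stated in the result
object's metadata rather than guessed from any particular software's
defaults. A constant response short-circuits to F = 0, p = 1 (OLS sums of
squares would be rounding noise). Blocks with missing means are dropped
listwise with a warning; an unbalanced layout is tolerated with a warning.

Post-hoc separation of the four condition means uses Tukey's HSD at
α = 0.05 (configurable) with a compact letter display: each maximal clique
of the "not significantly different" graph gets one letter, so conditions
share a letter iff they are not separable at α.

## Synthetic scenes

The synthetic module generates ground-truthed frame sequences standing in
for pen recordings: 10 dark elliptical birds (default semi-axes 14 × 20 px
at the native 496 × 976 frame) on litter at intensity 200, bird intensity
60, plus single-pixel dark specks (Poisson, default 2·10⁻⁴ per pixel per
frame). The movement model is a **bounded random walk with attractor
blending**: each second a bird sits with probability `sit_probability` or
steps with magnitude ~ Normal(`step_cm_per_s`, `step_dispersion_cm`)
(truncated at 0, converted to px through k) in the direction
`crowding_strength · (unit vector to its weight-discounted nearest
attractor) + (1 − crowding_strength) · (random unit vector)`, normalised.
Positions are clipped to the arena; a soft pairwise separation (capped at
2 px per step) prevents exact stacking while still allowing the touching
and merging that produce the crowding signal. One `numpy` Generator seeded
from `config.seed` drives the walk; rendering draws its speck and
orientation streams from child seeds of the same value, so scenes are fully
reproducible.

The four regime presets encode the qualitative study conditions:

| preset            | step (cm/s) | sit prob. | crowding | drinker weight | attractors |
|-------------------|------------:|----------:|---------:|---------------:|------------|
| comfort_enriched  | 14.0        | 0.15      | 0.20     | 1.5            | drinker, feeder + 3 objects |
| comfort_plain     | 12.0        | 0.25      | 0.15     | 1.5            | drinker, feeder |
| stress_enriched   | 8.0         | 0.45      | 0.80     | 8.0            | drinker, feeder + 3 objects |
| stress_plain      | 6.5         | 0.55      | 0.80     | 8.0            | drinker, feeder |

Heat makes birds slower and sittier and pulls them toward the drinker
(microclimate near the water line — hence the raised drinker weight under
stress); enrichment raises activity within each temperature and adds
attractor objects, placed in one central band of the pen so that birds
drawn to them aggregate rather than scatter to corners. Step magnitudes are
chosen to reproduce the orderings between conditions only — no quantitative
displacement distributions for real birds are available, so absolute index
levels are not emulated and the tests make no claim about them.

**What the generator does not emulate:** lighting changes, shadows, feather
texture on the birds themselves, occlusion by equipment, camera noise or
lens distortion, diurnal activity rhythms, and individual-bird behavioural
states. Passing the recovery tests therefore shows the pipeline is
*sensitive to the modelled contrasts at realistic geometry and noise*, not
that it is validated on real pen video.

## The regime-recovery study

`flockvision.study.run_regime_study` runs the entire pipeline — simulate,
render, segment, index, block-average, split-plot ANOVA — over the four
presets for 20 seeds and reports how often the expected structure is
recovered: the unrest orderings (comfort > stress within each enrichment
level, enriched > plain within each temperature), the cluster ordering
(stress ≥ comfort within each enrichment level), and the temperature main
effect at p < 0.05.

The study's default problem size is the package's own choice of a
desk-scale experiment: a half-resolution camera (`scale=0.5`: 248 × 488
frames with a 488-px sensor, so k doubles and all cm-level statistics are
unchanged — a legitimate lower-resolution deployment of the same camera
model) and 14 blocks of 15 s per condition (210 frames per regime per
seed), preserving the full 14-block split-plot structure. The minimum blob
area scales with resolution (area ∝ scale²). At these sizes the 20-seed
study completes in a few minutes on one CPU.

## Design choices and limitations

* **Segmentation method** is not prescribed by any reference; median
  background + Otsu on |difference| was chosen for determinism and
  robustness to litter texture, and every threshold/kernel/area parameter is
  exposed rather than claimed to match the original deployment.
* **Video containers** are read through imageio when a video backend is
  available; directories of numbered PNG/JPEG/TIFF frames are the fully
  supported interchange format and what the synthetic module writes.
  Timestamps always derive from index/rate, not container metadata.
* **No tracking**: the indices are group-level by construction. Merged
  blobs are not split; bird identity is never assigned.
* The split-plot ANOVA uses fixed-effects sums of squares with the
  split-plot error strata, not a REML mixed model; with one observation per
  temperature × enrichment × block cell this is the standard analysis and a
  mixed model would add nothing identifiable.
* The compact letter display is a maximal-clique cover, which can produce
  more letters than the minimal cover in pathological non-transitive cases;
  for four conditions this does not occur.
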