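# flockvision

Computer-vision **cluster** and **unrest** indices for analysing broiler
flock behaviour from top-view pen video, with the split-plot statistical
comparison of rearing conditions (temperature × environmental enrichment)
and a ground-truthed synthetic scene generator.

## The problem

Heat stress and barren pens change how a flock of broilers moves and groups:
heat-stressed birds move less and huddle near the drinker; enrichment
objects (perch, sand box, hanging rings) raise activity. Group-level
computer vision can monitor this continuously and non-invasively, without
tracking individual birds. Two per-frame statistics do the work:

* **Cluster index** (crowding, dimensionless), from the segmented bird
  blobs of one frame:

  ```
  CI(i) = 2 · Ā · √(h² + w²) / (P̄ · D̄ · (n_A − 1))
  ```

  Ā, P̄ — mean blob area and perimeter (px); D̄ — mean pairwise distance
  between blob centroids (px); n_A — number of blobs; h, w — frame
  dimensions. Fewer, larger, closer blobs (birds huddling and merging) give
  a higher value.

* **Unrest index** (movement, cm), between consecutive frames one second
  apart:

  ```
  UI(i, i−1) = k · max{ d_H(F(i), F(i−1)), d_H(F(i−1), F(i)) }
  ```

  the symmetric Hausdorff distance between the two frames' bird pixel sets,
  scaled to centimetres by the camera factor `k = 2H·tan(α/2)/w` (mount
  height H, lens angle α, sensor length w in px).

The package covers the full pipeline: frame ingestion at 1 fps →
segmentation (median-background subtraction, Otsu, morphology) → indices →
30-min block averages → split-plot repeated-measures ANOVA with Tukey
letters. Because pen recordings of this kind are rarely shared, a synthetic
module simulates ten elliptical birds with regime-dependent movement and
crowding so every stage is testable end to end. See `docs/methods.md` for
the full model description.

## Worked example

Simulate all four regimes (comfort/heat-stress × enriched/plain), run the
pipeline, and compare conditions:

```python
from flockvision import (
    compute_index_series, regime_preset, render_frames, simulate_flock,
    block_averages, condition_report, split_plot_anova,
)
from flockvision.study import scaled_design, default_study_seg_params, REGIME_CONDITIONS

design = scaled_design()                    # 14 blocks × 15 s per condition
params = default_study_seg_params(0.5)      # half-resolution camera
all_blocks = []
for regime, condition in REGIME_CONDITIONS.items():
    config = regime_preset(regime, seed=42, scale=0.5)
    track = simulate_flock(config, design.frames_per_condition - 1)
    series = compute_index_series(render_frames(track), params, config.geometry)
    all_blocks += block_averages(series, design, condition)

print(split_plot_anova(all_blocks, response="unrest").summary())
print(condition_report(all_blocks))
```

Output:

```
Split-plot ANOVA (response: unrest)
model: y ~ C(temperature) * C(enrichment) + C(block_id) + C(temperature):C(block_id)  [temperature tested vs temperature:block MS]
blocks used: 14

                        df_num  df_den      F   p_value
factor
temperature                  1      13  726.7 8.544e-13
enrichment                   1      26  47.34 2.644e-07
temperature:enrichment       1      26 0.5528    0.4638

| Index | Temperature | enriched | nonenriched |
|---|---|---|---|
| Cluster | comfort | 3.42 (b) | 2.88 (b) |
| Cluster | heat_stress | 4.18 (b) | 25.31 (a) |
| Unrest | comfort | 19.29 (a) | 17.16 (b) |
| Unrest | heat_stress | 9.81 (c) | 8.09 (d) |
```

The unrest rows show the expected structure: comfort > heat stress within
each enrichment level, enriched > plain within each temperature (distinct
Tukey letters throughout), and the ANOVA flags the temperature main effect
(F = 726.7 against the temperature × block stratum). Heat-stressed birds
crowd near the drinker, which drives the heat-stress cluster means above
their comfort counterparts — extremely so in the plain pen, where all ten
birds pile into one region and merge into very few blobs.

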