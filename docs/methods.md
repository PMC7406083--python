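# Methods

`depthseg` studies how network depth yields *implicit* figure-ground
segmentation: the observation that deeper image classifiers rely less on
background context and more on the object region, without any explicit
segmentation mechanism. Because the phenomenon is about *which image regions
drive classification*, everything in the package revolves around stimuli with
exact ground-truth object masks and probes that measure region reliance.

## Synthetic stimulus model

Real congruency experiments composite cut-out photographic objects onto
scenes whose semantic category matches (congruent) or mismatches
(incongruent) the object, or onto uniform white (segmented). The synthetic
generator reproduces the *statistical skeleton* of that design:

- **Objects.** Category `c` of `K` owns a shape family (ellipse, rectangle,
  triangle, annulus, cross, diamond), a grating-orientation band of width
  `pi/K` (disjoint across categories), a coarse stripe-wavelength band
  (4–6 px), and a hue arc (width `0.8/K` of the hue circle, disjoint across
  categories). An exemplar draws nuisance parameters — size jitter
  (0.78–1.0), rotation (±0.35 rad), grating phase, within-arc hue — inside
  those bands. All class-diagnostic signal is confined to the mask; pixels
  outside the mask are a neutral placeholder that compositing never copies.
- **Backgrounds.** The background family of category `c` draws its base hue
  from the *same* hue arc as the category's objects (appearance statistics
  co-vary with the category), a low-frequency luminance texture from a
  disjoint per-category frequency band, plus an oriented high-frequency
  grating at object-scale wavelengths with random orientation. The last
  component makes backgrounds texturally competitive with objects, so
  clutter is a real cost and not trivially separable from object texture.
- **Scenes.** A sprite (canvas = `object_scale * image_size`) is pasted at
  one of nine positions of a 3x3 grid. Outside the translated mask the scene
  equals the background (or white) exactly; inside, the sprite exactly.

**The congruence parameter `rho`** is the object–background correlation of
the *training* distribution: each training image draws its background from
the object's own family with probability `rho`, else from a foreign family.
Evaluation stimulus sets are unaffected (their congruent condition is
matched by definition). `rho < 1` is what makes context an informative but
imperfect cue, as in natural scene statistics; with `rho = 1` the background
would be perfectly predictive and no classifier, at any depth, would have a
reason to learn object features.

Two generator profiles are used, mirroring the fact that the congruency
evaluation and the training-diet comparison are different corpora in the
original design:

| profile | K | E | B | image | object_scale | rho |
|---|---|---|---|---|---|---|
| experiment 1 (congruency/attribution) | 6 | 12 | 3 | 32 px | 0.50 | 0.80 |
| experiment 2 (training diets) | 6 | — | 3 | 32 px | 0.625 | 0.25 |

Experiment 2's low `rho` encodes backgrounds that are largely shared across
classes (scene statistics of related animal categories), which is what makes
unsegmented training a clutter problem rather than a context bonus.

**What the generator does not emulate:** photographic texture statistics,
occlusion and lighting, semantic (as opposed to appearance-level)
congruency, and the heavy-tailed complexity of real exemplars. Passing
directional tests here shows the *mechanism* (depth -> less background
reliance) operates when class signal is mask-confined and context is
correlated but imperfect; it does not certify effect sizes on photographs.

## Classifier family

A depth-parametric family of small convolutional classifiers, written on a
compact numpy stack (im2col convolution, manual backpropagation):

    stem conv3x3(3 -> C) + ReLU
    avgpool 2x2
    blocks 1..n: [conv3x3(C -> C) (+ identity if residual)] + ReLU
    avgpool 2x2 after block ceil(n/2)   (mid-stack downsampling)
    global average pool -> linear readout (pre-softmax scores)

- `n_blocks` is the depth proxy; the default family is 1, 2, and 4 blocks
  with `C = 24` channels. The shallowest member has no residual connection
  (a shortcut over a single block is architecturally meaningless, matching
  the convention for the shallowest member of a residual family).
- `recurrent_steps > 0` re-applies each block that many extra times with
  tied weights — the weight-clamped unrolling that links very deep residual
  nets to recurrent computation. Parameter count is independent of the
  unrolling depth, and `n_params` is reported so capacity confounds can be
  noted alongside depth comparisons.
- The family is normalization-free. Batch normalization was evaluated and
  rejected: with batch size 8, batch statistics on white-background
  (segmented) images are dominated by the small object region and produce
  erratic validation curves. Stability for the deeper members comes instead
  from a fixup-style damped initialization of residual branches (scale
  `(n_blocks * steps)^-1/2`) and gradient-norm clipping at 5.
- Training: SGD, lr 0.05, momentum 0.9, batch 8, no weight decay, random
  translation augmentation (reflect-pad 2 px + crop). Every stochastic
  choice — initialization, shuffling, crops — derives from the run seed, so
  a (config, seed) pair reproduces curves bit-identically on one machine.

## Feature-reliance probes

- **Region noise.** I.i.d. Gaussian pixel noise (default sigma 0.5 on the
  [0,1] scale, clipped) added to the object, the background, or both. One
  noise field is drawn per image so "both" equals the two single-region
  perturbations composed on their disjoint supports.
- **Occlusion importance.** A `patch`-sized square of mid-gray
  (0.5, 0.5, 0.5) slides over the image in `stride` steps (defaults
  `image_size/4` and `image_size/16`, preserving the 128/512 and 32/512
  proportions of the original protocol). Importance of a placement is
  `(original - occluded) / original` on the true class's pre-softmax score.
  Placements are only those fully inside the image, so the grid is
  `floor((H - patch)/stride) + 1` per axis. The grid is projected to pixels
  by averaging over all placements covering a pixel (an unbiased choice; a
  max-projection would emphasize the single most damaging occlusion).
  Region importance is the plain mean of the pixel map over the mask (or
  its complement); since grid values are already normalized by the original
  score, the region means are importance *ratios* and no second
  normalization is applied. A zero original score flags the map undefined
  rather than dividing. Attribution averages use only correctly classified
  scenes (within top-k), because relative score changes are uninterpretable
  when the unoccluded score is already near zero.
- **Filter heatmaps.** Per layer, the elementwise sum of absolute filter
  activations; bright regions carry the features the layer responds to.

## Statistics

Friedman (within-subject ranks across the three conditions), Wilcoxon
signed-rank (pairwise conditions), Mann-Whitney U (between independent
groups: depth contrasts on congruency gaps, diet contrasts across seeds),
Benjamini-Hochberg step-up FDR across each family of pairwise tests, and
seeded percentile-bootstrap 95% intervals of the mean (resampling whatever
units are passed in — subsets or seeds — and recording which). Midranks
handle ties; exact null distributions are used up to n = 25 when no
ties/zeros are present, otherwise the normal approximation with continuity
correction. The test suite cross-checks all three tests against exhaustive
enumeration oracles on samples of n <= 8.

Training curves are summarized by the convergence epoch — the first (1-based)
epoch reaching 95% of the curve's own maximum — and the mean validation
accuracy of the first 10 epochs. An all-zero curve has no meaningful maximum
and is flagged undefined (NaN in reports).

## Default study sizes

The default desk-scale study (what `scripts/acceptance.py` and the
acceptance tests run) uses: experiment 1 — 3 family members x 5 seeds,
training on 24 images/class, 8 epochs, evaluation on 10 balanced subsets
(3 per category per condition), occlusion on up to 24 correct scenes per
member at patch 8 / stride 2; experiment 2 — shallowest and deepest members
x 2 diets x 10 seeds, 40 images/class, 16 epochs. These sizes were chosen
so the complete study runs in minutes on a single CPU core while the
directional effects remain stable across seeds; they are the package's
default experimental conditions, not tuning knobs.

## Design choices and numerical notes

- Incongruent backgrounds are assigned by a seeded cyclic category shift
  (drawn once per stimulus set from [1, K-1]), guaranteeing a derangement
  with uniform background usage; the original selection of atypical scenes
  was manual, so any deterministic mismatch rule is a stand-in (recorded in
  the set's design provenance).
- Locations are uniform seeded draws per scene; a Latin-square
  exemplar-background-location assignment is available
  (`latin_square_locations`) but not the default, since the model analyses
  do not require participant-level counterbalancing.
- Top-k policy: top-5 scoring when the label space has >= 10 classes,
  top-1 otherwise (a 6-class study would be trivial under top-5).
- Degenerate inputs are flagged, not silently processed: all-constant
  Friedman matrices, identical Wilcoxon pairs, empty regions in region
  importance, zero original scores in occlusion maps.
- Float32 forward/backward; accuracy bookkeeping in float64. Bit-level
  reproducibility holds per machine/BLAS build (the claim tested is
  same-machine rerun identity, not cross-platform identity).

## Known limitations

- Depth and capacity co-vary in the family (as they do in real residual
  families); the parameter count is reported, not controlled for.
- The desk-scale networks are far below the capacity where the original
  effect sizes live; only directions and orderings are expected to
  transfer, which is why the acceptance checks are property-based.
- The recurrent members share the feedforward members' training recipe; no
  attempt is made to tune unrolling-specific optimization.
- With 6 categories, chance is 16.7% and accuracy differences of a few
  percent are within seed noise; all headline comparisons therefore average
  5–10 seeds and the diet contrast is tested nonparametrically.
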