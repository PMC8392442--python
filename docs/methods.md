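# Methods

## Model

`minml` implements a two-class classifier built from two summary
statistics. Let Tr be a training set of m patterns over n numeric
attributes with classes C₁ (the lexicographically smaller label) and C₂.

**Ranking.** For each attribute i the per-class means M1ᵢ, M2ᵢ and the
difference dᵢ = M1ᵢ − M2ᵢ are computed; sorting the dᵢ from high to low
(stable, ties broken by ascending attribute position) gives the relevance
permutation. The `signed` mode is the literal rule; the `absolute` mode
sorts |dᵢ| instead. The two coincide whenever all dᵢ ≥ 0. The signed rule
demotes attributes whose C₂ mean exceeds their C₁ mean regardless of
discriminative power — an intentional property of the original
formulation that the absolute mode corrects. Both are first-class; the
default is `signed`. Which mode is appropriate depends on which class is
"bright": in the image workflow, the hemorrhage class (C₁ = "IVH") has the
higher intensities, so the signed rule already ranks the informative
pixels on top.

**Projection.** A pattern restricted to the first k permutation positions
is collapsed to (sample standard deviation, mean). The standard deviation
uses divisor k − 1 (for two values a, b it is |a − b|/√2, e.g.
std(67.9, 81.6) = 9.6874); it exists only for k ≥ 2, which is why the
attribute-growth search starts at k = 2.

**Decision rule.** At each k, the class whose average projected mean is
lower is the *minor* class (ties in the averages go to C₁, a deterministic
convention). The hypothesis is the horizontal line

    h = ( max(minor-class means) + min(major-class means) ) / 2,

defined even when the two sets of means overlap. A pattern is assigned the
below-side class if its projected mean is < h, the above-side class if
> h, and the below-side class at exact equality (`tie_policy="below"`,
configurable; the comparison rule itself is silent about equality). The
standard-deviation coordinate never influences the decision — it exists
for visualization, where each class is drawn as a curve sorted by
ascending std.

**Attribute growth.** Training sweeps k = 2..n (configurable to a coarse
grid such as {3, 5, 10, 100, 1000, n} for very wide tables), recomputing
minor/major roles, h and the training accuracy at every k. The search
stops at the first k reaching training accuracy 1.0; otherwise the
smallest k maximizing training accuracy is kept. "Maximum separation" is
thus operationalized as training accuracy with a smallest-k tie-break;
geometric margin is not considered, which only matters when several k
separate fully. The sweep is evaluated vectorized via cumulative sums
(O(m·n) overall), so a full sweep over a 16 384-attribute image table is
cheap; an independent per-k loop implementation is kept in the test suite
as an oracle.

## Evaluation

Leave-one-out cross-validation: each of the m folds recomputes the
relevance permutation *and* retrains the model on the m − 1 remaining
patterns, then classifies the held-out one. No statistic of the held-out
pattern enters its fold's model (leakage freedom is property-tested). The
per-fold verdicts aggregate into one 2×2 confusion matrix; accuracy,
sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) derive from it.
Undefined ratios are reported as NaN with a warning rather than 0, so a
degenerate evaluation cannot silently inflate a score. The positive class
defaults to C₁ ("IVH" sorts below "Normal") and is configurable. k\* may
legitimately differ across folds; the result records its distribution.

## Image preprocessing

Stage order: CLAHE → noise filter → skull removal → band segmentation →
morphology → superimposition → flattening.

- **CLAHE** is delegated to `skimage.exposure.equalize_adapthist`; the
  tile grid is given as (rows, cols) and converted to a kernel size. Only
  uniform redistribution is supported; requesting a Rayleigh profile
  raises. Constant images are returned unchanged (there is no contrast to
  create, and it keeps the all-zero image a fixed point of the chain).
  The stage can be disabled in config.
- **Noise filter**: 9×9 median by default (robust to impulse noise and to
  bone residue); a mean filter (rounded half-up, clamped to [0, 255]) is
  available. Both use replicate padding at the borders. A config flag can
  move the filter after skull removal for workflows that prefer smoothing
  the stripped image.
- **Skull removal**: pixels strictly above the bone threshold α become 0;
  everything else is untouched, so the output never exceeds the input.
- **Band segmentation**: the closed band [α₁, α₂] becomes foreground 255.
  α, α₁, α₂ are dataset properties, never universal constants: the
  supported calibration is `estimate_alpha`, the average of per-image
  (region-restricted) mean intensities over a small calibration set. The
  config defaults (α = 200, band [130, 200]) are placeholders for
  uncalibrated use.
- **Morphology**: opening (erosion then dilation) with a full 3×3 square,
  both operations implemented directly from their set definitions with
  background (zero) padding outside the raster. On a finite raster the
  erosion/dilation duality only holds if erosion pads with foreground;
  `erode(..., pad=255)` provides exactly that, and the duality is tested
  with it. Order (opening/closing/none) and SE size are configurable.
- **Superimposition** hard-overwrites mask pixels with 255 on the
  skull-removed grayscale image; **flattening** is row-major and
  invertible given the shape.

The whole chain is deterministic: same image and config, bit-identical
outputs.

## Synthetic data

**Tables** (`make_table`): both classes draw i.i.d. Gaussian noise of
scale σ (default 1) around 0; the larger-labelled class adds a shift δ
(default 5) on `n_informative` (default 5 of n = 100) positions chosen
uniformly per seed. 20 patterns per class by default — small enough for
exhaustive oracles, large enough that the planted positions dominate the
ranking (d̄ᵢ noise scale is σ·√(2/m) ≈ 0.32 against δ = 5). The planted
positions are always returned.

**Phantoms** (`make_phantom`): a 128×128 8-bit slice with a dark
background, an elliptical skull ring filled uniformly from [230, 255]
(bone band), brain tissue from [80, 120], an optional hemorrhage blob
from [150, 200] that must fit inside the brain, plus Gaussian noise
(σ = 2) and clamping. The bands are deliberately non-overlapping so every
preprocessing stage has a clean oracle; the ground-truth blob mask and
the region masks (skull/brain/blob) are available for calibration and
scoring. Image datasets write `<root>/IVH` and `<root>/Normal` trees,
each image differing only by its derived seed; `jitter_blob=True`
additionally perturbs blob position/radii per image — a deliberately
harder variant that is off by default.

What the phantoms do *not* model: Hounsfield calibration, anatomy,
partial-volume effects, texture, or the four other hemorrhage types.
Passing the phantom study therefore shows that the chain recovers planted
intensity structure under its stated assumptions, not that it reaches any
particular performance on real CT.

## Study sizes and numerical choices

The shipped studies use 100 seeded tables for the ranking-recovery rate
and 20+20 phantoms for the end-to-end LOOCV — sizes at which every result
is exactly reproducible in seconds while the statistics (100 Bernoulli
trials; 40 folds) are stable. Threshold calibration in the phantom study
averages region intensities over five enhanced calibration phantoms and
places α at the midpoint of the blob and skull means, the band at
[midpoint(brain, blob), α]. Rounding after averaging filters is
half-up; all 8-bit outputs are clamped to [0, 255]. All comparisons with
h are exact floating-point comparisons; the tie at equality is governed
by `tie_policy` alone.

## Known limitations

- Two classes only; no probabilistic outputs; the boundary is always
  horizontal in the (std, mean) plane.
- The signed ranking's asymmetry (above) can bury informative attributes;
  users of tables where the second class is elevated should use
  `mode="absolute"`.
- LOOCV retrains m models; on very wide data this is O(m²·n) overall,
  fine at desk scale (40×16 384 in ~2 s) but quadratic in m.
- CLAHE is the one stage whose exact pixel arithmetic is inherited from
  its backend; its contract (range preservation, constant fixed point,
  dynamic-range gain on low-contrast input) is tested rather than its
  bit-level output.
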