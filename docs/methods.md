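# Methods

## Viewport logs and the derived dwell time

A log records, per interpretation (one pathologist reading one case), an
ordered list of viewport rectangles with magnification and timestamp.
Coordinates are 0-based pixels of the 10× reference frame; rectangles are
half-open `[x, x+w) × [y, y+h)`. Durations are not logged directly: the
dwell of entry *i* is defined as `timestamp[i+1] − timestamp[i]`, and the
final entry gets 0 because no end-of-session marker exists. Consequently the
final entry can never be a fixation, and per-interpretation dwell sums
telescope to the session span — an invariant the tests rely on.

## Behavior detection

Three rules flag attention, all with strict inequalities:

| behavior | rule | default |
|---|---|---|
| zoom peak | `zoom[i] > zoom[i−1]` and `zoom[i] > zoom[i+1]` (interior entries only) | — |
| slow panning | same zoom as previous entry and center displacement `< panning_max_displacement` | 100 px |
| fixation | `fixation_min_s < dwell ≤ fixation_max_s` | 2 s / 60 s |

Zoom equality for panning is tested after rounding zoom to 3 decimals, since
viewer zoom levels are discrete states. Only entries with magnification
strictly above `min_zoom` (default 5×) become viewing ROIs; lower-power
viewports cover too much tissue to be informative. An entry flagged by k
behaviors yields k ROIs — de-duplication is deliberately left to the
accumulation stage, which is insensitive to it only in the sense that
overlap raises the local count as intended. Displacement is measured in
reference-frame pixels; the threshold is configurable because tracking
set-ups may log screen pixels instead.

## Viewing heatmaps

Per case, the dwell durations of all viewing ROIs from *qualifying*
interpretations (absolute difference between the reader's diagnostic class
and the consensus class ≤ 1) are accumulated per pixel with a 2-D difference
array (O(#ROIs) instead of per-pixel rasterization; a brute-force rasterizer
serves as the test oracle), then divided by the maximum so the most-viewed
pixel is exactly 1. A case with no positive dwell returns an all-zero grid
with an `empty` flag rather than an error. Binarization at threshold t maps
values strictly above t to 1; a pixel exactly at the threshold is background.
Accumulation defaults to the behavior-filtered viewing ROIs; a
`source="viewports"` mode accumulates every raw viewport instead, since
either reading of the accumulation set is defensible.

## Patch extraction and data split

Slides are analyzed at the 10× frame and cut into non-overlapping square
patches anchored at (0,0); trailing partial patches are dropped so all
patches share one shape. Tissue is segmented by an HSV rule (saturation
> 0.07 and value < 0.95, then 5×5 majority smoothing); patches under 5%
tissue are discarded. The case-level split is stratified by consensus class
with `n_val = round(0.2·n)`, `n_test = round(0.2·n)` per class and the
remainder to train (0.2·n never lands on .5 for integer n, so no tie-break
is needed); classes with fewer than 3 cases fall back to train with a
warning. Splitting at case level prevents texture leakage between splits.

## Heatmap regression models

Three encoder-decoder architectures share a residual encoder built on the
package's own numpy autograd engine (`gazemap.nn`: conv / transposed conv /
max-pool / nearest upsampling / group-norm / scSE, Adam, fused losses;
gradients are verified against finite differences):

* **ConvAE** — ResNet-18-topology encoder (stage depths 2-2-2-2, overall
  stride 32) and a plain decoder of five stride-2 transposed convolutions,
  ReLU between stages, final sigmoid. No skips: reconstruction happens from
  the bottleneck alone.
* **U-Net** — ResNet-34-topology encoder (3-4-6-3) and a five-stage decoder
  with nearest upsampling, skip concatenation and two 3×3 convolutions per
  stage, sigmoid 1×1 head.
* **Attention U-Net** — the same plus a concurrent spatial/channel
  squeeze-and-excitation (scSE) block after every decoder stage.

Residual blocks use group normalization instead of batch normalization so
tiny desk-scale batches train stably. The decoder channel ladder mirrors
the encoder (4w, 2w, w, w/2, w/4) but is floored at 8 channels: at desk
widths the unfloored ladder ends in a 2-channel stage whose ReLUs die and
cap the attainable output range.

Training: Adam at lr 10⁻³, per-pixel MSE in raw [0,1] heatmap space, inputs
(never targets) normalized with ImageNet statistics (mean 0.485/0.456/0.406,
std 0.229/0.224/0.225), early stopping after 5 epochs without validation
improvement with best-weights restoration. Augmentation applies flips and
crop-resize (to 87.5% and back) jointly to image and target, and sharpening,
embossing, brightness, hue/saturation, grayscale and contrast to the image
only, in randomized order. `pretrained=True` loads encoder weights from a
user-supplied checkpoint; there is no weight download, and the default is
seeded random initialization.

Two profiles are exercised: the full-scale profile (widths from 64
channels, 256- or 512-px patches, batch 64/32) matches the published
training conditions but is GPU-scale; the desk-scale profile used
throughout the tests runs width-8 encoders on 64×64 patches with batch 4,
so the entire learning loop finishes in minutes on one CPU core.

## Bag-of-words baseline

Sliding 1024×1024 bags at stride 512; 8×8 words of 128 px per bag. Word
features: Lab histogram (8 bins × 3 channels) concatenated with a uniform
LBP histogram (radius 1, 8 neighbours, 10 bins), each block L1-normalized —
the literature specifies only "Lab color and LBP texture", so the exact
binning is a package choice exposed in `BagConfig`. A seeded k-means
codebook (k = 40) turns each bag into a 64-word cluster-frequency histogram;
a 100-tree random forest classifies bags as ROI/non-ROI, where a training
bag is positive when viewing ROIs cover at least half of it (threshold
configurable — only "intersection" is specified). Test-bag ROI
probabilities are painted onto the slide and averaged where bags overlap.
Synthetic slides are far smaller than real WSIs, so the cohort tests use a
proportionally shrunk geometry (128/64/16) that preserves the 8×8-words and
40-cluster structure.

## Metrics

MSE is the mean squared per-pixel difference. SSIM uses the standard
windowed form (11×11 Gaussian window, σ = 1.5, K₁ = 0.01, K₂ = 0.03, data
range 1) with configurable component exponents α, β, γ defaulting to 1; the
implementation matches `skimage.metrics.structural_similarity` to machine
precision at the defaults, and skimage serves as the independent oracle in
the tests. F1 is the standard harmonic mean 2PR/(P+R). Empty-denominator
conventions: a score whose denominator is 0 is 0, except that comparing two
empty masks scores 1 (vacuous agreement). Test-set reports average MSE/SSIM
over cases and pool pixel counts across cases for precision/recall/F1/IoU
(case-macro averages are reported alongside, since either aggregation is a
reasonable reading). Multi-class diagnosis uses micro-averaged
sensitivity/specificity/F1 from one-vs-rest counts summed over classes.

## Synthetic cohort

`generate_slide` plants a rotated elliptical pink tissue blob (smooth
Gaussian color noise) on white glass and darker purple lesion ellipses with
high-frequency noise fully inside the tissue; tissue and lesion masks are
exact. The lesion signature (hue shift + texture) is chosen so that both
LBP/Lab features and a small network can separate lesion from tissue.
Optional *distractor* blobs share the signature but are excluded from the
lesion mask — regions that look suspicious yet carry no diagnostic weight.

`plan_session` scripts a session: a low-zoom scan (2–4×, dwells under 2 s),
then per visited lesion an approach dwell at 8–20× (a fixation), a brief
deeper peek at 1.5× that zoom (a zoom peak), a return dwell and small
same-zoom moves of 15–60 px (slow pannings that also fixate). Dwells are
drawn from 3–10 s, inside the (2 s, 60 s] fixation band. A viewport at zoom
z spans 768/z reference pixels. The plan records exactly which entry
carries which behavior, so detector recall is checkable against ground
truth (and equals 1 by construction when the profile respects the detector
thresholds). Diagnoses equal the consensus class, flipped to an adjacent
class with probability `diagnosis_error_prob` (default 0.2).

What the generator does **not** emulate: real H&E texture and stain
variation, scanner artifacts, irregular lesion morphology, idiosyncratic
scanning styles, re-reads, or viewports whose logged geometry disagrees
with the rendered screen. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that its signal flow works end-to-end —
not that the models reach any particular accuracy on clinical data.

## Study conditions of the end-to-end tests

* *Planted-pattern recovery*: 12 cases × 3 pathologists, no distractor
  visits; every planted behavior must be recovered, and at least 70% of
  each case's heatmap mass must fall inside the lesion mask dilated by the
  largest inspect viewport (96 px at 8×).
* *Learning comparison*: 24 cases × 5 pathologists (five readers per case,
  matching the viewing-session design the log model assumes). A width-8
  U-Net trained 5 epochs (batch 4, lr 10⁻³) on 64×64 patches must reach
  mean test IoU ≥ 0.3 at threshold 0.5 against the planted lesion masks and
  a higher pooled F1 than the BoW baseline on the same split. The 24-case
  cohort gives the 5-epoch budget enough gradient steps for the sigmoid
  outputs to polarize; with 12 cases the optimizer stops short of the 0.5
  threshold even though the ranking of regions is already correct.
* *Diagnosis fusion*: 60 cases whose class equals the lesion count (1–4),
  0–2 distractor blobs per slide, oracle heatmaps equal to the lesion
  masks, inputs downscaled to 64×64. Matched 3- vs 4-channel classifiers
  (identical seeds, splits and architecture except the first layer) are
  trained for 30 epochs over 5 seeds; the 4-channel mean micro-F1 must not
  be lower. Distractors make RGB-only lesion counting ambiguous, which is
  exactly the situation in which an attention prior should help.

## Numerical choices and degenerate inputs

* Difference-array accumulation leaves ~10⁻¹³ negative residue where the
  true sum is 0; values are clipped to [0, ∞) before normalization.
* Max-pooling breaks ties toward the first maximal position so gradients
  are deterministic.
* k-means assignment breaks center ties toward the lowest index.
* Empty logs, all-background slides, zero-duration ROI sets, and empty
  masks all return well-defined results (empty lists, zero grids, flagged
  heatmaps, score 1 for two empty masks) rather than raising.
* All stochastic stages consume an explicit seed; cohort generation,
  training, k-means and the random forest replay bit-identically.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; full-scale widths and
  256/512-px patches are supported by the code but impractical without
  hours of CPU time.
* SSIM exponents other than 1 use a signed-power extension (sign(x)·|x|^a)
  to keep negative structure terms meaningful; published SSIM variants
  rarely exercise this path.
* The BoW baseline's feature parameterization follows common practice, not
  a published exact recipe; its absolute scores are sensitive to bag
  geometry on small synthetic slides.
* Pyramidal TIFFs are read at the base level only; callers must supply
  slides already rendered at the 10× reference frame.
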