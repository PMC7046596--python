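# Methods

This note records the models and procedures histofuse implements, the
defaults and why they are set where they are, what the synthetic generators
do and do not emulate, and the numerical choices a maintainer would want
spelled out.

## Mask-level non-maximum suppression

Candidates are scored binary masks over one tile grid. The fusion loop is
greedy and deterministic:

1. pick the remaining candidate with the highest score (ties: larger area,
   then lower `source_id`, then input order);
2. in `merge_union` mode, union into it every remaining candidate whose IOU
   with the *picked* mask is ≥ `merge_iou` (the winner keeps its own
   score); the merge set is decided against the winner as picked, while the
   subsequent suppression uses the grown mask — the one place the verbal
   description of the procedure is ambiguous, resolved this way and frozen;
3. suppress every remaining candidate whose IOU with the (possibly grown)
   winner is strictly greater than `suppress_iou`;
4. repeat until no candidates remain, then rasterize; residual overlaps
   (IOU ≤ N but non-zero) go to the higher-priority mask under the same
   score/area/source tie rule.

Defaults: `suppress_iou = 0.5` (the conventional detection-NMS operating
point; no value is prescribed by the method description), `merge_mode =
merge_union`, `merge_iou = 0.8`. Strict `>` for suppression and `≥` for
merging. Both a pure-suppression and a union-merging reading of the
procedure are defensible, so both are implemented behind `merge_mode` and
neither is claimed as canonical.

**Cross-fold false-positive removal.** A pure greedy loop can only remove
*overlapping* duplicates; a spurious mask that no other model predicts
overlaps nothing and survives, so pooling five folds would *accumulate*
false positives rather than remove them. The ensemble's advertised
false-positive reduction is therefore implemented as consensus: during the
loop each output instance records which source folds attested to it (the
winner plus every candidate merged into or suppressed by it), and
`fuse_folds` drops instances attested by fewer than `min_support` folds.
The default is a majority, `ceil(n_folds/2)`, which degenerates to keeping
everything for one or two folds; `min_support=1` disables the filter and
recovers the raw greedy result. On the standard synthetic conditions this
single rule is what turns five ~0.78 folds into a ~0.90 fused result with
zero residual false positives.

## Segmentation scoring

*Standard Dice* pools all labeled pixels of each map and compares the two
foregrounds; it is blind to how nuclei are individuated.

*Object-aware Dice* penalizes splits and merges. Objects are matched
one-to-one greedily by descending pixel overlap (ties: descending pair IOU,
then ascending gt label, then ascending prediction label), and the score is
`2·Σ_matched |g∩p| / (Σ_gt |g| + Σ_pred |p|)`. Splitting one object into
two equal tiling fragments leaves standard Dice at 1.0 but halves this
score, because only one fragment can match. The historic formulation of the
split/merge-aware metric lives in a prior publication that is not
reproduced here; this object-aware surrogate has the same intent and sits
behind a single function (`dice_modified`) so it can be swapped without
touching callers. Greedy matching is not guaranteed optimal; against an
exhaustive (Hungarian) assignment on small random fixtures its total
matched overlap stays within 90%, and the metric's orderings are unaffected
in practice. The *challenge score* is the arithmetic mean of the two Dice
variants.

*AP over an IOU grid*: at each threshold t (default 0.05…0.95, step 0.05 —
19 values; the grid step is a convention, not a prescribed value),
predictions are visited in descending score (ties: larger best-available
IOU) and claim the unused ground-truth object of highest IOU when that IOU
≥ t. The per-threshold score is `TP/(TP+FP+FN)` — the nucleus-challenge
convention that folds missed objects into the denominator — and the
reported value is the mean over the grid.

Degenerate inputs: comparing two empty segmentations (or empty-vs-empty
IOU/Dice) raises rather than returning 1.0, to surface broken fixtures; an
empty prediction against a non-empty truth scores 0.

## Mask morphology

Component labeling is 8-connected everywhere (one module constant). Hole
filling fills background components not reaching the border. Touching-blob
splitting erodes with a disk (the structuring-element shape is not
prescribed anywhere; a disk is the isotropic choice and is documented as a
guess), relabels the surviving seeds, and assigns every original foreground
pixel within the erosion radius of a seed to its nearest seed, ties to the
lower label. The output never contains a pixel that was not foreground in
the input; pixels of thin necks beyond the radius of any seed are dropped
(standard opening behavior). If erosion wipes the mask out entirely, the
input is returned as one instance with an "over-eroded" warning.

Mask sets serialize as COCO-style *uncompressed* column-major RLE JSON with
`score` and `source_id` per mask; label maps as 16-bit single-channel
PNG/TIFF. Both round-trip losslessly for non-overlapping instances.

## WSI patch pipeline

Tissue detection thresholds the HSV representation channelwise. No
numerical HSV bounds are prescribed by the source methods, so the defaults
are wide-open hue/value with saturation ≥ 0.05 — glass is near-white
(saturation ≈ 0), any stained tissue is not. Holes and clumps smaller than
64 px at the working scale are cleaned up, and detection on large tiles is
run at a downsample factor (default 32). The alternative detector is an
Otsu split of the grayscale tile, keeping the darker class.

Grid extraction tiles each tissue bounding box row-major; patches crossing
a box edge are dropped, not padded. Random extraction samples window
origins uniformly (without replacement) among those whose tissue fraction
is ≥ 0.5 by default, via an integral image; it returns fewer with a warning
if the tile cannot supply the requested count.

Reinhard normalization matches per-channel mean/std in CIELAB to a target;
a constant patch passes through with a warning (zero std). Histogram
equalization is the classic per-channel min-shifted CDF mapping, so a
two-level channel spreads to 0 and 255 exactly.

Isolation-forest filtering accepts any per-patch feature vectors (the
feature-learning autoencoder is out of scope — the filter is agnostic to
where the vectors come from) and keeps `⌈(1−contamination)·n⌉ ± 1` inliers;
contamination 0 short-circuits to keeping everything.

Rotation balancing grows every minority class to the majority count,
exhausting the deterministic dihedral transforms (90°/180°/270°, flips,
transposed flips) before drawing random rotations within ±15°; originals
are never dropped and augmented copies are flagged. Effective-patch
selection keeps patches with max class probability ≥ 0.99 (the prescribed
operating point) and falls back to the single most confident patch, with a
warning, when nothing qualifies. Patch votes aggregate either as the mean
probability vector or as argmax-vote fractions (exact ties contribute half
a vote to each class); both return a proper distribution.

## Case fusion

Class order is fixed as (oligodendroglioma, astrocytoma) and every tie rule
resolves toward the earlier class; a tie between the two modalities'
confidences resolves to pathology. `weighted_average` is the convex
combination `α·f(X_p) + (1−α)·g(X_r)`; α is grid-searched (step 0.01) for
maximum training accuracy, returning the *smallest* maximizing α for
determinism. How α was estimated originally is not specified beyond
"empirically"; an exhaustive accuracy grid is the transparent choice.

The dropout ensemble draws k concatenated pathology+radiology feature
vectors per case from two extractors satisfying a small contract
(fixed-length `sample(case_id, seed)`, a `stochastic` flag). Child seeds
are derived with `numpy.random.SeedSequence`, so the whole procedure is
bit-reproducible from one integer. A linear SVM (primal liblinear-style
solver) is trained on all sampled vectors, each inheriting its case label;
`C` weighs the *mean* hinge loss — divided internally by the sample count —
so the fit is invariant to duplicating the sample set or raising k.
Test-time aggregation is not specified by the source methods; the default
is majority voting over the k sampled vectors (vote fractions become the
class probabilities), with sigmoid-of-mean-margin as the alternative. The
extractor feature lengths are configurable (the source description is
internally inconsistent about 50- vs 100-dimensional vectors); the
synthetic cohort defaults to 50+50.

The radiomics head reduces 105-dimensional feature vectors to 16 principal
components and fits a liblinear logistic regression. Within the fivefold
cross-validation the PCA is refit on each training fold — fitting it on all
data first would leak test information into the reported accuracy — while
the returned deployable model is fit on the entire training set.

## Synthetic data

`gen_nuclei_scene` places n random ellipses (radii 5–9 px by default) with
a one-pixel exclusion halo, so the truth map has exactly n 8-connected
instances, and paints them blue-purple on a noisy pink-white background.
The standard fixture is 10 nuclei on a 256×256 tile, a nucleus density
comparable to hand-annotated glioma tiles of a few hundred pixels across.

`perturb_truth` emulates one fold's model: each surviving instance is
translated by up to `jitter_px` per axis and occasionally dilated or eroded
by one pixel; a `fn_rate` Bernoulli drops instances; `round(fp_rate·n)`
random blobs are added; `split_rate` instances are cut in two by a random
line through their centroid; `merge_rate` instances grab their nearest
neighbor. Scores are `clip(0.5 + 0.5·IOU(mask, its source truth pixels) +
N(0, σ), 0.05, 1)`, so a perfect mask scores 1, a false positive ~0.5 —
confidence correlates with quality the way a calibrated detector's would.
The returned metadata (kept/dropped/split/merged/added/lost) reconciles
exactly with the emitted mask count, and is tested to. Standard
fold-disagreement conditions: jitter 1 px, fp_rate 0.2, fn_rate 0.1, score
noise σ = 0.05.

`gen_cohort` draws per-case, per-modality standard-normal feature vectors
whose first coordinate is shifted by ±d/2 by class, where d is the
modality's informativeness in sd units; modality probabilities are the
Bayes posterior `sigmoid(d·x₀)`, so a stream is exactly as good as its
informativeness allows (d = 3 ≈ 93% accuracy, d = 0 is chance). Extractors
apply multiplicative Bernoulli(1−dropout) masks with inverted scaling. The
default cohort is 32 cases split 16/16, the scale of the original training
cohort; the fusion studies run at n = 200 so held-out accuracies are stable
across seeds.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: stain variability, texture, overlapping/clumped
nuclei, spatially correlated model errors, miscalibrated confidence scores,
class imbalance, and any real relationship between image content and the
feature vectors. The tests establish that the fusion, scoring and
decision machinery is correct and beneficial under controlled error models,
not that any particular accuracy will transfer to challenge images.

## Limitations

- The object-aware Dice is a documented surrogate, not the historic
  formula; absolute values are not comparable across implementations.
- Greedy matching and greedy AP assignment are conventions, not optima.
- No pyramidal WSI decoding; inputs are ordinary RGB tiles.
- No learned components: scores, probabilities and feature vectors must be
  supplied by the caller or by the synthetic generators.
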