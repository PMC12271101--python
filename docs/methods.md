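# Methods

## Problem and model

The package stages liver fibrosis in Sirius-Red-stained rodent liver
sections under Kleiner's CRN scheme, either as five classes (0–4) or as
seven (0, 1A, 1B, 1C, 2, 3, 4, with the score-1 subclasses distinguished
by lesion location). The unit of annotation is the whole slide; the unit
of learning is the patch. Every retained patch inherits its slide's
expert score, a CNN classifies patches, and the slide-level stage is the
modal patch class. This weak-label design assumes the dominant tissue
pattern of a slide matches its expert score; heterogeneous slides are
exactly where the patch-ratio vector (used for one-vs-rest curves and
heatmaps) carries more information than the argmax.

## Patch geometry

Tiles are anchored at the slide origin, non-overlapping, of constant
physical size 0.27 × 0.27 mm — 1024 px at 40× (0.264 µm/px) or 512 px at
20× (0.528 µm/px) — with partial edge tiles dropped. Tissue is
"grayscale luma strictly below 0.88 of full brightness"; a patch is
retained when its tissue fraction is ≥ 0.75 (inclusive: a patch with
exactly 75% tissue is kept). Retained tiles are BOX (area-average)
downsampled to 256 × 256. The grayscale threshold is configuration: the
original protocol thresholded manually, and the default 0.88 was chosen
so near-white glass is background while pale-yellow parenchyma counts as
tissue under the simulator's color model.

## Preprocessing

The fixed order is highlight → augment (training only) → normalize.
Collagen highlighting thresholds HSV: hue in the wrapping red band
[0.92, 1] ∪ [0, 0.06], saturation ≥ 0.3, value ≥ 0.15. In-band pixels
are pushed to full saturation/value at their own hue; out-of-band pixels
are blended halfway toward their grayscale value rather than deleted —
staging is location-dependent, so the network needs the surrounding
architecture, but at reduced contrast. Whether the original heuristic
masked or merely emphasized is unknowable from its description; the
blend factor records that ambiguity and is exposed as an argument.
Augmentations are 90°-multiple rotations and flips (pixel-multiset
preserving) plus optional brightness/contrast/gamma and
saturation/value/hue-like channel shifts, all clipped to the valid
range; normalization is pixel/255. Validation and inference run the
identical path minus augmentation.

## Classifier and optimization

The patch classifier (`tiny_cnn`) is a NumPy implementation: inputs are
centered, average-pooled 4×, passed through three 3×3 conv blocks (16,
32, 64 channels, each conv → batch norm → ReLU → 2× max pool), pooled to
a 4×4 map and mapped through a 512-unit batch-normed hidden layer (the
512-dimensional penultimate feature is kept deliberately) to the class
logits. Batch normalization is the package's own architectural choice:
with only a handful of minibatches per desk-scale epoch, an
unnormalized network does not converge within the 50-epoch budget at
the fixed 10⁻³ learning rate. A `resnet34` option is reserved in the
configuration but raises, as no deep-learning backend is bundled and a
34-layer network is not trainable at desk scale on one CPU.

The loss is class-weighted cross-entropy with w_i = ΣN_j/(2·N_i)
computed per fold from the training split's patch counts (never from
global tables), reduced as a weight-normalized mean (sum of per-sample
losses over the sum of the selected weights). This reduction keeps the
loss scale independent of the batch's class mix; with equal counts it
reduces exactly to the unweighted mean. The optimizer is RAdam
(rectified Adam: momentum-SGD warm-up while the variance estimate is
unreliable, variance-rectified updates afterwards) with lr 10⁻³, β₁ 0.9,
β₂ 0.999, ε 10⁻⁸, minibatches of 128. One epoch is one seeded-shuffle
pass over all retained training patches. After each epoch the validation
slides are scored end to end (patch prediction → majority vote) and
training stops as soon as slide-level unweighted kappa *and* MCC exceed
0.8, or at 50 epochs; the returned checkpoint is the stopping-epoch
model.

## Aggregation and evaluation

Slide stage = modal patch class; ties break toward the more severe stage
(severity-conservative reporting; `tie_break="lower"` is available). The
ratio vector r (class frequencies among the slide's patches) sums to 1
and r[target] is the slide's score in one-vs-rest analyses.

Metrics per fold: Cohen's kappa with 0/1, linear |i−j|/(C−1) and
quadratic ((i−j)/(C−1))² disagreement weights over the ordinal stage
ranks (0,1A,1B,1C,2,3,4 ranked 0..6, making weighted kappa well-defined
in 7-class mode); Gorodkin's multiclass MCC; one-vs-rest AUROC (rank
statistic, ties ½) and AUPRC (step-wise average precision, both via
scikit-learn) macro-averaged over the classes that admit a
positive/negative split, with a warning for those that do not. Fold rows
are averaged with an unweighted mean — classes first within a fold, then
across folds — and displayed at three decimals. Degenerate confusion
matrices (one-cell mass, zero-variance marginals) return 0 with a
warning rather than raising.

## Synthetic slides

The simulator's purpose is a solvable, fully labeled stand-in for the
proprietary animal data. Geometry is computed in microns and scaled by
the magnification, so a 20× and a 40× render of the same seed cover the
same physical scene. Lobules are hexagonally packed circles (default
radius 60 µm — deliberately small so that every 0.27-mm patch contains
several central veins and portal vertices and thus carries the stage
signature); central veins sit at lobule centers, portal tracts at the
Delaunay-triangle centroids of the vein lattice. Vessels are lumens with
1.2-µm collagen walls — the stage-0 baseline.

Stage recipes: 1A = 7 short (10–16 µm) radial strands per vein in the
zone-3 annulus; 1B = 3 × that density (the 3× ratio is a free parameter:
the scheme distinguishes the two only as mild vs moderate); 1C =
2.5-µm-wide collagen annuli around portal tracts only; 2 = union of 1B
and 1C; 3 = stage 2 plus vein-to-nearest-portal septa, about one per
lobule, each guaranteed to intersect two distinct vessel disks; 4 =
strands + rings + a septal network along every Voronoi ridge of the vein
lattice (closed boundaries partition the tissue into nodules) plus
sparser bridges. Mean collagen fraction is strictly increasing along
0 < 1A < 1B ≤ 2 < 3 < 4 (1C differs in location, not amount — it is not
ordered against 1A/1B). Colors come from HSV centers (collagen ≈ red
(0.98, 0.78, 0.62); parenchyma pale yellow (0.13, 0.42, 0.90)) with
optional per-pixel Gaussian jitter; the default jitter is zero, making
the stain colors exactly separable. Artifacts (overstain blobs pulled
toward the collagen color, dark debris) recolor pixels without touching
ground truth — by definition they are not fibrosis.

A mask-level staging oracle inverts the recipes (wall-stripped collagen
burden, nodule partition count, vessel-bridging components, per-
compartment collagen vs the area its minimal lesion would cover) and
recovers the generating stage for ≥ 95% of scenes across canvas sizes;
this certifies the task is solvable before any learning happens.

What the simulator does *not* model: steatosis, ballooning,
inflammation, staining-protocol variation, scanner optics, real sinusoid
texture. Passing tests therefore demonstrate that the pipeline's
mechanics (tiling, filtering, preprocessing, optimization, aggregation,
metrics) are correct and that the architecture can learn
location-dependent collagen patterns — not that the reported real-data
performance transfers.

## Experiment orchestration and problem sizes

A single global seed fans out through independent seed sequences to the
simulator, the fold split and each fold's training run; identical
config + seed reproduces every output byte for byte. Stratified folds
deal each class's shuffled slides into k near-equal parts, rotating the
fold that receives the remainder with the class index so no fold
accumulates every remainder (per-class fold sizes differ by ≤ 1).

The desk-scale benchmark uses 12 slides per stage (84 WSIs, 1024-px
scenes at 20×, 4 patches each — 336 patches), seven-class mode, one
held-out fold of five. Under the reference optimization protocol this
reaches slide-level validation kappa and MCC of ~0.86 in 20–30 epochs,
comfortably inside the 50-epoch stopping budget, in about three minutes
on one CPU. Geometric-only augmentation is the pipeline default on
synthetic data: the simulator's deterministic stain colors leave nothing
for color jitter to regularize — it only erases the class signal that
collagen quantity carries. On real slides with staining variability the
full color augmentation (available in `AugmentConfig`) is the
appropriate setting.

## Known limitations

- Majority vote ignores patch confidence; probability-averaging or
  learned aggregation is deliberately out of scope.
- Artifact injection exists, but artifact *detection* does not; an
  overstained slide will shift patch predictions upward.
- The 1A/1B boundary is a density convention (3×), not a biological
  constant.
- The NumPy backend is single-threaded and desk-scale; it is not a
  substitute for GPU training on gigapixel datasets.
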