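# Methods

## The problem

Cone-beam CT (CBCT) of the head is the workhorse 3-D modality of
orthodontics and oral–maxillofacial surgery.  Manual segmentation of
skull structures (mandible, maxilla, cranial base, vertebrae, skin) from
these low-dose, low-SNR scans takes hours per patient and varies between
operators and centers.  `cbctseg` implements an automatic pipeline:
intensity normalization, a transformer-based segmentation network
trained on random crops, overlapping sliding-window inference over whole
volumes, morphological cleanup, and a voxel-overlap evaluation suite
designed for heavy class imbalance (bone is typically only a few percent
of a head volume).

## Pre-processing

Scans arrive with center-dependent spacing (0.16–0.5 mm) and contrast.
Each scan and its ground-truth mask are resampled to an isotropic
working grid (default 0.4 mm; linear interpolation for images, nearest
neighbour for labels, output size `ceil(size x spacing / target)` so no
anatomy is cropped).  Contrast is normalized by a cumulative-histogram
window: the histogram is built *excluding the background*, the window
opens where the cumulative fraction reaches `x_min_pct` (default 1%) and
closes at `x_max_pct` (99%), and intensities are clamped and affinely
mapped to [0, 1].

Two numerical choices here are deliberate:

- **Background = modal intensity.**  Air outside the patient dominates a
  head scan's histogram and is near-constant, so the mode is a robust
  stand-in for an unknown background value.  The histogram uses 1024
  uniform bins (configurable); when an image has at most that many
  distinct values the histogram is exact over those values, which makes
  low-cardinality examples reproduce hand computation exactly.
- **The 0% endpoint means the global minimum.**  At `x_min_pct = 0`
  every intensity satisfies the cumulative condition, so the window
  opens at the global minimum.  A consequence worth having: re-applying
  `(0, 100)` to an already-normalized image is an exact no-op.

Ground-truth masks are canonicalized: any nonzero label becomes 1, and
internal cavities (background pockets with no 6-connected path to the
volume border) are filled.  Face-adjacency for the background is the
stricter choice and fills the most aggressively, matching the intent of
solid bone masks.

## The network

The segmenter is a UNETR: a cubic window of the scan (full scale
128 voxels) is cut into non-overlapping 16-voxel patches, each flattened
and linearly projected into an embedding (full scale 768-wide) with a
learned position embedding; a stack of pre-norm transformer blocks
(12 layers, 12 heads, 3072-wide GELU feed-forward, dropout 0.05)
encodes the sequence.  The decoder rebuilds the segmentation U-Net
style: token grids tapped from intermediate layers (3/6/9/12 at full
scale) are upsampled by stacked kernel-2/stride-2 transposed
convolutions to intermediate resolutions, and the stream rising from the
final layer is repeatedly upsampled, concatenated with the matching
lateral (or, at full resolution, with a convolutional encoding of the
raw crop) and mixed by a 3x3x3 convolution + instance norm + ReLU.
Decoder widths follow `feature_size x {8, 4, 2, 1}` (feature_size 16 at
full scale).  The head is a 1x1x1 convolution to two classes.

Design choices the architecture description leaves open, fixed here:

- transformer depth 12 with taps at {3, 6, 9, 12} (the reference UNETR
  layout); pre-layer-norm blocks with GELU;
- each decoder block uses *one* convolution after its upsample (the
  reference uses two).  On CPU the full-resolution convolutions dominate
  the training cost and one mixing convolution suffices at the scales
  this package trains at;
- the two-class head's bias is initialized to the log-odds of a ~10%
  foreground prior — bone occupies only a small fraction of a head
  volume, and starting from the anatomical prior instead of a 50/50
  guess saves the optimizer the first many epochs of merely correcting
  gross over-segmentation;
- tie-break and normalization details live in config, so a CPU-sized
  network (window 32, hidden 64, 2 layers, 4 heads, feature_size 8)
  exists for tests and the desk-scale study.

### Numerics

The network, its gradients and Adam (with L2-coupled weight decay, the
common `torch`-style semantics) are implemented on a small reverse-mode
autodiff engine over float32 NumPy arrays (`cbctseg.nn`).  Convolutions
are sums of shifted channel-mixing BLAS calls, channels-last;
transposed kernel-2/stride-2 convolutions reduce to a tensordot plus an
interleaving reshape.  Every primitive's gradient is verified against
central finite differences in the test-suite, and the whole network's
gradient was spot-checked end to end the same way.

## Training

One binary model per structure.  Scans are grouped by clinical center
and split 70/10/20 *within each center* (floor for train/val, remainder
to test), so no center dominates a partition.  Each step draws `N_i`
scans and `N_s` random crops from each (window-sized, uniform corners,
small volumes symmetrically zero-padded), augments them, and minimizes

    L = (λ_d · DL + λ_c · CE) / (λ_d + λ_c),      λ_d = λ_c = 0.5

where `DL = 1 − (2Σ p g + ε)/(Σ p² + Σ g² + ε)` is the soft Dice loss
(ε = 1e-5 keeps all-background crops defined; the printed formula is
0/0 there) and CE is the mean voxel-wise cross-entropy (class weights
default to 1; the loss is the plain mean of weighted terms, so scaling
the weights scales the loss).  Equal loss weights are the neutral
reading of "weighted average" absent printed values.

Augmentation (probabilities are per draw): per axis an independent 25%
flip and 25% 90-degree rotation (applied identically to image and
label); with 50% probability an intensity shift of 0.1 with uniform
random sign; with 80% probability a gamma draw from [0.5, 2] — intensity
ops touch the image only, which is re-clamped to [0, 1].  The source
recipe lumps "flip and rotation" at one 25% figure; independent events
is the reading implemented, and the empirical event rates are tested
against binomial intervals.

Validation predicts whole held-out volumes by sliding window
(overlap 0.2) — by default *with* augmentation minus the cropping, as
the original recipe states, switchable off — and the checkpoint with the
best validation Dice is kept.  All randomness fans out from one master
seed into separate split/crop/augment/dropout streams, so runs are
reproducible bit for bit.

## Inference and post-processing

Whole volumes are tiled with windows at a configurable overlap (stride
`floor(window x (1 − overlap))`, last window clamped to the volume edge
so coverage is total; 0.5 is the test-time default, 0.8 for high
precision).  Per-voxel class probabilities are blended by uniform
averaging over covering windows (a Gaussian importance map is available
behind a flag; the blending mode used by the original runs is not
documented).  Argmax with ties broken toward background yields the raw
mask; cleanup keeps the largest 26-connected component (ties: smallest
lexicographic corner), fills holes on the working grid (where the
morphology is scale-consistent), and resamples the result back onto the
original scan geometry by nearest neighbour, so the output overlays the
input voxel for voxel.

## Evaluation

For a prediction A and ground truth M: Dice `2|A∩M|/(|A|+|M|)`,
F2 `TP/(TP + 0.2 FP + 0.8 FN)` (recall twice as important as precision —
clinically, over-segmentation beats under-segmentation), accuracy,
recall, precision, and AUPRC with its chance baseline (the foreground
prevalence).  The PR curve thresholds on all unique scores when there
are at most 1024 of them, else on 1024 uniform quantiles; the curve is
anchored at R = 0 by extending the strictest precision horizontally and
reaches R = 1 at the loosest threshold, which makes an uninformative
constant predictor integrate exactly to the prevalence.  The area is the
standard trapezoid Σ (R[n] − R[n−1])(P[n] + P[n−1])/2; a published
variant that multiplies by the *difference* of precisions telescopes to
~0 on flat curves and is kept only behind an audit flag.  Metrics raise
on empty-vs-empty comparisons rather than silently returning 1, to
surface pipeline failures.

## The phantom generator

Clinical CBCT datasets of this kind are not shareable, so the package
ships a generator of skull-like phantoms that reproduce the statistical
structure the pipeline assumes: a dominant near-constant air background;
a bright ellipsoidal bone "shell" (semi-axes drawn from 0.45–0.58 of the
half-grid, wall ~2.5 voxels) optionally enclosing a dark cavity;
optional small bright satellite blobs that are *not* ground truth (so
largest-component filtering has a measurable effect); Gaussian noise
(sd 40 on a 100/1000 air/bone scale); per-phantom gamma in [0.8, 1.25]
and per-center intensity offsets (120 units between centers) emulating
scanner differences; anisotropic spacing drawn per axis from
[0.16, 0.5] mm.  Ground truth is the solid (cavity-filled) shell without
satellites; at the defaults it occupies roughly 5–10% of the volume,
matching the class imbalance of real bone structures.

What phantoms do *not* emulate: real anatomy's shape complexity, beam
hardening, metal artifacts, soft-tissue gradations, and
center-dependent annotation style.  Tests passing on phantoms therefore
establish that the pipeline's machinery is correct and learnable — not
that the reported full-scale clinical accuracy transfers.

## The desk-scale study

`cbctseg.experiment.scaled_down_study` replays the full study in
miniature on one CPU: 20 phantoms of 64 cubes from 2 pseudo-centers,
70/10/20 split, the tiny network (window 32, patch 16, hidden 64,
2 layers, 4 heads, feature_size 8, dropout 0.05), combined loss, Adam
at lr 1e-4 with weight decay 1e-5, one scan x four crops per step
(14 steps/epoch — at a fixed learning rate the optimizer's travel grows
with the step count, so many small steps beat few large ones on a fixed
epoch budget), up to 30 epochs with validation every second epoch and
without validation-time augmentation (which would inject gamma/flip
noise into checkpoint selection), then full-pipeline evaluation of the
4 held-out phantoms at overlap 0.5.  These sizes were chosen so a run
takes a few minutes; with them the held-out mean Dice lands above 0.8
and post-processing never hurts any held-out phantom (satellites make
it strictly help).  The same driver backs `scripts/acceptance.py` and
the test-suite.

## Known limitations

- No pretrained weights are distributed; the full-scale configuration
  needs GPU-class budgets to train.
- CPU training is minutes-scale only for the tiny configuration.
- Multi-class heads beyond binary-vs-background are out of scope (one
  model per structure by design), as are surface-distance metrics,
  DICOM writing and anonymization.
- Resampling assumes orthonormal direction matrices and operates in
  physical (LPS) space; oblique acquisitions are resampled, not
  reoriented.
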