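# cbctseg

Automatic multi-anatomical segmentation of cone-beam CT (CBCT) head
scans: a UNETR (vision-transformer encoder, U-shaped convolutional
decoder) trained on random crops of contrast-normalized volumes, applied
to whole scans by overlapping sliding windows, cleaned by
connected-component and hole-filling morphology, and evaluated with an
imbalance-aware metric suite.  A synthetic skull-phantom generator
stands in for clinical data, so the entire pipeline — including a small
training run — is reproducible on one CPU with no downloads.

**Who it is for.**  Researchers in dental/craniofacial imaging who need
a transparent, dependency-light reference implementation of this
segmentation pipeline, and anyone who wants to study its components
(histogram contrast windowing, crop-based training, sliding-window
blending, PR-curve evaluation) in isolation.

## The method in brief

A scan is resampled to an isotropic 0.4 mm grid and its intensities
windowed between the 1% and 99% points of the background-excluded
cumulative histogram, then rescaled to [0, 1].  The network sees cubic
windows (128 voxels at full scale): each window is cut into 16-voxel
patches, linearly embedded (hidden size 768, 12 heads, 12 pre-norm
transformer layers, feed-forward 3072, dropout 0.05), and decoded
U-Net-style from skip connections tapped at layers 3/6/9/12.  Training
minimizes the equally weighted average of the soft Dice loss

    DL = 1 − 2 Σᵢ pᵢgᵢ / (Σᵢ pᵢ² + Σᵢ gᵢ²)

and voxel-wise cross-entropy, with Adam (lr 1e-4, weight decay 1e-5) on
batches of N_i scans x N_s random crops under random flip/rotation,
intensity-shift and gamma augmentation.  Whole-volume prediction blends
overlapping windows (overlap 0.5 at test time), argmaxes, keeps the
largest 26-connected component, fills holes, and resamples back onto
the original scan geometry.  Quality is reported as Dice, F2
(= TP/(TP + 0.2 FP + 0.8 FN)), accuracy, recall, precision, and AUPRC
against its chance baseline (the foreground prevalence).  Details and
design rationale: [docs/methods.md](docs/methods.md).

The network, its gradients, and the optimizer are implemented on a
small NumPy autodiff engine inside the package (`cbctseg.nn`);
SimpleITK handles file formats and resampling, scipy the morphology.

## Worked example

```bash
python examples/03_train_and_segment.py
```

trains the CPU-sized network (window 32, hidden 64, 2 layers) for 8
epochs on 20 synthetic phantoms from 2 pseudo-centers and evaluates the
4 held-out phantoms end to end.  Output from a run:

```
epoch  train_loss  val_dice
    1      0.5152    -
    2      0.4315  0.453
    4      0.3776  0.490
    6      0.3250  0.514
    8      0.2713  0.526

held-out phantoms (full pipeline: sliding window, argmax, cleanup):
  scan 0: dice 0.630 (raw argmax 0.610), auprc 0.698 vs baseline 0.080
  scan 1: dice 0.698 (raw argmax 0.679), auprc 0.786 vs baseline 0.067
  scan 2: dice 0.758 (raw argmax 0.743), auprc 0.908 vs baseline 0.085
  scan 3: dice 0.713 (raw argmax 0.707), auprc 0.802 vs baseline 0.073

mean held-out Dice 0.700
```

The training loss falls while validation Dice rises; post-processing
lifts the raw argmax Dice on every scan (it removes satellite artifacts
and fills the bone cavity); AUPRC sits far above the ~7% prevalence
baseline.  At the study's full 30 epochs the mean held-out Dice exceeds
0.8 (0.84-0.86 across seeds).

The same flow is available as a command-line tool:

```bash
cbctseg generate-phantoms --n 10 --centers 2 --out data/ --seed 7 --config examples/tiny_config.yaml
cbctseg train --data-dir data/ --out model.ckpt --seed 7 --config examples/tiny_config.yaml
cbctseg predict --model model.ckpt --in data/center_00/phantom_000_img.nii.gz \
                --out seg.nii.gz --overlap 0.5 --keep-intermediate
cbctseg evaluate --pred seg.nii.gz --probs seg_probs.nii.gz \
                 --gt data/center_00/phantom_000_seg.nii.gz --out report.json
```

NIfTI (`.nii`/`.nii.gz`) and NRRD volumes are read and written; DICOM
series directories are read.

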