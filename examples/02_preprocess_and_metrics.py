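"""Contrast normalization, label cleanup, and the evaluation suite.

Builds one phantom, normalizes its intensities with the cumulative
histogram window, fills the cavity in its shell mask, then scores a
deliberately imperfect segmentation with the full metric suite.
"""

import numpy as np

from cbctseg import (
    ContrastParams,
    LabelMap,
    PhantomSpec,
    canonicalize_label,
    contrast_adjust,
    evaluate,
    generate_phantom,
)
from cbctseg.phantom import phantom_masks

img, gt = generate_phantom(PhantomSpec(seed=3))
norm = contrast_adjust(img, ContrastParams(x_min_pct=1.0, x_max_pct=99.0))
print(f"raw intensities   [{img.voxels.min():7.1f}, {img.voxels.max():7.1f}]")
print(f"normalized        [{norm.voxels.min():7.3f}, {norm.voxels.max():7.3f}]  (clamped to the 1-99% window)")

# the raw shell mask has a cavity; canonicalization fills it
masks = phantom_masks(PhantomSpec(seed=3), np.random.default_rng(3))
shell = LabelMap(voxels=masks["shell"].astype(np.uint8), spacing=img.spacing)
filled = canonicalize_label(shell)
print(f"\nshell voxels {int(shell.voxels.sum())} -> filled {int(filled.voxels.sum())} "
      f"(ground truth {int(gt.voxels.sum())})")

# score a degraded prediction: erode the truth and add a fake blob
pred = gt.voxels.copy()
pred[:, :, ::7] = 0                     # missing slices -> false negatives
pred[2:5, 2:5, 2:5] = 1                 # spurious blob  -> false positives
probs = np.clip(pred + np.random.default_rng(0).normal(0, 0.1, pred.shape), 0, 1)
report = evaluate(probs, LabelMap(voxels=pred, spacing=gt.spacing), gt)
for key, value in report.to_dict().items():
    print(f"{key:16s} {value:.4f}")
print(
    "\nAUPRC sits far above its baseline (the ~6% bone prevalence): the scores\n"
    "rank bone above background even though the binary mask is imperfect.\n"
    "F2 is below recall-weighted perfection because of the missing slices."
)
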