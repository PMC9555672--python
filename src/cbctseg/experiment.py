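"""A desk-scale replica of the full training-and-evaluation study.

The full-scale study (hundreds of multi-center scans, a 128-voxel-window
network, hours of GPU training) is reproduced here in miniature so the
whole pipeline — phantom generation, splitting, crop training with
augmentation, sliding-window prediction, post-processing and the metric
suite — runs end to end on one CPU in a few minutes: a tiny network
(32-voxel window, 64-wide embedding, 2 transformer layers, 4 heads) is
trained on 20 synthetic 64-cube phantoms from 2 pseudo-centers with the
standard 70/10/20 split, combined Dice + cross-entropy loss and Adam
(lr 1e-4, weight decay 1e-5), then scored on the held-out phantoms.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import asdict

import numpy as np

from .infer import SlidingWindowSpec, argmax_segment
from .io_geometry import read_volume, resample_to_reference
from .metrics import evaluate
from .phantom import PhantomSpec, generate_dataset, load_manifest
from .postprocess import predict_pipeline
from .train import AugmentationSpec, TrainConfig, split_dataset, train_model
from .unetr_model import UNETR, UNETRConfig

__all__ = ["TINY_UNETR", "tiny_train_config", "scaled_down_study", "evaluate_model_on_scan"]

#: CPU-sized network used by the desk-scale study.
TINY_UNETR = UNETRConfig(
    window_edge=32,
    patch_edge=16,
    hidden_dim=64,
    mlp_dim=128,
    num_heads=4,
    num_layers=2,
    skip_layers=(1, 2),
    feature_size=8,
    dropout_rate=0.05,
)


def tiny_train_config(seed: int, epochs: int = 30) -> TrainConfig:
    """Optimization settings for the desk-scale study.

    The full-scale recipe's learning rate, weight decay, loss weighting
    and split fractions are kept.  Batch geometry is shrunk to one scan
    and four crops per step: at a fixed learning rate the optimizer
    distance grows with the step count, so many small steps beat few
    large ones on a fixed epoch budget.  Validation runs every second
    epoch and without validation-time augmentation, which would inject
    gamma/flip noise into checkpoint selection.
    """
    return TrainConfig(
        n_images_per_batch=1,
        n_crops_per_image=4,
        crop_edges=(TINY_UNETR.window_edge,) * 3,
        learning_rate=1e-4,
        weight_decay=1e-5,
        epochs=epochs,
        seed=seed,
        val_interval=2,
        val_augment=False,
    )


def evaluate_model_on_scan(model: UNETR, image_path, label_path, overlap: float = 0.5):
    """Score one scan end to end; also report the raw (uncleaned) Dice.

    Returns ``(report, raw_dice)`` where ``report`` is the full metric
    suite of the post-processed segmentation against ground truth on the
    original grid and ``raw_dice`` is the Dice of the plain argmax
    segmentation mapped back without largest-component/hole cleanup.
    """
    from .metrics import dice_coefficient

    scan = read_volume(image_path)
    gt = read_volume(label_path, as_label=True)
    spec = SlidingWindowSpec(window_edge=model.config.window_edge, overlap=overlap)
    seg, probs, work = predict_pipeline(model, scan, spec=spec, return_probs=True)
    probs_orig = resample_to_reference(work.with_voxels(probs[1]), gt, mode="linear")
    report = evaluate(probs_orig.voxels, seg, gt)
    raw = resample_to_reference(argmax_segment(probs, like=work), gt)
    raw_dice = dice_coefficient(gt, raw) if (raw.voxels.sum() + gt.voxels.sum()) else 0.0
    return report, raw_dice


def scaled_down_study(
    seed: int,
    epochs: int = 30,
    n_per_center: int = 10,
    n_centers: int = 2,
    data_dir: str | None = None,
    progress: bool = False,
) -> dict:
    """Run the miniature study once and return its numbers.

    The returned dict holds per-scan reports for the held-out test
    phantoms, their means, the raw-argmax Dice values (to quantify what
    post-processing contributes), and the training history.
    """
    ss = np.random.SeedSequence(seed)
    data_seed, split_seed, train_seed = (int(s.generate_state(1)[0]) % 2**31 for s in ss.spawn(3))
    tmp = None
    if data_dir is None:
        tmp = tempfile.TemporaryDirectory(prefix="cbctseg_study_")
        data_dir = tmp.name
    try:
        generate_dataset(n_per_center, n_centers, PhantomSpec(seed=data_seed), data_dir, seed=data_seed)
        centers = load_manifest(os.path.join(data_dir, "manifest.json"))
        cfg = tiny_train_config(train_seed, epochs=epochs)
        split = split_dataset(centers, cfg.split_fractions, seed=split_seed)
        model, history = train_model(split, TINY_UNETR, cfg, AugmentationSpec(), progress=progress)
        reports, raw_dices = [], []
        for image_path, label_path in split.test:
            report, raw = evaluate_model_on_scan(model, image_path, label_path)
            reports.append(report)
            raw_dices.append(raw)
    finally:
        if tmp is not None:
            tmp.cleanup()
    means = {
        key: float(np.mean([r.to_dict()[key] for r in reports]))
        for key in reports[0].to_dict()
    }
    return {
        "seed": seed,
        "n_test": len(reports),
        "per_scan": [r.to_dict() for r in reports],
        "mean": means,
        "raw_dice": raw_dices,
        "raw_dice_mean": float(np.mean(raw_dices)),
        "history": history,
        "config": {"unetr": asdict(TINY_UNETR), "train": asdict(tiny_train_config(train_seed, epochs))},
    }
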