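"""Training: dataset splitting, crop sampling, augmentation, losses, loop.

One binary model is trained per anatomical structure.  Scans are grouped
by the clinical center they came from and split 70/10/20 into
train/validation/test *within each center*, so no center is over- or
under-represented in any partition.  Each optimization step draws ``N_i``
scans, samples ``N_s`` random cubic crops from each (batch ``N_i x N_s``),
augments them (random flips/90-degree rotations per axis, intensity
shift, gamma), and minimizes a weighted average of the soft Dice loss and
voxel-wise cross-entropy with Adam plus weight decay.  Validation runs
sliding-window prediction on whole held-out scans; the checkpoint with
the best validation Dice is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .infer import SlidingWindowSpec, sliding_window_predict
from .io_geometry import LabelMap, VolumeImage, read_volume, resample_to_spacing
from .preprocess import ContrastParams, canonicalize_label, contrast_adjust
from .unetr_model import UNETR, UNETRConfig

__all__ = [
    "TrainConfig",
    "AugmentationSpec",
    "DatasetSplit",
    "split_dataset",
    "sample_crops",
    "augment",
    "dice_loss",
    "ce_loss",
    "combined_loss",
    "train_model",
]


@dataclass(frozen=True)
class AugmentationSpec:
    """Random training transforms and their probabilities.

    Per axis, a flip and (independently) a 90-degree rotation each occur
    with probability 0.25; a signed intensity shift of 0.1 occurs with
    probability 0.5 and a gamma change drawn from [0.5, 2] with
    probability 0.8.  Geometric transforms apply to image and label
    alike; intensity transforms touch the image only.
    """

    flip_rot_prob_per_axis: float = 0.25
    intensity_shift_prob: float = 0.5
    intensity_shift_magnitude: float = 0.1
    gamma_prob: float = 0.8
    gamma_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self):
        for p in (self.flip_rot_prob_per_axis, self.intensity_shift_prob, self.gamma_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        lo, hi = self.gamma_range
        if not (0.0 < lo < hi):
            raise ValueError(f"gamma_range must be positive with lower < upper, got {self.gamma_range}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    ``n_images_per_batch`` (N_i) scans contribute ``n_crops_per_image``
    (N_s) crops each per step, a batch of N_i x N_s.  Defaults follow the
    full-scale recipe: N_i = N_s = 10 (batch 100), crops of 128**3,
    learning rate 1e-4, weight decay 1e-5, equal Dice/cross-entropy
    weights.
    """

    n_images_per_batch: int = 10
    n_crops_per_image: int = 10
    crop_edges: tuple[int, int, int] = (128, 128, 128)
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    loss_weights: tuple[float, float] = (0.5, 0.5)
    epochs: int = 100
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    dice_smooth: float = 1e-5
    val_interval: int = 1
    val_overlap: float = 0.2
    val_augment: bool = True
    target_spacing: float | None = 0.4
    contrast: ContrastParams = field(default_factory=ContrastParams)

    def __post_init__(self):
        if self.n_images_per_batch < 1 or self.n_crops_per_image < 1:
            raise ValueError("N_i and N_s must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split_fractions}")
        if sum(self.loss_weights) <= 0:
            raise ValueError("loss weights must not both be zero")


@dataclass(frozen=True)
class DatasetSplit:
    """Per-center file lists partitioned into train/val/test."""

    train: tuple
    val: tuple
    test: tuple
    per_center: dict

    @property
    def all_items(self) -> tuple:
        return self.train + self.val + self.test


def split_dataset(centers: dict, fractions=(0.7, 0.1, 0.2), seed: int = 0) -> DatasetSplit:
    """Shuffle each center's file list and slice it proportionally.

    ``centers`` maps a center name to a list of items (e.g. image/label
    path pairs).  Train and validation take ``floor(n * fraction)`` items
    per center, the remainder goes to test, so each center's proportions
    are within one file of the global fractions.  Deterministic given
    ``seed``.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ValueError(f"fractions must be 3 nonnegative values summing to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    per_center = {}
    for name in sorted(centers):
        items = list(centers[name])
        if not items:
            raise ValueError(f"center {name!r} has no files")
        order = rng.permutation(len(items))
        items = [items[i] for i in order]
        n = len(items)
        n_tr = int(math.floor(n * fractions[0] + 1e-9))
        n_va = int(math.floor(n * fractions[1] + 1e-9))
        parts = (items[:n_tr], items[n_tr : n_tr + n_va], items[n_tr + n_va :])
        per_center[name] = parts
        train += parts[0]
        val += parts[1]
        test += parts[2]
    return DatasetSplit(tuple(train), tuple(val), tuple(test), per_center)


def _pad_to(arr: np.ndarray, edges, value=0.0) -> np.ndarray:
    """Symmetric zero-pad up to at least ``edges`` per axis."""
    pads = []
    for s, e in zip(arr.shape, edges):
        gap = max(0, e - s)
        pads.append((gap // 2, gap - gap // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, constant_values=value)
    return arr


def sample_crops(
    img: VolumeImage | np.ndarray,
    label: LabelMap | np.ndarray,
    n_crops: int,
    crop_edges,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw aligned random cubic crops, corner uniform over valid positions.

    Scans smaller than the crop are symmetrically zero-padded first, so
    small-field-of-view volumes are never rejected.
    """
    iarr = img.voxels if isinstance(img, VolumeImage) else np.asarray(img)
    larr = label.voxels if isinstance(label, VolumeImage) else np.asarray(label)
    if iarr.shape != larr.shape:
        raise ValueError(f"image {iarr.shape} and label {larr.shape} shapes differ")
    crop_edges = tuple(int(e) for e in np.broadcast_to(crop_edges, (3,)))
    iarr = _pad_to(iarr, crop_edges)
    larr = _pad_to(larr, crop_edges)
    out = []
    for _ in range(n_crops):
        corner = [rng.integers(0, s - e + 1) for s, e in zip(iarr.shape, crop_edges)]
        sl = tuple(slice(c, c + e) for c, e in zip(corner, crop_edges))
        out.append((iarr[sl].copy(), larr[sl].copy()))
    return out


def augment(
    pair: tuple[np.ndarray, np.ndarray],
    spec: AugmentationSpec,
    rng: np.random.Generator,
    return_events: bool = False,
):
    """Apply the random training transforms to an (image, label) pair.

    Flips and rotations permute both grids identically; the intensity
    shift (random sign) and gamma change touch the image only, which is
    re-clamped to [0, 1] afterwards.  With ``return_events=True`` a third
    element records which random events fired (and the drawn shift sign /
    gamma), for logging and calibration checks.
    """
    img, lab = pair
    img = np.asarray(img, dtype=np.float32)
    lab = np.asarray(lab)
    q = spec.flip_rot_prob_per_axis
    planes = ((1, 2), (0, 2), (0, 1))  # rotation plane about each axis
    events: dict = {"flip": [False] * 3, "rot": [False] * 3, "shift": 0.0, "gamma": None}
    for axis in range(3):
        if rng.random() < q:
            events["flip"][axis] = True
            img = np.flip(img, axis=axis)
            lab = np.flip(lab, axis=axis)
        if rng.random() < q:
            events["rot"][axis] = True
            img = np.rot90(img, k=1, axes=planes[axis])
            lab = np.rot90(lab, k=1, axes=planes[axis])
    if rng.random() < spec.intensity_shift_prob:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        events["shift"] = sign * spec.intensity_shift_magnitude
        img = img + events["shift"]
    if rng.random() < spec.gamma_prob:
        events["gamma"] = rng.uniform(*spec.gamma_range)
        img = np.clip(img, 0.0, None) ** events["gamma"]
    img = np.clip(img, 0.0, 1.0)
    img, lab = np.ascontiguousarray(img), np.ascontiguousarray(lab)
    if return_events:
        return img, lab, events
    return img, lab


# -- losses -------------------------------------------------------------

def dice_loss(p: np.ndarray, g: np.ndarray, eps: float = 1e-5) -> float:
    """Soft Dice loss ``1 - (2 Σ pg + ε) / (Σ p² + Σ g² + ε)``.

    ``p``: predicted foreground probabilities; ``g``: binary ground
    truth; both flattened over all voxels.  Zero when ``p == g`` binary
    and nonempty; 1 for disjoint nonempty masks at ε = 0.  Computed in
    double precision; the float32 tape twin used during optimization is
    :func:`cbctseg.nn.soft_dice_loss`.
    """
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    num = 2.0 * float((p * g).sum()) + eps
    den = float((p * p).sum() + (g * g).sum()) + eps
    return 1.0 - num / den


def ce_loss(
    scores: np.ndarray, targets: np.ndarray, class_weights: np.ndarray | None = None
) -> float:
    """Mean weighted cross-entropy from raw class scores.

    ``scores``: (..., C) raw (pre-softmax) per-voxel class scores;
    ``targets``: integer class per voxel; ``class_weights``: per-class
    nonnegative weights (default 1).  The per-voxel term is
    ``-w[y] * log softmax(x)[y]``; the loss is the plain mean, so
    scaling the weights scales the loss.  Double precision; the float32
    tape twin is :func:`cbctseg.nn.cross_entropy_loss`.
    """
    scores = np.asarray(scores, dtype=np.float64)
    targets = np.asarray(targets).reshape(-1).astype(np.intp)
    x = scores.reshape(-1, scores.shape[-1])
    if x.shape[0] != targets.size:
        raise ValueError(f"shape mismatch: scores {scores.shape}, targets {targets.shape}")
    C = x.shape[1]
    w = np.ones(C) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    z = x - x.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-(w[targets] * logp[np.arange(targets.size), targets]).mean())


def combined_loss(dice_value: float, ce_value: float, lam_dice: float, lam_ce: float) -> float:
    """Weighted average ``(λ_d·DL + λ_c·CE) / (λ_d + λ_c)``."""
    if lam_dice + lam_ce <= 0:
        raise ValueError("loss weights must not both be zero")
    return (lam_dice * dice_value + lam_ce * ce_value) / (lam_dice + lam_ce)


def _combined_loss_t(
    logits: nn.Tensor, labels: np.ndarray, cfg: TrainConfig, channels_last: bool = False
) -> nn.Tensor:
    """Differentiable combined loss on a logits tensor.

    ``logits``: (B, C, *spatial), or (B, *spatial, C) with
    ``channels_last=True``.
    """
    lam_d, lam_c = cfg.loss_weights
    if not channels_last:
        logits = logits.transpose(0, 2, 3, 4, 1)
    C = logits.shape[-1]
    probs = logits.softmax(axis=-1)
    dl = nn.soft_dice_loss(probs[..., 1], labels, eps=cfg.dice_smooth, batched=True)
    ce = nn.cross_entropy_loss(logits.reshape(-1, C), labels.reshape(-1))
    return (dl * lam_d + ce * lam_c) * (1.0 / (lam_d + lam_c))


# -- data loading -------------------------------------------------------

def load_preprocessed_pair(
    image_path, label_path, cfg: TrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Read, resample to the working spacing, normalize, canonicalize."""
    img = read_volume(image_path)
    lab = read_volume(label_path, as_label=True)
    if cfg.target_spacing is not None:
        sp = (cfg.target_spacing,) * 3
        if not np.allclose(img.spacing, sp, atol=1e-6):
            img = resample_to_spacing(img, sp, mode="linear")
            lab = resample_to_spacing(lab, sp, mode="nearest")
    img = contrast_adjust(img, cfg.contrast)
    lab = canonicalize_label(lab)
    return img.voxels.astype(np.float32), lab.voxels.astype(np.uint8)


def train_model(
    split: DatasetSplit,
    unetr_config: UNETRConfig,
    train_config: TrainConfig,
    aug_spec: AugmentationSpec | None = None,
    progress: bool = False,
) -> tuple[UNETR, list[dict]]:
    """Run the optimization loop; return the best-validation model and history.

    Each history entry records the epoch, mean train loss, batch size and
    (on validation epochs) the mean validation Dice of full-volume
    sliding-window predictions.  The returned model carries the weights
    of the epoch with the best validation Dice.  Deterministic given
    ``train_config.seed`` up to floating-point rounding.
    """
    if aug_spec is None:
        aug_spec = AugmentationSpec()
    cfg = train_config
    if not split.train or not split.val:
        raise ValueError("train and validation partitions must be non-empty")
    if tuple(cfg.crop_edges) != (unetr_config.window_edge,) * 3:
        raise ValueError(
            f"crop edges {cfg.crop_edges} must match the network window "
            f"{unetr_config.window_edge}"
        )

    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_order, rng_crop, rng_aug, rng_drop, rng_valaug = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    cache: dict = {}

    def fetch(item):
        key = tuple(item)
        if key not in cache:
            cache[key] = load_preprocessed_pair(item[0], item[1], cfg)
        return cache[key]

    model = UNETR(unetr_config, rng=rng_init)
    opt = nn.Adam(
        model.parameters(),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    sw_spec = SlidingWindowSpec(window_edge=unetr_config.window_edge, overlap=cfg.val_overlap)

    history: list[dict] = []
    best = {"dice": -1.0, "state": model.state_dict(), "epoch": 0}
    n_i = min(cfg.n_images_per_batch, len(split.train))
    for epoch in range(1, cfg.epochs + 1):
        order = rng_order.permutation(len(split.train))
        losses = []
        for start in range(0, len(order), n_i):
            chunk = order[start : start + n_i]
            if len(chunk) < n_i:  # drop ragged tail batch
                break
            imgs, labs = [], []
            for idx in chunk:
                iarr, larr = fetch(split.train[idx])
                for ic, lc in sample_crops(
                    iarr, larr, cfg.n_crops_per_image, cfg.crop_edges, rng_crop
                ):
                    ia, la = augment((ic, lc), aug_spec, rng_aug)
                    imgs.append(ia)
                    labs.append(la)
            batch = np.stack(imgs)
            target = np.stack(labs).astype(np.float32)
            logits = model.forward_logits(batch, train=True, rng=rng_drop, channels_last=True)
            loss = _combined_loss_t(logits, target, cfg, channels_last=True)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)) if losses else float("nan"),
            "batch_size": n_i * cfg.n_crops_per_image,
        }
        if epoch % cfg.val_interval == 0 or epoch == cfg.epochs:
            dices = []
            for item in split.val:
                iarr, larr = fetch(item)
                if cfg.val_augment:
                    iarr, larr = augment((iarr, larr), aug_spec, rng_valaug)
                probs = sliding_window_predict(model, iarr, sw_spec)
                pred = np.argmax(probs, axis=0)
                denom = pred.sum() + larr.sum()
                dices.append(
                    1.0 if denom == 0 else 2.0 * float((pred * larr).sum()) / float(denom)
                )
            entry["val_dice"] = float(np.mean(dices))
            if entry["val_dice"] > best["dice"]:
                best = {"dice": entry["val_dice"], "state": model.state_dict(), "epoch": epoch}
        history.append(entry)
        if progress:
            print(f"epoch {epoch}: {entry}", flush=True)
    model.load_state_dict(best["state"])
    return model, history
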