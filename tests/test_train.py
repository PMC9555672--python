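import numpy as np
import pytest

from cbctseg.train import (
    AugmentationSpec,
    TrainConfig,
    augment,
    ce_loss,
    combined_loss,
    dice_loss,
    sample_crops,
    split_dataset,
)


# -- dataset splitting -------------------------------------------------


def _centers(n_centers, n_files):
    return {
        f"center_{c}": [(f"img_{c}_{i}", f"seg_{c}_{i}") for i in range(n_files)]
        for c in range(n_centers)
    }


def test_split_70_10_20_per_center():
    for n_centers in (1, 2):
        split = split_dataset(_centers(n_centers, 10), (0.7, 0.1, 0.2), seed=3)
        assert len(split.train) == 7 * n_centers
        assert len(split.val) == 1 * n_centers
        assert len(split.test) == 2 * n_centers
        for parts in split.per_center.values():
            assert tuple(len(p) for p in parts) == (7, 1, 2)


def test_split_partitions_are_disjoint_and_complete():
    centers = _centers(3, 7)
    split = split_dataset(centers, (0.7, 0.1, 0.2), seed=5)
    allocated = set(split.train) | set(split.val) | set(split.test)
    everything = {item for files in centers.values() for item in files}
    assert allocated == everything
    assert len(split.train) + len(split.val) + len(split.test) == len(everything)


def test_split_deterministic_and_seed_sensitive():
    centers = _centers(2, 12)
    a = split_dataset(centers, seed=11)
    b = split_dataset(centers, seed=11)
    c = split_dataset(centers, seed=12)
    assert a == b
    assert a != c


def test_split_rejects_bad_fractions():
    with pytest.raises(ValueError):
        split_dataset(_centers(1, 5), (0.5, 0.2, 0.2), seed=0)


# -- crop sampling -----------------------------------------------------


def test_crop_equals_volume_when_sizes_match(rng):
    img = rng.random((16, 16, 16)).astype(np.float32)
    lab = (img > 0.5).astype(np.uint8)
    crops = sample_crops(img, lab, 5, (16, 16, 16), rng)
    assert len(crops) == 5
    for ic, lc in crops:
        assert np.array_equal(ic, img)
        assert np.array_equal(lc, lab)


def test_crop_content_matches_direct_indexing():
    """Re-running the RNG reproduces the corners; crops equal the
    corresponding sub-grids of image and label."""
    rng = np.random.default_rng(77)
    img = np.random.default_rng(1).random((24, 20, 30)).astype(np.float32)
    lab = (img > 0.6).astype(np.uint8)
    crops = sample_crops(img, lab, 10, (8, 8, 8), rng)
    replay = np.random.default_rng(77)
    for ic, lc in crops:
        corner = [replay.integers(0, s - 8 + 1) for s in img.shape]
        sl = tuple(slice(c, c + 8) for c in corner)
        assert np.array_equal(ic, img[sl])
        assert np.array_equal(lc, lab[sl])


def test_small_volume_padded_not_rejected(rng):
    img = rng.random((10, 10, 10)).astype(np.float32)
    lab = np.ones_like(img, dtype=np.uint8)
    crops = sample_crops(img, lab, 3, (16, 16, 16), rng)
    for ic, lc in crops:
        assert ic.shape == (16, 16, 16)
        assert lc.sum() == 1000  # all original foreground survives the pad
        assert ic[0, 0, 0] == 0.0  # zero padding


# -- augmentation ------------------------------------------------------


def test_zero_probability_is_identity(rng):
    spec = AugmentationSpec(
        flip_rot_prob_per_axis=0.0, intensity_shift_prob=0.0, gamma_prob=0.0
    )
    img = rng.random((8, 8, 8)).astype(np.float32)
    lab = (img > 0.5).astype(np.uint8)
    out_img, out_lab = augment((img, lab), spec, rng)
    assert np.array_equal(out_img, img)
    assert np.array_equal(out_lab, lab)


def test_geometric_ops_preserve_label_count_and_alignment(rng):
    spec = AugmentationSpec(intensity_shift_prob=0.0, gamma_prob=0.0)
    img = rng.random((8, 8, 8)).astype(np.float32)
    lab = (img > 0.7).astype(np.uint8)
    for _ in range(20):
        oi, ol = augment((img, lab), spec, rng)
        assert ol.sum() == lab.sum()
        # image and label permuted identically
        assert np.array_equal(ol, (oi > 0.7).astype(np.uint8))


def test_intensity_ops_leave_label_untouched_and_clamp(rng):
    spec = AugmentationSpec(
        flip_rot_prob_per_axis=0.0, intensity_shift_prob=1.0, gamma_prob=1.0
    )
    img = rng.random((8, 8, 8)).astype(np.float32)
    lab = (img > 0.5).astype(np.uint8)
    oi, ol = augment((img, lab), spec, rng)
    assert np.array_equal(ol, lab)
    assert oi.min() >= 0.0 and oi.max() <= 1.0
    assert not np.array_equal(oi, img)


def _binomial_ci99(p, n):
    half = 2.576 * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


def test_event_records_match_observable_changes(rng):
    """The event record reflects what actually happened to the image."""
    img = np.full((4, 4, 4), 0.45, dtype=np.float32)
    lab = np.zeros_like(img, dtype=np.uint8)
    spec = AugmentationSpec(flip_rot_prob_per_axis=0.0)
    for _ in range(50):
        oi, _, ev = augment((img, lab), spec, rng, return_events=True)
        expected = np.clip(
            np.clip(img + ev["shift"], 0, None) ** (ev["gamma"] or 1.0), 0.0, 1.0
        )
        assert np.allclose(oi, expected, atol=1e-6)


def test_event_frequencies_match_probabilities():
    """Empirical per-axis flip/rotation, shift and gamma rates over
    10,000 draws stay inside 99% binomial intervals of 0.25/0.50/0.80."""
    spec = AugmentationSpec()
    rng = np.random.default_rng(2024)
    n = 10_000
    img = np.full((4, 4, 4), 0.45, dtype=np.float32)
    lab = np.zeros_like(img, dtype=np.uint8)
    flips = np.zeros(3)
    rots = np.zeros(3)
    shifts = 0
    gammas = 0
    for _ in range(n):
        _, _, ev = augment((img, lab), spec, rng, return_events=True)
        flips += ev["flip"]
        rots += ev["rot"]
        shifts += ev["shift"] != 0.0
        gammas += ev["gamma"] is not None
    lo, hi = _binomial_ci99(0.25, n)
    for axis in range(3):
        assert lo <= flips[axis] / n <= hi
        assert lo <= rots[axis] / n <= hi
    lo, hi = _binomial_ci99(0.50, n)
    assert lo <= shifts / n <= hi
    lo, hi = _binomial_ci99(0.80, n)
    assert lo <= gammas / n <= hi


# -- losses ------------------------------------------------------------


def test_dice_loss_closed_form_cases():
    ones = np.ones(8, dtype=np.float32)
    zeros = np.zeros(8, dtype=np.float32)
    assert dice_loss(ones, ones, eps=0.0) == pytest.approx(0.0)
    assert dice_loss(ones, zeros, eps=0.0) == pytest.approx(1.0)
    p = np.full(4, 0.5, dtype=np.float32)
    g = np.array([1.0, 1.0, 0.0, 0.0], dtype=np.float32)
    # 1 - 2*1.0 / (1.0 + 2.0) = 1/3
    assert dice_loss(p, g, eps=0.0) == pytest.approx(1.0 / 3.0, abs=1e-6)


def test_dice_loss_is_one_minus_dice_on_binary(rng):
    from cbctseg.metrics import dice_coefficient

    for _ in range(10):
        p = (rng.random((6, 6, 6)) < 0.4).astype(np.float32)
        g = (rng.random((6, 6, 6)) < 0.4).astype(np.float32)
        if p.sum() + g.sum() == 0:
            continue
        assert dice_loss(p, g, eps=0.0) == pytest.approx(
            1.0 - dice_coefficient(p, g), abs=1e-6
        )


def test_ce_loss_closed_form_cases(rng):
    # uniform two-class scores: -log(0.5)
    scores = np.zeros((10, 2), dtype=np.float32)
    targets = rng.integers(0, 2, size=10)
    assert ce_loss(scores, targets) == pytest.approx(np.log(2), abs=1e-6)
    # near-certain true class drives the loss toward 0
    confident = np.zeros((4, 2), dtype=np.float32)
    confident[:, 1] = 50.0
    assert ce_loss(confident, np.ones(4, dtype=int)) == pytest.approx(0.0, abs=1e-6)
    # doubling the class weights doubles the loss
    scores = rng.normal(size=(20, 2)).astype(np.float32)
    targets = rng.integers(0, 2, size=20)
    w = np.array([1.0, 1.5])
    assert ce_loss(scores, targets, 2 * w) == pytest.approx(
        2 * ce_loss(scores, targets, w), rel=1e-6
    )


def test_reference_losses_agree_with_tape_losses(rng):
    """The double-precision reference losses match the float32 autodiff
    versions used during optimization to float32 resolution."""
    from cbctseg import nn

    p = rng.random((5, 5, 5)).astype(np.float32)
    g = (rng.random((5, 5, 5)) < 0.3).astype(np.float32)
    assert dice_loss(p, g) == pytest.approx(
        float(nn.soft_dice_loss(nn.Tensor(p), g).data), abs=1e-5
    )
    scores = rng.normal(size=(40, 2)).astype(np.float32)
    targets = rng.integers(0, 2, size=40)
    assert ce_loss(scores, targets) == pytest.approx(
        float(nn.cross_entropy_loss(nn.Tensor(scores), targets).data), abs=1e-5
    )


def test_combined_loss_weighting():
    assert combined_loss(0.4, 0.6, 1.0, 1.0) == pytest.approx(0.5)
    assert combined_loss(0.4, 0.6, 1.0, 0.0) == pytest.approx(0.4)
    assert combined_loss(0.4, 0.6, 0.0, 1.0) == pytest.approx(0.6)
    with pytest.raises(ValueError):
        combined_loss(0.4, 0.6, 0.0, 0.0)


def test_train_model_bookkeeping_and_learning(tmp_path, micro_config):
    """Three epochs on small phantoms: one history entry per epoch with
    the configured batch size, validation Dice at the configured
    interval, a best-checkpoint model returned, and a falling loss."""
    from cbctseg.phantom import PhantomSpec, generate_dataset, load_manifest
    from cbctseg.train import TrainConfig, train_model

    spec = PhantomSpec(grid_size=32, n_satellites=1)
    generate_dataset(10, 1, spec, tmp_path, seed=3)
    centers = load_manifest(tmp_path / "manifest.json")
    cfg = TrainConfig(
        n_images_per_batch=2,
        n_crops_per_image=2,
        crop_edges=(16, 16, 16),
        learning_rate=1e-3,
        epochs=3,
        seed=5,
        val_interval=2,
        val_overlap=0.0,
        val_augment=False,
        target_spacing=None,
    )
    split = split_dataset(centers, cfg.split_fractions, seed=5)
    model, history = train_model(split, micro_config, cfg)
    assert [h["epoch"] for h in history] == [1, 2, 3]
    assert all(h["batch_size"] == 4 for h in history)
    assert "val_dice" in history[1] and "val_dice" in history[2]
    assert "val_dice" not in history[0]
    assert history[-1]["train_loss"] < history[0]["train_loss"]
    assert model.config == micro_config
    # empty-partition contract
    bad = split_dataset(centers, (0.9, 0.0, 0.1), seed=1)
    with pytest.raises(ValueError):
        train_model(bad, micro_config, cfg)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(split_fractions=(0.5, 0.2, 0.2))
    with pytest.raises(ValueError):
        TrainConfig(loss_weights=(0.0, 0.0))
    with pytest.raises(ValueError):
        TrainConfig(n_images_per_batch=0)
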