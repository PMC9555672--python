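import numpy as np
import pytest

from cbctseg.metrics import (
    ConfusionCounts,
    UndefinedMetricError,
    accuracy,
    auprc,
    auprc_baseline,
    confusion,
    dice_coefficient,
    evaluate,
    f2_score,
    pr_curve,
    precision,
    recall,
)
from conftest import auprc_sweep_oracle


def test_confusion_basic_cases(rng):
    gt = np.zeros((10, 10), dtype=np.uint8).reshape(10, 10, 1)
    gt = np.zeros((100,), dtype=np.uint8)
    gt[:10] = 1
    gt = gt.reshape(10, 10, 1)
    c = confusion(gt, gt)
    assert (c.tp, c.tn, c.fp, c.fn) == (10, 90, 0, 0)
    inv = confusion(1 - gt, gt)
    assert inv.tp == 0 and inv.tn == 0 and inv.fp == 90 and inv.fn == 10
    assert c.total == 100


def test_confusion_matches_per_voxel_loop(rng):
    p = (rng.random((8, 8, 8)) < 0.4).astype(np.uint8)
    g = (rng.random((8, 8, 8)) < 0.4).astype(np.uint8)
    c = confusion(p, g)
    tp = tn = fp = fn = 0
    for i in range(8):
        for j in range(8):
            for k in range(8):
                if p[i, j, k] and g[i, j, k]:
                    tp += 1
                elif p[i, j, k]:
                    fp += 1
                elif g[i, j, k]:
                    fn += 1
                else:
                    tn += 1
    assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)


def test_dice_closed_form():
    a = np.zeros(20, dtype=np.uint8)
    m = np.zeros(20, dtype=np.uint8)
    a[:10] = 1       # |A| = 10
    m[4:12] = 1      # |M| = 8, overlap 6
    a, m = a.reshape(4, 5, 1), m.reshape(4, 5, 1)
    assert dice_coefficient(m, a) == pytest.approx(12 / 18)
    assert dice_coefficient(a, m) == pytest.approx(12 / 18)  # symmetric
    assert dice_coefficient(a, a) == 1.0
    disjoint = np.roll(a, 10)
    assert dice_coefficient(a, disjoint.reshape(4, 5, 1)) == 0.0
    with pytest.raises(UndefinedMetricError):
        dice_coefficient(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))


def test_f2_closed_form():
    assert f2_score(ConfusionCounts(tp=5, tn=0, fp=0, fn=0)) == 1.0
    assert f2_score(ConfusionCounts(tp=8, tn=0, fp=2, fn=2)) == pytest.approx(0.8)
    assert f2_score(ConfusionCounts(tp=0, tn=0, fp=3, fn=1)) == 0.0
    with pytest.raises(UndefinedMetricError):
        f2_score(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))


def test_accuracy_recall_precision_closed_form():
    perfect = ConfusionCounts(tp=10, tn=90, fp=0, fn=0)
    assert accuracy(perfect) == recall(perfect) == precision(perfect) == 1.0
    assert recall(ConfusionCounts(tp=10, tn=0, fp=0, fn=30)) == pytest.approx(0.25)
    assert precision(ConfusionCounts(tp=10, tn=0, fp=30, fn=0)) == pytest.approx(0.25)
    with pytest.raises(UndefinedMetricError):
        recall(ConfusionCounts(tp=0, tn=5, fp=2, fn=0))
    with pytest.raises(UndefinedMetricError):
        precision(ConfusionCounts(tp=0, tn=5, fp=0, fn=2))


def test_metric_identities(rng):
    """Dice == 2TP/(2TP+FP+FN) == F1 on the same counts; F2 <= 1."""
    for _ in range(20):
        p = (rng.random((6, 6, 6)) < 0.35).astype(np.uint8)
        g = (rng.random((6, 6, 6)) < 0.35).astype(np.uint8)
        if (p | g).sum() == 0 or p.sum() == 0 or g.sum() == 0:
            continue
        c = confusion(p, g)
        dice = dice_coefficient(p, g)
        assert dice == pytest.approx(2 * c.tp / (2 * c.tp + c.fp + c.fn), abs=1e-12)
        if c.tp > 0:
            f1 = 2 / (1 / recall(c) + 1 / precision(c))
            assert dice == pytest.approx(f1, abs=1e-12)
        assert f2_score(c) <= 1.0


def test_pr_curve_perfect_predictor(rng):
    gt = (rng.random((6, 6, 6)) < 0.2).astype(np.uint8)
    gt[0, 0, 0] = 1
    gt[1, 1, 1] = 0
    curve = pr_curve(gt.astype(np.float32), gt)
    hits = (curve.recall == 1.0) & (curve.precision == 1.0)
    assert hits.any()
    assert auprc(curve) == pytest.approx(1.0)


def test_pr_curve_constant_predictor_gives_prevalence():
    gt = np.zeros((10, 10, 10), dtype=np.uint8)
    gt[:2] = 1  # prevalence 0.2
    probs = np.full(gt.shape, 0.5, dtype=np.float32)
    curve = pr_curve(probs, gt)
    assert curve.recall[-1] == 1.0
    assert curve.precision[-1] == pytest.approx(0.2)
    assert auprc(curve) == pytest.approx(0.2)


def test_pr_curve_monotone_recall_and_degenerate_gt(rng):
    probs = rng.random((8, 8, 8)).astype(np.float32)
    gt = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
    gt[0, 0, 0] = 1
    gt[1, 0, 0] = 0
    curve = pr_curve(probs, gt)
    assert np.all(np.diff(curve.recall) >= 0)
    assert np.all((curve.recall >= 0) & (curve.recall <= 1))
    assert np.all((curve.precision >= 0) & (curve.precision <= 1))
    with pytest.raises(UndefinedMetricError):
        pr_curve(probs, np.ones_like(gt))


@pytest.mark.parametrize("trial", range(5))
def test_auprc_matches_all_threshold_sweep(trial):
    rng = np.random.default_rng(500 + trial)
    probs = rng.random((8, 8, 8)).astype(np.float32)
    gt = (rng.random((8, 8, 8)) < 0.25).astype(np.uint8)
    gt[0, 0, 0] = 1
    gt[-1, -1, -1] = 0
    ours = auprc(pr_curve(probs, gt))
    assert ours == pytest.approx(auprc_sweep_oracle(probs, gt), abs=1e-6)


def test_auprc_cross_checked_against_sklearn(rng):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    probs = rng.random(4000).astype(np.float32)
    gt = (rng.random(4000) < 0.15).astype(np.uint8)
    gt[0] = 1
    gt[1] = 0
    p3, g3 = probs.reshape(10, 20, 20), gt.reshape(10, 20, 20)
    ours = auprc(pr_curve(p3, g3))
    prec, rec, _ = sklearn_metrics.precision_recall_curve(gt, probs)
    # sklearn integrates stepwise (average precision); trapezoid differs
    # by at most the largest inter-threshold precision jump
    ap = sklearn_metrics.average_precision_score(gt, probs)
    assert ours == pytest.approx(ap, abs=0.02)


def test_quantile_thresholds_approximate_full_sweep(rng):
    probs = rng.random((12, 12, 12)).astype(np.float32)
    gt = (rng.random((12, 12, 12)) < 0.2).astype(np.uint8)
    gt[0, 0, 0] = 1
    gt[1, 1, 1] = 0
    dense = auprc(pr_curve(probs, gt, n_thresholds=100_000))
    coarse = auprc(pr_curve(probs, gt, n_thresholds=256))
    assert coarse == pytest.approx(dense, abs=5e-3)


def test_auprc_baseline_prevalence():
    gt = np.zeros((10, 10, 10), dtype=np.uint8)
    gt.ravel()[:11] = 1
    assert auprc_baseline(gt) == pytest.approx(0.011)
    assert auprc_baseline(np.ones((4, 4, 4))) == 1.0
    half = np.zeros((4, 4, 4), dtype=np.uint8)
    half[:2] = 1
    assert auprc_baseline(half) == 0.5


def test_midpoint_delta_variant_is_not_an_area(rng):
    gt = np.zeros((10, 10, 10), dtype=np.uint8)
    gt[:2] = 1
    probs = np.full(gt.shape, 0.5, dtype=np.float32)
    curve = pr_curve(probs, gt)
    # the printed-form integrand telescopes to ~0 on a flat curve
    assert abs(auprc(curve, variant="midpoint_delta")) < 1e-9


def test_evaluate_composes_standalone_metrics(rng):
    probs = rng.random((8, 8, 8)).astype(np.float32)
    pred = (probs > 0.5).astype(np.uint8)
    gt = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
    gt[0, 0, 0] = 1
    gt[1, 1, 1] = 0
    rep = evaluate(probs, pred, gt)
    c = confusion(pred, gt)
    assert rep.dice == pytest.approx(dice_coefficient(gt, pred))
    assert rep.f2 == pytest.approx(f2_score(c))
    assert rep.accuracy == pytest.approx(accuracy(c))
    assert rep.recall == pytest.approx(recall(c))
    assert rep.precision == pytest.approx(precision(c))
    assert rep.auprc == pytest.approx(auprc(pr_curve(probs, gt)))
    assert rep.auprc_baseline == pytest.approx(auprc_baseline(gt))
    assert all(0.0 <= v <= 1.0 for v in rep.to_dict().values())


def test_perfect_prediction_maxes_all_metrics(rng):
    gt = (rng.random((6, 6, 6)) < 0.3).astype(np.uint8)
    gt[0, 0, 0] = 1
    gt[1, 1, 1] = 0
    rep = evaluate(gt.astype(np.float32), gt, gt)
    assert rep.dice == rep.f2 == rep.accuracy == rep.recall == rep.precision == 1.0
    assert rep.auprc == pytest.approx(1.0)


def test_metrics_invariant_under_common_permutation(rng):
    probs = rng.random((6, 6, 6)).astype(np.float32)
    pred = (probs > 0.6).astype(np.uint8)
    gt = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
    gt[0, 0, 0] = 1
    gt[1, 1, 1] = 0
    rep = evaluate(probs, pred, gt)
    perm = rng.permutation(6 * 6 * 6)
    shuffle = lambda a: a.ravel()[perm].reshape(6, 6, 6)
    rep2 = evaluate(shuffle(probs), shuffle(pred), shuffle(gt))
    for k, v in rep.to_dict().items():
        assert rep2.to_dict()[k] == pytest.approx(v, abs=1e-12)


def test_random_scores_auprc_near_prevalence():
    """Scores independent of truth give AUPRC ~ prevalence (3 sigma)."""
    rng = np.random.default_rng(8)
    n = 100 ** 3
    probs = rng.random(n).astype(np.float32).reshape(100, 100, 100)
    gt = (rng.random(n) < 0.1).astype(np.uint8).reshape(100, 100, 100)
    val = auprc(pr_curve(probs, gt, n_thresholds=1024))
    # binomial-scale fluctuation of the precision estimate
    sigma = 3 * np.sqrt(0.1 * 0.9 / n) * 10
    assert abs(val - 0.1) < max(sigma, 5e-3)
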