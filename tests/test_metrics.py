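"""Metric correctness against hand computations and brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import imau_seg as I

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementations under test)
# ---------------------------------------------------------------------------

def naive_counts(pred, truth):
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = pred[i, j], truth[i, j]
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def naive_auc(prob, truth):
    """Mann–Whitney pair enumeration with half credit for ties."""
    pos = prob[truth == 1]
    neg = prob[truth == 0]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


def naive_hd95(pred, truth):
    def boundary(mask):
        pts = []
        h, w = mask.shape
        for i in range(h):
            for j in range(w):
                if not mask[i, j]:
                    continue
                nbrs = [
                    mask[i + di, j + dj]
                    if 0 <= i + di < h and 0 <= j + dj < w
                    else 0
                    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
                ]
                if not all(nbrs):
                    pts.append((i, j))
        return np.array(pts, float)

    bp, bt = boundary(pred), boundary(truth)
    d = lambda a, b: np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    directed_pt = d(bp, bt).min(axis=1)
    directed_tp = d(bt, bp).min(axis=1)
    return float(np.percentile(np.concatenate([directed_pt, directed_tp]), 95))


# ---------------------------------------------------------------------------
# hand-evaluated examples
# ---------------------------------------------------------------------------

def test_confusion_counts_on_half_overlap():
    truth = np.zeros((4, 4), np.uint8)
    truth[:, :2] = 1  # left half
    pred = np.zeros((4, 4), np.uint8)
    pred[:2, :] = 1  # top half
    c = I.confusion_counts(pred, truth)
    assert (c.tp, c.fp, c.fn, c.tn) == (4, 4, 4, 4)
    assert c.total == 16


def test_confusion_counts_edge_cases():
    ones = np.ones((4, 4), np.uint8)
    zeros = np.zeros((4, 4), np.uint8)
    c = I.confusion_counts(ones, zeros)
    assert (c.tp, c.fp) == (0, 16)
    same = I.confusion_counts(ones, ones)
    assert same.fp == 0 and same.fn == 0
    with pytest.raises(ValueError, match="shape"):
        I.confusion_counts(ones, np.ones((3, 3), np.uint8))


def test_dice_and_jaccard_hand_values():
    c = I.ConfusionCounts(tp=3, fp=1, fn=1, tn=11)
    assert I.dice(c) == pytest.approx(0.75)
    assert I.jaccard(c) == pytest.approx(0.6)
    assert I.precision_recall(c) == pytest.approx((0.75, 0.75))
    assert I.dice(I.ConfusionCounts(0, 2, 3, 5)) == 0.0
    assert I.dice(I.ConfusionCounts(0, 0, 0, 16)) == 1.0  # both empty
    assert I.jaccard(I.ConfusionCounts(0, 0, 0, 16)) == 1.0


def test_published_iou_dice_pair_is_consistent():
    assert I.dice_from_jaccard(0.8483) == pytest.approx(0.9179, abs=5e-5)


def test_precision_undefined_when_no_positive_predictions():
    p, r = I.precision_recall(I.ConfusionCounts(0, 0, 2, 14))
    assert math.isnan(p) and r == 0.0


def test_mae_hand_sum():
    prob = np.array([[0.2, 0.8], [0.6, 0.4]])
    truth = np.array([[0, 1], [1, 0]])
    assert I.mae(prob, truth) == pytest.approx(0.3)
    assert I.mae(truth.astype(float), truth) == 0.0
    assert I.mae(np.full((4, 4), 0.5), np.eye(4)) == pytest.approx(0.5)


def test_hd95_identical_and_single_pixels():
    a = np.zeros((10, 10), np.uint8)
    a[3, 2] = 1
    b = np.zeros((10, 10), np.uint8)
    b[3, 7] = 1
    assert I.hd95(a, a) == 0.0
    assert I.hd95(a, b) == pytest.approx(5.0)
    assert math.isnan(I.hd95(a, np.zeros((10, 10), np.uint8)))


def test_auc_hand_example_and_extremes():
    prob = np.array([0.1, 0.4, 0.35, 0.8])
    truth = np.array([0, 0, 1, 1])
    assert I.auc_roc(prob, truth) == pytest.approx(naive_auc(prob, truth)) == 0.75
    assert I.auc_roc(truth.astype(float), truth) == 1.0
    assert I.auc_roc(1.0 - truth, truth) == 0.0
    assert math.isnan(I.auc_roc(prob, np.ones(4)))


def test_dice_loss_hand_value_and_limits():
    truth = np.array([[1.0, 1.0], [0.0, 0.0]])
    half = np.full((2, 2), 0.5)
    assert I.dice_loss(half, truth, smooth=1.0) == pytest.approx(0.4)
    assert I.dice_loss(truth, truth, smooth=1e-12) == pytest.approx(0.0, abs=1e-9)
    assert I.dice_loss(1 - truth, truth, smooth=1e-12) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# properties and oracle equivalence
# ---------------------------------------------------------------------------

@given(
    tp=st.integers(0, 500),
    fp=st.integers(0, 500),
    fn=st.integers(0, 500),
    tn=st.integers(0, 500),
)
@settings(deadline=None, max_examples=200)
def test_dice_iou_identity_on_random_tallies(tp, fp, fn, tn):
    c = I.ConfusionCounts(tp, fp, fn, tn)
    assert I.dice(c) == pytest.approx(I.dice_from_jaccard(I.jaccard(c)), abs=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_counts_metrics_match_naive_double_loop(seed):
    rng = np.random.default_rng(seed)
    pred = (rng.uniform(size=(16, 16)) > 0.6).astype(np.uint8)
    truth = (rng.uniform(size=(16, 16)) > 0.6).astype(np.uint8)
    c = I.confusion_counts(pred, truth)
    assert (c.tp, c.fp, c.fn, c.tn) == naive_counts(pred, truth)


@pytest.mark.parametrize("seed", range(4))
def test_auc_matches_pair_enumeration(seed):
    rng = np.random.default_rng(100 + seed)
    prob = rng.choice(np.linspace(0, 1, 11), size=50)  # ties included
    truth = (rng.uniform(size=50) > 0.5).astype(int)
    if truth.min() == truth.max():
        truth[0] = 1 - truth[0]
    assert I.auc_roc(prob, truth) == pytest.approx(naive_auc(prob, truth))


@pytest.mark.parametrize("seed", range(3))
def test_hd95_matches_allpairs_oracle_and_is_symmetric(seed):
    rng = np.random.default_rng(200 + seed)
    pred = np.zeros((12, 12), np.uint8)
    truth = np.zeros((12, 12), np.uint8)
    pred[2:8, 2:8] = 1
    y0, x0 = rng.integers(0, 5), rng.integers(0, 5)
    truth[y0 : y0 + 6, x0 : x0 + 6] = 1
    assert I.hd95(pred, truth) == pytest.approx(naive_hd95(pred, truth))
    assert I.hd95(pred, truth) == pytest.approx(I.hd95(truth, pred))


def test_shifted_square_hd95_matches_oracle():
    a = np.zeros((20, 20), np.uint8)
    b = np.zeros((20, 20), np.uint8)
    a[5:15, 5:15] = 1
    b[8:18, 5:15] = 1  # shifted by (3, 0)
    assert I.hd95(a, b) == pytest.approx(naive_hd95(a, b))


def test_dice_loss_complements_dice_for_binary_predictions(rng):
    truth = (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8)
    pred = (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8)
    c = I.confusion_counts(pred, truth)
    loss = I.dice_loss(pred.astype(float), truth, smooth=1e-12)
    assert loss + I.dice(c) == pytest.approx(1.0, abs=1e-6)


def test_evaluate_pair_produces_full_row(rng):
    truth = np.zeros((32, 32), np.uint8)
    truth[8:24, 8:24] = 1
    prob = np.clip(truth + rng.normal(0, 0.2, truth.shape), 0, 1)
    row = I.evaluate_pair(prob, truth, sample_id="x")
    assert 0 <= row.dice <= 1 and 0 <= row.iou <= 1
    assert row.dice == pytest.approx(I.dice_from_jaccard(row.iou), abs=1e-9)
    assert row.hd95 >= 0 and 0 <= row.auc <= 1
    assert row.sample_id == "x"
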