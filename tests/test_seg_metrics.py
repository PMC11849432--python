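import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from contrast_gate import seg_metrics as sm
from contrast_gate.errors import (
    DimensionMismatchError,
    EmptyLesionError,
    EmptyMaskPairError,
    UnpairedEvaluationsError,
)

from conftest import random_mask


# ---------------------------------------------------------------------------
# independent oracles


def confusion_loop(pred, gt):
    tp = fp = fn = tn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def hausdorff_all_pairs(pred, gt):
    a = np.argwhere(pred > 0)
    b = np.argwhere(gt > 0)
    d_ab = max(min(np.hypot(*(p - q)) for q in b) for p in a)
    d_ba = max(min(np.hypot(*(q - p)) for p in a) for q in b)
    return max(d_ab, d_ba)


def signed_rank_enumeration(diffs):
    """Exact one-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    return float(np.mean(np.asarray(stats) >= w_obs))


# ---------------------------------------------------------------------------


class TestMetricOracles:
    def test_counts_and_metrics_match_brute_force(self):
        rng = np.random.default_rng(0)
        for trial in range(200):
            shape = (int(rng.integers(4, 33)), int(rng.integers(4, 33)))
            gt = random_mask(rng, shape, p=0.08)
            pred = random_mask(rng, shape, p=0.08)
            c = sm.confusion_counts(pred, gt)
            assert (c.tp, c.fp, c.fn, c.tn) == confusion_loop(pred, gt)
            assert c.total == shape[0] * shape[1]
            if gt.any():
                assert sm.detection(pred, gt) == int(bool(np.sum(pred & gt)))
                assert sm.raad(c) == pytest.approx(
                    ((c.tp + c.fp) - (c.tp + c.fn)) / (c.tp + c.fn)
                )
                if pred.any():
                    assert sm.hausdorff(pred, gt) == pytest.approx(
                        hausdorff_all_pairs(pred, gt), abs=1e-9
                    )
            if c.tp + c.fp + c.fn > 0:
                assert sm.dice(c) == pytest.approx(
                    2 * c.tp / (c.fn + c.fp + 2 * c.tp), abs=1e-12
                )

    def test_dice_hand_values(self):
        assert sm.dice(sm.ConfusionCounts(2, 2, 2, 10)) == pytest.approx(0.5)
        assert sm.dice(sm.ConfusionCounts(5, 0, 0, 10)) == 1.0
        assert sm.dice(sm.ConfusionCounts(0, 3, 4, 10)) == 0.0
        with pytest.raises(EmptyMaskPairError):
            sm.dice(sm.ConfusionCounts(0, 0, 0, 16))

    def test_raad_hand_values(self):
        # predicted area 6, true area 4
        assert sm.raad(sm.ConfusionCounts(3, 3, 1, 10)) == pytest.approx(0.5)
        assert sm.raad(sm.ConfusionCounts(4, 0, 0, 10)) == 0.0
        assert sm.raad(sm.ConfusionCounts(0, 0, 4, 10)) == -1.0

    def test_hausdorff_known_distance(self):
        pred = np.zeros((8, 8), dtype=np.uint8)
        gt = np.zeros((8, 8), dtype=np.uint8)
        pred[0, 0] = 1
        gt[3, 4] = 1
        assert sm.hausdorff(pred, gt) == pytest.approx(5.0)

    def test_empty_prediction_gets_the_cap(self):
        gt = np.zeros((8, 8), dtype=np.uint8)
        gt[2:4, 2:4] = 1
        pred = np.zeros_like(gt)
        assert sm.hausdorff(pred, gt) == 60.0
        ev = sm.evaluate_slice(pred, gt, "s")
        assert ev.hd_degenerate and ev.hd == 60.0 and ev.raad == -1.0

    def test_empty_ground_truth_rejected(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        o = np.ones((4, 4), dtype=np.uint8)
        for fn in (sm.detection, sm.hausdorff):
            with pytest.raises(EmptyLesionError):
                fn(o, z)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DimensionMismatchError):
            sm.confusion_counts(np.zeros((3, 3)), np.zeros((3, 4)))

    def test_detection_requires_overlap(self):
        gt = np.zeros((6, 6), dtype=np.uint8)
        gt[0:2, 0:2] = 1
        disjoint = np.zeros_like(gt)
        disjoint[4:6, 4:6] = 1
        touching = np.zeros_like(gt)
        touching[1, 1] = 1
        assert sm.detection(disjoint, gt) == 0
        assert sm.detection(np.zeros_like(gt), gt) == 0
        assert sm.detection(touching, gt) == 1


class TestMetricProperties:
    def test_symmetries(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = random_mask(rng, (16, 16), 0.15)
            b = random_mask(rng, (16, 16), 0.15)
            if not (a.any() and b.any()):
                continue
            assert sm.dice(sm.confusion_counts(a, b)) == pytest.approx(
                sm.dice(sm.confusion_counts(b, a))
            )
            assert sm.hausdorff(a, b) == pytest.approx(sm.hausdorff(b, a))
        # RAAD is directional: swapping flips which area is the reference
        gt = np.zeros((8, 8), dtype=np.uint8); gt[0:2, 0:4] = 1
        pred = np.zeros_like(gt); pred[0:2, 0:2] = 1
        assert sm.raad(sm.confusion_counts(pred, gt)) == pytest.approx(-0.5)
        assert sm.raad(sm.confusion_counts(gt, pred)) == pytest.approx(1.0)

    def test_perfect_prediction_fixed_points(self):
        rng = np.random.default_rng(2)
        gt = random_mask(rng, (12, 12), 0.2)
        gt[0, 0] = 1
        ev = sm.evaluate_slice(gt, gt, "s")
        assert ev.dsc == 1.0 and ev.hd == 0.0 and ev.raad == 0.0 and ev.detection == 1

    def test_flags_follow_thresholds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            gt = random_mask(rng, (16, 16), 0.15)
            pred = random_mask(rng, (16, 16), 0.15)
            if not gt.any():
                continue
            ev = sm.evaluate_slice(pred, gt, "s")
            assert ev.dsc_ok == (ev.dsc >= 0.1)
            assert ev.hd_ok == (ev.hd <= 60.0)
            assert ev.raad_ok == (abs(ev.raad) <= 0.5)
            if ev.detection:
                assert ev.dsc > 0


class TestCombinedLoss:
    def test_half_foreground_uniform_prediction(self):
        y = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        p = np.full(8, 0.5)
        # softDice = 0.5, BCE = ln 2
        assert sm.combined_loss(y, p) == pytest.approx(0.5 + np.log(2.0), abs=1e-9)

    def test_perfect_prediction_loss_vanishes(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert sm.combined_loss(y, y, epsilon=1e-9) == pytest.approx(0.0, abs=1e-7)

    def test_empty_target_with_tiny_prediction(self):
        # with no foreground the soft-Dice overlap is zero, so the Dice term
        # saturates at 1 and the BCE term is epsilon-order
        y = np.zeros(16)
        eps = 1e-6
        loss = sm.combined_loss(y, np.full(16, eps), epsilon=eps)
        assert loss == pytest.approx(1.0 + eps, abs=1e-4)

    def test_both_empty_is_a_perfect_match(self):
        y = np.zeros(16)
        p = np.zeros(16)
        loss = sm.combined_loss(y, p, epsilon=1e-9)
        assert loss == pytest.approx(0.0, abs=1e-7)


class TestWilcoxon:
    def test_five_positive_differences_exact_p(self):
        p = sm.wilcoxon_one_sided(np.array([0.2, 0.5, 0.1, 0.9, 0.3]))
        assert p == pytest.approx(1.0 / 32.0)

    def test_matches_full_enumeration(self):
        rng = np.random.default_rng(4)
        for n in (4, 6, 9, 12):
            for _ in range(5):
                d = rng.normal(0.2, 1.0, n)
                d = d[np.abs(d) > 1e-6]
                if len(np.unique(np.abs(d))) != len(d) or not len(d):
                    continue
                assert sm.wilcoxon_one_sided(d) == pytest.approx(
                    signed_rank_enumeration(d), abs=1e-12
                )

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 1.0, 8)
        ranks = rankdata(np.abs(d))
        point_mass = None
        p_fwd = sm.wilcoxon_one_sided(d)
        p_rev = sm.wilcoxon_one_sided(-d)
        # P(W >= w) + P(W >= sum-w) = 1 + P(W == w) under the exact null
        stats = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
        w_obs = ranks[d > 0].sum()
        point_mass = float(np.mean(np.asarray(stats) == w_obs))
        assert p_fwd + p_rev == pytest.approx(1.0 + point_mass, abs=1e-12)

    def test_all_zero_differences_flagged_undefined(self):
        assert np.isnan(sm.wilcoxon_one_sided(np.zeros(6)))

    def test_bin_compare_orientation_and_pairing(self):
        rng = np.random.default_rng(6)
        evals_a, evals_b, contrasts = [], [], {}
        for i in range(10):
            sid = f"s{i}"
            contrasts[sid] = 0.02 if i < 5 else 0.2
            # model A strictly better: higher dsc, lower hd, smaller |raad|
            evals_a.append(sm.SliceEvaluation(sid, 1, 0.8 + 0.01 * i, 5.0, 0.1,
                                              True, True, True))
            evals_b.append(sm.SliceEvaluation(sid, 1, 0.5 + 0.01 * i, 15.0, -0.6,
                                              True, True, False))
        table = sm.wilcoxon_bin_compare(evals_a, evals_b, contrasts, [0.0, 0.1, 0.3])
        for m in ("dsc", "hd", "raad"):
            sub = table[table["metric"] == m]
            assert np.allclose(sub["p_value"].dropna(), 1 / 32)
        with pytest.raises(UnpairedEvaluationsError):
            sm.wilcoxon_bin_compare(evals_a[:-1], evals_b, contrasts, [0.0, 0.3])
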