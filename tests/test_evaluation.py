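import numpy as np
import pytest

from nodugrowth import (
    GrowthEstimate,
    bacc_2std,
    classification_metrics,
    closest_annotator_growth,
    closest_annotator_segmentation,
    dice,
    ged,
    mae_growth,
    stratified_report,
)
from nodugrowth.cohort_io import GrowthRecord

from conftest import disk_mask


def estimate(delta_mean, delta_std=0.0, prob_mean=0.5, K=10):
    return GrowthEstimate(
        deltas=np.full(K, delta_mean),
        delta_mean=delta_mean,
        delta_std=delta_std,
        prob_mean=prob_mean,
        prob_std=0.0,
        mean_image=np.zeros((32, 32)),
        std_image=np.zeros((32, 32)),
        K=K,
        d0_mm=8.0,
    )


class TestDice:
    def test_identity_and_disjoint(self):
        a = disk_mask(5)
        assert dice(a, a) == 1.0
        b = np.zeros_like(a)
        b[0, 0] = 1
        assert dice(disk_mask(3, centre=(20, 20)), b) == 0.0
        assert dice(np.zeros((32, 32)), np.zeros((32, 32))) == 1.0

    def test_matches_set_arithmetic(self, rng):
        for _ in range(20):
            a = rng.random((32, 32)) > 0.6
            b = rng.random((32, 32)) > 0.6
            expected = 2 * np.sum(a & b) / (a.sum() + b.sum())
            assert dice(a, b) == pytest.approx(expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((32, 32)), np.zeros((16, 16)))


class TestClassificationMetrics:
    def test_perfect(self):
        assert classification_metrics([1, 0, 1], [1, 0, 1]) == (1.0, 1.0, 1.0)

    def test_constant_positive_on_balanced_set(self):
        bacc, prec, rec = classification_metrics([1, 1, 1, 1], [1, 0, 1, 0])
        assert bacc == 0.5 and rec == 1.0

    def test_confusion_arithmetic(self):
        # TP=3, FP=1, TN=4, FN=2
        y_true = [1] * 5 + [0] * 5
        y_pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        bacc, prec, rec = classification_metrics(y_pred, y_true)
        assert bacc == pytest.approx((0.6 + 0.8) / 2)
        assert prec == pytest.approx(0.75)
        assert rec == pytest.approx(0.6)

    def test_undefined_denominators_are_nan(self):
        bacc, prec, rec = classification_metrics([0, 0], [0, 0])
        assert np.isnan(prec) and np.isnan(rec) and np.isnan(bacc)
        with pytest.raises(ValueError):
            classification_metrics([0], [0, 1])


class TestGED:
    def test_identical_single_masks(self):
        m = disk_mask(4)
        g, two_cross, wp, wg = ged([m], [m])
        assert (g, two_cross, wp, wg) == (0.0, 0.0, 0.0, 0.0)

    def test_disjoint_single_masks(self):
        a = disk_mask(3, centre=(8, 8))
        b = disk_mask(3, centre=(24, 24))
        g, two_cross, wp, wg = ged([a], [b])
        assert two_cross == pytest.approx(2.0)
        assert wp == wg == 0.0
        assert g == pytest.approx(np.sqrt(2.0))

    def test_matches_brute_force_double_loop(self, rng):
        def iou(a, b):
            u = np.sum(a | b)
            return np.sum(a & b) / u if u else 1.0

        preds = [rng.random((32, 32)) > 0.7 for _ in range(5)]
        gts = [rng.random((32, 32)) > 0.7 for _ in range(3)]
        g, two_cross, wp, wg = ged(preds, gts)
        cross = np.mean([[1 - iou(a, b) for b in gts] for a in preds])
        wp_o = np.mean([[1 - iou(a, b) for b in preds] for a in preds])
        wg_o = np.mean([[1 - iou(a, b) for b in gts] for a in gts])
        assert two_cross == pytest.approx(2 * cross)
        assert wp == pytest.approx(wp_o)
        assert wg == pytest.approx(wg_o)
        assert g == pytest.approx(np.sqrt(max(0, 2 * cross - wp_o - wg_o)))

    def test_same_set_ged_is_zero(self, rng):
        masks = [rng.random((32, 32)) > 0.6 for _ in range(4)]
        g, two_cross, wp, wg = ged(masks, masks)
        assert two_cross == pytest.approx(wp + wg)
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ged([], [disk_mask(3)])


class TestBacc2Std:
    CASES = [
        (3.0, 2.5, 3.5, "TP"),  # truth grows, interval entirely above 2 mm
        (3.0, 1.5, 4.5, "FN"),  # truth grows but lower bound dips below
        (1.0, 0.0, 1.8, "TN"),  # no growth, interval entirely at/below 2 mm
        (1.0, 0.0, 2.5, "FP"),  # no growth but upper bound crosses 2 mm
    ]

    @pytest.mark.parametrize(
        "pos_kind,neg_kind,expected",
        [
            ("TP", "TN", 1.0),
            ("TP", "FP", 0.5),
            ("FN", "TN", 0.5),
            ("FN", "FP", 0.0),
        ],
    )
    def test_interval_confusion_cells(self, pos_kind, neg_kind, expected):
        """Pairing each positive-class case with each negative-class case
        pins down all four interval confusion cells."""
        by_kind = {k: (gt, lo, hi) for gt, lo, hi, k in self.CASES}
        ests, gts = [], []
        for kind in (pos_kind, neg_kind):
            gt, lo, hi = by_kind[kind]
            ests.append(estimate((lo + hi) / 2, (hi - lo) / 4))
            gts.append(gt)
        assert bacc_2std(ests, gts) == pytest.approx(expected)

    def test_four_case_cohort_scores_half(self):
        ests = [estimate((lo + hi) / 2, (hi - lo) / 4) for _, lo, hi, _ in self.CASES]
        gts = [gt for gt, *_ in self.CASES]
        assert bacc_2std(ests, gts) == pytest.approx(0.5)

    def test_interval_criterion_not_easier_than_mean_criterion(self, rng):
        """The +/-2 std interval call is harder on both classes than the
        plain mean-growth call whenever std > 0."""
        for _ in range(20):
            n = 40
            gts = rng.normal(2, 2, size=n)
            ests = [
                estimate(rng.normal(2, 2), rng.uniform(0.1, 2.0)) for _ in range(n)
            ]
            mean_calls = [int(e.delta_mean > 2) for e in ests]
            truths = [int(g > 2) for g in gts]
            bacc_mean, _, _ = classification_metrics(mean_calls, truths)
            b2 = bacc_2std(ests, gts)
            if not (np.isnan(bacc_mean) or np.isnan(b2)):
                assert b2 <= bacc_mean + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bacc_2std([estimate(1.0)], [1.0, 2.0])


class TestClosestAnnotator:
    def test_growth_single_and_arithmetic(self):
        est = estimate(2.2, 1.0)
        assert closest_annotator_growth(est, [5.0]) == 0
        assert closest_annotator_growth(est, [2.0, 5.0]) == 0
        assert closest_annotator_growth(est, [5.0, 2.0]) == 1
        # equidistant: lowest index wins
        assert closest_annotator_growth(estimate(3.0, 1.0), [2.0, 4.0]) == 0
        # zero std falls back to absolute difference
        assert closest_annotator_growth(estimate(3.0, 0.0), [10.0, 3.1]) == 1
        with pytest.raises(ValueError):
            closest_annotator_growth(est, [])

    def test_segmentation_selection(self, rng):
        gt_masks = [disk_mask(3), disk_mask(5), disk_mask(7)]
        samples = [disk_mask(5) for _ in range(4)]
        assert closest_annotator_segmentation(samples, gt_masks) == 1
        # brute-force mean-Dice table agreement on random fixtures
        samples = [rng.random((32, 32)) > 0.7 for _ in range(5)]
        gts = [rng.random((32, 32)) > 0.7 for _ in range(3)]
        table = [np.mean([dice(s, g) for s in samples]) for g in gts]
        assert closest_annotator_segmentation(samples, gts) == int(np.argmax(table))
        with pytest.raises(ValueError):
            closest_annotator_segmentation([], gt_masks)


def _rec(growth_mm, elapsed_days):
    img = np.full((32, 32), 0.5)
    mask = np.zeros((32, 32), dtype=np.uint8)
    mask[14:18, 14:18] = 1
    return GrowthRecord(
        nodule_id=f"N{growth_mm}_{elapsed_days}",
        annotator_id="RX0",
        image_t0=img,
        image_t1=img,
        mask_t0=mask,
        mask_t1=mask,
        d0_mm=8.0,
        d1_mm=8.0 + growth_mm,
        elapsed_days=elapsed_days,
        spacing_mm=0.75,
    )


class TestStratifiedReport:
    def test_all_correct(self):
        records = [_rec(3.0, 100), _rec(1.0, 400), _rec(6.0, 800)]
        ests = [
            estimate(r.growth_mm, prob_mean=0.9 if r.growth_mm > 2 else 0.1)
            for r in records
        ]
        rep = stratified_report(ests, records)
        acc = rep["accuracy"]
        assert np.nansum(acc == 1.0) == 3
        assert rep["accuracy_within_24mo"] == 1.0

    def test_single_wrong_record(self):
        records = [_rec(3.0, 100)]
        rep = stratified_report([estimate(0.0, prob_mean=0.1)], records)
        assert rep["accuracy"][2, 0] == 0.0
        assert np.isnan(rep["accuracy"]).sum() == 15

    def test_matches_hand_count(self):
        # two in (2,5] x <=6mo cell: one right one wrong -> 0.5; one
        # correct >24mo case excluded from the aggregate
        records = [_rec(3.0, 90), _rec(4.0, 90), _rec(1.0, 900)]
        ests = [
            estimate(3.0, prob_mean=0.9),
            estimate(0.0, prob_mean=0.1),
            estimate(1.0, prob_mean=0.1),
        ]
        rep = stratified_report(ests, records)
        assert rep["accuracy"][2, 0] == pytest.approx(0.5)
        assert rep["accuracy"][1, 3] == 1.0
        assert rep["accuracy_within_24mo"] == pytest.approx(0.5)
        assert rep["counts"].sum() == 3


class TestMAE:
    def test_cases(self):
        assert mae_growth([estimate(1.0), estimate(3.0)], [2.0, 2.0]) == 1.0
        assert mae_growth([estimate(2.0)], [2.0]) == 0.0
        rng = np.random.default_rng(1)
        means = rng.normal(size=10)
        gts = rng.normal(size=10)
        ests = [estimate(m) for m in means]
        assert mae_growth(ests, gts) == pytest.approx(np.abs(means - gts).mean())
        with pytest.raises(ValueError):
            mae_growth([], [])

    def test_permutation_invariance(self, rng):
        means = rng.normal(size=8)
        gts = rng.normal(size=8)
        perm = rng.permutation(8)
        a = mae_growth([estimate(m) for m in means], gts)
        b = mae_growth([estimate(m) for m in means[perm]], gts[perm])
        assert a == pytest.approx(b)
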