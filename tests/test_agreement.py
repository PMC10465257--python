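"""Agreement metrics against hand-worked values and brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from annotqc.agreement import (
    ConfusionCounts,
    cohens_kappa,
    confusion_counts,
    gwets_ac1,
    kappa_category,
    overlap_metrics,
    pairwise_matrix,
    per_region_metrics,
    score_counts,
)
from annotqc.io_manifest import AlignmentError, AnnotationMask


def brute_force_counts(pred, ref):
    """Independent oracle: tally every pixel with explicit Python loops."""
    tp = tn = fp = fn = 0
    for i in range(len(pred)):
        for j in range(len(pred[0])):
            p, r = bool(pred[i][j]), bool(ref[i][j])
            if p and r:
                tp += 1
            elif p and not r:
                fp += 1
            elif not p and r:
                fn += 1
            else:
                tn += 1
    return tp, tn, fp, fn


class TestConfusionCounts:
    def test_identity_has_no_errors(self):
        rng = np.random.default_rng(0)
        m = rng.random((10, 10)) < 0.4
        c = confusion_counts(m, m)
        assert c.fp == 0 and c.fn == 0
        assert c.tp == int(m.sum())

    def test_complement_of_all_positive(self):
        ref = np.ones((10, 10), bool)
        c = confusion_counts(~ref, ref)
        assert (c.tp, c.fn, c.fp, c.tn) == (0, 100, 0, 0)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            pred = rng.random((50, 50)) < rng.uniform(0.05, 0.5)
            ref = rng.random((50, 50)) < rng.uniform(0.05, 0.5)
            c = confusion_counts(pred, ref)
            assert (c.tp, c.tn, c.fp, c.fn) == tuple(
                brute_force_counts(pred, ref)[k] for k in (0, 1, 2, 3))

    def test_window_restricts_evaluation(self):
        pred = np.ones((4, 4), bool)
        ref = np.zeros((4, 4), bool)
        window = np.zeros((4, 4), bool)
        window[:2] = True
        c = confusion_counts(pred, ref, window=window)
        assert c.total == 8 and c.fp == 8

    def test_shape_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            confusion_counts(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestOverlapMetrics:
    def test_hand_worked_half_overlap(self):
        iou, dsc, *_ = overlap_metrics(ConfusionCounts(50, 0, 25, 25))
        assert iou == pytest.approx(0.5)
        assert dsc == pytest.approx(2 / 3)

    def test_empty_foreground_degenerate(self):
        iou, dsc, tnr, tpr, precision = overlap_metrics(
            ConfusionCounts(0, 100, 0, 0))
        assert all(math.isnan(v) for v in (iou, dsc, tpr, precision))
        assert tnr == 1.0

    @settings(max_examples=100, deadline=None)
    @given(tp=st.integers(0, 1000), fp=st.integers(0, 1000),
           fn=st.integers(0, 1000), tn=st.integers(0, 1000))
    def test_dsc_iou_identity(self, tp, fp, fn, tn):
        iou, dsc, *_ = overlap_metrics(ConfusionCounts(tp, tn, fp, fn))
        if not math.isnan(iou):
            assert dsc == pytest.approx(2 * iou / (1 + iou), abs=1e-15)


class TestCohensKappa:
    def test_hand_worked_balanced(self):
        kappa, po, pe = cohens_kappa(ConfusionCounts(40, 40, 10, 10))
        assert po == pytest.approx(0.8)
        assert pe == pytest.approx(0.5)
        assert kappa == pytest.approx(0.6)

    def test_hand_worked_imbalanced(self):
        kappa, po, pe = cohens_kappa(ConfusionCounts(90, 5, 3, 2))
        assert pe == pytest.approx(0.8612)
        assert kappa == pytest.approx(0.639769, abs=1e-5)

    def test_perfect_agreement_is_one(self):
        kappa, po, _ = cohens_kappa(ConfusionCounts(30, 70, 0, 0))
        assert po == 1.0 and kappa == pytest.approx(1.0)

    def test_symmetric_in_pred_ref(self):
        c = ConfusionCounts(17, 50, 9, 24)
        swapped = ConfusionCounts(17, 50, 24, 9)
        assert cohens_kappa(c)[0] == pytest.approx(cohens_kappa(swapped)[0])

    def test_agrees_with_sklearn(self):
        """Independent general-purpose implementation as cross-check."""
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = rng.random(400) < 0.3
            b = rng.random(400) < 0.25
            c = confusion_counts(a.reshape(20, 20), b.reshape(20, 20))
            assert cohens_kappa(c)[0] == pytest.approx(
                cohen_kappa_score(b, a), abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(ConfusionCounts(0, 0, 0, 0))


class TestKappaCategory:
    @pytest.mark.parametrize("kappa, label", [
        (0.94, "almost-perfect"),
        (0.56, "moderate"),
        (0.0, "none"),
        (-0.5, "none"),
        (0.01, "none-to-slight"),
        (0.20, "none-to-slight"),
        (0.21, "fair"),
        (0.40, "fair"),
        (0.41, "moderate"),
        (0.61, "substantial"),
        (0.80, "substantial"),
        (0.81, "almost-perfect"),
        (1.0, "almost-perfect"),
    ])
    def test_interpretation_bands(self, kappa, label):
        assert kappa_category(kappa) == label

    @pytest.mark.parametrize("bad", [-1.5, 1.01])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            kappa_category(bad)


class TestGwetsAC1:
    def test_hand_worked_balanced_paper_variant(self):
        ac1, po, pe = gwets_ac1(ConfusionCounts(40, 40, 10, 10), "paper")
        assert pe == pytest.approx(0.5)
        assert ac1 == pytest.approx(0.6)

    def test_hand_worked_imbalanced_both_variants(self):
        c = ConfusionCounts(90, 5, 3, 2)
        ac1_p, _, pe_p = gwets_ac1(c, "paper")
        assert pe_p == pytest.approx(0.93**2 + 0.07**2)
        assert ac1_p == pytest.approx(0.6160, abs=1e-4)
        ac1_s, _, pe_s = gwets_ac1(c, "standard")
        assert pe_s == pytest.approx(0.13875)
        assert ac1_s == pytest.approx(0.9419, abs=1e-4)

    def test_variants_coincide_on_balanced_counts(self):
        c = ConfusionCounts(40, 40, 10, 10)
        assert gwets_ac1(c, "paper")[0] == pytest.approx(
            gwets_ac1(c, "standard")[0])

    def test_paper_variant_is_asymmetric_standard_is_not(self):
        c = ConfusionCounts(90, 5, 3, 2)
        swapped = ConfusionCounts(90, 5, 2, 3)
        assert gwets_ac1(c, "paper")[0] != pytest.approx(
            gwets_ac1(swapped, "paper")[0], abs=1e-6)
        assert gwets_ac1(c, "standard")[0] == pytest.approx(
            gwets_ac1(swapped, "standard")[0])

    def test_prevalence_direction_on_imbalanced_counts(self):
        """With heavy background prevalence and the annotator-marginal
        chance term, AC1 falls below kappa whenever its chance agreement is
        larger."""
        c = ConfusionCounts(20, 950, 5, 25)
        kappa, _, pe_k = cohens_kappa(c)
        ac1, _, pe_a = gwets_ac1(c, "paper")
        assert pe_a > pe_k
        assert ac1 < kappa


@settings(max_examples=50, deadline=None)
@given(tp=st.integers(0, 500), fp=st.integers(0, 500),
       fn=st.integers(0, 500), tn=st.integers(0, 500))
def test_perfect_observed_agreement_forces_coefficients_to_one(tp, fp, fn, tn):
    c = ConfusionCounts(tp, tn, 0, 0)
    if c.total == 0:
        return
    scores = score_counts(c)
    assert scores.po == 1.0
    for coef in (scores.kappa, scores.ac1_paper, scores.ac1_standard):
        if not math.isnan(coef):
            assert coef == pytest.approx(1.0)


def _mask(arr, rater="r", image_id="img"):
    return AnnotationMask(image_id=image_id, rater_id=rater, round_id=1,
                          mask=np.asarray(arr, bool))


class TestPairwiseMatrix:
    def test_identical_raters_score_one(self):
        arr = np.zeros((6, 6), bool)
        arr[2:4, 2:4] = True
        mat = pairwise_matrix({"a": [arr], "b": [arr.copy()]}, "kappa")
        assert mat.entry("a", "b") == pytest.approx(1.0)

    def test_three_raters_match_per_pair_computation(self):
        rng = np.random.default_rng(8)
        masks = {r: [rng.random((12, 12)) < 0.3 for _ in range(3)]
                 for r in ("a", "b", "c")}
        mat = pairwise_matrix(masks, "kappa", pooled=True)
        for x in ("a", "b", "c"):
            for y in ("a", "b", "c"):
                if x == y:
                    continue
                pooled = ConfusionCounts(0, 0, 0, 0)
                for mx, my in zip(masks[x], masks[y]):
                    pooled = pooled + confusion_counts(mx, my)
                assert mat.entry(x, y) == pytest.approx(
                    cohens_kappa(pooled)[0])

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(9)
        masks = {r: [rng.random((10, 10)) < 0.4] for r in "abcd"}
        for coef in ("kappa", "ac1_paper", "ac1_standard"):
            mat = pairwise_matrix(masks, coef)
            assert np.allclose(mat.values, mat.values.T)
            assert np.allclose(np.diag(mat.values), 1.0)

    def test_pooled_counts_equal_sum_of_per_image_counts(self):
        """Additivity: pooling images then counting equals summing counts."""
        rng = np.random.default_rng(10)
        a = [rng.random((8, 8)) < 0.3 for _ in range(4)]
        b = [rng.random((8, 8)) < 0.3 for _ in range(4)]
        total = ConfusionCounts(0, 0, 0, 0)
        for x, y in zip(a, b):
            total = total + confusion_counts(x, y)
        stacked = confusion_counts(np.concatenate(a), np.concatenate(b))
        assert (total.tp, total.tn, total.fp, total.fn) == (
            stacked.tp, stacked.tn, stacked.fp, stacked.fn)


def _disc(shape, center, radius):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


class TestPerRegionMetrics:
    def test_identity_scores_one_per_region(self):
        mask = np.zeros((40, 60), bool)
        mask[5:10, 5:10] = True
        mask[25:32, 40:50] = True
        scores, n_areas = per_region_metrics(mask, mask)
        assert len(scores) == 2 and n_areas == 2
        assert all(s.scores.iou == pytest.approx(1.0) for s in scores)

    def test_empty_pred_scores_zero(self):
        mask = np.zeros((40, 60), bool)
        mask[5:10, 5:10] = True
        scores, n_areas = per_region_metrics(np.zeros_like(mask), mask)
        assert n_areas == 0
        assert scores[0].scores.iou == 0.0
        assert scores[0].scores.tpr == 0.0

    def test_dilated_disc_matches_pixel_count_oracle(self):
        """Concentric discs: IoU equals the ratio of rasterised areas."""
        consensus = _disc((80, 80), (40, 40), 20)
        pred = _disc((80, 80), (40, 40), 22)
        scores, _ = per_region_metrics(pred, consensus, window_margin_px=30)
        expected = consensus.sum() / pred.sum()  # nested: |A∩B|/|A∪B| = |A|/|B|
        assert scores[0].scores.iou == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(400 / 484, abs=0.02)

    def test_neighbouring_regions_do_not_contaminate_window(self):
        consensus = np.zeros((30, 30), bool)
        consensus[5:10, 5:10] = True
        consensus[5:10, 14:19] = True  # within the other's dilated window
        pred = consensus.copy()
        scores, _ = per_region_metrics(pred, consensus, window_margin_px=10)
        for s in scores:
            assert s.scores.iou == pytest.approx(1.0)
            assert s.scores.precision == pytest.approx(1.0)

    def test_unmatched_pred_components_counted_as_areas(self):
        consensus = np.zeros((30, 30), bool)
        consensus[5:10, 5:10] = True
        pred = consensus.copy()
        pred[20:24, 20:24] = True  # spurious annotation, overlaps nothing
        scores, n_areas = per_region_metrics(pred, consensus)
        assert n_areas == 2
        assert scores[0].scores.iou == pytest.approx(1.0)
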