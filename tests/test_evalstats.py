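"""Evaluation statistics against independent oracles.

AUROC is checked against brute-force pairwise concordance counting;
DeLong's SE against a bootstrap; chi-squared against the hand Pearson
formula; document extraction against enumeration.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepscan.evalstats import (
    auroc,
    bonferroni,
    chi2_compare,
    delong,
    document_accuracy,
    extract_document,
    mcnemar_compare,
    segment_metrics,
    wald_ci,
    wilson_ci,
)
from sleepscan.segmenter import Label
from tests.test_bow import cand


def brute_force_auroc(scores, truth):
    """Oracle: explicit concordance count over all (positive, negative) pairs."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


class TestSegmentMetrics:
    def test_perfect_predictions(self):
        labs = [Label.AHI, Label.SAO2, Label.OTHER] * 3
        assert segment_metrics(labs, labs, Label.AHI) == (1.0, 1.0, 1.0)

    def test_hand_counted_example(self):
        # TP=1, FP=1, FN=1 for AHI
        pred = [Label.AHI, Label.AHI, Label.OTHER]
        true = [Label.AHI, Label.OTHER, Label.AHI]
        assert segment_metrics(pred, true, Label.AHI) == (0.5, 0.5, 0.5)

    def test_f1_matches_confusion_matrix_tally(self, rng):
        labels = [Label.AHI, Label.SAO2, Label.OTHER]
        pred = [labels[i] for i in rng.integers(0, 3, 50)]
        true = [labels[i] for i in rng.integers(0, 3, 50)]
        for c in (Label.AHI, Label.SAO2):
            r, p, f1 = segment_metrics(pred, true, c)
            tp = sum(1 for a, b in zip(pred, true) if a == c and b == c)
            fp = sum(1 for a, b in zip(pred, true) if a == c and b != c)
            fn = sum(1 for a, b in zip(pred, true) if a != c and b == c)
            p_ref = tp / (tp + fp) if tp + fp else 0.0
            r_ref = tp / (tp + fn) if tp + fn else 0.0
            f1_ref = 2 * p_ref * r_ref / (p_ref + r_ref) if p_ref + r_ref else 0.0
            assert np.isclose((r, p, f1), (r_ref, p_ref, f1_ref)).all()

    def test_zero_predictions_warns(self):
        with pytest.warns(UserWarning, match="no predicted positives"):
            segment_metrics([Label.OTHER], [Label.AHI], Label.AHI)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segment_metrics([Label.AHI], [], Label.AHI)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 10, [1] * 4 + [0] * 6) == 0.5

    def test_hand_example_three_quarters(self):
        # pos {0.9, 0.4}, neg {0.6, 0.1}: 3 of 4 pairs concordant
        assert auroc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_bruteforce_on_random_fixtures(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 500))
            truth = rng.random(n) < rng.uniform(0.2, 0.8)
            if truth.all() or not truth.any():
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            assert np.isclose(auroc(scores, truth), brute_force_auroc(scores, truth), atol=1e-12)


class TestDelong:
    def test_identical_models_give_p_one(self):
        rng = np.random.default_rng(0)
        truth = rng.random(80) < 0.4
        truth[:2] = [True, False]
        s = truth * 1.0 + rng.normal(0, 0.5, 80)
        res = delong(s, s, truth)
        assert res.z == 0.0 and res.p == 1.0

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        truth = rng.random(100) < 0.3
        truth[:2] = [True, False]
        a = truth + rng.normal(0, 1, 100)
        b = truth + rng.normal(0, 1.5, 100)
        res = delong(a, b, truth)
        assert res.ci_a[0] <= res.auc_a <= res.ci_a[1]
        assert res.ci_b[0] <= res.auc_b <= res.ci_b[1]

    def test_se_matches_bootstrap_within_20pct(self):
        rng = np.random.default_rng(7)
        n = 200
        truth = rng.random(n) < 0.35
        truth[:2] = [True, False]
        scores = truth * 1.0 + rng.normal(0, 0.9, n)
        res = delong(scores, scores, truth)

        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            t = truth[idx]
            if t.all() or not t.any():
                continue
            boots.append(auroc(scores[idx], t))
        boot_se = float(np.std(boots, ddof=1))
        assert abs(res.se_a - boot_se) / boot_se < 0.20

    def test_null_rejection_rate_near_5pct(self):
        """Under equal-quality paired models the test rejects at ~5%."""
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 200
        for _ in range(reps):
            truth = rng.random(200) < 0.35
            truth[:2] = [True, False]
            a = truth * 1.0 + rng.normal(0, 1, 200)
            b = truth * 1.0 + rng.normal(0, 1, 200)
            if delong(a, b, truth).p < 0.05:
                rejections += 1
        # binomial 99% band around 10/200
        assert 2 <= rejections <= 18

    def test_degenerate_variance_warns(self):
        # both models have zero placement variance but unequal AUCs
        truth = np.array([1, 1, 0, 0], dtype=bool)
        a = np.array([0.9, 0.8, 0.2, 0.1])
        with pytest.warns(UserWarning, match="degenerate"):
            res = delong(a, -a, truth)
        assert res.p == 1.0

    def test_both_perfect_models_collapse_quietly(self):
        truth = np.array([1, 1, 0, 0], dtype=bool)
        a = np.array([0.9, 0.8, 0.2, 0.1])
        res = delong(a, 0.5 * a, truth)
        assert res.p == 1.0 and res.ci_a == (1.0, 1.0)


class TestDocumentExtraction:
    def test_accuracy_formula(self):
        assert document_accuracy([True, True, False, False]) == 0.5
        assert document_accuracy([True] * 7) == 1.0

    def test_oracle_scorer_extracts_gold(self):
        cands = [cand(["w"], value=v, idx=i, report_id="R1") for i, v in enumerate([5.0, 19.5, 80.0])]
        scores = np.zeros((3, 3))
        scores[:, 0] = [0.1, 0.9, 0.2]  # oracle: truth indicator for AHI
        value, ok = extract_document(cands, scores, Label.AHI, gold_value=19.5)
        assert value == 19.5 and ok

    def test_tie_breaks_to_earliest_reading_order(self):
        cands = [cand(["w"], value=v, idx=i) for i, v in enumerate([7.0, 9.0])]
        scores = np.array([[0.5, 0, 0], [0.5, 0, 0]])
        value, _ = extract_document(cands, scores, Label.AHI, gold_value=9.0)
        assert value == 7.0

    def test_empty_document_counts_incorrect(self):
        value, ok = extract_document([], np.zeros((0, 3)), Label.AHI, gold_value=1.0)
        assert value is None and not ok

    def test_order_invariance_with_distinct_scores(self, rng):
        vals = [3.0, 8.0, 21.0, 44.0]
        scores = np.array([[0.2, 0, 0], [0.9, 0, 0], [0.4, 0, 0], [0.1, 0, 0]])
        cands = [cand(["w"], value=v, idx=i) for i, v in enumerate(vals)]
        base, _ = extract_document(cands, scores, Label.AHI, gold_value=8.0)
        perm = rng.permutation(4)
        shuffled, _ = extract_document([cands[i] for i in perm], scores[perm],
                                       Label.AHI, gold_value=8.0)
        assert base == shuffled == 8.0

    def test_wald_ci_shrinks_as_sqrt_n(self):
        w100 = wald_ci(0.8, 100)
        w400 = wald_ci(0.8, 400)
        ratio = (w100[1] - w100[0]) / (w400[1] - w400[0])
        assert np.isclose(ratio, 2.0, rtol=1e-6)

    def test_wilson_ci_contains_estimate(self):
        lo, hi = wilson_ci(0.9, 50)
        assert lo <= 0.9 <= hi


class TestChi2:
    def test_identical_counts(self):
        stat, p = chi2_compare((90, 100), (90, 100))
        assert stat == 0.0 and p == 1.0

    def test_hand_pearson_example(self):
        # E = [[80,20],[80,20]]; sum (O-E)^2/E = 1.25 + 5 + 1.25 + 5
        stat, p = chi2_compare((90, 100), (70, 100))
        assert np.isclose(stat, 12.5)
        assert p < 0.001

    def test_symmetry(self):
        s1, _ = chi2_compare((80, 100), (60, 90))
        s2, _ = chi2_compare((60, 90), (80, 100))
        assert np.isclose(s1, s2)

    def test_zero_margin_warns(self):
        with pytest.warns(UserWarning, match="zero margin"):
            stat, p = chi2_compare((100, 100), (100, 100))
        assert p == 1.0

    def test_null_rejection_rate_near_5pct(self):
        rng = np.random.default_rng(23)
        reps, rejections = 200, 0
        for _ in range(reps):
            a = int(rng.binomial(200, 0.8))
            b = int(rng.binomial(200, 0.8))
            _, p = chi2_compare((a, 200), (b, 200))
            if p < 0.05:
                rejections += 1
        assert 2 <= rejections <= 18

    def test_mcnemar_no_discordance(self):
        assert mcnemar_compare(50, 0, 0, 10) == (0.0, 1.0)


class TestBonferroni:
    def test_simple_multiplication(self):
        assert bonferroni([0.01], 3) == [0.03]

    def test_capped_at_one(self):
        assert bonferroni([0.4], 6) == [1.0]

    def test_m_one_is_identity(self):
        assert bonferroni([0.2, 0.03], 2)[1] == 0.06
        assert bonferroni([0.2], 1) == [0.2]

    def test_family_smaller_than_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6), st.integers(6, 20))
    def test_adjusted_at_least_raw_and_capped(self, ps, m):
        adj = bonferroni(ps, m)
        for raw, a in zip(ps, adj):
            assert a >= raw and a <= 1.0
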