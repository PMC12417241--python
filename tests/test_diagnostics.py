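"""ROC/AUC, Youden thresholds, confusion metrics, Fagan updates, bootstrap CI."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cemquant.diagnostics import (
    HIGHER_IS_MALIGNANT,
    LOWER_IS_MALIGNANT,
    DiagnosticsError,
    auc_ci,
    confusion_metrics,
    evaluate_all,
    fagan_posttest,
    roc_auc,
    youden_threshold,
)


# ----------------------------------------------------------------------
# Independent oracles
# ----------------------------------------------------------------------

def auc_pair_counting(scores, labels):
    """AUC by enumerating all (negative, positive) pairs; ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def youden_exhaustive(scores, labels):
    """Best J over every threshold between adjacent distinct scores."""
    uniq = sorted(set(scores))
    cuts = ([-np.inf] + [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]
            + [np.inf])
    best = None
    for thr in cuts:
        tp = sum(s >= thr and l for s, l in zip(scores, labels))
        tn = sum(s < thr and not l for s, l in zip(scores, labels))
        sens = tp / sum(labels)
        spec = tn / (len(labels) - sum(labels))
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    return best


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4, 5, 6],
                       [0, 0, 0, 1, 1, 1]) == pytest.approx(1.0)

    def test_all_tied_scores(self):
        assert roc_auc([5.0] * 6, [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)

    def test_hand_counted_pairs(self):
        # benign {1,3}, malignant {2,4}: wins 3 of 4 pairs
        assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(0, 12, 150).astype(float)
        labels = rng.random(150) < 0.4
        labels[0], labels[1] = True, False
        assert roc_auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels))

    def test_direction_negation(self):
        scores = [4.0, 3.0, 2.0, 1.0]
        labels = [1, 1, 0, 0]
        assert roc_auc(scores, labels, LOWER_IS_MALIGNANT) == pytest.approx(0.0)

    def test_complement_identity_tie_free(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        labels[:2] = [True, False]
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == \
            pytest.approx(1.0)

    @given(st.integers(1, 50))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = np.concatenate([np.ones(20, bool), np.zeros(20, bool)])
        transformed = np.exp(3.0 * scores) + 1.0
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc(transformed, labels))

    def test_single_class_rejected(self):
        with pytest.raises(DiagnosticsError):
            roc_auc([1.0, 2.0], [1, 1])


class TestYouden:
    def test_perfect_separation_midpoint(self):
        thr, sens, spec = youden_threshold([1, 2, 3, 4, 5, 6],
                                           [0, 0, 0, 1, 1, 1])
        assert thr == pytest.approx(3.5)
        assert (sens, spec) == (100.0, 100.0)

    def test_hand_worked_overlap(self):
        # benign {1,4}, malignant {2,3,5}: exhaustive search -> thr 1.5
        thr, sens, spec = youden_threshold([1, 4, 2, 3, 5],
                                           [0, 0, 1, 1, 1])
        assert thr == pytest.approx(1.5)
        assert (sens, spec) == (100.0, 50.0)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(17)
        scores = np.round(rng.normal(size=80), 1)
        labels = rng.random(80) < 0.45
        labels[:2] = [True, False]
        thr, sens, spec = youden_threshold(scores, labels)
        j_best, thr_o, sens_o, spec_o = youden_exhaustive(
            scores.tolist(), labels.tolist())
        assert sens / 100 + spec / 100 - 1 == pytest.approx(j_best)
        assert thr == pytest.approx(thr_o)

    def test_tie_takes_lowest_threshold(self):
        # thresholds 1.5 and 3.5 both give J = 0.5 here; lowest wins
        thr, _, _ = youden_threshold([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        assert thr == pytest.approx(1.5)

    def test_self_consistency_with_confusion_metrics(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=60)
        labels = np.concatenate([np.ones(25, bool), np.zeros(35, bool)])
        thr, sens, spec = youden_threshold(scores, labels)
        sens2, spec2, _ = confusion_metrics(scores, labels, thr)
        assert (sens, spec) == (sens2, spec2)

    def test_lower_is_malignant_direction(self):
        scores = [10.0, 9.0, 1.0, 2.0]   # malignant have LOW scores
        labels = [0, 0, 1, 1]
        thr, sens, spec = youden_threshold(scores, labels, LOWER_IS_MALIGNANT)
        assert sens == 100.0 and spec == 100.0
        sens2, spec2, acc = confusion_metrics(scores, labels, thr,
                                              LOWER_IS_MALIGNANT)
        assert (sens2, spec2, acc) == (100.0, 100.0, 100.0)


class TestConfusionMetrics:
    def test_perfect_separation(self):
        out = confusion_metrics([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1], 3.5)
        assert out == (100.0, 100.0, 100.0)

    def test_all_predicted_positive(self):
        sens, spec, _ = confusion_metrics([1, 2, 3, 4], [0, 0, 1, 1], -np.inf)
        assert (sens, spec) == (100.0, 0.0)

    def test_hand_counted_table(self):
        sens, spec, acc = confusion_metrics([1, 4, 2, 3, 5],
                                            [0, 0, 1, 1, 1], 1.5)
        assert (sens, spec, acc) == (100.0, 50.0, 80.0)


class TestFagan:
    def test_uninformative_test_keeps_pretest(self):
        post_mal, _ = fagan_posttest(0.5, 0.5, 0.5)
        assert post_mal == pytest.approx(50.0)

    def test_hand_odds_arithmetic(self):
        # LR+ = 0.8/0.2 = 4; odds 1 -> 4 -> p = 80%
        post_mal, _ = fagan_posttest(0.5, 0.8, 0.8)
        assert post_mal == pytest.approx(80.0)

    def test_perfect_rule_out(self):
        _, post_ben = fagan_posttest(0.3, 1.0, 0.7)
        assert post_ben == pytest.approx(100.0)

    def test_perfect_specificity_flagged_certain(self):
        post_mal, _ = fagan_posttest(0.3, 0.8, 1.0)
        assert post_mal == 100.0

    @given(st.floats(0.05, 0.95))
    def test_lr_one_fixed_point(self, pretest):
        """sens + spec = 1 gives LR+ = 1: the probability must not move."""
        post_mal, _ = fagan_posttest(pretest, 0.6, 0.4)
        assert post_mal == pytest.approx(100.0 * pretest)

    def test_invalid_pretest_rejected(self):
        with pytest.raises(DiagnosticsError):
            fagan_posttest(0.0, 0.5, 0.5)


class TestAucCi:
    def test_perfect_separation_upper_bound_one(self):
        scores = np.concatenate([np.arange(50), np.arange(100, 150)])
        labels = np.concatenate([np.zeros(50, bool), np.ones(50, bool)])
        lo, hi = auc_ci(scores, labels, n_boot=300, seed=0)
        assert hi == pytest.approx(1.0)

    def test_all_tied_contains_half(self):
        scores = np.full(40, 3.0)
        labels = np.concatenate([np.zeros(20, bool), np.ones(20, bool)])
        lo, hi = auc_ci(scores, labels, n_boot=300, seed=1)
        assert lo <= 0.5 <= hi

    def test_matches_independent_bootstrap_loop(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(size=40)
        labels = np.concatenate([np.zeros(22, bool), np.ones(18, bool)])
        seed, n_boot = 7, 400
        lo, hi = auc_ci(scores, labels, n_boot=n_boot, seed=seed)

        # Oracle: same resampling protocol, AUC by brute-force pair counting.
        pos, neg = scores[labels], scores[~labels]
        oracle_rng = np.random.default_rng(seed)
        stats = []
        for _ in range(n_boot):
            bp = oracle_rng.choice(pos, size=pos.size, replace=True)
            bn = oracle_rng.choice(neg, size=neg.size, replace=True)
            stats.append(auc_pair_counting(
                np.concatenate([bn, bp]),
                [False] * bn.size + [True] * bp.size))
        lo_o, hi_o = np.quantile(stats, [0.025, 0.975])
        assert (lo, hi) == pytest.approx((lo_o, hi_o))

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = np.concatenate([np.zeros(15, bool), np.ones(15, bool)])
        assert auc_ci(scores, labels, n_boot=250, seed=5) == \
            auc_ci(scores, labels, n_boot=250, seed=5)

    def test_tiny_class_rejected(self):
        with pytest.raises(DiagnosticsError):
            auc_ci([1.0, 2.0, 3.0], [0, 0, 1], n_boot=300)


class TestEvaluateAll:
    def test_fixture_comparison_sizes(self, paper_fixture):
        summaries = evaluate_all(paper_fixture, n_boot=300, seed=0)
        by = {(s.comparison, s.metric_name): s for s in summaries}
        benign = by[("benign_vs_malignant", "ce_early")]
        assert (benign.n_negative, benign.n_positive) == (28, 55)
        bpe = by[("bpe_vs_malignant", "ce_early")]
        assert (bpe.n_negative, bpe.n_positive) == (48, 55)

    def test_one_summary_per_metric_and_comparison(self, paper_fixture):
        summaries = evaluate_all(paper_fixture, n_boot=300, seed=0)
        assert len(summaries) == 10
        for s in summaries:
            assert s.auc_ci[0] <= s.auc <= s.auc_ci[1] or \
                s.auc == pytest.approx(s.auc_ci[0]) or \
                s.auc == pytest.approx(s.auc_ci[1])
            assert 0 <= s.sensitivity <= 100
            assert 0 <= s.specificity <= 100

    def test_rsd_direction_lower_is_malignant(self, paper_fixture):
        summaries = evaluate_all(paper_fixture, metrics=("rsd",),
                                 n_boot=300, seed=0)
        assert all(s.direction == LOWER_IS_MALIGNANT for s in summaries)
        assert all(s.auc > 0.5 for s in summaries)
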