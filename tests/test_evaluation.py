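"""ROC/AUC with DeLong CIs, cut-off and binary-rule performance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lynchpred import (ValidationError, auc, binary_rule_performance,
                       compare_aucs, per_gene_auc, performance_at_cutoff)


def concordance_oracle(scores, labels):
    """Brute-force pairwise concordance with ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def delong_variance_oracle(scores, labels):
    """Direct O(n^2) DeLong variance from the structural components."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    v01 = np.array([np.mean((x > neg) + 0.5 * (x == neg)) for x in pos])
    v10 = np.array([np.mean((pos > y) + 0.5 * (pos == y)) for y in neg])
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return s01 / m + s10 / n


class TestAuc:
    def test_perfect_separation(self):
        r = auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_complete_tie(self):
        assert auc([0.5, 0.5], [1, 0]).auc == 0.5

    def test_eight_point_mixed_set_matches_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.2, 0.6, 0.05]
        labels = [0, 1, 0, 1, 0, 1, 1, 0]
        r = auc(scores, labels)
        assert r.auc == pytest.approx(concordance_oracle(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([0.1, 0.2], [1, 1])

    def test_delong_variance_matches_structural_oracle(self):
        rng = np.random.default_rng(8)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        r = auc(scores, labels)
        assert r.se ** 2 == pytest.approx(
            delong_variance_oracle(scores, labels), abs=1e-12)

    def test_roc_points_monotone_and_anchored(self):
        rng = np.random.default_rng(2)
        r = auc(rng.random(40), rng.integers(0, 2, 40))
        pts = r.points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()
        assert r.ci_low <= r.auc <= r.ci_high

    @given(st.data())
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_concordance_oracle_on_random_instances(self, data):
        n = data.draw(st.integers(4, 50))
        scores = data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=n, max_size=n))
        k = data.draw(st.integers(1, n - 1))
        labels = [1] * k + [0] * (n - k)
        r = auc(scores, labels)
        assert r.auc == pytest.approx(concordance_oracle(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        base = auc(scores, labels).auc
        for f in (lambda s: 3 * s - 1, np.exp, lambda s: s ** 3):
            assert auc(f(scores), labels).auc == pytest.approx(base, abs=1e-12)


class TestPerGeneAuc:
    @staticmethod
    def _frame(status, score):
        return pd.DataFrame({"mutation_status": status, "p_overall": score})

    def test_perfectly_ranked_carriers(self):
        df = self._frame(["PMS2", "PMS2", "none", "none", "MLH1"],
                         [0.9, 0.8, 0.1, 0.2, 0.05])
        assert per_gene_auc(df, "PMS2").auc == 1.0

    def test_other_gene_carriers_excluded_from_negatives(self):
        # the low-scoring MLH1 carrier above must not count as a negative
        df = self._frame(["PMS2", "none", "MLH1"], [0.5, 0.1, 0.9])
        r = per_gene_auc(df, "PMS2")
        assert r.n_pos == 1 and r.n_neg == 1 and r.auc == 1.0

    def test_permutation_null_centres_at_half(self):
        rng = np.random.default_rng(31)
        n = 150
        status = np.array(["none"] * (n - 20) + ["PMS2"] * 20)
        scores = rng.random(n)
        aucs = []
        for _ in range(2000):
            perm = rng.permutation(status)
            df = self._frame(perm, scores)
            aucs.append(per_gene_auc(df, "PMS2").auc)
        aucs = np.array(aucs)
        se = aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 2 * se + 1e-3

    def test_zero_positives_rejected(self):
        df = self._frame(["none", "none"], [0.1, 0.2])
        with pytest.raises(ValidationError):
            per_gene_auc(df, "MSH6")


class TestCutoffPerformance:
    def test_all_flagged_extreme(self):
        perf = performance_at_cutoff([0.9, 0.8, 0.7], [1, 0, 1], 0.05)
        assert perf.sensitivity == 100 and perf.specificity == 0

    def test_hand_counted_confusion_matrix(self):
        scores = [0.01, 0.05, 0.30, 0.04, 0.90, 0.05]
        labels = [0, 1, 1, 1, 0, 0]
        perf = performance_at_cutoff(scores, labels, 0.05)
        # rule is score >= cutoff
        assert (perf.tp, perf.fp, perf.tn, perf.fn) == (2, 2, 1, 1)
        assert perf.sensitivity == 67 and perf.specificity == 33
        assert perf.n == 6

    def test_binary_scores_reduce_to_rule_performance(self):
        flags = [1, 0, 1, 1, 0]
        labels = [1, 1, 0, 1, 0]
        a = performance_at_cutoff([float(f) for f in flags], labels, 0.5)
        b = binary_rule_performance(flags, labels)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)

    def test_sensitivity_nonincreasing_in_cutoff(self):
        rng = np.random.default_rng(12)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        sens = [performance_at_cutoff(scores, labels, c).sensitivity
                for c in (0.05, 0.10, 0.20, 0.40, 0.80)]
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_counts_always_sum_to_n(self):
        rng = np.random.default_rng(13)
        scores = rng.random(57)
        labels = rng.integers(0, 2, 57)
        labels[:2] = [0, 1]
        assert performance_at_cutoff(scores, labels, 0.3).n == 57


class TestBinaryRulePerformance:
    def test_fulfilment_counts_by_mutation_status(self):
        """Rule flagged for 75/83 carriers and 494/651 non-carriers."""
        flags = [1] * 75 + [0] * 8 + [1] * 494 + [0] * 157
        labels = [1] * 83 + [0] * 651
        perf = binary_rule_performance(flags, labels)
        assert perf.sensitivity == 90
        assert perf.specificity == 24

    def test_all_flagged(self):
        perf = binary_rule_performance([1, 1, 1], [1, 0, 1])
        assert perf.sensitivity == 100 and perf.specificity == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            binary_rule_performance([1, 0], [1, 0, 1])


class TestCompareAucs:
    def test_identical_scores_give_zero_difference(self):
        rng = np.random.default_rng(21)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        r = auc(scores, labels)
        d = compare_aucs(r, auc(scores, labels), paired=True)
        assert d.delta == 0.0 and d.se == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(22)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        ra = auc(rng.random(80), labels)
        rb = auc(rng.random(80), labels)
        d1 = compare_aucs(ra, rb, paired=True)
        d2 = compare_aucs(rb, ra, paired=True)
        assert d1.delta == pytest.approx(-d2.delta, abs=1e-12)
        assert d1.se == pytest.approx(d2.se, abs=1e-12)

    def test_nested_strictly_better_model_detected(self):
        rng = np.random.default_rng(23)
        n = 4000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        eta = -1.0 + 1.2 * x1 + 1.2 * x2
        labels = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        full = auc(x1 + x2, labels)
        reduced = auc(x1, labels)
        d = compare_aucs(full, reduced, paired=True)
        assert d.delta > 0 and d.ci_low > 0

    def test_paired_with_different_subjects_rejected(self):
        ra = auc([0.1, 0.9, 0.3], [0, 1, 0])
        rb = auc([0.1, 0.9], [0, 1])
        with pytest.raises(ValidationError):
            compare_aucs(ra, rb, paired=True)
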