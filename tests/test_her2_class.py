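"""ROC/Youden threshold derivation, four-group assignment, diagnostic
metrics, and the packaged contingency-table arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddherd.her2_class import (
    ThresholdSet,
    assign_group,
    classify_her2,
    group_table,
    performance_metrics,
    roc_curve,
    table3_counts,
    table3_samples,
    youden_threshold,
)


def mann_whitney_auc(scores, labels):
    """Pair-counting AUC oracle: (concordant + half ties) / (n_pos * n_neg)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    score = 0.0
    for p in pos:
        for q in neg:
            score += 1.0 if p > q else (0.5 if p == q else 0.0)
    return score / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Brute-force best (J, threshold) over all midpoint candidates."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    uniq = np.unique(scores)
    best = (-np.inf, None)
    for t in (uniq[:-1] + uniq[1:]) / 2:
        sens = (scores[labels] >= t).mean()
        spec = (scores[~labels] < t).mean()
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, t)
    return best


class TestRoc:
    def test_perfect_separation_auc_one(self):
        r = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(1.0)
        assert r.optimal_youden == pytest.approx(1.0)
        # smallest midpoint inside the gap
        assert 3 < r.optimal_threshold <= 6.5

    def test_worked_eight_sample_set_matches_pair_counting(self):
        scores = [1, 2, 3, 4, 3, 5, 6, 7]
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        r = roc_curve(scores, labels)
        assert r.auc == pytest.approx(14.5 / 16)  # brute force over 16 pairs
        j, t = exhaustive_youden(scores, labels)
        assert youden_threshold(r) == pytest.approx((t, j))

    def test_uninformative_scores_auc_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_constant_scores_degenerate_j_zero(self):
        r = roc_curve([1.0] * 10, [0, 1] * 5)
        assert r.optimal_youden == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [1, 1, 1])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_auc_equals_mann_whitney_on_random_instances(self, data):
        n = data.draw(st.integers(4, 30))
        scores = data.draw(
            st.lists(st.integers(0, 8), min_size=n, max_size=n).map(
                lambda xs: [float(x) for x in xs]
            )
        )
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if all(labels) or not any(labels):
            labels[0] = not labels[0]
        r = roc_curve(scores, labels)
        assert r.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_youden_equals_exhaustive_search(self, data):
        n = data.draw(st.integers(4, 50))
        scores = [float(x) for x in data.draw(st.lists(st.integers(0, 12), min_size=n, max_size=n))]
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if all(labels) or not any(labels):
            labels[0] = not labels[0]
        if len(set(scores)) < 2:
            scores[0] += 1.0
        r = roc_curve(scores, labels)
        j, t = exhaustive_youden(scores, labels)
        assert r.optimal_youden == pytest.approx(j, abs=1e-12)
        assert r.optimal_threshold == pytest.approx(t, abs=1e-12)


class TestClassification:
    def setup_method(self):
        self.t = ThresholdSet()

    def test_published_group_means_classify_as_expected(self):
        # IHC 3+ group means (CN 12.0, ratio 5.71) -> positive everywhere;
        # IHC 0-1+ group means (CN 2.0, ratio 1.06) -> negative everywhere
        pos = {"erbb2_cn": 12.0, "erbb2_cep17_ratio": 5.71}
        neg = {"erbb2_cn": 2.0, "erbb2_cep17_ratio": 1.06}
        for criterion in ("cn", "ratio", "combination"):
            assert classify_her2(pos, self.t, criterion)
            assert not classify_her2(neg, self.t, criterion)

    def test_boundary_values_are_inclusive(self):
        boundary = {"erbb2_cn": 3.05, "erbb2_cep17_ratio": 1.55}
        for criterion in ("cn", "ratio", "combination"):
            assert classify_her2(boundary, self.t, criterion)
        assert assign_group(boundary, self.t) == 1

    def test_missing_field_raises_with_field_name(self):
        with pytest.raises(ValueError, match="erbb2_cep17_ratio"):
            classify_her2({"erbb2_cn": 5.0}, self.t, "ratio")

    @pytest.mark.parametrize(
        "cn,ratio,group",
        [
            (12.0, 5.0, 1),  # classic amplified
            (2.5, 1.7, 2),  # monosomy pattern
            (4.0, 1.2, 3),  # co-amplification
            (2.0, 1.0, 5),  # classic non-amplified
        ],
    )
    def test_four_group_rules(self, cn, ratio, group):
        assert assign_group({"erbb2_cn": cn, "erbb2_cep17_ratio": ratio}, self.t) == group

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        cn=st.floats(0.01, 60, allow_nan=False),
        ratio=st.floats(0.01, 20, allow_nan=False),
    )
    def test_group_assignment_is_total_partition(self, cn, ratio):
        g = assign_group({"erbb2_cn": cn, "erbb2_cep17_ratio": ratio}, ThresholdSet())
        assert g in {1, 2, 3, 5}
        positive = classify_her2(
            {"erbb2_cn": cn, "erbb2_cep17_ratio": ratio}, ThresholdSet(), "combination"
        )
        assert positive == (g in {1, 2, 3})

    def test_combination_is_or_of_criteria(self):
        t = self.t
        only_cn = {"erbb2_cn": 4.0, "erbb2_cep17_ratio": 1.2}
        only_ratio = {"erbb2_cn": 2.5, "erbb2_cep17_ratio": 1.7}
        assert classify_her2(only_cn, t, "combination")
        assert classify_her2(only_ratio, t, "combination")


class TestPerformanceMetrics:
    def test_perfect_prediction(self):
        m = performance_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert (m.sensitivity, m.specificity, m.accuracy, m.ppv, m.npv) == (1, 1, 1, 1, 1)

    def test_all_positive_prediction_has_missing_npv(self):
        m = performance_metrics([1, 1, 1], [1, 0, 1])
        assert m.specificity == 0.0
        assert math.isnan(m.npv)

    def test_missing_reference_excluded_and_counted(self):
        m = performance_metrics([1, 0, 1], [1, 0, None])
        assert (m.tp, m.tn, m.n_missing_reference) == (1, 1, 1)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
    def test_accuracy_identity(self, pairs):
        pred, ref = zip(*pairs)
        m = performance_metrics(pred, ref)
        assert m.accuracy == pytest.approx(
            (m.tp + m.tn) / (m.tp + m.tn + m.fp + m.fn)
        )


class TestGroupTable:
    def test_packaged_counts_reproduce_published_predictive_values(self):
        t3 = table3_counts()
        assert t3.n_total == 909
        assert t3.ppv[1] == pytest.approx(211 / 217)
        assert t3.ppv[2] == pytest.approx(4 / 14)
        assert t3.ppv[3] == pytest.approx(15 / 26)
        assert t3.npv[2] == pytest.approx(10 / 14)
        assert t3.npv[3] == pytest.approx(11 / 26)
        assert t3.npv[5] == pytest.approx(618 / 652)
        assert t3.group_shares[1] == pytest.approx(217 / 909)

    def test_expanded_samples_roundtrip_through_group_table(self):
        s = table3_samples()
        assert len(s) == 909
        gt = group_table(s["group"], s["ihc"], s["ish"])
        assert gt.counts.equals(table3_counts().counts)

    def test_single_sample_table(self):
        gt = group_table([1], ["3+"], ["amplified"])
        assert gt.counts.loc[1, "ihc_3"] == 1
        assert gt.counts["n"].sum() == 1
        assert gt.ppv[1] == 1.0

    def test_unknown_levels_rejected(self):
        with pytest.raises(ValueError):
            group_table([1], ["4+"], ["amplified"])


def test_threshold_set_validation():
    with pytest.raises(ValueError):
        ThresholdSet(cn_threshold=-1)
    with pytest.raises(ValueError):
        ThresholdSet(ultrahigh_cutoff=2.0)
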