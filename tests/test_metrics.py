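"""Confusion-matrix measures, ROC/PR areas vs brute-force oracles, and the
class-discrimination tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rnam5c as r
from rnam5c.errors import ValidationError
from rnam5c.metrics import round3


def roc_oracle(scores, labels):
    """O(n^2) Mann-Whitney oracle: P(s+ > s-) + 0.5 P(s+ = s-)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def pr_oracle(scores, labels):
    """Exhaustive threshold enumeration of the step-wise PR area:
    sum over descending unique score thresholds of (R_t - R_prev) * P_t."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


# (sn, sp) pairs on the balanced 100/100 hold-out with the metrics they
# must reproduce at 3 decimals (half-up): the four confidence modes of the
# ensemble predictor plus the two external-predictor comparison rows.
HOLD_OUT_ROWS = [
    pytest.param(0.330, 1.000, 1.000, 0.665, 0.445, 0.496, id="VHmode"),
    pytest.param(0.720, 0.950, 0.935, 0.835, 0.688, 0.814, id="HMode"),
    pytest.param(0.860, 0.900, 0.896, 0.880, 0.761, 0.878, id="NMode"),
    pytest.param(0.900, 0.860, 0.865, 0.880, 0.761, 0.882, id="LMode"),
    pytest.param(0.010, 0.980, 0.333, 0.495, -0.041, 0.019, id="webserver"),
    pytest.param(0.610, 0.720, 0.685, 0.665, 0.332, 0.646, id="retrained"),
]


class TestComputeMetrics:
    @pytest.mark.parametrize("sn, sp, pr, acc, mcc, f1", HOLD_OUT_ROWS)
    def test_holdout_rows_internally_consistent(self, sn, sp, pr, acc, mcc, f1):
        c = r.confusion_from_rates(sn, sp, n_pos=100, n_neg=100)
        m = r.compute_metrics(c)
        assert round3(m.sn) == sn
        assert round3(m.sp) == sp
        assert round3(m.pr) == pr
        assert round3(m.acc) == acc
        assert round3(m.mcc) == mcc
        assert round3(m.f1) == f1

    def test_perfect_prediction(self):
        m = r.compute_metrics(r.ConfusionCounts(tp=100, tn=100, fp=0, fn=0))
        assert (m.sn, m.sp, m.pr, m.acc, m.f1, m.mcc) == (1, 1, 1, 1, 1, 1)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = r.compute_metrics(r.ConfusionCounts(tp=0, tn=10, fp=0, fn=5))
        assert m.pr is None and m.mcc is None
        assert m.sp == 1.0

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValidationError):
            r.ConfusionCounts(0, 0, 0, 0)

    @given(
        tp=st.integers(1, 50), tn=st.integers(1, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_mcc_symmetry_and_balanced_identities(self, tp, tn, fp, fn):
        m = r.compute_metrics(r.ConfusionCounts(tp, tn, fp, fn))
        swapped = r.compute_metrics(r.ConfusionCounts(tn, tp, fn, fp))
        if m.mcc is not None and swapped.mcc is not None:
            assert m.mcc == pytest.approx(swapped.mcc)
        if m.pr is not None and (m.pr + m.sn) > 0:
            assert m.f1 == pytest.approx(2 * m.pr * m.sn / (m.pr + m.sn))
        if tp + fn == tn + fp:  # balanced design
            assert m.acc == pytest.approx((m.sn + m.sp) / 2)


class TestRocAuc:
    def test_perfect_separation(self):
        assert r.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert r.roc_auc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_one_class_raises(self):
        with pytest.raises(ValidationError):
            r.roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            labels = np.zeros(n, dtype=int)
            labels[: max(1, n // 3)] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            # quantized scores force ties
            scores = rng.integers(0, 6, size=n) / 5.0
            assert r.roc_auc(scores, labels) == pytest.approx(
                roc_oracle(scores, labels), abs=1e-12
            )


class TestPrAuc:
    def test_perfect_separation(self):
        assert r.pr_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_random_balanced_near_half(self):
        rng = np.random.default_rng(0)
        labels = np.array([0, 1] * 2000)
        scores = rng.random(4000)
        assert r.pr_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_matches_threshold_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(5, 30))
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)
            assert r.pr_auc(scores, labels) == pytest.approx(
                pr_oracle(scores, labels), abs=1e-12
            )

    def test_no_positives_raises(self):
        with pytest.raises(ValidationError):
            r.pr_auc([0.1, 0.9], [0, 0])


def permutation_pvalue(x, y, n_perm=10_000, seed=0):
    """Two-sided permutation test on the difference of means of 0/1
    indicators — the independent oracle for the rank-sum indicator test."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    observed = abs(x.mean() - y.mean())
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[: len(x)].mean() - pooled[len(x):].mean()) >= observed - 1e-12:
            hits += 1
    return hits / n_perm


class TestPositionalBaseTest:
    def test_identical_compositions_not_significant(self):
        wins = ["ACGUC"] * 50
        res = r.positional_base_test(wins, wins, alpha=1e-10)
        assert not any(row.significant for row in res)
        assert all(row.p_value == 1.0 for row in res)

    def test_maximal_separation_significant(self):
        pos = ["AGGUA"] * 200  # G at offset -1
        neg = ["AAUUA"] * 200
        res = r.positional_base_test(pos, neg, alpha=1e-10)
        flagged = {(row.position, row.base) for row in res if row.significant}
        assert (-1, "G") in flagged

    def test_against_permutation_oracle(self):
        """A moderate planted base-usage shift: the analytic rank-sum
        p-value tracks the exact permutation law."""
        rng = np.random.default_rng(9)
        n = 200

        def make(p_g):
            out = []
            for _ in range(n):
                w = list(rng.choice(list("ACU"), 3))
                if rng.random() < p_g:
                    w[0] = "G"
                out.append("".join(w))
            return out

        pos = make(0.40)  # G enriched at offset -1
        neg = make(0.25)
        res = {(row.position, row.base): row for row in
               r.positional_base_test(pos, neg, alpha=0.05)}
        row = res[(-1, "G")]
        x = np.array([1.0 if w[0] == "G" else 0.0 for w in pos])
        y = np.array([1.0 if w[0] == "G" else 0.0 for w in neg])
        p_perm = permutation_pvalue(x, y, n_perm=10_000, seed=1)
        assert row.p_value == pytest.approx(p_perm, abs=0.02)
        assert (row.p_value <= 0.01) == (p_perm <= 0.01)

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValidationError):
            r.positional_base_test(["ACG"], ["ACGU"])


class TestFeatureTtest:
    def test_hand_computed_welch_t(self):
        # pos = {1, 2}, neg = {4, 6}: t = (1.5-5)/sqrt(0.25+1) = -3.1305
        pos = np.array([[1.0], [2.0]])
        neg = np.array([[4.0], [6.0]])
        res = r.feature_ttest(pos, neg, ["f"], alpha=0.05)
        assert res[0].t == pytest.approx(-3.130495, abs=1e-5)

    def test_shifted_feature_significant(self):
        rng = np.random.default_rng(1)
        pos = rng.normal(5.0, 1.0, size=(100, 1))
        neg = rng.normal(0.0, 1.0, size=(100, 1))
        res = r.feature_ttest(pos, neg, ["f"], alpha=1e-4)
        assert res[0].significant

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(size=(200, 50))
        neg = rng.normal(size=(200, 50))
        res = r.feature_ttest(pos, neg, [f"f{i}" for i in range(50)], alpha=0.05)
        assert sum(row.significant for row in res) <= 10  # ~2.5 expected
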