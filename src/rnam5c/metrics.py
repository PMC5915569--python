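"""Performance measures and class-discrimination statistics.

Implements the six confusion-matrix measures (Sn, Sp, Pr, Acc, F1, MCC),
ROC/AUC and precision-recall/auPRC, plus the per-position base-usage
rank-sum test and the per-feature Welch t-test used to characterize what
separates methylated from unmethylated windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve
from sklearn.metrics import precision_recall_curve

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValidationError("confusion counts are all zero")


@dataclass(frozen=True)
class MetricsReport:
    """The six derived measures; a metric whose denominator is zero is
    reported as None (undefined), never as 0."""

    sn: float | None
    sp: float | None
    pr: float | None
    acc: float | None
    f1: float | None
    mcc: float | None
    auc: float | None = None
    auprc: float | None = None
    threshold_used: float | None = None


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Sn = TP/(TP+FN); Sp = TN/(TN+FP); Pr = TP/(TP+FP);
    Acc = (TP+TN)/total; F1 = 2·TP/(2·TP+FP+FN);
    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn

    def ratio(num: float, den: float) -> float | None:
        return num / den if den else None

    sn = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    pr = ratio(tp, tp + fp)
    acc = ratio(tp + tn, tp + tn + fp + fn)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den else None
    return MetricsReport(sn=sn, sp=sp, pr=pr, acc=acc, f1=f1, mcc=mcc)


def confusion_from_rates(sn: float, sp: float, n_pos: int, n_neg: int) -> ConfusionCounts:
    """Reconstruct integer counts from printed sensitivity/specificity on a
    known class design (e.g. a balanced 100/100 hold-out)."""
    tp = round(sn * n_pos)
    tn = round(sp * n_neg)
    return ConfusionCounts(tp=tp, tn=tn, fp=n_neg - tn, fn=n_pos - tp)


def round3(x: float) -> float:
    """Round half-up to 3 decimals, the convention used in report tables."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (trapezoidal; tie-aware, equal to the
    Mann-Whitney statistic P(s+ > s−) + ½·P(tie))."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve with right-continuous step
    interpolation (no linear interpolation of precision)."""
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise ValidationError("no positive labels for the precision-recall curve")
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def roc_coordinates(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FPR, TPR and the thresholds, for plotting by the caller."""
    fpr, tpr, thr = roc_curve(np.asarray(labels), np.asarray(scores, dtype=float))
    return fpr, tpr, thr


def pr_coordinates(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision, recall and the thresholds, for plotting by the caller."""
    pre, rec, thr = precision_recall_curve(np.asarray(labels), np.asarray(scores, dtype=float))
    return pre, rec, thr


class PositionalBaseResult(NamedTuple):
    position: int  # offset relative to the central cytosine
    base: str
    p_value: float
    significant: bool


def positional_base_test(
    pos_samples: Sequence[str],
    neg_samples: Sequence[str],
    alpha: float = 1e-10,
) -> list[PositionalBaseResult]:
    """Per (position, base) two-sided rank-sum test comparing the 0/1
    indicator of that base between classes.

    On indicators the Wilcoxon rank-sum statistic reduces to a two-
    proportion comparison; positions are reported as offsets from the
    window center.  Flags p <= alpha.
    """
    if not pos_samples or not neg_samples:
        raise ValidationError("both classes must be non-empty")
    lengths = {len(w) for w in pos_samples} | {len(w) for w in neg_samples}
    if len(lengths) != 1:
        raise ValidationError("all windows must have the same length")
    L = lengths.pop()
    center = L // 2
    pos_arr = np.array([list(w) for w in pos_samples])
    neg_arr = np.array([list(w) for w in neg_samples])
    out = []
    for i in range(L):
        for base in "ACGU":
            x = (pos_arr[:, i] == base).astype(float)
            y = (neg_arr[:, i] == base).astype(float)
            if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
                p = 1.0
            else:
                # tie-corrected asymptotic rank-sum (Mann-Whitney form),
                # no continuity correction: indicators are maximally tied
                # and this tracks the exact permutation law at the sample
                # sizes the test is meant for
                p = float(
                    stats.mannwhitneyu(
                        x, y, alternative="two-sided", method="asymptotic",
                        use_continuity=False,
                    ).pvalue
                )
            out.append(PositionalBaseResult(i - center, base, p, p <= alpha))
    return out


class FeatureTestResult(NamedTuple):
    feature: str
    t: float
    p_value: float
    significant: bool


def feature_ttest(
    pos_features: np.ndarray,
    neg_features: np.ndarray,
    feature_names: Sequence[str],
    alpha: float = 1e-4,
) -> list[FeatureTestResult]:
    """Per-feature Welch (unequal-variance) two-sample t-test; flags
    p <= alpha."""
    pos_features = np.asarray(pos_features, dtype=float)
    neg_features = np.asarray(neg_features, dtype=float)
    if pos_features.shape[0] < 2 or neg_features.shape[0] < 2:
        raise ValidationError("need at least 2 samples per class")
    if pos_features.shape[1] != neg_features.shape[1] or pos_features.shape[1] != len(feature_names):
        raise ValidationError("feature dimensions do not match the names")
    res = stats.ttest_ind(pos_features, neg_features, axis=0, equal_var=False)
    out = []
    for name, t, p in zip(feature_names, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)):
        p = 1.0 if np.isnan(p) else float(p)
        t = 0.0 if np.isnan(t) else float(t)
        out.append(FeatureTestResult(name, t, p, p <= alpha))
    return out
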