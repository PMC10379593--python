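"""Binary-classification metrics, ROC/AUC and DeLong's paired AUC test.

Malignant is the positive class throughout. Accuracy is
(TP+TN)/(TP+TN+FP+FN); precision, sensitivity (=recall), specificity and
F1 follow the standard definitions, with undefined ratios (zero
denominator) reported as NaN rather than 0.

AUC is computed by the Mann–Whitney identity — the probability that a
random positive outranks a random negative, ties counted 1/2. DeLong's
test compares two correlated AUCs measured on the same samples using the
fast midrank algorithm (Sun & Xu, 2014) for the U-statistic covariance;
per-curve 95% confidence intervals come from the DeLong variance by
default, with a Clopper–Pearson-style "binomial exact" option that treats
the concordant-pair proportion as a binomial success rate with the
effective sample size min(n_pos, n_neg).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan, sqrt

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RocComparison",
    "confusion",
    "classification_metrics",
    "f1_from_precision_recall",
    "roc_auc",
    "auc_variance",
    "auc_ci",
    "delong_compare",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None


def confusion(pred_labels, true_labels) -> ConfusionCounts:
    """Confusion counts with malignant (1/True/"malignant") as positive."""
    pred = _as_binary(pred_labels)
    true = _as_binary(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        tn=int(np.sum(~pred & ~true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return np.asarray([str(x) == "malignant" for x in arr])
    return arr.astype(bool)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, sensitivity, specificity and F1 from counts."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn)
    f1 = (
        float("nan")
        if isnan(precision) or isnan(sensitivity)
        else f1_from_precision_recall(precision, sensitivity)
    )
    return MetricsReport(
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=precision,
        sensitivity=sensitivity,
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        f1=f1,
    )


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    pos, neg = s[y], s[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(random positive > random negative), ties 1/2."""
    pos, neg = _split_scores(scores, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the positive- and negative-side structural components."""
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    tz = _midrank(combined)
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # per-positive placement values
    v10 = 1.0 - (tz[m:] - ty) / m  # per-negative placement values
    return float(auc), v01, v10


def auc_variance(scores, labels) -> float:
    """DeLong variance of a single AUC estimate."""
    pos, neg = _split_scores(scores, labels)
    _, v01, v10 = _delong_components(pos, neg)
    return float(np.var(v01, ddof=1) / len(pos) + np.var(v10, ddof=1) / len(neg))


def auc_ci(scores, labels, level: float = 0.95, method: str = "delong") -> tuple[float, float]:
    """Confidence interval for one AUC.

    ``delong``: normal interval from the DeLong variance (default).
    ``binomial``: Clopper–Pearson interval on the concordant-pair
    proportion with effective n = min(n_pos, n_neg); a labelled heuristic
    for the "binomial exact" convention, not a U-statistic interval.
    """
    auc = roc_auc(scores, labels)
    if method == "delong":
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * sqrt(auc_variance(scores, labels))
        return (max(0.0, auc - half), min(1.0, auc + half))
    if method == "binomial":
        pos, neg = _split_scores(scores, labels)
        n_eff = min(len(pos), len(neg))
        k = int(round(auc * n_eff))
        lo, hi = stats.beta.ppf(
            [(1 - level) / 2.0, 0.5 + level / 2.0], [k, k + 1], [n_eff - k + 1, n_eff - k]
        )
        return (0.0 if k == 0 else float(lo), 1.0 if k == n_eff else float(hi))
    raise ValueError(f"unknown CI method {method!r}")


@dataclass
class RocComparison:
    """Paired comparison of two ROC curves on the same samples."""

    auc_a: float
    auc_b: float
    z: float
    p_value: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    var_a: float
    var_b: float
    covariance: float


def delong_compare(scores_a, scores_b, labels, level: float = 0.95) -> RocComparison:
    """DeLong's test for two paired AUCs.

    Both score vectors must be measured on the identical samples/labels.
    Returns the two AUCs, the z statistic with two-sided normal p-value,
    and per-curve confidence intervals from the DeLong variances.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("paired score vectors differ in length")
    y = _as_binary(labels)
    if sa.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    pos_mask = y
    auc_a, va01, va10 = _delong_components(sa[pos_mask], sa[~pos_mask])
    auc_b, vb01, vb10 = _delong_components(sb[pos_mask], sb[~pos_mask])
    m, n = int(pos_mask.sum()), int((~pos_mask).sum())
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    cov_matrix = s01 / m + s10 / n
    var_a, var_b = float(cov_matrix[0, 0]), float(cov_matrix[1, 1])
    cov_ab = float(cov_matrix[0, 1])
    var_diff = var_a + var_b - 2.0 * cov_ab
    if var_diff <= 0.0:
        z, p = 0.0, 1.0
    else:
        z = (auc_a - auc_b) / sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    zq = stats.norm.ppf(0.5 + level / 2.0)

    def _ci(auc: float, var: float) -> tuple[float, float]:
        half = zq * sqrt(max(var, 0.0))
        return (max(0.0, auc - half), min(1.0, auc + half))

    return RocComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        z=float(z),
        p_value=min(1.0, p),
        ci_a=_ci(auc_a, var_a),
        ci_b=_ci(auc_b, var_b),
        var_a=var_a,
        var_b=var_b,
        covariance=cov_ab,
    )
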