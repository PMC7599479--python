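"""Study-design machinery and diagnostic performance statistics.

Stratified hold-out splitting (one-third validation by default), confusion
counts with sensitivity/specificity (cancer = positive class, percentages
rounded half-up to one decimal), ROC curves with tie-aware AUC, a
rank-based univariate panel with Benjamini-Hochberg FDR, pooled serum
tumor-marker arithmetic, and the fold-change/FDR volcano filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _round1(x: float) -> float:
    """Round half-up to 1 decimal, the convention of clinical tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table with cancer as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    best_threshold: float        # maximizes Youden's J
    best_sensitivity: float      # percent, at the Youden point
    best_specificity: float      # percent


@dataclass
class SplitPlan:
    validation_fraction: float = 1.0 / 3.0
    seed: int = 0
    stratify_stage: bool = False


def split_train_validation(
    labels,
    plan: SplitPlan | None = None,
    stages=None,
) -> tuple[list[int], list[int]]:
    """Seeded stratified hold-out split.

    Within each stratum (class, optionally class x stage),
    ``round(n * validation_fraction)`` samples are drawn for validation;
    e.g. 103 cancers / 100 controls at one-third yield 34 / 33 validation
    samples. Returns (train_indices, validation_indices), both sorted.
    """
    if plan is None:
        plan = SplitPlan()
    labels = list(labels)
    strata: dict = {}
    for i, lab in enumerate(labels):
        key = (lab, stages[i]) if (plan.stratify_stage and stages is not None) else lab
        strata.setdefault(key, []).append(i)
    rng = np.random.default_rng(plan.seed)
    val: list[int] = []
    for key in sorted(strata, key=str):
        idx = np.array(strata[key])
        if idx.size < 3:
            raise ValueError(f"stratum {key!r} has fewer than 3 samples")
        n_val = int(Decimal(idx.size * plan.validation_fraction).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP))
        val.extend(rng.choice(idx, size=n_val, replace=False).tolist())
    val_set = set(val)
    train = [i for i in range(len(labels)) if i not in val_set]
    return train, sorted(val)


def confusion_from_labels(true_labels, pred_labels, positive: str = "case") -> ConfusionCounts:
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, pred_labels):
        if t == positive:
            tp += p == positive
            fn += p != positive
        else:
            tn += p != positive
            fp += p == positive
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity %, specificity %), rounded half-up to 1 decimal.

    sensitivity = 100 tp/(tp+fn); specificity = 100 tn/(tn+fp).
    """
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("both classes must be present")
    return (
        _round1(100.0 * c.tp / (c.tp + c.fn)),
        _round1(100.0 * c.tn / (c.tn + c.fp)),
    )


def roc(scores, labels, positive: str = "case") -> RocCurve:
    """ROC curve with tie-aware AUC.

    Thresholds sweep the unique scores (equal scores collapse to one step);
    AUC is the trapezoidal area, which equals the Mann-Whitney U statistic
    over n1*n0 with the usual half-credit for ties. The Youden point
    maximizes sensitivity + specificity - 1; sensitivity/specificity at that
    point are returned in percent.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.array([lab == positive for lab in labels], dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate([[np.inf], uniq])
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, th in enumerate(thresholds):
        pred_pos = scores >= th
        tpr[i] = (pred_pos & y).sum() / n1
        fpr[i] = (pred_pos & ~y).sum() / n0
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    k = int(np.argmax(j))
    return RocCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        best_threshold=float(thresholds[k]),
        best_sensitivity=_round1(100.0 * tpr[k]),
        best_specificity=_round1(100.0 * (1.0 - fpr[k])),
    )


def univariate_panel(levels: np.ndarray, labels, positive: str = "case",
                     method: str = "mannwhitney") -> tuple[np.ndarray, np.ndarray]:
    """Per-metabolite two-sided tests with Benjamini-Hochberg adjustment.

    ``levels`` is samples x metabolites. Returns (p_values, q_values).
    """
    levels = np.atleast_2d(np.asarray(levels, dtype=float))
    y = np.array([lab == positive for lab in labels], dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    pvals = np.empty(levels.shape[1])
    for j in range(levels.shape[1]):
        a, b = levels[y, j], levels[~y, j]
        if method == "mannwhitney":
            pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        elif method == "ttest":
            pvals[j] = stats.ttest_ind(a, b).pvalue
        else:
            raise ValueError(f"unknown method {method!r}")
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pvals, qvals


def marker_sensitivity_from_counts(positives_by_cohort) -> float:
    """Pooled positivity rate in percent, rounded half-up to 1 decimal.

    ``positives_by_cohort`` is a list of (positive_count, n) pairs, e.g. the
    training and validation rows of a serum tumor-marker table.
    """
    pairs = list(positives_by_cohort)
    if not pairs:
        raise ValueError("empty input")
    pos = sum(c for c, _ in pairs)
    n = sum(m for _, m in pairs)
    if any(c > m for c, m in pairs) or n == 0:
        raise ValueError("counts exceed totals")
    return _round1(100.0 * pos / n)


def marker_specificity_from_counts(positives_by_cohort) -> float:
    """Pooled specificity in percent: negatives over total among controls."""
    pairs = list(positives_by_cohort)
    if not pairs:
        raise ValueError("empty input")
    pos = sum(c for c, _ in pairs)
    n = sum(m for _, m in pairs)
    return _round1(100.0 * (n - pos) / n)


@dataclass(frozen=True)
class GeneRecord:
    gene: str
    fold_change: float
    p_value: float
    fdr: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")


def volcano_filter(genes, fc_cut: float = 1.5, fdr_cut: float = 0.005) -> list[GeneRecord]:
    """Select genes by fold change and FDR, as in a volcano plot.

    Keeps records with (fold_change >= fc_cut or <= 1/fc_cut) and
    fdr <= fdr_cut; both boundaries are inclusive. Sorted by FDR ascending.
    """
    kept = [
        g for g in genes
        if (g.fold_change >= fc_cut or g.fold_change <= 1.0 / fc_cut) and g.fdr <= fdr_cut
    ]
    kept.sort(key=lambda g: g.fdr)
    return kept
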