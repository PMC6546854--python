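"""LOOCV evaluation (confusion matrix, CA/Sen/Spe/ER) and permutation testing.

The confusion matrix accumulates the same leave-one-out loop the selection
criterion runs, so its error rate (FP+FN)/total equals the criterion output
bit-exactly.  Significance of an observed error rate is assessed against an
empirical null built by re-running the cross-validated classifier under
random label permutations; with a paired design the natural permutation unit
is the subject, whose two condition labels are swapped or not with equal
probability (free permutation over all samples is available as an alternate
scheme).  The p-value uses the add-one formula p = (1 + #{null <= observed})
/ (1 + n_perm), which never returns 0 and gives p = 1/10000 = 0.0001 when the
observed error beats all of 9,999 permutations.

Two modes: ``post_selection`` permutes labels with the evaluated region
subset held fixed, which is cheap but anti-conservative when that subset was
selected on the same data; ``full_pipeline`` re-runs the selection inside
every permutation, which keeps the p-value calibrated at a much higher cost.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

from .datatypes import (
    ConfusionMatrix,
    FeatureTable,
    MetricsReport,
    PermutationNull,
    SelectionTrace,
    SvmConfig,
)
from .selection import _folds_groups, criterion_loocv_error
from .svm import loocv_predictions

__all__ = ["loocv_confusion", "metrics", "permutation_test"]

FULL_PIPELINE_MAX_PERM = 2_000


def loocv_confusion(table: FeatureTable, subset: Iterable[int],
                    svm_config: SvmConfig | None = None,
                    folds: str = "sample") -> ConfusionMatrix:
    """Confusion matrix of the LOOCV loop on a region subset.

    Hunger is the positive class: TP counts hunger scans classified as
    hunger, TN satiety scans classified as satiety.
    """
    subset = sorted(int(s) for s in subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    config = svm_config or SvmConfig()
    cols = table.column_index(subset)
    y = table.numeric_labels(positive=config.positive_class)
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("need at least two samples per class")
    preds = loocv_predictions(table.X[:, cols], y, config,
                              groups=_folds_groups(table, folds))
    tp = int(np.sum((preds == 1) & (y == 1)))
    fp = int(np.sum((preds == 1) & (y == -1)))
    fn = int(np.sum((preds == -1) & (y == 1)))
    tn = int(np.sum((preds == -1) & (y == -1)))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """CA, sensitivity, specificity and error rate from a confusion matrix.

    CA = (TP+TN)/total, Sen = TP/(TP+FN), Spe = TN/(TN+FP),
    ER = (FP+FN)/total = 1 - CA.  A metric whose denominator is zero is
    reported as ``None`` (undefined), never coerced to 0.
    """
    if cm.total <= 0:
        raise ValueError("confusion matrix is empty")
    ca = (cm.tp + cm.tn) / cm.total
    er = (cm.fp + cm.fn) / cm.total
    sen = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    spe = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    return MetricsReport(ca=ca, sen=sen, spe=spe, er=er)


def _permute_labels(table: FeatureTable, rng: np.random.Generator,
                    scheme: str) -> np.ndarray:
    y = table.y
    if scheme == "within_subject":
        # swap each subject's paired labels with probability 1/2
        out = y.copy()
        for sid in np.unique(table.subject_id):
            if rng.random() < 0.5:
                idx = np.flatnonzero(table.subject_id == sid)
                out[idx] = out[idx][::-1]
        return out
    if scheme == "free":
        return y[rng.permutation(len(y))]
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def permutation_test(table: FeatureTable,
                     subset_or_selector: Iterable[int] | Callable[[FeatureTable], SelectionTrace],
                     n_perm: int = 10_000, mode: str = "post_selection",
                     seed: int = 0, svm_config: SvmConfig | None = None,
                     scheme: str = "within_subject",
                     folds: str = "sample") -> PermutationNull:
    """Label-permutation null distribution of the LOOCV error rate.

    ``subset_or_selector`` is a fixed region subset (``post_selection``) or a
    callable running the selection strategy on a (permuted) table and
    returning its trace (``full_pipeline``).  The observed error is computed
    the same way on the unpermuted labels.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("post_selection", "full_pipeline"):
        raise ValueError(f"unknown mode {mode!r}")
    config = svm_config or SvmConfig()

    if mode == "full_pipeline":
        if not callable(subset_or_selector):
            raise ValueError("full_pipeline mode needs a selector callable")
        if n_perm > FULL_PIPELINE_MAX_PERM:
            raise ValueError(
                f"full_pipeline permutation re-runs selection {n_perm} times; "
                f"limit is {FULL_PIPELINE_MAX_PERM} — reduce n_perm or use "
                "post_selection mode")

        def error_of(tbl: FeatureTable) -> float:
            trace = subset_or_selector(tbl)
            return float(trace.final_criterion)
    else:
        if callable(subset_or_selector):
            raise ValueError("post_selection mode needs a fixed region subset")
        subset = tuple(sorted(int(s) for s in subset_or_selector))

        def error_of(tbl: FeatureTable) -> float:
            return criterion_loocv_error(tbl, subset, config, folds)

    observed = error_of(table)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = error_of(table.with_labels(_permute_labels(table, rng, scheme)))
    count = int(np.sum(null <= observed + 1e-12))
    p = (1.0 + count) / (1.0 + n_perm)
    return PermutationNull(null_errors=null, observed_error=observed,
                           n_perm=n_perm, p_value=p, mode=mode, scheme=scheme,
                           seed=int(seed))
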