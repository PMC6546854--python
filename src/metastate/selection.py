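"""Wrapper region selection: SFS and SFFS around a LOOCV-SVM criterion.

The criterion is the leave-one-out misclassification rate of a linear
soft-margin SVM restricted to the candidate region subset — a wrapper
objective, so the search cost is dominated by classifier refits.  Sequential
forward selection (SFS) greedily adds the region that most reduces the
criterion and stops when no addition strictly helps.  Sequential forward
floating selection (SFFS, the Pudil scheme) adds the same way but, after each
addition, repeatedly tests conditional exclusion: a member is dropped whenever
the reduced subset beats the best subset previously seen at that size, which
lets the search escape the nesting effect of plain SFS.

Tie-breaking is everywhere deterministic: smallest region label first, then
lexicographically smallest subset.  Error rates are multiples of 1/n_samples,
so "strictly better" is tested with a 1e-12 guard tolerance.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .datatypes import FeatureTable, SelectionStep, SelectionTrace, SvmConfig
from .svm import loocv_predictions

__all__ = ["criterion_loocv_error", "sfs", "sffs"]

_TOL = 1e-12
DEFAULT_MAX_K = 10
SFFS_EVAL_BUDGET = 10_000


def _folds_groups(table: FeatureTable, folds: str) -> np.ndarray | None:
    if folds == "sample":
        return None
    if folds == "subject":
        return table.subject_id
    raise ValueError(f"unknown folds mode {folds!r} (use 'sample' or 'subject')")


def criterion_loocv_error(table: FeatureTable, subset: Iterable[int],
                          svm_config: SvmConfig | None = None,
                          folds: str = "sample") -> float:
    """LOOCV misclassification rate of the linear SVM on a region subset.

    Each sample (or each subject, with ``folds='subject'``) is held out once;
    the SVM is trained on the rest, restricted to the subset's columns, and
    the fraction of misclassified held-out samples is returned.
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
    return float(np.mean(preds != y))


class _Evaluator:
    """Criterion evaluation with memoization and a call budget."""

    def __init__(self, table: FeatureTable, svm_config: SvmConfig | None,
                 folds: str, budget: int) -> None:
        self.table = table
        self.config = svm_config
        self.folds = folds
        self.budget = budget
        self.n_evaluations = 0
        self.exhausted = False
        self._cache: dict[tuple[int, ...], float] = {}

    def __call__(self, subset: tuple[int, ...]) -> float:
        key = tuple(sorted(subset))
        if key in self._cache:
            return self._cache[key]
        if self.n_evaluations >= self.budget:
            self.exhausted = True
            raise _BudgetExhausted
        self.n_evaluations += 1
        val = criterion_loocv_error(self.table, key, self.config, self.folds)
        self._cache[key] = val
        return val


class _BudgetExhausted(Exception):
    pass


def _best_candidate(evaluate: _Evaluator, current: tuple[int, ...],
                    candidates: Sequence[int], action: str) -> tuple[int, tuple[int, ...], float]:
    """Best single add/remove; ties resolved by smallest label."""
    best_label, best_subset, best_val = None, None, np.inf
    for label in sorted(candidates):
        if action == "add":
            subset = tuple(sorted(current + (label,)))
        else:
            subset = tuple(l for l in current if l != label)
        val = evaluate(subset)
        if val < best_val - _TOL:
            best_label, best_subset, best_val = label, subset, val
    return best_label, best_subset, best_val


def _finalize(trace: SelectionTrace) -> SelectionTrace:
    # smallest criterion wins; ties -> smallest size, then lexicographic subset
    best = min(trace.best_per_size.items(),
               key=lambda kv: (kv[1][1], kv[0], kv[1][0]))
    trace.final_subset = best[1][0]
    trace.final_criterion = best[1][1]
    return trace


def _record_best(trace: SelectionTrace, subset: tuple[int, ...], val: float) -> bool:
    """Update the best-per-size record; True only on strict improvement."""
    k = len(subset)
    prev = trace.best_per_size.get(k)
    if prev is None or val < prev[1] - _TOL:
        trace.best_per_size[k] = (subset, val)
        return True
    if abs(val - prev[1]) <= _TOL and subset < prev[0]:
        trace.best_per_size[k] = (subset, prev[1])  # deterministic tie-break
    return False


def sfs(table: FeatureTable, max_k: int = DEFAULT_MAX_K,
        svm_config: SvmConfig | None = None, folds: str = "sample") -> SelectionTrace:
    """Sequential forward selection.

    Greedy: start from the best singleton, then repeatedly add the region
    whose inclusion minimizes the criterion, stopping when no addition
    strictly decreases it or the subset reaches ``max_k``.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    max_k = min(max_k, table.n_regions)
    evaluate = _Evaluator(table, svm_config, folds, budget=10 ** 9)
    trace = SelectionTrace(strategy="sfs")
    current: tuple[int, ...] = ()
    current_val = np.inf
    all_labels = set(table.region_labels)
    while len(current) < max_k:
        remaining = sorted(all_labels - set(current))
        label, subset, val = _best_candidate(evaluate, current, remaining, "add")
        if current and val >= current_val - _TOL:
            break  # no strict improvement
        current, current_val = subset, val
        trace.steps.append(SelectionStep("add", label, current, val))
        _record_best(trace, current, val)
    trace.n_evaluations = evaluate.n_evaluations
    return _finalize(trace)


def sffs(table: FeatureTable, max_k: int = DEFAULT_MAX_K,
         svm_config: SvmConfig | None = None, folds: str = "sample",
         eval_budget: int = SFFS_EVAL_BUDGET) -> SelectionTrace:
    """Sequential forward floating selection (Pudil scheme).

    After every forward addition, conditional exclusion repeatedly removes
    the member (other than the one just added) whose removal yields a
    criterion strictly better than the best subset recorded at the reduced
    size.  The search stops when a forward step at ``max_k`` no longer
    improves the best-per-size record, or when the evaluation budget is
    exhausted (flagged in the trace).
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    max_k = min(max_k, table.n_regions)
    evaluate = _Evaluator(table, svm_config, folds, budget=eval_budget)
    trace = SelectionTrace(strategy="sffs")
    all_labels = set(table.region_labels)
    current: tuple[int, ...] = ()
    try:
        while True:
            # forward step
            remaining = sorted(all_labels - set(current))
            if not remaining:
                break
            label, subset, val = _best_candidate(evaluate, current, remaining, "add")
            current = subset
            trace.steps.append(SelectionStep("add", label, current, val))
            improved = _record_best(trace, current, val)
            just_added = label
            # conditional exclusion
            while len(current) > 2:
                cand = [l for l in current if l != just_added]
                rlabel, rsubset, rval = _best_candidate(evaluate, current, cand, "remove")
                prev = trace.best_per_size.get(len(current) - 1)
                if prev is not None and rval >= prev[1] - _TOL:
                    break
                current = rsubset
                trace.steps.append(SelectionStep("remove", rlabel, current, rval))
                _record_best(trace, current, rval)
                improved = True
                just_added = -1  # further exclusions unrestricted
            if len(current) >= max_k:
                # no forward move is allowed beyond max_k and conditional
                # exclusion has already settled, so the frontier is stable
                break
    except _BudgetExhausted:
        trace.budget_exhausted = True
    trace.n_evaluations = evaluate.n_evaluations
    return _finalize(trace)
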