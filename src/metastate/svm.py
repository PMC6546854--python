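"""Cross-validated linear SVM predictions.

The wrapper-selection criterion and the permutation test both reduce to the
same primitive: leave-one-fold-out predictions of a linear soft-margin SVM on
a small samples x features matrix.  Because sequential selection and the
permutation null evaluate that primitive tens of thousands of times, the
default engine is a numba-compiled dual coordinate-descent solver for the
hinge-loss linear SVM (the liblinear algorithm, with the intercept handled as
a regularized bias feature).  scikit-learn's ``LinearSVC(loss="hinge")``
solves the identical optimization problem and is available as the ``sklearn``
engine; the test suite asserts the two produce identical held-out
predictions.

Ties on the decision boundary (decision value exactly 0) are resolved to the
positive class, deterministically.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .datatypes import SvmConfig

__all__ = ["cv_predictions", "loocv_predictions"]


@njit(cache=True)
def _dual_cd(X, y, C, tol, max_passes):  # pragma: no cover - compiled
    """Hinge-loss SVM dual coordinate descent; returns primal weights.

    X already carries the bias column.  Deterministic cyclic sweeps; stops
    when the largest projected gradient of a full sweep drops below tol.
    """
    n, d = X.shape
    w = np.zeros(d)
    alpha = np.zeros(n)
    qii = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += X[i, j] * X[i, j]
        qii[i] = s
    for _ in range(max_passes):
        max_pg = 0.0
        for i in range(n):
            g = 0.0
            for j in range(d):
                g += w[j] * X[i, j]
            grad = y[i] * g - 1.0
            if alpha[i] <= 0.0:
                pg = min(grad, 0.0)
            elif alpha[i] >= C:
                pg = max(grad, 0.0)
            else:
                pg = grad
            if abs(pg) > max_pg:
                max_pg = abs(pg)
            if abs(pg) > 1e-14:
                a_new = alpha[i] - grad / qii[i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                da = a_new - alpha[i]
                if da != 0.0:
                    for j in range(d):
                        w[j] += da * y[i] * X[i, j]
                    alpha[i] = a_new
        if max_pg < tol:
            break
    return w


@njit(cache=True)
def _cv_predict(X, y, fold, n_folds, C, standardize, tol, max_passes):  # pragma: no cover
    n, d = X.shape
    preds = np.empty(n, np.float64)
    for f in range(n_folds):
        n_tr = 0
        for i in range(n):
            if fold[i] != f:
                n_tr += 1
        if n_tr == 0 or n_tr == n:
            continue
        Xtr = np.empty((n_tr, d + 1))
        ytr = np.empty(n_tr)
        k = 0
        for i in range(n):
            if fold[i] != f:
                for j in range(d):
                    Xtr[k, j] = X[i, j]
                Xtr[k, d] = 1.0
                ytr[k] = y[i]
                k += 1
        mean = np.zeros(d)
        sd = np.ones(d)
        if standardize:
            for j in range(d):
                m = 0.0
                for i in range(n_tr):
                    m += Xtr[i, j]
                m /= n_tr
                v = 0.0
                for i in range(n_tr):
                    v += (Xtr[i, j] - m) ** 2
                s = np.sqrt(v / n_tr)
                if s == 0.0:
                    s = 1.0
                mean[j] = m
                sd[j] = s
                for i in range(n_tr):
                    Xtr[i, j] = (Xtr[i, j] - m) / s
        w = _dual_cd(Xtr, ytr, C, tol, max_passes)
        for i in range(n):
            if fold[i] == f:
                dec = w[d]
                for j in range(d):
                    dec += w[j] * (X[i, j] - mean[j]) / sd[j]
                preds[i] = 1.0 if dec >= 0.0 else -1.0
    return preds


def _cv_predict_sklearn(X, y, fold, n_folds, config: SvmConfig) -> np.ndarray:
    from sklearn.svm import LinearSVC

    n = X.shape[0]
    preds = np.empty(n)
    for f in range(n_folds):
        tr = fold != f
        te = ~tr
        if not te.any() or not tr.any():
            continue
        Xtr, Xte = X[tr], X[te]
        if config.standardize:
            m = Xtr.mean(axis=0)
            s = Xtr.std(axis=0)
            s[s == 0.0] = 1.0
            Xtr = (Xtr - m) / s
            Xte = (Xte - m) / s
        clf = LinearSVC(loss="hinge", C=config.C, tol=1e-9, max_iter=500_000, random_state=0)
        clf.fit(Xtr, y[tr])
        dec = clf.decision_function(Xte)
        preds[te] = np.where(dec >= 0.0, 1.0, -1.0)
    return preds


def cv_predictions(X: np.ndarray, y: np.ndarray, fold: np.ndarray,
                   config: SvmConfig | None = None) -> np.ndarray:
    """Held-out +/-1 predictions under a fold partition.

    Parameters
    ----------
    X : (n, d) feature matrix (subset columns already extracted).
    y : (n,) labels coded +1 / -1.
    fold : (n,) integer fold id per sample; each fold is held out once and
        predicted by a model trained on the remainder.
    """
    config = config or SvmConfig()
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    fold = np.asarray(fold, dtype=np.int64)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2-D with at least one feature column")
    if len(y) != X.shape[0] or len(fold) != X.shape[0]:
        raise ValueError("y and fold must have one entry per row of X")
    uniq = np.unique(fold)
    n_folds = int(fold.max()) + 1
    for f in uniq:
        tr_labels = y[fold != f]
        if len(np.unique(tr_labels)) < 2:
            raise ValueError("a training fold contains a single class")
    if config.engine == "sklearn":
        return _cv_predict_sklearn(X, y, fold, n_folds, config)
    return _cv_predict(X, y, fold, n_folds, config.C, config.standardize,
                       config.tol, config.max_passes)


def loocv_predictions(X: np.ndarray, y: np.ndarray,
                      config: SvmConfig | None = None,
                      groups: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out predictions; with ``groups``, leave-one-group-out.

    Sample-level folds (the default) mirror the study's 48-fold LOOCV; passing
    subject ids as ``groups`` holds out both conditions of a subject at once,
    which avoids paired-subject leakage.
    """
    n = np.asarray(X).shape[0]
    if groups is None:
        fold = np.arange(n)
    else:
        _, fold = np.unique(np.asarray(groups), return_inverse=True)
    return cv_predictions(X, y, fold, config)
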