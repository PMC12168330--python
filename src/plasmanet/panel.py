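"""Multivariate biomarker panel selection.

Recursive feature elimination with cross-validation (RFECV) around a linear
maximum-margin classifier: the regularization strength C is tuned by
stratified k-fold accuracy, then features are eliminated one at a time by
smallest absolute weight, the cross-validated accuracy is recorded at every
subset size, and the smallest size attaining the best mean accuracy wins.
Features are standardized inside each training fold only, so no test-fold
information leaks into the scaling.  Panel and per-protein discrimination
are summarized by the Mann–Whitney AUC with percentile bootstrap confidence
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["PanelResult", "tune_c", "rfecv_select", "auc_with_bootstrap_ci"]

DEFAULT_C_GRID = tuple(10.0 ** np.arange(-3, 4))


@dataclass
class PanelResult:
    selected: list[str]
    cv_accuracy: float
    panel_auc: float
    panel_auc_ci: tuple[float, float]
    per_protein_auc: pd.DataFrame
    C: float
    cv_curve: pd.DataFrame            # subset size -> mean CV accuracy
    fold_assignments: pd.Series
    seed: int
    notes: list = field(default_factory=list)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    return X, (y == classes.max()).astype(int), classes


def _fold_iter(y, k, seed):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def _effective_k(y, k):
    smallest = np.bincount(y).min()
    if smallest < k:
        warnings.warn(f"smallest class has {smallest} members; reducing folds to {smallest}")
        return int(smallest)
    return k


def tune_c(X, y, c_grid=DEFAULT_C_GRID, k: int = 5, seed: int = 0) -> float:
    """Pick C by mean stratified k-fold accuracy; ties go to the smallest C."""
    X, y, _ = _check_xy(X, y)
    k = _effective_k(y, k)
    folds = _fold_iter(y, k, seed)
    best_c, best_acc = None, -np.inf
    for C in sorted(c_grid):
        accs = []
        for tr, te in folds:
            scaler = StandardScaler().fit(X[tr])
            clf = SVC(kernel="linear", C=C).fit(scaler.transform(X[tr]), y[tr])
            accs.append((clf.predict(scaler.transform(X[te])) == y[te]).mean())
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_acc, best_c = acc, C
    return float(best_c)


def _rfe_path(Xtr, ytr, C):
    """Feature-elimination order on one training set; returns list of
    (active feature indices) from full set down to one feature."""
    active = list(range(Xtr.shape[1]))
    path = []
    scaler = StandardScaler().fit(Xtr)
    Xs = scaler.transform(Xtr)
    while active:
        path.append(list(active))
        if len(active) == 1:
            break
        clf = SVC(kernel="linear", C=C).fit(Xs[:, active], ytr)
        w = np.abs(clf.coef_[0])
        drop = int(np.argmin(w))
        del active[drop]
    return path, scaler


def auc_with_bootstrap_ci(scores, y, n_boot: int = 1000, seed: int = 0,
                          ci: float = 0.95) -> tuple[float, float, float]:
    """Mann–Whitney AUC (ties count half) with a stratified percentile bootstrap CI."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need both classes present")
    pos = scores[y == classes.max()]
    neg = scores[y == classes.min()]

    def _auc(p, n):
        ranks = rankdata(np.concatenate([p, n]))
        u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2.0
        return u / (len(p) * len(n))

    point = float(_auc(pos, neg))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        boots[b] = _auc(bp, bn)
    lo, hi = np.quantile(boots, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return point, float(lo), float(hi)


def rfecv_select(
    X: pd.DataFrame,
    y,
    C: float | None = None,
    k: int = 5,
    step: int = 1,
    seed: int = 0,
    n_boot: int = 1000,
) -> PanelResult:
    """Select the optimal protein panel by recursive feature elimination.

    Within each training fold an elimination path is computed (dropping the
    feature with the smallest absolute SVM weight, one per step) and the
    held-out accuracy is recorded at every subset size; the size with the
    best mean accuracy across folds wins, ties to the smaller panel.  The
    final membership comes from an elimination path on the full data cut at
    the optimal size, and the final model is re-validated by stratified
    k-fold, yielding the panel's cross-validated accuracy and AUC.
    """
    if step != 1:
        raise NotImplementedError("only step=1 elimination is supported")
    feat_names = list(X.columns) if isinstance(X, pd.DataFrame) else [str(i) for i in range(np.shape(X)[1])]
    sample_index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(np.shape(X)[0])
    Xv, yv, classes = _check_xy(np.asarray(X, dtype=float), y)
    notes = []

    const = Xv.std(axis=0) == 0
    if const.any():
        notes.append(f"dropped {int(const.sum())} constant feature(s)")
        warnings.warn(notes[-1])
        keep = ~const
        Xv = Xv[:, keep]
        feat_names = [f for f, kf in zip(feat_names, keep) if kf]

    if C is None:
        C = tune_c(Xv, yv, k=k, seed=seed)
    k_eff = _effective_k(yv, k)
    folds = _fold_iter(yv, k_eff, seed)

    d = Xv.shape[1]
    acc_by_size = np.zeros((k_eff, d + 1))  # index by subset size
    for fi, (tr, te) in enumerate(folds):
        path, scaler = _rfe_path(Xv[tr], yv[tr], C)
        Xs_tr, Xs_te = scaler.transform(Xv[tr]), scaler.transform(Xv[te])
        for active in path:
            clf = SVC(kernel="linear", C=C).fit(Xs_tr[:, active], yv[tr])
            acc = (clf.predict(Xs_te[:, active]) == yv[te]).mean()
            acc_by_size[fi, len(active)] = acc
    mean_acc = acc_by_size[:, 1:].mean(axis=0)        # sizes 1..d
    best_size = int(np.argmax(mean_acc >= mean_acc.max() - 1e-12) + 1)
    cv_curve = pd.DataFrame({"size": np.arange(1, d + 1), "cv_accuracy": mean_acc}).set_index("size")

    full_path, _ = _rfe_path(Xv, yv, C)
    selected_idx = next(a for a in full_path if len(a) == best_size)
    selected = [feat_names[i] for i in selected_idx]

    # Re-validate on the selected panel: out-of-fold accuracy and scores.
    oof_scores = np.zeros(len(yv))
    fold_assign = np.zeros(len(yv), dtype=int)
    accs = []
    for fi, (tr, te) in enumerate(folds):
        scaler = StandardScaler().fit(Xv[tr][:, selected_idx])
        clf = SVC(kernel="linear", C=C).fit(scaler.transform(Xv[tr][:, selected_idx]), yv[tr])
        Xt = scaler.transform(Xv[te][:, selected_idx])
        accs.append((clf.predict(Xt) == yv[te]).mean())
        oof_scores[te] = clf.decision_function(Xt)
        fold_assign[te] = fi
    cv_accuracy = float(np.mean(accs))
    panel_auc, lo, hi = auc_with_bootstrap_ci(oof_scores, yv, n_boot=n_boot, seed=seed + 1)

    rows = []
    for i in selected_idx:
        a, alo, ahi = auc_with_bootstrap_ci(Xv[:, i], yv, n_boot=n_boot, seed=seed + 2 + i)
        if a < 0.5:  # report direction-free discriminability with a matching CI
            a, alo, ahi = auc_with_bootstrap_ci(-Xv[:, i], yv, n_boot=n_boot, seed=seed + 2 + i)
        rows.append({"protein": feat_names[i], "auc": a, "ci_low": alo, "ci_high": ahi})
    per_protein = pd.DataFrame(rows).set_index("protein") if rows else pd.DataFrame()

    return PanelResult(
        selected=selected,
        cv_accuracy=cv_accuracy,
        panel_auc=panel_auc,
        panel_auc_ci=(lo, hi),
        per_protein_auc=per_protein,
        C=float(C),
        cv_curve=cv_curve,
        fold_assignments=pd.Series(fold_assign, index=sample_index),
        seed=seed,
        notes=notes,
    )
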