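"""Genotype classification from coactivation features with a permutation null.

The full per-subject coactivation matrix (lower triangle, diagonal excluded)
is the feature vector. A linear-kernel SVM is scored by stratified k-fold
cross-validation using balanced accuracy (mean of per-class recalls, pooled
over folds), and significance comes from re-running the whole CV loop on
label permutations: p = (1 + #{null >= observed}) / (1 + n_perm), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .boundary import CoactivationMatrix

__all__ = [
    "PermutationResult",
    "vectorize_coactivation",
    "unvectorize_coactivation",
    "crossval_balanced_accuracy",
    "permutation_test",
]


@dataclass(frozen=True)
class PermutationResult:
    """Observed balanced accuracy against its label-permutation null."""

    observed_bacc: float
    null_baccs: np.ndarray
    p: float
    n_perm: int
    k_folds: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_bacc": self.observed_bacc,
            "p": self.p,
            "n_perm": self.n_perm,
            "k_folds": self.k_folds,
            "seed": self.seed,
        }


def _pair_columns(labels: list[str]) -> list[tuple[int, int, str]]:
    cols = []
    for i in range(1, len(labels)):
        for j in range(i):
            cols.append((i, j, f"{labels[i]}__{labels[j]}"))
    return cols


def vectorize_coactivation(matrices: list[CoactivationMatrix]) -> pd.DataFrame:
    """Flatten each subject's matrix lower triangle into one feature row.

    Column order is row-major over the lower triangle (ROI_i__ROI_j, i > j)
    and identical ROI ordering is required across subjects.
    """
    if not matrices:
        raise ValueError("no coactivation matrices supplied")
    labels = matrices[0].roi_labels
    cols = _pair_columns(labels)
    rows, index = [], []
    for m in matrices:
        if m.roi_labels != labels:
            raise ValueError(
                f"ROI labels of subject {m.subject_id!r} do not match the first subject"
            )
        vals = m.betas.to_numpy()
        rows.append([vals[i, j] for i, j, _ in cols])
        index.append(m.subject_id)
    return pd.DataFrame(rows, index=index, columns=[c for _, _, c in cols])


def unvectorize_coactivation(features: pd.Series, labels: list[str]) -> pd.DataFrame:
    """Rebuild a symmetric matrix (diagonal NaN) from one feature row."""
    mat = np.full((len(labels), len(labels)), np.nan)
    for i, j, name in _pair_columns(labels):
        mat[i, j] = mat[j, i] = features[name]
    return pd.DataFrame(mat, index=labels, columns=labels)


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    recalls = [
        (y_pred[y_true == cls] == cls).mean() for cls in np.unique(y_true)
    ]
    return float(np.mean(recalls))


def crossval_balanced_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> float:
    """Stratified k-fold CV balanced accuracy of a linear-kernel SVM.

    Features are standardized with training-fold statistics only (no
    leakage); predictions are pooled over folds before computing the mean of
    per-class recalls.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if counts.min() < k:
        raise ValueError(f"both classes need >= k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty(y.size, dtype=y.dtype)
    for train, test in skf.split(X, y):
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((X[train] - mu) / sd, y[train])
        pred[test] = clf.predict((X[test] - mu) / sd)
    return _balanced_accuracy(y, pred)


def permutation_test(
    features: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 5000,
    k: int = 5,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance of the cross-validated classifier.

    The full CV loop is re-run for each of ``n_perm`` permuted label vectors;
    the p-value is (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(labels)
    X = np.ascontiguousarray(np.asarray(features, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    observed = crossval_balanced_accuracy(X, y, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    # inputs validated once above; skip per-fit finiteness checks in the loop
    with sklearn.config_context(assume_finite=True):
        for b in range(n_perm):
            null[b] = crossval_balanced_accuracy(
                X, rng.permutation(y), k=k, seed=seed
            )
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return PermutationResult(observed, null, float(p), n_perm, k, seed)
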