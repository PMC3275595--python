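"""Two-level (nested) 10-fold cross-validation of an SVM over feature subsets.

The outer level partitions the data into stratified folds; each held-out
fold is scored by an SVM trained on the remaining folds with
hyperparameters chosen by an *inner* 10-fold grid search run only on those
remaining folds, so the outer test fold never influences model selection.
Overall accuracy is pooled over the outer folds (correct predictions /
dataset size); the per-fold mean is reported alongside.

Feature subsets are whole propensity groups (20 columns each) of the
grouped encoding, or the 400-dimensional one-hot identity encoding as a
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: Default RBF hyperparameter grid: C = 2^-5..2^15, gamma = 2^-15..2^3, step 2^2.
DEFAULT_GRID = {
    "C": [2.0**e for e in range(-5, 16, 2)],
    "gamma": [2.0**e for e in range(-15, 4, 2)],
}


def feature_subset(
    X: np.ndarray, groups: Sequence[int], group_size: int = 20
) -> np.ndarray:
    """Columns of the chosen 1-based groups, concatenated in group-index order."""
    groups = sorted(set(int(g) for g in groups))
    if not groups:
        raise ValueError("feature subset must name at least one group")
    X = np.atleast_2d(np.asarray(X))
    n_groups = X.shape[1] // group_size
    for g in groups:
        if not 1 <= g <= n_groups:
            raise ValueError(f"group {g} outside 1..{n_groups}")
    cols = np.concatenate(
        [np.arange((g - 1) * group_size, g * group_size) for g in groups]
    )
    return X[:, cols]


@dataclass
class FoldDetail:
    """Bookkeeping for one outer fold of the nested scheme."""

    fold: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    inner_indices_seen: np.ndarray  # union of all inner-fold indices
    best_params: dict
    inner_accuracy: float  # mean inner-CV accuracy of the chosen parameters
    test_accuracy: float
    n_correct: int


@dataclass
class CVResult:
    """Outcome of a nested cross-validation run."""

    overall_accuracy: float  # pooled: 100 * total correct / dataset size
    fold_mean_accuracy: float
    fold_details: list[FoldDetail]
    n_samples: int
    outer: int
    inner: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": [f.fold for f in self.fold_details],
                "test_size": [f.test_indices.size for f in self.fold_details],
                "C": [f.best_params["C"] for f in self.fold_details],
                "gamma": [f.best_params["gamma"] for f in self.fold_details],
                "inner_accuracy": [f.inner_accuracy for f in self.fold_details],
                "test_accuracy": [f.test_accuracy for f in self.fold_details],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Nested {self.outer}x{self.inner}-fold SVM cross-validation "
            f"(n={self.n_samples}, seed={self.seed})",
            self.to_frame().to_string(index=False),
            f"pooled accuracy: {self.overall_accuracy:.2f}%   "
            f"fold-mean accuracy: {self.fold_mean_accuracy:.2f}%",
        ]
        return "\n".join(lines)


def _inner_grid_search(
    X: np.ndarray, y: np.ndarray, inner: int, grid: dict, seed: int
) -> tuple[dict, float, np.ndarray]:
    """Pick (C, gamma) maximising mean stratified inner-fold accuracy.

    Ties break toward smaller C, then smaller gamma.  Returns the chosen
    parameters, their mean inner accuracy, and the union of inner indices
    touched (all of 0..len(X)) for audit.
    """
    skf = StratifiedKFold(n_splits=inner, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None
    for C in sorted(grid["C"]):
        for gamma in sorted(grid["gamma"]):
            accs = []
            for tr, va in splits:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(X[tr], y[tr])
                accs.append(np.mean(clf.predict(X[va]) == y[va]))
            mean_acc = float(np.mean(accs))
            if best is None or mean_acc > best[0] + 1e-12:
                best = (mean_acc, {"C": C, "gamma": gamma})
    seen = np.unique(np.concatenate([np.concatenate(s) for s in splits]))
    return best[1], best[0], seen


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    feature_groups: Sequence[int] | str = "all",
    outer: int = 10,
    inner: int = 10,
    grid: dict | None = None,
    seed: int = 0,
    group_size: int = 20,
) -> CVResult:
    """Two-level stratified k-fold SVM evaluation of a feature subset.

    ``feature_groups`` is a list of 1-based propensity groups to keep,
    ``"all"`` for the full matrix, or ``"binary"`` to signal that ``X`` is
    already the identity encoding (used as-is).  Folds are stratified by
    class with a seeded shuffle; inner folds are drawn exclusively from
    each outer training set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    if X.shape[0] < outer:
        raise ValueError(f"dataset of {X.shape[0]} too small for {outer} outer folds")
    if isinstance(feature_groups, str):
        if feature_groups not in ("all", "binary"):
            raise ValueError("feature_groups must be group indices, 'all' or 'binary'")
    else:
        X = feature_subset(X, feature_groups, group_size)
    grid = grid or DEFAULT_GRID

    # Canonicalise row order (lexicographic by features, then label) so the
    # result is invariant to how the input records happened to be ordered.
    order = np.lexsort(tuple(X[:, c] for c in range(X.shape[1] - 1, -1, -1)) + (y,))
    Xs, ys = X[order], y[order]

    outer_skf = StratifiedKFold(n_splits=outer, shuffle=True, random_state=seed)
    details: list[FoldDetail] = []
    total_correct = 0
    for k, (tr, te) in enumerate(outer_skf.split(Xs, ys)):
        params, inner_acc, seen_local = _inner_grid_search(
            Xs[tr], ys[tr], inner, grid, seed=seed + 1 + k
        )
        clf = SVC(kernel="rbf", **params)
        clf.fit(Xs[tr], ys[tr])
        pred = clf.predict(Xs[te])
        n_correct = int(np.sum(pred == ys[te]))
        total_correct += n_correct
        details.append(
            FoldDetail(
                fold=k,
                train_indices=order[tr],  # original dataset indices
                test_indices=order[te],
                inner_indices_seen=order[tr[seen_local]],
                best_params=params,
                inner_accuracy=100.0 * inner_acc,
                test_accuracy=100.0 * n_correct / te.size,
                n_correct=n_correct,
            )
        )
    return CVResult(
        overall_accuracy=100.0 * total_correct / y.size,
        fold_mean_accuracy=float(np.mean([f.test_accuracy for f in details])),
        fold_details=details,
        n_samples=int(y.size),
        outer=outer,
        inner=inner,
        seed=seed,
    )
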