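"""Two-stage filter feature selection: t-test at p < alpha, then mutual
information ranking, plus the cross-validation selection-frequency ledger.

The t-test stage keeps features whose two-sample p-value is strictly below
alpha (Welch by default; pooled-variance available). The surviving features
are then ranked by estimated mutual information with the class label and the
top k kept. Selection is always fitted on training folds only.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import mutual_info_score

from .errors import InvalidInputError


@dataclass
class SelectionResult:
    """Outcome of the two-stage filter on one training split.

    ``selected`` holds original column indices ordered by decreasing MI
    (ties by ascending index); ``pvalues`` covers every input feature;
    ``mi_scores`` is NaN for features that did not survive the t-test.
    """

    selected: np.ndarray
    pvalues: np.ndarray
    mi_scores: np.ndarray
    alpha: float
    k: int
    degenerate: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __len__(self) -> int:
        return len(self.selected)


def ttest_filter(X: np.ndarray, y: np.ndarray, alpha: float = 0.05, *,
                 equal_var: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Indices (ascending) and p-values of features with two-sample p < alpha.

    Features constant in both groups have no test statistic; they get p = 1
    and are excluded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise InvalidInputError(f"t-test filter needs exactly 2 classes, got {len(classes)}")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("both classes need at least 2 subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pvals = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    pvals = np.asarray(pvals, dtype=float)
    pvals[~np.isfinite(pvals)] = 1.0  # constant-in-both-groups features
    keep = np.flatnonzero(pvals < alpha)
    return keep, pvals


def mi_rank(X: np.ndarray, y: np.ndarray, k: int, *, estimator: str = "knn",
            n_neighbors: int = 3, n_bins: int = 8, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Top-k column indices by estimated mutual information with the label.

    ``estimator="knn"`` uses the nearest-neighbour estimator for continuous
    features; ``estimator="bins"`` discretises each feature into
    equal-frequency bins first. Ties break toward the lower original index.
    Returns (ordered indices, per-column MI scores).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 0:
        raise InvalidInputError("k must be >= 0")
    p = X.shape[1]
    if k == 0 or p == 0:
        return np.array([], dtype=int), np.zeros(p)
    if estimator == "knn":
        mi = mutual_info_classif(X, y, n_neighbors=n_neighbors, random_state=seed)
    elif estimator == "bins":
        mi = np.empty(p)
        for j in range(p):
            edges = np.quantile(X[:, j], np.linspace(0, 1, n_bins + 1)[1:-1])
            mi[j] = mutual_info_score(y, np.digitize(X[:, j], np.unique(edges)))
    else:
        raise InvalidInputError(f"unknown MI estimator {estimator!r}")
    if k > p:
        warnings.warn(f"requested k={k} exceeds {p} available features; returning all")
        k = p
    order = np.lexsort((np.arange(p), -mi))  # MI desc, index asc on ties
    return order[:k], mi


def select_features(X: np.ndarray, y: np.ndarray, alpha: float = 0.05,
                    k: int | None = None, *, equal_var: bool = False,
                    estimator: str = "knn", seed: int = 0) -> SelectionResult:
    """t-test filter then MI ranking; deterministic given inputs and seed.

    ``k=None`` caps the selection at the number of training subjects. If no
    feature survives the t-test the result is empty (callers fall back to
    all features) and a warning is issued.
    """
    X = np.asarray(X, dtype=float)
    survivors, pvals = ttest_filter(X, y, alpha, equal_var=equal_var)
    degenerate = np.flatnonzero(pvals >= 1.0)
    if k is None:
        k = min(len(survivors), X.shape[0])
    mi_all = np.full(X.shape[1], np.nan)
    if len(survivors) == 0:
        warnings.warn("no feature survived the t-test filter; empty selection")
        return SelectionResult(np.array([], dtype=int), pvals, mi_all, alpha, k, degenerate)
    local_order, mi_local = mi_rank(X[:, survivors], y, min(k, len(survivors)),
                                    estimator=estimator, seed=seed)
    mi_all[survivors] = mi_local
    return SelectionResult(survivors[local_order], pvals, mi_all, alpha, k, degenerate)


def tally_frequency(selections: list[SelectionResult], n_features: int | None = None,
                    names: list[str] | None = None):
    """Count how often each feature index (or name) was selected across runs.

    With 5 repeats x 5 folds the maximum attainable count is 25. Returns a
    Counter keyed by name when ``names`` is given, else by index.
    """
    counts: Counter = Counter()
    for sel in selections:
        for idx in sel.selected:
            key = names[int(idx)] if names is not None else int(idx)
            counts[key] += 1
    if n_features is not None and names is None:
        for i in range(n_features):
            counts.setdefault(i, 0)
    return counts
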