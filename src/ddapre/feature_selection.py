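"""One-way ANOVA F-test feature ranking and top-k selection.

For each feature, F is the ratio of the between-group variance
(sum_i n_i (mean_i - grand_mean)^2 / (k - 1)) to the within-group
variance (sum_ij (x_ij - mean_i)^2 / (N - k)), with the class label
defining the groups. Large F marks class-discriminative features.

Degenerate cases: zero within-variance with nonzero between-variance
maps to +inf (perfectly separated constant groups rank first); the 0/0
case (a globally constant feature) maps to 0, ranking last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ddapre.fixtures import FeatureMatrix


@dataclass
class FTestResult:
    """Per-feature F values and the retained top-k index set."""

    f_values: np.ndarray
    between_variance: np.ndarray
    within_variance: np.ndarray
    selected_indices: np.ndarray  # sorted by F descending, ties by index
    k_selected: int
    mean_f_selected: float
    mean_f_all: float


def _group_stats(X: np.ndarray, labels: np.ndarray):
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    N = X.shape[0]
    k = len(groups)
    if N - k < 1:
        raise ValueError("need N - k >= 1 residual degrees of freedom")
    grand = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for g in groups:
        block = X[labels == g]
        mean_g = block.mean(axis=0)
        between += len(block) * (mean_g - grand) ** 2
        within += ((block - mean_g) ** 2).sum(axis=0)
    return between / (k - 1), within / (N - k)


def f_score(feature_column: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F for a single feature against the group labels."""
    col = np.asarray(feature_column, dtype=np.float64).reshape(-1, 1)
    between, within = _group_stats(col, np.asarray(labels))
    b, w = float(between[0]), float(within[0])
    if w == 0.0:
        return float("inf") if b > 0.0 else 0.0
    return b / w


def select_top_k(
    features: np.ndarray, labels: np.ndarray, k_selected: int
) -> FTestResult:
    """Rank all features by F and keep the top ``k_selected``.

    Selection order is F descending with ties broken by feature index;
    +inf features (perfect separators) sort first. Both the full-set and
    selected-set mean F are reported (the means ignore infinite values,
    which would otherwise swamp the average).
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if not 1 <= k_selected <= X.shape[1]:
        raise ValueError(f"k_selected must be in [1, {X.shape[1]}]")
    between, within = _group_stats(X, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_values = np.where(
            within == 0.0,
            np.where(between > 0.0, np.inf, 0.0),
            between / np.where(within == 0.0, 1.0, within),
        )
    order = np.lexsort((np.arange(len(f_values)), -f_values))
    selected = order[:k_selected]

    def _finite_mean(vals: np.ndarray) -> float:
        finite = vals[np.isfinite(vals)]
        return float(finite.mean()) if len(finite) else float("inf")

    return FTestResult(
        f_values=f_values,
        between_variance=between,
        within_variance=within,
        selected_indices=selected,
        k_selected=k_selected,
        mean_f_selected=_finite_mean(f_values[selected]),
        mean_f_all=_finite_mean(f_values),
    )


def reduce_matrix(matrix: FeatureMatrix, result: FTestResult) -> FeatureMatrix:
    """Column-subset a feature matrix to the selected features."""
    idx = result.selected_indices
    if idx.max(initial=-1) >= matrix.n_features:
        raise IndexError("selected index out of range for matrix")
    return FeatureMatrix(
        matrix.X[:, idx],
        matrix.y,
        matrix.drug_ids,
        matrix.disease_ids,
        [matrix.feature_names[i] for i in idx],
    )
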