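"""Adaptive multi-distance K-means similarity undersampling (AMDKSU).

The primary variant (``ksu_pairs``) clusters the majority class with
K-means, ranks within-cluster sample pairs by a configurable distance
metric, and repeatedly deletes one member of each most-similar disjoint
pair until the majority count reaches the target (the minority count by
default, giving a 1:1 balanced set). A secondary variant (``enn_edit``)
is an edited-nearest-neighbor rule: a majority sample is dropped when at
least half of its k nearest neighbors carry the other label. Grouped
sampling partitions the majority class (by drug, typically) and applies
the procedure per group under largest-remainder quotas. Adaptive metric
selection resamples under each candidate metric, scores a probe
classifier by cross-validated AUC, and keeps the argmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold, cross_val_score

METRIC_KINDS = ("euclidean", "hamming", "chebyshev", "manhattan", "minkowski")


@dataclass(frozen=True)
class DistanceMetric:
    """One of the five supported metrics.

    ``p`` applies to Minkowski only. ``hamming_thresholds`` is the
    quantizer for Hamming on continuous vectors: each coordinate is
    binarized as ``x > threshold`` before disagreements are counted
    (per-feature median split when fitted from data). With no quantizer,
    raw coordinate inequality is counted, which is the textbook rule on
    already-discrete vectors.
    """

    kind: str = "euclidean"
    p: float = 3.0
    hamming_thresholds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in METRIC_KINDS:
            raise ValueError(f"unknown metric {self.kind!r}")
        if self.kind == "minkowski" and self.p < 1:
            raise ValueError("minkowski requires p >= 1")


def fit_median_quantizer(X: np.ndarray) -> tuple[float, ...]:
    """Per-feature median thresholds for Hamming binarization."""
    return tuple(np.median(np.asarray(X, dtype=np.float64), axis=0))


def distance(x: np.ndarray, y: np.ndarray, metric: DistanceMetric) -> float:
    """Scalar distance under ``metric`` (closed forms, no library call)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if metric.kind == "euclidean":
        return float(np.sqrt(np.sum((x - y) ** 2)))
    if metric.kind == "manhattan":
        return float(np.sum(np.abs(x - y)))
    if metric.kind == "chebyshev":
        return float(np.max(np.abs(x - y))) if x.size else 0.0
    if metric.kind == "minkowski":
        return float(np.sum(np.abs(x - y) ** metric.p) ** (1.0 / metric.p))
    # hamming
    if metric.hamming_thresholds is not None:
        thr = np.asarray(metric.hamming_thresholds)
        if thr.shape != x.shape:
            raise ValueError("quantizer thresholds do not match vector length")
        x, y = (x > thr).astype(int), (y > thr).astype(int)
    return float(np.sum(x != y))


def pairwise_distances(X: np.ndarray, metric: DistanceMetric) -> np.ndarray:
    """Square distance matrix under ``metric`` (vectorized)."""
    X = np.asarray(X, dtype=np.float64)
    if metric.kind == "euclidean":
        return cdist(X, X, "euclidean")
    if metric.kind == "manhattan":
        return cdist(X, X, "cityblock")
    if metric.kind == "chebyshev":
        return cdist(X, X, "chebyshev")
    if metric.kind == "minkowski":
        return cdist(X, X, "minkowski", p=metric.p)
    if metric.hamming_thresholds is not None:
        X = (X > np.asarray(metric.hamming_thresholds)).astype(np.float64)
    return cdist(X, X, "hamming") * X.shape[1]


@dataclass
class ResampleConfig:
    """Settings for the undersampler.

    ``target_majority_count`` of None means "match the minority count"
    (the 1:1 balancing policy). ``n_clusters`` of None uses
    ``max(2, floor(sqrt(majority / 2)))``.
    """

    n_clusters: int | None = None
    metric: DistanceMetric = field(default_factory=DistanceMetric)
    target_majority_count: int | None = None
    group_key: str | None = None  # None | "by_drug"
    variant: str = "ksu_pairs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("ksu_pairs", "enn_edit"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


@dataclass
class ResampleResult:
    """Bookkeeping of an undersampling run.

    ``retained_indices`` are all surviving row indices (minority plus
    retained majority); ``removed_indices`` are the deleted majority
    rows. Retained-majority and removed together partition the majority
    index set exactly; no minority row is ever removed.
    """

    retained_indices: np.ndarray
    removed_indices: np.ndarray
    majority_label: int
    per_cluster_removed: dict[int, int] = field(default_factory=dict)
    metric: DistanceMetric = field(default_factory=DistanceMetric)
    diagnostics: dict = field(default_factory=dict)

    def apply(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return X[self.retained_indices], y[self.retained_indices]


def _majority_minority(y: np.ndarray) -> tuple[int, int]:
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) != 2:
        raise ValueError("exactly two classes required")
    order = np.argsort(counts)  # ascending
    return int(labels[order[1]]), int(labels[order[0]])


def _default_k(n_majority: int) -> int:
    return max(2, int(math.floor(math.sqrt(n_majority / 2))))


def _greedy_disjoint_pairs(
    dist: np.ndarray, rows: np.ndarray, need: int
) -> list[tuple[int, int]]:
    """Most-similar disjoint pairs, ascending by (distance, i, j).

    ``rows`` are global row indices addressing ``dist``'s axes; each row
    participates in at most one selected pair.
    """
    m = len(rows)
    iu, ju = np.triu_indices(m, k=1)
    if len(iu) == 0 or need <= 0:
        return []
    dvals = dist[iu, ju]
    order = np.lexsort((rows[ju], rows[iu], dvals))
    used: set[int] = set()
    pairs = []
    for idx in order:
        a, b = int(rows[iu[idx]]), int(rows[ju[idx]])
        if a in used or b in used:
            continue
        pairs.append((a, b))
        used.update((a, b))
        if len(pairs) == need:
            break
    return pairs


def ksu_pairs_undersample(
    features: np.ndarray, labels: np.ndarray, cfg: ResampleConfig
) -> ResampleResult:
    """Cluster + similar-pair removal undersampling of the majority class.

    K-means partitions the majority rows once; then, in repeated rounds,
    the globally most-similar disjoint within-cluster pairs are selected
    greedily (ascending distance, ties by row index) and one member of
    each pair is removed uniformly at random, until the retained majority
    count equals the target. Clusters shrink to singletons eventually; a
    final random-removal fallback covers that degenerate tail.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    maj_label, min_label = _majority_minority(y)
    maj_idx = np.flatnonzero(y == maj_label)
    min_idx = np.flatnonzero(y != maj_label)
    target = (
        cfg.target_majority_count
        if cfg.target_majority_count is not None
        else len(min_idx)
    )
    if target < 1:
        raise ValueError("target majority count must be >= 1")
    if target > len(maj_idx):
        raise ValueError("target exceeds current majority count")

    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_clusters if cfg.n_clusters is not None else _default_k(len(maj_idx))
    k = min(k, len(maj_idx))
    km = KMeans(n_clusters=k, random_state=cfg.seed % (2**31), n_init=10)
    assignment = km.fit_predict(X[maj_idx])
    cluster_of = dict(zip(maj_idx.tolist(), assignment.tolist()))

    dist = pairwise_distances(X[maj_idx], cfg.metric)
    pos_of = {int(g): i for i, g in enumerate(maj_idx)}

    retained = set(maj_idx.tolist())
    removed: list[int] = []
    per_cluster: dict[int, int] = {c: 0 for c in range(k)}
    while len(retained) > target:
        need = len(retained) - target
        round_pairs: list[tuple[float, int, int]] = []
        for c in range(k):
            rows = np.array(
                sorted(g for g in retained if cluster_of[g] == c), dtype=int
            )
            if len(rows) < 2:
                continue
            sub = np.array([pos_of[g] for g in rows])
            local = dist[np.ix_(sub, sub)]
            for a, b in _greedy_disjoint_pairs(local, rows, need):
                round_pairs.append((dist[pos_of[a], pos_of[b]], a, b))
        round_pairs.sort()
        if not round_pairs:
            # singleton clusters only: fall back to random removal
            pool = sorted(retained)
            for g in rng.choice(pool, size=need, replace=False):
                retained.discard(int(g))
                removed.append(int(g))
                per_cluster[cluster_of[int(g)]] += 1
            break
        for d, a, b in round_pairs[:need]:
            victim = a if rng.random() < 0.5 else b
            retained.discard(victim)
            removed.append(victim)
            per_cluster[cluster_of[victim]] += 1

    kept = np.sort(np.concatenate([min_idx, np.array(sorted(retained), dtype=int)]))
    return ResampleResult(
        retained_indices=kept,
        removed_indices=np.array(sorted(removed), dtype=int),
        majority_label=maj_label,
        per_cluster_removed=per_cluster,
        metric=cfg.metric,
        diagnostics={
            "cluster_sizes": np.bincount(assignment, minlength=k).tolist(),
            "n_majority": len(maj_idx),
            "n_minority": len(min_idx),
            "target": target,
        },
    )


def enn_edit_undersample(
    features: np.ndarray,
    labels: np.ndarray,
    k_nn: int = 5,
    metric: DistanceMetric | None = None,
) -> ResampleResult:
    """Edited-nearest-neighbor undersampling.

    A row is marked when at least ``k_nn / 2`` of its ``k_nn`` nearest
    neighbors (self excluded; ties broken by row index) carry a different
    label; marks are applied to majority rows only, since the procedure's
    purpose is filtering the majority class.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    n = len(y)
    if k_nn < 1:
        raise ValueError("k_nn must be >= 1")
    if k_nn >= n:
        raise ValueError("k_nn must be smaller than the sample count")
    metric = metric or DistanceMetric()
    maj_label, _ = _majority_minority(y) if len(np.unique(y)) == 2 else (None, None)

    dist = pairwise_distances(X, metric)
    marked = []
    for i in range(n):
        order = np.lexsort((np.arange(n), dist[i]))
        neighbors = [j for j in order if j != i][:k_nn]
        diff = sum(1 for j in neighbors if y[j] != y[i])
        if diff >= k_nn / 2:
            marked.append(i)
    if maj_label is not None:
        removed = np.array([i for i in marked if y[i] == maj_label], dtype=int)
    else:
        removed = np.array([], dtype=int)
    keep = np.setdiff1d(np.arange(n), removed)
    return ResampleResult(
        retained_indices=keep,
        removed_indices=removed,
        majority_label=maj_label if maj_label is not None else -1,
        metric=metric,
        diagnostics={"marked": marked, "k_nn": k_nn},
    )


def _largest_remainder_quotas(
    sizes: dict[str, int], total: int
) -> dict[str, int]:
    """Proportional integer quotas summing exactly to ``total``.

    Quotas are capped at group sizes; any surplus freed by capping is
    redistributed to the remaining groups by the same rule.
    """
    keys = list(sizes)
    n = sum(sizes.values())
    if total > n:
        raise ValueError("quota total exceeds available rows")
    shares = {g: sizes[g] * total / n if n else 0.0 for g in keys}
    quotas = {g: min(int(math.floor(shares[g])), sizes[g]) for g in keys}
    remainder = total - sum(quotas.values())
    frac_order = sorted(
        keys, key=lambda g: (-(shares[g] - math.floor(shares[g])), g)
    )
    i = 0
    while remainder > 0:
        g = frac_order[i % len(frac_order)]
        if quotas[g] < sizes[g]:
            quotas[g] += 1
            remainder -= 1
        i += 1
        if i > 10 * len(frac_order) * (remainder + 1):
            raise RuntimeError("quota redistribution failed to converge")
    return quotas


def grouped_undersample(
    features: np.ndarray,
    labels: np.ndarray,
    group_ids: list[str],
    cfg: ResampleConfig,
) -> ResampleResult:
    """KSU applied independently per group (drug, typically).

    Majority rows are partitioned by ``group_ids``; each group receives a
    proportional retention quota (largest-remainder rounding, capped at
    group size with redistribution) so the global retained majority count
    equals the global target exactly.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if len(group_ids) != len(y):
        raise ValueError("group_ids length must match labels")
    maj_label, min_label = _majority_minority(y)
    maj_idx = np.flatnonzero(y == maj_label)
    min_idx = np.flatnonzero(y != maj_label)
    target = (
        cfg.target_majority_count
        if cfg.target_majority_count is not None
        else len(min_idx)
    )
    groups: dict[str, list[int]] = {}
    for i in maj_idx:
        groups.setdefault(group_ids[i], []).append(int(i))
    sizes = {g: len(rows) for g, rows in groups.items()}
    quotas = _largest_remainder_quotas(sizes, target)

    retained_majority: list[int] = []
    removed: list[int] = []
    per_cluster: dict[int, int] = {}
    for gi, (g, rows) in enumerate(sorted(groups.items())):
        quota = quotas[g]
        rows_arr = np.array(rows, dtype=int)
        if quota == 0:
            removed.extend(rows)
            continue
        if quota == len(rows):
            retained_majority.extend(rows)
            continue
        # per-group subproblem: majority rows of this group vs a dummy
        # minority; easier to call the pair remover on the subset directly
        sub_cfg = replace(
            cfg,
            target_majority_count=quota,
            group_key=None,
            seed=cfg.seed + gi,
            n_clusters=(
                min(cfg.n_clusters, len(rows))
                if cfg.n_clusters is not None
                else min(_default_k(len(rows)), len(rows))
            ),
        )
        sub_y = np.ones(len(rows) + quota, dtype=int)
        sub_y[len(rows) :] = 0  # synthetic minority block sets the target
        sub_X = np.vstack([X[rows_arr], np.zeros((quota, X.shape[1]))])
        sub = ksu_pairs_undersample(sub_X, sub_y, sub_cfg)
        kept_local = [i for i in sub.retained_indices if i < len(rows)]
        retained_majority.extend(rows_arr[kept_local].tolist())
        removed.extend(rows_arr[sub.removed_indices].tolist())
        for c, cnt in sub.per_cluster_removed.items():
            per_cluster[(gi, c)] = cnt  # type: ignore[index]

    kept = np.sort(
        np.concatenate([min_idx, np.array(sorted(retained_majority), dtype=int)])
    )
    return ResampleResult(
        retained_indices=kept,
        removed_indices=np.array(sorted(removed), dtype=int),
        majority_label=maj_label,
        per_cluster_removed=per_cluster,
        metric=cfg.metric,
        diagnostics={"group_quotas": quotas, "group_sizes": sizes, "target": target},
    )


def default_probe_classifier(seed: int = 42):
    """Gradient-boosted tree probe with the framework's reference settings."""
    from xgboost import XGBClassifier

    return XGBClassifier(
        colsample_bytree=0.8,
        subsample=0.8,
        learning_rate=0.1,
        max_depth=5,
        n_estimators=100,
        random_state=seed,
        eval_metric="logloss",
        n_jobs=1,
    )


def candidate_metrics(X: np.ndarray, p: float = 3.0) -> list[DistanceMetric]:
    """The five candidate metrics, Hamming fitted with a median quantizer."""
    return [
        DistanceMetric("euclidean"),
        DistanceMetric("hamming", hamming_thresholds=fit_median_quantizer(X)),
        DistanceMetric("chebyshev"),
        DistanceMetric("manhattan"),
        DistanceMetric("minkowski", p=p),
    ]


def adaptive_metric_select(
    features: np.ndarray,
    labels: np.ndarray,
    metrics: list[DistanceMetric] | None = None,
    probe_cv_folds: int = 5,
    seed: int = 0,
    probe_factory=default_probe_classifier,
):
    """Pick the distance metric whose resampled set best trains a probe.

    For each candidate: resample with ``ksu_pairs``, fit the probe
    classifier under stratified CV on the balanced set, record mean
    validation AUC. Returns (best metric, score table); ties keep the
    earlier candidate.
    """
    import pandas as pd

    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if metrics is None:
        metrics = candidate_metrics(X)
    if len(metrics) < 1:
        raise ValueError("at least one candidate metric required")
    rows = []
    for m in metrics:
        cfg = ResampleConfig(metric=m, seed=seed)
        try:
            result = ksu_pairs_undersample(X, y, cfg)
            Xb, yb = result.apply(X, y)
            cv = StratifiedKFold(
                n_splits=probe_cv_folds, shuffle=True, random_state=seed % (2**31)
            )
            auc = float(
                np.mean(
                    cross_val_score(
                        probe_factory(), Xb, yb, cv=cv, scoring="roc_auc"
                    )
                )
            )
        except ValueError:
            auc = 0.0
        rows.append({"metric": m.kind, "mean_cv_auc": auc})
    table = pd.DataFrame(rows)
    best = int(np.argmax(table["mean_cv_auc"].to_numpy()))
    return metrics[best], table
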