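import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddapre.resampling import (
    DistanceMetric,
    ResampleConfig,
    adaptive_metric_select,
    candidate_metrics,
    distance,
    enn_edit_undersample,
    fit_median_quantizer,
    grouped_undersample,
    ksu_pairs_undersample,
    pairwise_distances,
    _largest_remainder_quotas,
)

ALL_METRICS = [
    DistanceMetric("euclidean"),
    DistanceMetric("hamming"),
    DistanceMetric("chebyshev"),
    DistanceMetric("manhattan"),
    DistanceMetric("minkowski", p=3),
]


class TestDistance:
    @pytest.mark.parametrize(
        "x, y, metric, expected",
        [
            ([0, 0], [3, 4], DistanceMetric("euclidean"), 5.0),
            ([1, 0, 1], [1, 1, 1], DistanceMetric("hamming"), 1.0),
            ([1, 2], [4, 6], DistanceMetric("manhattan"), 7.0),
            ([1, 2], [4, 3], DistanceMetric("chebyshev"), 3.0),
            ([0, 0], [3, 4], DistanceMetric("minkowski", p=3), 91 ** (1 / 3)),
        ],
    )
    def test_worked_values(self, x, y, metric, expected):
        assert distance(np.array(x), np.array(y), metric) == pytest.approx(expected)

    def test_minkowski_collapses_to_manhattan_and_euclidean(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x, y = rng.normal(size=(2, 6))
            assert distance(x, y, DistanceMetric("minkowski", p=1)) == pytest.approx(
                distance(x, y, DistanceMetric("manhattan"))
            )
            assert distance(x, y, DistanceMetric("minkowski", p=2)) == pytest.approx(
                distance(x, y, DistanceMetric("euclidean"))
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distance(np.ones(3), np.ones(4), DistanceMetric("euclidean"))

    def test_minkowski_p_below_one_rejected(self):
        with pytest.raises(ValueError):
            DistanceMetric("minkowski", p=0.5)

    def test_hamming_quantizer_median_split(self):
        X = np.array([[0.0, 10.0], [1.0, 20.0], [2.0, 30.0], [3.0, 40.0]])
        thr = fit_median_quantizer(X)
        metric = DistanceMetric("hamming", hamming_thresholds=thr)
        # rows 0 and 3 disagree in both binarized coordinates
        assert distance(X[0], X[3], metric) == 2.0
        assert distance(X[0], X[1], metric) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=(3, 5))
        for metric in ALL_METRICS:
            dxy = distance(x, y, metric)
            assert dxy >= 0
            assert dxy == pytest.approx(distance(y, x, metric))
            assert distance(x, x, metric) == pytest.approx(0.0)
            if metric.kind != "hamming":  # triangle inequality for Lp family
                assert dxy <= (
                    distance(x, z, metric) + distance(z, y, metric) + 1e-9
                )

    def test_pairwise_matches_scalar(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 4))
        for metric in ALL_METRICS:
            full = pairwise_distances(X, metric)
            for i, j in itertools.combinations(range(8), 2):
                assert full[i, j] == pytest.approx(
                    distance(X[i], X[j], metric), abs=1e-9
                )


def _brute_force_ksu_pairs(X, assignment, retained, need, metric):
    """O(n^2) oracle: all intra-cluster pairs, ascending (d, i, j),
    greedy disjoint selection of `need` pairs."""
    pairs = []
    rows = sorted(retained)
    for i, j in itertools.combinations(rows, 2):
        if assignment[i] == assignment[j]:
            pairs.append((distance(X[i], X[j], metric), i, j))
    pairs.sort()
    used, chosen = set(), []
    for d, i, j in pairs:
        if i in used or j in used:
            continue
        chosen.append((i, j))
        used.update((i, j))
        if len(chosen) == need:
            break
    return chosen


class TestKsuPairs:
    def test_exact_duplicate_removed_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.zeros(20, dtype=int)
        y[:3] = 1  # minority; rows 3..19 are majority
        X[7] = X[3]  # plant a zero-distance duplicate pair in the majority
        cfg = ResampleConfig(
            n_clusters=1, target_majority_count=16, seed=5
        )
        result = ksu_pairs_undersample(X, y, cfg)
        assert len(result.removed_indices) == 1
        assert result.removed_indices[0] in (3, 7)

    def test_default_target_balances_one_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 6))
        y = np.array([1] * 20 + [0] * 100)
        result = ksu_pairs_undersample(X, y, ResampleConfig(seed=2))
        _, yb = result.apply(X, y)
        assert (yb == 0).sum() == (yb == 1).sum() == 20

    def test_partition_and_minority_preserved(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(90, 4))
        y = (rng.random(90) < 0.25).astype(int)
        result = ksu_pairs_undersample(X, y, ResampleConfig(seed=0))
        maj = np.flatnonzero(y == result.majority_label)
        minority = np.flatnonzero(y != result.majority_label)
        retained_maj = np.setdiff1d(result.retained_indices, minority)
        assert set(retained_maj) | set(result.removed_indices) == set(maj)
        assert not set(retained_maj) & set(result.removed_indices)
        assert set(minority) <= set(result.retained_indices)

    def test_selected_pairs_match_brute_force_oracle(self):
        # k=2 well-separated blobs, N=3: selection must equal the three
        # globally smallest intra-cluster distances
        rng = np.random.default_rng(7)
        X = np.vstack(
            [rng.normal(-10, 1, size=(30, 2)), rng.normal(10, 1, size=(30, 2))]
        )
        y = np.zeros(60, dtype=int)
        y[:5] = 1
        X[:5] = rng.normal(0, 0.1, size=(5, 2))
        maj = np.flatnonzero(y == 0)
        cfg = ResampleConfig(
            n_clusters=2, target_majority_count=len(maj) - 3, seed=11
        )
        result = ksu_pairs_undersample(X, y, cfg)
        # recover cluster assignment exactly as the implementation does
        from sklearn.cluster import KMeans

        assignment_arr = KMeans(2, random_state=11, n_init=10).fit_predict(X[maj])
        assignment = dict(zip(maj.tolist(), assignment_arr.tolist()))
        oracle = _brute_force_ksu_pairs(
            X, assignment, maj.tolist(), 3, cfg.metric
        )
        oracle_rows = {r for pair in oracle for r in pair}
        assert all(r in oracle_rows for r in result.removed_indices)
        assert len(result.removed_indices) == 3
        # one removal per oracle pair
        for a, b in oracle:
            assert (a in result.removed_indices) != (b in result.removed_indices)

    @pytest.mark.parametrize("seed", range(10))
    def test_single_round_equivalence_randomized(self, seed):
        rng = np.random.default_rng(seed)
        n_maj = int(rng.integers(20, 60))
        n_min = int(rng.integers(5, 10))
        need = int(rng.integers(1, n_maj // 3))
        X = rng.normal(size=(n_maj + n_min, 4))
        y = np.array([0] * n_maj + [1] * n_min)
        k = int(rng.integers(1, 4))
        metric = ALL_METRICS[seed % len(ALL_METRICS)]
        if metric.kind == "hamming":
            metric = DistanceMetric(
                "hamming", hamming_thresholds=fit_median_quantizer(X)
            )
        cfg = ResampleConfig(
            n_clusters=k,
            metric=metric,
            target_majority_count=n_maj - need,
            seed=seed,
        )
        result = ksu_pairs_undersample(X, y, cfg)
        from sklearn.cluster import KMeans

        maj = np.arange(n_maj)
        assignment_arr = KMeans(k, random_state=seed, n_init=10).fit_predict(X[maj])
        assignment = dict(zip(maj.tolist(), assignment_arr.tolist()))
        oracle = _brute_force_ksu_pairs(X, assignment, maj.tolist(), need, metric)
        assert len(result.removed_indices) == need
        for a, b in oracle:
            assert (a in result.removed_indices) != (b in result.removed_indices)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(80, 5))
        y = np.array([1] * 15 + [0] * 65)
        r1 = ksu_pairs_undersample(X, y, ResampleConfig(seed=42))
        r2 = ksu_pairs_undersample(X, y, ResampleConfig(seed=42))
        np.testing.assert_array_equal(r1.retained_indices, r2.retained_indices)
        np.testing.assert_array_equal(r1.removed_indices, r2.removed_indices)

    def test_target_too_large_rejected(self):
        X = np.zeros((10, 2))
        y = np.array([0] * 7 + [1] * 3)
        with pytest.raises(ValueError):
            ksu_pairs_undersample(
                X, y, ResampleConfig(target_majority_count=8)
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ksu_pairs_undersample(
                np.zeros((5, 2)), np.zeros(5, dtype=int), ResampleConfig()
            )


def _brute_force_enn(X, y, k_nn, metric):
    n = len(y)
    marked = []
    for i in range(n):
        dists = sorted(
            (distance(X[i], X[j], metric), j) for j in range(n) if j != i
        )
        neighbors = [j for _, j in dists[:k_nn]]
        if sum(y[j] != y[i] for j in neighbors) >= k_nn / 2:
            marked.append(i)
    return marked


class TestEnnEdit:
    def test_homogeneous_data_untouched(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.array([0] * 15 + [1] * 5)
        # make classes perfectly separated so no neighborhood disagrees
        X[y == 1] += 100.0
        result = enn_edit_undersample(X, y, k_nn=3)
        assert len(result.removed_indices) == 0

    def test_lone_majority_point_in_minority_cluster_removed(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(10, 0.5, (5, 2))])
        y = np.array([0] * 10 + [1] * 5)
        X[0] = [10.0, 10.0]  # majority point dropped inside minority blob
        result = enn_edit_undersample(X, y, k_nn=3)
        assert 0 in result.removed_indices

    def test_matches_exhaustive_oracle_on_interleaved_grid(self):
        xs, ys_ = np.meshgrid(np.arange(8), np.arange(5))
        X = np.column_stack([xs.ravel(), ys_.ravel()]).astype(float)
        y = ((xs + ys_) % 2).ravel()
        # make class 0 the majority by flipping two rows
        y[:2] = 0
        metric = DistanceMetric("euclidean")
        result = enn_edit_undersample(X, y, k_nn=5, metric=metric)
        marked = _brute_force_enn(X, y, 5, metric)
        maj = result.majority_label
        expected = sorted(i for i in marked if y[i] == maj)
        assert sorted(result.removed_indices.tolist()) == expected

    def test_k_nn_bounds(self):
        X = np.zeros((5, 2))
        y = np.array([0, 0, 0, 1, 1])
        with pytest.raises(ValueError):
            enn_edit_undersample(X, y, k_nn=5)
        with pytest.raises(ValueError):
            enn_edit_undersample(X, y, k_nn=0)


class TestGroupedUndersample:
    def test_single_group_matches_ungrouped(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = np.array([1] * 10 + [0] * 50)
        cfg = ResampleConfig(seed=3, n_clusters=2)
        grouped = grouped_undersample(X, y, ["d0"] * 60, cfg)
        _, yb = grouped.apply(X, y)
        assert (yb == 0).sum() == 10

    def test_two_equal_groups_split_evenly(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        y = np.array([1] * 10 + [0] * 40)
        groups = ["?"] * 10 + ["a"] * 20 + ["b"] * 20
        cfg = ResampleConfig(seed=1, target_majority_count=10, n_clusters=2)
        result = grouped_undersample(X, y, groups, cfg)
        assert result.diagnostics["group_quotas"] == {"a": 5, "b": 5}
        retained_maj = [i for i in result.retained_indices if y[i] == 0]
        assert len(retained_maj) == 10

    def test_largest_remainder_quotas(self):
        assert _largest_remainder_quotas({"a": 50, "b": 30, "c": 20}, 30) == {
            "a": 15, "b": 9, "c": 6,
        }

    def test_quota_capped_and_redistributed(self):
        # group 'tiny' cannot supply its proportional share
        quotas = _largest_remainder_quotas({"big": 98, "tiny": 2}, 60)
        assert quotas["tiny"] <= 2
        assert sum(quotas.values()) == 60

    def test_global_target_met_exactly_with_uneven_groups(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(110, 4))
        y = np.array([1] * 10 + [0] * 100)
        groups = ["?"] * 10 + ["a"] * 50 + ["b"] * 30 + ["c"] * 20
        cfg = ResampleConfig(seed=2, target_majority_count=30)
        result = grouped_undersample(X, y, groups, cfg)
        retained_maj = [i for i in result.retained_indices if y[i] == 0]
        assert len(retained_maj) == 30
        assert result.diagnostics["group_quotas"] == {"a": 15, "b": 9, "c": 6}


from sklearn.base import BaseEstimator, ClassifierMixin


class _StubProbe(ClassifierMixin, BaseEstimator):
    """Probe whose CV AUC is driven by feature 0 only."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        s = 1 / (1 + np.exp(-X[:, 0]))
        return np.column_stack([1 - s, s])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class TestAdaptiveMetricSelect:
    def test_single_candidate_returned_with_score(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 4))
        X[:, 0] += 2.0 * np.r_[np.ones(20), -np.ones(60)]
        y = np.array([1] * 20 + [0] * 60)
        metric, table = adaptive_metric_select(
            X, y, metrics=[DistanceMetric("euclidean")],
            probe_cv_folds=3, seed=1, probe_factory=_StubProbe,
        )
        assert metric.kind == "euclidean"
        assert len(table) == 1

    def test_score_table_contract_and_argmax(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 5))
        X[:, 0] += 3.0 * np.r_[np.ones(25), -np.ones(75)]
        y = np.array([1] * 25 + [0] * 75)
        metrics = candidate_metrics(X)
        best, table = adaptive_metric_select(
            X, y, metrics=metrics, probe_cv_folds=3, seed=2,
            probe_factory=_StubProbe,
        )
        assert len(table) == len(metrics)
        assert table["mean_cv_auc"].between(0, 1).all()
        assert best.kind == table.loc[table["mean_cv_auc"].idxmax(), "metric"]

    def test_tie_keeps_earlier_candidate(self):
        class ConstantProbe(_StubProbe):
            def predict_proba(self, X):
                return np.full((len(X), 2), 0.5)

        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = np.array([1] * 15 + [0] * 45)
        metrics = [DistanceMetric("chebyshev"), DistanceMetric("manhattan")]
        best, table = adaptive_metric_select(
            X, y, metrics=metrics, probe_cv_folds=3, seed=0,
            probe_factory=ConstantProbe,
        )
        assert best.kind == "chebyshev"
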