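"""LIME-style local explanations for individual predictions.

Around one instance, features are discretized into background quartile
bins and perturbed by resampling bins; the black-box scorer evaluates
the perturbations; a proximity-kernel-weighted ridge regression on the
binary same-bin-as-instance indicators (after forward selection down to
the displayed feature count) yields signed per-feature contributions
with human-readable threshold rules such as ``f3 <= -0.30``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BackgroundStats:
    """Quartile bins and per-bin moments of the training distribution."""

    bin_edges: np.ndarray  # (d, 3) 25/50/75th percentiles
    bin_means: np.ndarray  # (d, 4)
    bin_sds: np.ndarray  # (d, 4)
    feature_names: list[str] = field(default_factory=list)

    @staticmethod
    def from_matrix(
        X: np.ndarray, feature_names: list[str] | None = None
    ) -> "BackgroundStats":
        X = np.asarray(X, dtype=np.float64)
        d = X.shape[1]
        edges = np.percentile(X, [25, 50, 75], axis=0).T  # (d, 3)
        means = np.zeros((d, 4))
        sds = np.zeros((d, 4))
        for j in range(d):
            bins = np.digitize(X[:, j], edges[j])
            for b in range(4):
                vals = X[bins == b, j]
                if len(vals):
                    means[j, b] = vals.mean()
                    sds[j, b] = vals.std()
                else:  # empty bin (constant-ish feature): fall back
                    means[j, b] = X[:, j].mean()
                    sds[j, b] = X[:, j].std()
        return BackgroundStats(
            edges, means, sds, feature_names or [f"f{j}" for j in range(d)]
        )


@dataclass
class Explanation:
    instance_id: str
    feature_indices: np.ndarray
    contributions: np.ndarray  # signed, sorted by |magnitude| desc
    rules: list[str]
    intercept: float
    local_r2: float
    n_perturbations: int
    kernel_width: float
    seed: int
    degenerate: bool = False
    neighborhood: dict | None = None  # optional captured perturbation set

    def as_dict(self) -> dict:
        return {
            "instance_id": self.instance_id,
            "features": [
                {
                    "index": int(i),
                    "rule": r,
                    "contribution": float(c),
                }
                for i, r, c in zip(
                    self.feature_indices, self.rules, self.contributions
                )
            ],
            "intercept": self.intercept,
            "local_r2": self.local_r2,
            "n_perturbations": self.n_perturbations,
            "kernel_width": self.kernel_width,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def _rule_string(name: str, bin_idx: int, edges: np.ndarray) -> str:
    q1, q2, q3 = edges
    if bin_idx == 0:
        return f"{name} <= {q1:.2f}"
    if bin_idx == 1:
        return f"{q1:.2f} < {name} <= {q2:.2f}"
    if bin_idx == 2:
        return f"{q2:.2f} < {name} <= {q3:.2f}"
    return f"{name} > {q3:.2f}"


def _weighted_ridge(
    Z: np.ndarray, y: np.ndarray, w: np.ndarray, alpha: float = 1.0
) -> tuple[np.ndarray, float]:
    """Closed-form ridge with sample weights; returns (coef, intercept)."""
    Zb = np.column_stack([Z, np.ones(len(Z))])
    A = Zb.T @ (w[:, None] * Zb)
    reg = alpha * np.eye(Zb.shape[1])
    reg[-1, -1] = 0.0  # do not penalize the intercept
    beta = np.linalg.solve(A + reg, Zb.T @ (w * y))
    return beta[:-1], float(beta[-1])


def explain_instance(
    model_scorer,
    instance: np.ndarray,
    background_stats: BackgroundStats,
    n_perturbations: int = 5000,
    kernel_width: float | None = None,
    n_features_shown: int = 25,
    seed: int = 0,
    instance_id: str = "instance",
    alpha: float = 1.0,
    capture_neighborhood: bool = False,
) -> Explanation:
    """Explain ``model_scorer(instance)`` by a local weighted surrogate.

    ``model_scorer`` maps an (n, d) array to positive-class probabilities.
    Perturbations resample each feature's quartile bin uniformly and draw
    a value from that bin's background moments; proximity weights are
    exp(-d^2 / width^2) on the binary same-bin representation.
    """
    x = np.asarray(instance, dtype=np.float64)
    d = len(x)
    stats = background_stats
    n_features_shown = min(n_features_shown, d)
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d)
    rng = np.random.default_rng(seed)

    inst_bins = np.array(
        [np.digitize(x[j], stats.bin_edges[j]) for j in range(d)]
    )
    bins = rng.integers(0, 4, size=(n_perturbations, d))
    bins[0] = inst_bins  # keep the instance itself in the neighborhood
    noise = rng.normal(size=(n_perturbations, d))
    values = (
        stats.bin_means[np.arange(d), bins]
        + noise * stats.bin_sds[np.arange(d), bins]
    )
    values[0] = x
    Z = (bins == inst_bins).astype(np.float64)  # binary representation

    dist = np.sqrt((1.0 - Z).sum(axis=1))
    weights = np.exp(-(dist**2) / kernel_width**2)
    y = np.asarray(model_scorer(values), dtype=np.float64)

    if np.ptp(y) < 1e-12:  # constant black box
        return Explanation(
            instance_id=instance_id,
            feature_indices=np.arange(n_features_shown),
            contributions=np.zeros(n_features_shown),
            rules=[
                _rule_string(
                    stats.feature_names[j], inst_bins[j], stats.bin_edges[j]
                )
                for j in range(n_features_shown)
            ],
            intercept=float(y[0]),
            local_r2=0.0,
            n_perturbations=n_perturbations,
            kernel_width=kernel_width,
            seed=seed,
            degenerate=True,
        )

    # forward selection on weighted ridge residual improvement
    selected: list[int] = []
    if n_features_shown < d:
        remaining = list(range(d))
        for _ in range(n_features_shown):
            best_j, best_err = None, np.inf
            for j in remaining:
                cols = selected + [j]
                coef, icpt = _weighted_ridge(Z[:, cols], y, weights, alpha)
                resid = y - (Z[:, cols] @ coef + icpt)
                err = float(np.sum(weights * resid**2))
                if err < best_err:
                    best_err, best_j = err, j
            selected.append(best_j)
            remaining.remove(best_j)
    else:
        selected = list(range(d))

    cols = np.array(selected)
    coef, intercept = _weighted_ridge(Z[:, cols], y, weights, alpha)
    fitted = Z[:, cols] @ coef + intercept
    ybar = np.average(y, weights=weights)
    ss_res = float(np.sum(weights * (y - fitted) ** 2))
    ss_tot = float(np.sum(weights * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    order = np.argsort(-np.abs(coef), kind="stable")
    idx = cols[order]
    neighborhood = (
        {"values": values, "scores": y, "weights": weights, "binary": Z}
        if capture_neighborhood
        else None
    )
    return Explanation(
        instance_id=instance_id,
        feature_indices=idx,
        contributions=coef[order],
        rules=[
            _rule_string(stats.feature_names[j], inst_bins[j], stats.bin_edges[j])
            for j in idx
        ],
        intercept=intercept,
        local_r2=r2,
        n_perturbations=n_perturbations,
        kernel_width=kernel_width,
        seed=seed,
        neighborhood=neighborhood,
    )
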