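"""Training-free one-shot classifier.

Fitting is a single analytic pass over the support set — no gradient
steps anywhere:

1. standardize: x_tilde = (x - mu) / sigma (sigma floored at 1e-8);
2. random nonlinear feature map: z = relu(x_tilde R + b) with a seeded
   Gaussian matrix R in R^{d x h} (an arc-cosine-kernel style random
   projection);
3. PCA: z' = (z - z_bar) W_k, W_k the top-k orthonormal eigenvectors of
   the support feature covariance;
4. weight generation from pooled support statistics: the two hidden
   layers of a 3-layer residual MLP get seeded Gaussian weights scaled
   by the global-average-pooled RMS of the support activations (so the
   map is well-conditioned for the support distribution), and the
   classification layer is built by class-wise mean pooling — class
   prototype weights with a bias placing the decision boundary on the
   perpendicular bisector of the prototypes.

Inference is a forward pass under these static weights followed by a
softmax. All pooling is order-invariant, so permuting support rows
leaves the generated weights unchanged (up to float summation noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SIGMA_FLOOR = 1e-8


@dataclass
class OneShotState:
    """Frozen parameters generated from one pass over the support set."""

    mu: np.ndarray
    sigma: np.ndarray
    R: np.ndarray
    b: np.ndarray
    z_mean: np.ndarray
    W_k: np.ndarray
    hidden_weights: list[np.ndarray]
    prototype_weights: np.ndarray  # (2, k) class prototypes
    prototype_bias: np.ndarray  # (2,)
    classes: np.ndarray
    seed: int = 0


@dataclass
class OneShotPrediction:
    logits: np.ndarray  # (n, 2)
    posterior: np.ndarray  # (n, 2) softmax rows


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _hidden_forward(state: OneShotState, z: np.ndarray) -> np.ndarray:
    h = z
    for W in state.hidden_weights:
        h = _relu(h @ W) + h  # residual connection
    return h


def fit_oneshot(
    support_features: np.ndarray,
    support_labels: np.ndarray,
    h: int = 1024,
    k_pca: int = 128,
    seed: int = 0,
) -> OneShotState:
    """Generate all network weights from the support set in one pass."""
    X = np.asarray(support_features, dtype=np.float64)
    y = np.asarray(support_labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("support set must contain exactly two classes")
    n, d = X.shape
    k_pca = min(k_pca, h, n)
    if k_pca < 1:
        raise ValueError("k_pca must be >= 1")

    mu = X.mean(axis=0)
    sigma = np.maximum(X.std(axis=0), SIGMA_FLOOR)
    X_tilde = (X - mu) / sigma

    rng = np.random.default_rng(seed)
    R = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, h))
    b = rng.normal(0.0, 0.1, size=h)
    Z = _relu(X_tilde @ R + b)

    z_mean = Z.mean(axis=0)
    Zc = Z - z_mean
    cov = (Zc.T @ Zc) / max(n - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    W_k = eigvecs[:, ::-1][:, :k_pca]  # descending eigenvalue order
    Zp = Zc @ W_k

    # hidden-layer generation: seeded Gaussian maps scaled by the
    # global-average-pooled RMS of the support activations
    hidden_weights = []
    h_cur = Zp
    for layer in range(2):
        rms = float(np.sqrt(np.mean(h_cur**2))) or 1.0
        G = rng.normal(0.0, 1.0, size=(k_pca, k_pca))
        W = G / (np.sqrt(k_pca) * rms)
        hidden_weights.append(W)
        h_cur = _relu(h_cur @ W) + h_cur

    # classification layer: class-wise mean pooling + bisecting bias
    protos = np.stack([h_cur[y == c].mean(axis=0) for c in classes])
    bias = -0.5 * np.sum(protos**2, axis=1)

    return OneShotState(
        mu=mu,
        sigma=sigma,
        R=R,
        b=b,
        z_mean=z_mean,
        W_k=W_k,
        hidden_weights=hidden_weights,
        prototype_weights=protos,
        prototype_bias=bias,
        classes=classes,
        seed=seed,
    )


def predict_oneshot(
    state: OneShotState, query_features: np.ndarray
) -> OneShotPrediction:
    """Forward pass under the static generated weights, then softmax."""
    X = np.asarray(query_features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != len(state.mu):
        raise ValueError(
            f"query feature dimension {X.shape} incompatible with "
            f"fitted dimension {len(state.mu)}"
        )
    X_tilde = (X - state.mu) / state.sigma
    Z = _relu(X_tilde @ state.R + state.b)
    Zp = (Z - state.z_mean) @ state.W_k
    h_out = _hidden_forward(state, Zp)
    logits = h_out @ state.prototype_weights.T + state.prototype_bias
    shifted = logits - logits.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    posterior = expd / expd.sum(axis=1, keepdims=True)
    return OneShotPrediction(logits=logits, posterior=posterior)


class OneShotClassifier:
    """Scikit-learn style wrapper used as a stacking base learner."""

    def __init__(self, h: int = 1024, k_pca: int = 128, seed: int = 0):
        self.h = h
        self.k_pca = k_pca
        self.seed = seed
        self.state_: OneShotState | None = None

    def get_params(self, deep: bool = True) -> dict:
        return {"h": self.h, "k_pca": self.k_pca, "seed": self.seed}

    def set_params(self, **params):
        for key, val in params.items():
            setattr(self, key, val)
        return self

    def fit(self, X, y):
        self.state_ = fit_oneshot(X, y, h=self.h, k_pca=self.k_pca, seed=self.seed)
        self.classes_ = self.state_.classes
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.state_ is None:
            raise RuntimeError("classifier not fitted")
        return predict_oneshot(self.state_, X).posterior

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
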