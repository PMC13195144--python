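"""Small graph convolutional network for graph-level classification.

Pure-numpy implementation with explicit backpropagation and Adam, sized
for 13-node connectomes: two graph-convolution layers (tanh, 16 and 32
channels) over the symmetrically normalized adjacency with self-loops,
global mean pooling, dropout on the pooled (standardized) graph
representation, and a two-layer perceptron with a sigmoid head. Node features are identical constants, so
the model learns from topology alone.

Because the normalized adjacency has near-constant row sums, the pooled
graph representation varies only at the 1e-3 scale between graphs, which
leaves gradient descent on a long plateau at the base-rate solution. The
pooled vector is therefore standardized (no learned affine) with training
batch statistics; the statistics are frozen into the parameters for
inference. With all trainable weights zero the pooled vector is constant,
its standardization is zero and the output is exactly sigmoid(0) = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import child_rng

__all__ = ["GCNConfig", "normalize_adjacency", "init_params", "gcn_forward", "train_gcn", "predict"]

_WEIGHT_KEYS = ("W1", "W2", "W3", "W4")


@dataclass(frozen=True)
class GCNConfig:
    channels: tuple[int, int] = (16, 32)
    mlp_units: tuple[int, int] = (32, 1)
    l2_lambda: float = 5e-4
    dropout: float = 0.4
    epochs: int = 200
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.mlp_units[1] != 1:
            raise ValueError("final MLP unit must be 1 (sigmoid head)")


def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """D^(-1/2) (A + I) D^(-1/2) with self-loops; requires symmetry."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-9):
        raise ValueError("adjacency must be symmetric")
    if np.any(a < 0):
        raise ValueError("adjacency entries must be >= 0")
    a_hat = a + np.eye(len(a))
    d = a_hat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return a_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


def init_params(config: GCNConfig) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases, seeded."""
    rng = child_rng(config.seed, "gcn-init")
    c1, c2 = config.channels
    m1, _ = config.mlp_units

    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return {
        "W1": glorot(1, c1),
        "b1": np.zeros(c1),
        "W2": glorot(c1, c2),
        "b2": np.zeros(c2),
        "W3": glorot(c2, m1),
        "b3": np.zeros(m1),
        "W4": glorot(m1, 1),
        "b4": np.zeros(1),
    }


_BN_EPS = 1e-8


def _forward(a_hat: np.ndarray, params: dict, dmask: np.ndarray | None, training: bool):
    """Batched forward pass; a_hat has shape (B, n, n).

    In training mode the pooled vector is standardized with batch
    statistics; at inference the frozen ``bn_mean`` / ``bn_var`` buffers
    stored in ``params`` are used instead.
    """
    b, n, _ = a_hat.shape
    ah0 = a_hat.sum(axis=2, keepdims=True)  # A_hat @ ones
    h1 = np.tanh(ah0 @ params["W1"] + params["b1"])
    m1 = a_hat @ h1
    h2 = np.tanh(m1 @ params["W2"] + params["b2"])
    pool = h2.mean(axis=1)
    if training:
        mu = pool.mean(axis=0)
        var = float(pool.var(axis=0).mean())
    else:
        mu = params.get("bn_mean", np.zeros(pool.shape[1]))
        var = float(params.get("bn_var", np.ones(1))[0])
    # single shared scale: per-channel scaling would blow up the
    # low-variance channels and swamp edge-ablation saliency with noise
    inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (pool - mu) * inv_sd
    xdrop = xhat if dmask is None else xhat * dmask
    u = np.tanh(xdrop @ params["W3"] + params["b3"])
    z = u @ params["W4"] + params["b4"]
    prob = 1.0 / (1.0 + np.exp(-z))
    cache = (ah0, h1, m1, h2, dmask, pool, xhat, xdrop, inv_sd, u)
    return prob, cache


def gcn_forward(adjacency: np.ndarray, params: dict) -> float:
    """Inference probability for one graph (dropout off, frozen stats)."""
    a_hat = normalize_adjacency(adjacency)[None]
    prob, _ = _forward(a_hat, params, None, training=False)
    return float(prob[0, 0])


def _backward(a_hat, params, cache, prob, y, l2):
    ah0, h1, m1, h2, dmask, pool, xhat, xdrop, inv_sd, u = cache
    b, n, _ = a_hat.shape
    grads = {}
    dz = (prob - y[:, None]) / b
    grads["W4"] = u.T @ dz + 2 * l2 * params["W4"]
    grads["b4"] = dz.sum(axis=0)
    du = dz @ params["W4"].T
    dz3 = du * (1 - u**2)
    grads["W3"] = xdrop.T @ dz3 + 2 * l2 * params["W3"]
    grads["b3"] = dz3.sum(axis=0)
    dxdrop = dz3 @ params["W3"].T
    dxhat = dxdrop if dmask is None else dxdrop * dmask
    # batch-norm backward (no affine, per-channel mean, shared variance)
    c2 = xhat.shape[1]
    dpool = inv_sd * (
        dxhat
        - dxhat.mean(axis=0)
        - xhat * float((dxhat * xhat).sum()) / (b * c2)
    )
    dh2 = np.repeat(dpool[:, None, :] / n, n, axis=1)
    dz2 = dh2 * (1 - h2**2)
    grads["W2"] = np.einsum("bnc,bnd->cd", m1, dz2) + 2 * l2 * params["W2"]
    grads["b2"] = dz2.sum(axis=(0, 1))
    dm1 = dz2 @ params["W2"].T
    dh1 = a_hat @ dm1  # a_hat symmetric
    dz1 = dh1 * (1 - h1**2)
    grads["W1"] = np.einsum("bnc,bnd->cd", ah0, dz1) + 2 * l2 * params["W1"]
    grads["b1"] = dz1.sum(axis=(0, 1))
    return grads


def _loss(prob: np.ndarray, y: np.ndarray, params: dict, l2: float) -> float:
    eps = 1e-12
    p = np.clip(prob[:, 0], eps, 1 - eps)
    bce = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return bce + l2 * sum(float(np.sum(params[k] ** 2)) for k in _WEIGHT_KEYS)


def train_gcn(
    adjacencies: list[np.ndarray], labels: np.ndarray, config: GCNConfig
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Fixed-epoch full-batch Adam training; returns (params, loss curve).

    Binary cross-entropy (the two-class case of categorical cross-entropy
    with a single sigmoid unit) plus L2 weight penalty; no validation
    split. Seeded init and dropout masks make training deterministic.
    """
    y = np.asarray(labels, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    a_hat = np.stack([normalize_adjacency(a) for a in adjacencies])
    b, n, _ = a_hat.shape
    params = init_params(config)
    drop_rng = child_rng(config.seed, "gcn-dropout")
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(val) for k, val in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    losses = []
    for t in range(1, config.epochs + 1):
        if config.dropout > 0:
            keep = drop_rng.random((b, config.channels[1])) >= config.dropout
            dmask = keep / (1.0 - config.dropout)
        else:
            dmask = None
        prob, cache = _forward(a_hat, params, dmask, training=True)
        losses.append(_loss(prob, y, params, config.l2_lambda))
        grads = _backward(a_hat, params, cache, prob, y, config.l2_lambda)
        for k in grads:
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
            m_hat = m[k] / (1 - beta1**t)
            v_hat = v[k] / (1 - beta2**t)
            params[k] = params[k] - config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
    # freeze pooled-feature statistics of the training set for inference
    _, cache = _forward(a_hat, params, None, training=True)
    pool = cache[5]
    params["bn_mean"] = pool.mean(axis=0)
    params["bn_var"] = np.array([pool.var(axis=0).mean()])
    return params, losses


def predict(params: dict, adjacencies: list[np.ndarray]) -> np.ndarray:
    """Batch inference probabilities (dropout off, frozen stats)."""
    a_hat = np.stack([normalize_adjacency(a) for a in adjacencies])
    prob, _ = _forward(a_hat, params, None, training=False)
    return prob[:, 0]
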