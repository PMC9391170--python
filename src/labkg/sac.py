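"""Self-attention + convolutional classifier over patient relation matrices.

The network reads the k x m relation matrix of a patient (one column per
lab indicator) and predicts a binary disease label:

1. two stacked single-head self-attention layers let every indicator's
   column attend to all others: Q = w_q E, K = w_k E, V = w_v E, and the
   layer output is V softmax(K'Q / sqrt(D_k)) with the softmax normalizing
   each column, so output columns are convex combinations of V's columns;
2. a bank of 1-D convolution filters with window sizes {2, 3, 4} (100
   filters each) slides over the m columns; each filter's relu feature map
   is max-pooled to one scalar, giving a 300-long vector Z;
3. dropout on Z, then an affine layer to two scores and a softmax,
   trained with mean cross-entropy by Adam.

The whole network, including backpropagation, is implemented in NumPy;
the analytic gradients are validated against numerical differentiation in
the test suite.  The first attention layer's m x m weight matrix, averaged
over a cohort, is exportable for interpretability: row i shows how much
query indicator i attends to each other indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._optim import Adam

__all__ = [
    "SACConfig",
    "AttentionLayerParams",
    "ConvParams",
    "Prediction",
    "SACModel",
    "attention_layer",
    "stack_attention",
    "conv_pool",
    "predict",
    "cross_entropy",
    "train_classifier",
    "export_attention",
]

_EPS = 1e-7  # probability clamp inside the cross-entropy


@dataclass(frozen=True)
class SACConfig:
    """Classifier hyperparameters.

    ``dim_k`` is the embedding (input-row) dimension; attention query/value
    dimensions equal ``dim_k`` so the two layers compose.  Defaults: Adam,
    batch 32, 100 epochs, dropout 0.5, learning rate 2e-4, windows
    {2, 3, 4} x 100 filters, 2 attention layers.
    """

    dim_k: int = 256
    n_attn_layers: int = 2
    window_sizes: tuple[int, ...] = (2, 3, 4)
    filters_per_window: int = 100
    dropout: float = 0.5
    learning_rate: float = 2e-4
    batch_size: int = 32
    epochs: int = 100
    init_scale: float = 0.1
    seed: int = 0

    @property
    def n_features(self) -> int:
        return len(self.window_sizes) * self.filters_per_window


@dataclass
class AttentionLayerParams:
    """One self-attention layer's projection tables (q x k each)."""

    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray


@dataclass
class ConvParams:
    """Convolution bank: per window size h, weights (F, h, d) and bias (F,)."""

    window_sizes: tuple[int, ...]
    filters_per_window: int
    weights: dict[int, np.ndarray] = field(default_factory=dict)
    biases: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class Prediction:
    """Output-layer result: raw scores s and softmax probabilities p."""

    scores: np.ndarray
    probs: np.ndarray


# ---------------------------------------------------------------------------
# Forward pieces (public single-sample ops wrap the batched internals)
# ---------------------------------------------------------------------------

def _attn_forward(X: np.ndarray, wq: np.ndarray, wk: np.ndarray, wv: np.ndarray):
    """Batched attention layer: X (B, k, m) -> output (B, v, m)."""
    Q = np.einsum("qk,bkm->bqm", wq, X)
    K = np.einsum("qk,bkm->bqm", wk, X)
    V = np.einsum("vk,bkm->bvm", wv, X)
    dk = wq.shape[0]
    S = np.einsum("bqi,bqj->bij", K, Q) / np.sqrt(dk)  # S[i, j] = k_i . q_j
    S = S - S.max(axis=1, keepdims=True)
    expS = np.exp(S)
    A = expS / expS.sum(axis=1, keepdims=True)  # columns sum to 1
    O = np.einsum("bvi,bij->bvj", V, A)
    return O, (X, Q, K, V, A)


def _attn_backward(dO: np.ndarray, cache, wq, wk, wv):
    X, Q, K, V, A = cache
    dk = wq.shape[0]
    dV = np.einsum("bvj,bij->bvi", dO, A)
    dA = np.einsum("bvi,bvj->bij", V, dO)
    dS = A * (dA - (A * dA).sum(axis=1, keepdims=True))
    dS = dS / np.sqrt(dk)
    dQ = np.einsum("bij,bqi->bqj", dS, K)
    dK = np.einsum("bij,bqj->bqi", dS, Q)
    dX = (
        np.einsum("qk,bqm->bkm", wq, dQ)
        + np.einsum("qk,bqm->bkm", wk, dK)
        + np.einsum("vk,bvm->bkm", wv, dV)
    )
    dwq = np.einsum("bqm,bkm->qk", dQ, X)
    dwk = np.einsum("bqm,bkm->qk", dK, X)
    dwv = np.einsum("bvm,bkm->vk", dV, X)
    return dX, dwq, dwk, dwv


def _conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray, h: int):
    """One window size: X (B, d, m), W (F, h, d) -> pooled (B, F)."""
    B, d, m = X.shape
    if m < h:
        raise ValueError(f"need at least {h} columns, got {m}")
    P = m - h + 1
    # windows of h consecutive columns, flattened position-major to match W
    Xw = np.stack([X[:, :, p : p + h].transpose(0, 2, 1) for p in range(P)], axis=1)
    Xw = Xw.reshape(B, P, h * d)
    Wf = W.reshape(W.shape[0], h * d)
    Cpre = Xw @ Wf.T + b  # (B, P, F)
    C = np.maximum(Cpre, 0.0)
    amax = C.argmax(axis=1)  # (B, F), first max wins -> deterministic
    Z = np.take_along_axis(C, amax[:, None, :], axis=1)[:, 0, :]
    return Z, (Xw, Cpre, amax, h, d, P)


def _conv_backward(dZ: np.ndarray, cache, W: np.ndarray):
    Xw, Cpre, amax, h, d, P = cache
    B = Xw.shape[0]
    F = W.shape[0]
    Wf = W.reshape(F, h * d)
    dC = np.zeros((B, P, F))
    np.put_along_axis(dC, amax[:, None, :], dZ[:, None, :], axis=1)
    dCpre = dC * (Cpre > 0)
    dW = np.einsum("bpf,bpx->fx", dCpre, Xw).reshape(F, h, d)
    db = dCpre.sum(axis=(0, 1))
    dXw = np.einsum("bpf,fx->bpx", dCpre, Wf).reshape(B, P, h, d)
    m = P + h - 1
    dX = np.zeros((B, d, m))
    for p in range(P):
        dX[:, :, p : p + h] += dXw[:, p].transpose(0, 2, 1)
    return dX, dW, db


def _softmax_rows(s: np.ndarray) -> np.ndarray:
    z = s - s.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# -- public single-sample operations ----------------------------------------

def attention_layer(E: np.ndarray, layer: AttentionLayerParams) -> np.ndarray:
    """Apply one self-attention layer to a single k x m relation matrix."""
    if E.ndim != 2 or layer.w_q.shape[1] != E.shape[0]:
        raise ValueError(f"shape mismatch: E {E.shape}, w_q {layer.w_q.shape}")
    O, _ = _attn_forward(E[None], layer.w_q, layer.w_k, layer.w_v)
    return O[0]


def stack_attention(E: np.ndarray, layers: list[AttentionLayerParams]) -> np.ndarray:
    """Compose the attention layers (no residuals, no normalization)."""
    H = E
    for layer in layers:
        H = attention_layer(H, layer)
    return H


def conv_pool(E_attn: np.ndarray, conv: ConvParams) -> np.ndarray:
    """Multi-window convolution + max-pooling of a single d x m matrix.

    Returns Z, the concatenation of each filter's max-pooled relu feature
    map, in window-then-filter order (length = #windows x filters).
    """
    m = E_attn.shape[1]
    if m < max(conv.window_sizes):
        raise ValueError(f"m={m} smaller than max window {max(conv.window_sizes)}")
    parts = []
    for h in conv.window_sizes:
        Z, _ = _conv_forward(E_attn[None], conv.weights[h], conv.biases[h], h)
        parts.append(Z[0])
    return np.concatenate(parts)


def predict(Z: np.ndarray, fc_w: np.ndarray, fc_b: np.ndarray) -> Prediction:
    """Affine map of Z to two class scores, softmax to probabilities."""
    if fc_w.shape[1] != Z.shape[0]:
        raise ValueError(f"fc expects {fc_w.shape[1]} features, got {Z.shape[0]}")
    s = fc_w @ Z + fc_b
    return Prediction(scores=s, probs=_softmax_rows(s))


def cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = _EPS) -> float:
    """Mean binary cross-entropy of predicted positive-class probabilities
    p against labels y, with p clamped to [eps, 1-eps]."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("p and y must have equal lengths")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

def _init_model_params(config: SACConfig, rng: np.random.Generator,
                       n_entities: int | None = None) -> dict[str, np.ndarray]:
    s = config.init_scale
    k = config.dim_k
    params: dict[str, np.ndarray] = {}
    for layer in range(config.n_attn_layers):
        for name in ("wq", "wk", "wv"):
            params[f"attn{layer}_{name}"] = rng.uniform(-s, s, size=(k, k))
    for h in config.window_sizes:
        params[f"conv{h}_w"] = rng.uniform(-s, s, size=(config.filters_per_window, h, k))
        params[f"conv{h}_b"] = np.zeros(config.filters_per_window)
    params["fc_w"] = rng.uniform(-s, s, size=(2, config.n_features))
    params["fc_b"] = np.zeros(2)
    if n_entities is not None:
        params["emb"] = rng.uniform(-s, s, size=(n_entities, k))
    return params


def _forward(params: dict[str, np.ndarray], X: np.ndarray, config: SACConfig,
             drop_mask: np.ndarray | None = None):
    """Full forward pass.  X is (B, k, m) floats, or (B, m) entity ids when
    the model owns a learned embedding table."""
    ids = None
    if X.ndim == 2 and np.issubdtype(X.dtype, np.integer):
        ids = X
        X = params["emb"][ids].transpose(0, 2, 1)
    attn_caches = []
    H = X
    for layer in range(config.n_attn_layers):
        H, cache = _attn_forward(
            H, params[f"attn{layer}_wq"], params[f"attn{layer}_wk"], params[f"attn{layer}_wv"]
        )
        attn_caches.append(cache)
    conv_caches = {}
    parts = []
    for h in config.window_sizes:
        Zh, cache = _conv_forward(H, params[f"conv{h}_w"], params[f"conv{h}_b"], h)
        conv_caches[h] = cache
        parts.append(Zh)
    Z = np.concatenate(parts, axis=1)
    Zd = Z * drop_mask if drop_mask is not None else Z
    logits = Zd @ params["fc_w"].T + params["fc_b"]
    return logits, (ids, attn_caches, conv_caches, Zd, drop_mask)


def _backward(params: dict[str, np.ndarray], config: SACConfig, cache, dlogits):
    ids, attn_caches, conv_caches, Zd, drop_mask = cache
    grads: dict[str, np.ndarray] = {}
    grads["fc_w"] = dlogits.T @ Zd
    grads["fc_b"] = dlogits.sum(axis=0)
    dZd = dlogits @ params["fc_w"]
    dZ = dZd * drop_mask if drop_mask is not None else dZd
    F = config.filters_per_window
    dH = None
    for i, h in enumerate(config.window_sizes):
        dZh = dZ[:, i * F : (i + 1) * F]
        dXh, dW, db = _conv_backward(dZh, conv_caches[h], params[f"conv{h}_w"])
        grads[f"conv{h}_w"] = dW
        grads[f"conv{h}_b"] = db
        dH = dXh if dH is None else dH + dXh
    for layer in reversed(range(config.n_attn_layers)):
        dH, dwq, dwk, dwv = _attn_backward(
            dH, attn_caches[layer],
            params[f"attn{layer}_wq"], params[f"attn{layer}_wk"], params[f"attn{layer}_wv"],
        )
        grads[f"attn{layer}_wq"] = dwq
        grads[f"attn{layer}_wk"] = dwk
        grads[f"attn{layer}_wv"] = dwv
    if ids is not None:
        demb = np.zeros_like(params["emb"])
        np.add.at(demb, ids, dH.transpose(0, 2, 1))
        grads["emb"] = demb
    return grads, dH


def loss_and_grads(params: dict[str, np.ndarray], X: np.ndarray, y: np.ndarray,
                   config: SACConfig, drop_mask: np.ndarray | None = None):
    """Mean cross-entropy and its analytic gradients for one batch."""
    logits, cache = _forward(params, X, config, drop_mask)
    probs = _softmax_rows(logits)
    loss = cross_entropy(probs[:, 1], y)
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(y)), y.astype(int)] = 1.0
    dlogits = (probs - onehot) / len(y)
    grads, _ = _backward(params, config, cache, dlogits)
    return loss, grads


@dataclass
class SACModel:
    """Trained classifier: parameter dict, config, and loss history."""

    config: SACConfig
    params: dict[str, np.ndarray]
    history: dict[str, list[float]] = field(default_factory=dict)
    trained: bool = False

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = _forward(self.params, X, self.config)
        return _softmax_rows(logits)

    def predict_label(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)

    def attention_layers(self) -> list[AttentionLayerParams]:
        return [
            AttentionLayerParams(
                w_q=self.params[f"attn{i}_wq"],
                w_k=self.params[f"attn{i}_wk"],
                w_v=self.params[f"attn{i}_wv"],
            )
            for i in range(self.config.n_attn_layers)
        ]

    def conv_params(self) -> ConvParams:
        return ConvParams(
            window_sizes=self.config.window_sizes,
            filters_per_window=self.config.filters_per_window,
            weights={h: self.params[f"conv{h}_w"] for h in self.config.window_sizes},
            biases={h: self.params[f"conv{h}_b"] for h in self.config.window_sizes},
        )


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    config: SACConfig = SACConfig(),
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    n_entities: int | None = None,
) -> SACModel:
    """Train the attention/CNN classifier with Adam.

    ``X`` is either an (n, k, m) float tensor of relation matrices, or an
    (n, m) integer matrix of entity ids when ``n_entities`` is given (the
    learned-embedding ablation: the model then owns an embedding table
    trained jointly with the classifier).  Dropout is applied to Z before
    the output layer during training only.  Per-epoch mean training loss
    (and, when ``validation`` is given, held-out loss) is recorded in the
    returned model's history.  Deterministic given ``config.seed``.
    """
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"training labels contain a single class ({classes.tolist()}); "
            "need both diseased and healthy examples"
        )
    rng = np.random.default_rng(config.seed)
    params = _init_model_params(config, rng, n_entities=n_entities)
    opt = Adam(params, config.learning_rate)
    n = len(y)
    keep = 1.0 - config.dropout
    history: dict[str, list[float]] = {"train_loss": []}
    if validation is not None:
        history["val_loss"] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, yb = X[idx], y[idx]
            mask = None
            if config.dropout > 0:
                mask = (rng.random((len(idx), config.n_features)) < keep) / keep
            loss, grads = loss_and_grads(params, Xb, yb, config, mask)
            opt.step(params, grads)
            batch_losses.append(loss)
        history["train_loss"].append(float(np.mean(batch_losses)))
        if validation is not None:
            Xv, yv = validation
            lv, _ = _forward(params, Xv, config)
            history["val_loss"].append(cross_entropy(_softmax_rows(lv)[:, 1], yv))
    return SACModel(config=config, params=params, history=history,
                    trained=config.epochs > 0)


def export_attention(
    model: SACModel,
    X: np.ndarray,
    indicator_names: list[str] | None = None,
) -> pd.DataFrame:
    """Mean first-layer attention weights over a dataset.

    Returns an m x m table whose row i gives how much query indicator i
    attends to each indicator; every row sums to 1.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    H = X
    if X.ndim == 2 and np.issubdtype(X.dtype, np.integer):
        H = model.params["emb"][X].transpose(0, 2, 1)
    _, cache = _attn_forward(
        H, model.params["attn0_wq"], model.params["attn0_wk"], model.params["attn0_wv"]
    )
    A = cache[4]  # (B, m, m), columns sum to 1; column j = query j
    W = A.transpose(0, 2, 1).mean(axis=0)  # row = query indicator
    if indicator_names is None:
        indicator_names = [str(i) for i in range(W.shape[0])]
    return pd.DataFrame(W, index=indicator_names, columns=indicator_names)
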