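"""A small, fully deterministic gated-attention multilayer perceptron.

The network learns an elementwise input gate over the gene dimension,
``g = sigmoid(x·W_g + b_g)``, and feeds the gated input ``x ⊙ g`` into a
ReLU MLP trunk with dropout and a softmax head.  The gate lets the model
down-weight uninformative genes early, which is the attention variant used
throughout this package; setting ``attention=False`` yields a plain MLP.

Everything — initialization, minibatch shuffling, dropout masks and the
validation split for early stopping — draws from one ``numpy`` Generator,
so training is bit-reproducible given (data, config, seed).  Optimization
is Adam on the weighted cross-entropy.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

Weights = Dict[str, np.ndarray]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_weights(
    n_features: int,
    hidden_sizes: List[int],
    n_classes: int,
    attention: bool,
    rng: np.random.Generator,
) -> Weights:
    weights: Weights = {}
    if attention:
        weights["gate_W"] = _glorot(rng, n_features, n_features)
        weights["gate_b"] = np.zeros(n_features)
    prev = n_features
    for i, h in enumerate(hidden_sizes):
        weights[f"layer{i}_W"] = _glorot(rng, prev, h)
        weights[f"layer{i}_b"] = np.zeros(h)
        prev = h
    weights["out_W"] = _glorot(rng, prev, n_classes)
    weights["out_b"] = np.zeros(n_classes)
    return weights


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def n_hidden_layers(weights: Weights) -> int:
    return sum(1 for k in weights if k.startswith("layer") and k.endswith("_W"))


def forward(
    weights: Weights,
    x: np.ndarray,
    dropout: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, dict]:
    """Forward pass; returns class probabilities and the cache for backprop.

    Dropout is applied (inverted scaling) only when ``dropout > 0`` and an
    ``rng`` is supplied, i.e. during training.
    """
    cache: dict = {"x": x}
    if "gate_W" in weights:
        pre_gate = x @ weights["gate_W"] + weights["gate_b"]
        gate = _sigmoid(pre_gate)
        h = x * gate
        cache["gate"] = gate
    else:
        h = x
    cache["h0_in"] = h
    n_layers = n_hidden_layers(weights)
    for i in range(n_layers):
        u = h @ weights[f"layer{i}_W"] + weights[f"layer{i}_b"]
        h = np.maximum(u, 0.0)
        if dropout > 0.0 and rng is not None:
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * mask
            cache[f"mask{i}"] = mask
        cache[f"u{i}"] = u
        cache[f"h{i}"] = h
    logits = h @ weights["out_W"] + weights["out_b"]
    probs = _softmax(logits)
    cache["probs"] = probs
    return probs, cache


def backward(
    weights: Weights,
    cache: dict,
    y_onehot: np.ndarray,
    sample_weight: np.ndarray,
) -> Weights:
    """Gradients of the weighted cross-entropy w.r.t. every parameter."""
    probs = cache["probs"]
    w = sample_weight / sample_weight.sum()
    dlogits = (probs - y_onehot) * w[:, None]
    grads: Weights = {}
    n_layers = n_hidden_layers(weights)
    h_prev = cache[f"h{n_layers - 1}"] if n_layers else cache["h0_in"]
    grads["out_W"] = h_prev.T @ dlogits
    grads["out_b"] = dlogits.sum(axis=0)
    dh = dlogits @ weights["out_W"].T
    for i in range(n_layers - 1, -1, -1):
        if f"mask{i}" in cache:
            dh = dh * cache[f"mask{i}"]
        du = dh * (cache[f"u{i}"] > 0)
        h_in = cache[f"h{i - 1}"] if i > 0 else cache["h0_in"]
        grads[f"layer{i}_W"] = h_in.T @ du
        grads[f"layer{i}_b"] = du.sum(axis=0)
        dh = du @ weights[f"layer{i}_W"].T
    if "gate_W" in weights:
        gate = cache["gate"]
        x = cache["x"]
        dgate = dh * x
        dpre = dgate * gate * (1.0 - gate)
        grads["gate_W"] = x.T @ dpre
        grads["gate_b"] = dpre.sum(axis=0)
    return grads


def cross_entropy(
    probs: np.ndarray, y_onehot: np.ndarray, sample_weight: np.ndarray
) -> float:
    w = sample_weight / sample_weight.sum()
    ll = np.log(np.maximum((probs * y_onehot).sum(axis=1), 1e-12))
    return float(-(w * ll).sum())


def train(
    x: np.ndarray,
    y_onehot: np.ndarray,
    hidden_sizes: List[int],
    attention: bool,
    dropout: float,
    learning_rate: float,
    max_epochs: int,
    batch_size: int,
    early_stop_patience: int,
    val_fraction: float,
    rng: np.random.Generator,
    class_weight: Optional[np.ndarray] = None,
) -> Tuple[Weights, int]:
    """Train the gated MLP with Adam and early stopping.

    A stratified ``val_fraction`` of the cells is held out; training stops
    when the validation loss has not improved for ``early_stop_patience``
    epochs and the best-scoring weights are restored.  Returns the weights
    and the number of epochs run.
    """
    n, n_features = x.shape
    n_classes = y_onehot.shape[1]
    labels = y_onehot.argmax(axis=1)
    sample_weight = (
        class_weight[labels] if class_weight is not None else np.ones(n)
    )

    # stratified validation split for early stopping
    val_idx: List[int] = []
    for c in range(n_classes):
        members = np.flatnonzero(labels == c)
        members = members[rng.permutation(members.size)]
        n_val = max(1, int(round(val_fraction * members.size))) if members.size > 1 else 0
        val_idx.extend(members[:n_val].tolist())
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    fit_idx = np.flatnonzero(~val_mask)
    xv, yv, wv = x[val_mask], y_onehot[val_mask], sample_weight[val_mask]

    weights = init_weights(n_features, hidden_sizes, n_classes, attention, rng)
    m_adam = {k: np.zeros_like(v) for k, v in weights.items()}
    v_adam = {k: np.zeros_like(v) for k, v in weights.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_loss = np.inf
    best_weights = {k: v.copy() for k, v in weights.items()}
    best_epoch = 0
    epochs_run = 0
    for epoch in range(max_epochs):
        epochs_run = epoch + 1
        order = fit_idx[rng.permutation(fit_idx.size)]
        for start in range(0, order.size, batch_size):
            batch = order[start : start + batch_size]
            probs, cache = forward(weights, x[batch], dropout=dropout, rng=rng)
            grads = backward(weights, cache, y_onehot[batch], sample_weight[batch])
            step += 1
            for k in weights:
                g = grads[k]
                m_adam[k] = beta1 * m_adam[k] + (1 - beta1) * g
                v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * g * g
                m_hat = m_adam[k] / (1 - beta1**step)
                v_hat = v_adam[k] / (1 - beta2**step)
                weights[k] -= learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        if xv.shape[0]:
            val_probs, _ = forward(weights, xv)
            val_loss = cross_entropy(val_probs, yv, wv)
        else:
            train_probs, _ = forward(weights, x)
            val_loss = cross_entropy(train_probs, y_onehot, sample_weight)
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_weights = {k: v.copy() for k, v in weights.items()}
            best_epoch = epoch
        elif epoch - best_epoch >= early_stop_patience:
            break
    return best_weights, epochs_run
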