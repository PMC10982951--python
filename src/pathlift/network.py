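"""The pathway-masked feed-forward network.

Every hidden layer's weight matrix ``W_i`` is shaped like a binary mask
``M_i`` compiled from the pathway hierarchy; the effective weight is the
elementwise product ``M_i * W_i``, applied at every forward call, so a
connection absent from the hierarchy can never carry signal regardless of
what training writes into the dead positions.  Masked layers use tanh; a
small MLP head (one tanh hidden layer, sigmoid output) maps the top pathway
layer to a recurrence probability.  Class imbalance is handled by a
class-weighted binary cross-entropy:

    Loss = 1/N sum_i -[ w1 * y_i * log(p_i) + w0 * (1 - y_i) * log(1 - p_i) ]

with inverse-frequency weights by default.  Training is full-batch Adam with
early stopping on a held-out validation split; everything is seeded and
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from ._optim import Adam
from .hierarchy import MaskStack

__all__ = [
    "MaskedNetParams",
    "TrainConfig",
    "init_params",
    "forward",
    "weighted_bce",
    "auto_class_weights",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-7


@dataclass
class MaskedNetParams:
    """Trainable weights of the masked network and its MLP head."""

    layer_weights: list[np.ndarray]   # one per mask, same shapes
    layer_biases: list[np.ndarray]    # one per mask, shape (n_out,)
    head_w1: np.ndarray               # top pathway layer -> hidden
    head_b1: np.ndarray
    head_w2: np.ndarray               # hidden -> logit, shape (hidden,)
    head_b2: float
    activation: str = "tanh"          # 'tanh' or 'identity' (diagnostics)

    def flat(self) -> list[np.ndarray]:
        return [*self.layer_weights, *self.layer_biases,
                self.head_w1, self.head_b1, self.head_w2,
                np.atleast_1d(np.asarray(self.head_b2, dtype=float))]

    def copy(self) -> "MaskedNetParams":
        return MaskedNetParams(
            [w.copy() for w in self.layer_weights],
            [b.copy() for b in self.layer_biases],
            self.head_w1.copy(), self.head_b1.copy(),
            self.head_w2.copy(), float(self.head_b2), self.activation,
        )


@dataclass
class TrainConfig:
    """Training hyper-parameters; defaults favour small, deterministic runs."""

    epochs: int = 100
    learning_rate: float = 1e-2
    optimizer: str = "adam"
    batch_size: int | None = None           # None = full batch
    class_weights: tuple[float, float] | str = "auto"
    seed: int = 0
    patience: int = 10                      # early-stopping patience, 0 disables
    val_fraction: float = 0.1
    hidden_width: int = 8

    def __post_init__(self) -> None:
        if isinstance(self.class_weights, tuple):
            w0, w1 = self.class_weights
            if w0 <= 0 or w1 <= 0:
                raise ValueError("class weights must be positive")


def _act(name: str) -> tuple[Callable, Callable]:
    if name == "tanh":
        return np.tanh, lambda z: 1.0 - np.tanh(z) ** 2
    if name == "identity":
        return (lambda z: z), (lambda z: np.ones_like(z))
    raise ValueError(f"unknown activation {name!r}")


def init_params(masks: MaskStack, seed: int = 0, hidden_width: int = 8,
                activation: str = "tanh") -> MaskedNetParams:
    """Glorot-uniform initialization on masked positions only, seed-controlled."""
    rng = np.random.default_rng(seed)
    ws, bs = [], []
    for m in masks.masks:
        n_in, n_out = m.shape
        limit = np.sqrt(6.0 / (n_in + n_out))
        w = rng.uniform(-limit, limit, size=m.shape) * m
        ws.append(w)
        bs.append(np.zeros(n_out))
    top = masks.masks[-1].shape[1]
    limit = np.sqrt(6.0 / (top + hidden_width))
    head_w1 = rng.uniform(-limit, limit, size=(top, hidden_width))
    head_w2 = rng.uniform(-np.sqrt(6.0 / (hidden_width + 1)),
                          np.sqrt(6.0 / (hidden_width + 1)), size=hidden_width)
    return MaskedNetParams(ws, bs, head_w1, np.zeros(hidden_width),
                           head_w2, 0.0, activation)


def forward(
    X: np.ndarray, masks: MaskStack, params: MaskedNetParams,
    return_intermediates: bool = False,
):
    """Masked forward pass: ``a_{i+1} = act((M_i * W_i)^T applied to a_i + b_i)``.

    Returns per-sample probabilities; with ``return_intermediates=True`` also
    a cache holding every pre-activation ``z`` and activation ``a`` (the
    attribution module consumes it).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != masks.input_mask.shape[0]:
        raise ValueError(
            f"input has {X.shape[1]} features, input mask expects {masks.input_mask.shape[0]}"
        )
    act, _ = _act(params.activation)
    zs, as_ = [], [X]
    a = X
    for k, (m, w, b) in enumerate(zip(masks.masks, params.layer_weights, params.layer_biases)):
        if w.shape != m.shape:
            raise ValueError(f"layer {k}: weight shape {w.shape} != mask shape {m.shape}")
        z = a @ (m * w) + b
        a = act(z)
        zs.append(z)
        as_.append(a)
    zh = a @ params.head_w1 + params.head_b1
    ah = act(zh)
    logit = ah @ params.head_w2 + params.head_b2
    prob = 1.0 / (1.0 + np.exp(-logit))
    if not return_intermediates:
        return prob
    cache = {"zs": zs, "as": as_, "zh": zh, "ah": ah, "logit": logit, "prob": prob}
    return prob, cache


def weighted_bce(y: np.ndarray, y_hat: np.ndarray, w0: float = 1.0, w1: float = 1.0) -> float:
    """Class-weighted binary cross-entropy (mean over samples)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    p = np.clip(y_hat, _EPS, 1.0 - _EPS)
    return float(np.mean(-(w1 * y * np.log(p) + w0 * (1.0 - y) * np.log(1.0 - p))))


def auto_class_weights(labels: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency class weights ``w_c = N / (2 * N_c)``."""
    y = np.asarray(labels).ravel()
    n = y.size
    n1 = int((y == 1).sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute class weights")
    return n / (2.0 * n0), n / (2.0 * n1)


def _backward(X, y, masks, params, cache, w0, w1):
    """Gradients of weighted_bce(forward(X)) w.r.t. all trainable arrays."""
    _, dact = _act(params.activation)
    n = X.shape[0]
    y = np.asarray(y, dtype=float).ravel()
    p = np.clip(cache["prob"], _EPS, 1.0 - _EPS)
    # d loss / d logit
    dt = (w0 * (1.0 - y) * p - w1 * y * (1.0 - p)) / n
    ah, zh = cache["ah"], cache["zh"]
    g_w2 = ah.T @ dt
    g_b2 = float(dt.sum())
    dah = np.outer(dt, params.head_w2)
    dzh = dah * dact(zh)
    a_top = cache["as"][-1]
    g_w1 = a_top.T @ dzh
    g_b1 = dzh.sum(axis=0)
    da = dzh @ params.head_w1.T
    g_ws, g_bs = [], []
    for k in range(len(masks.masks) - 1, -1, -1):
        z = cache["zs"][k]
        a_prev = cache["as"][k]
        dz = da * dact(z)
        m = masks.masks[k]
        g_ws.append((a_prev.T @ dz) * m)
        g_bs.append(dz.sum(axis=0))
        da = dz @ (m * params.layer_weights[k]).T
    g_ws.reverse()
    g_bs.reverse()
    return [*g_ws, *g_bs, g_w1, g_b1, g_w2, np.atleast_1d(g_b2)]


def train(
    X: np.ndarray, y: np.ndarray, masks: MaskStack, config: TrainConfig | None = None,
) -> tuple[MaskedNetParams, dict]:
    """Train the masked network by Adam on the class-weighted BCE.

    A stratified validation split (``val_fraction``) drives early stopping
    when ``patience > 0``; the best-validation parameters are restored.
    Returns the parameters and a log with the loss trajectory.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    rng = np.random.default_rng(config.seed)
    params = init_params(masks, seed=config.seed, hidden_width=config.hidden_width)

    if config.class_weights == "auto":
        w0, w1 = auto_class_weights(y)
    else:
        w0, w1 = config.class_weights

    # stratified validation split for early stopping
    use_val = config.patience > 0 and config.val_fraction > 0
    if use_val:
        val_idx = []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            n_val = max(1, int(round(config.val_fraction * idx.size)))
            val_idx.extend(idx[:n_val])
        val_mask = np.zeros(y.size, dtype=bool)
        val_mask[val_idx] = True
        Xtr, ytr = X[~val_mask], y[~val_mask]
        Xva, yva = X[val_mask], y[val_mask]
        if len(np.unique(ytr)) < 2:
            Xtr, ytr, use_val = X, y, False
    if not use_val:
        Xtr, ytr = X, y

    flat = params.flat()
    opt = Adam(flat, lr=config.learning_rate)
    log = {"train_loss": [], "val_loss": [], "w0": w0, "w1": w1, "seed": config.seed}
    best_val = np.inf
    best_params = params.copy()
    stall = 0
    n = Xtr.shape[0]
    bs = config.batch_size or n
    for epoch in range(config.epochs):
        order = rng.permutation(n) if bs < n else np.arange(n)
        for start in range(0, n, bs):
            sel = order[start:start + bs]
            prob, cache = forward(Xtr[sel], masks, params, return_intermediates=True)
            grads = _backward(Xtr[sel], ytr[sel], masks, params, cache, w0, w1)
            opt.step(grads)
            params.head_b2 = float(flat[-1][0])
        tr_loss = weighted_bce(ytr, forward(Xtr, masks, params), w0, w1)
        if not np.isfinite(tr_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        log["train_loss"].append(tr_loss)
        if use_val:
            va_loss = weighted_bce(yva, forward(Xva, masks, params), w0, w1)
            log["val_loss"].append(va_loss)
            if va_loss < best_val - 1e-9:
                best_val = va_loss
                best_params = params.copy()
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    log["stopped_epoch"] = epoch
                    break
    final = best_params if use_val and np.isfinite(best_val) else params
    return final, log


def save_checkpoint(path: str | Path, params: MaskedNetParams, masks: MaskStack,
                    config: TrainConfig | None = None) -> None:
    """Single-file .npz checkpoint: weights, masks, node orderings, config."""
    meta = {
        "activation": params.activation,
        "n_masks": len(masks.masks),
        "node_index": masks.node_index,
        "config": vars(config) if config else None,
    }
    arrays = {"head_w1": params.head_w1, "head_b1": params.head_b1,
              "head_w2": params.head_w2, "head_b2": np.array([params.head_b2])}
    for i, (w, b, m) in enumerate(zip(params.layer_weights, params.layer_biases, masks.masks)):
        arrays[f"w_{i}"] = w
        arrays[f"b_{i}"] = b
        arrays[f"m_{i}"] = m
    np.savez(path, meta=json.dumps(meta, default=str), **arrays)


def load_checkpoint(path: str | Path) -> tuple[MaskedNetParams, MaskStack]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        k = meta["n_masks"]
        ws = [z[f"w_{i}"] for i in range(k)]
        bs = [z[f"b_{i}"] for i in range(k)]
        ms = [z[f"m_{i}"] for i in range(k)]
        params = MaskedNetParams(ws, bs, z["head_w1"], z["head_b1"], z["head_w2"],
                                 float(z["head_b2"][0]), meta["activation"])
    masks = MaskStack(ms[0], ms[1], ms[2:], meta["node_index"])
    return params, masks
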