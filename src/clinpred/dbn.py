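"""Deep belief network feature extractor.

A stack of restricted Boltzmann machines trained greedily by CD-1
contrastive divergence, then fine-tuned end-to-end by back-propagation
through a single sigmoid output head on the binary labels.  After training,
the head is discarded and the top hidden layer's mean-field activations are
exported as the extracted feature matrix.

Conventions:
  * visible units carry probabilities in [0, 1]; real-valued inputs enter
    the hidden conditional directly,
  * forward passes (and the exported features) are deterministic mean-field
    probabilities — sampling happens only inside CD training,
  * hidden state is sampled during CD; visible reconstructions and the
    data-side hidden term use probabilities (the standard CD recipe).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RBM",
    "DBNModel",
    "sigmoid",
    "hidden_given_visible",
    "visible_given_hidden",
    "cd_train_rbm",
    "cd_gradient_estimate",
    "dbn_pretrain",
    "dbn_finetune",
    "dbn_transform",
]


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Logistic function 1 / (1 + exp(-x)), overflow-safe for |x| <= ~700."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class RBM:
    """Restricted Boltzmann machine: bipartite model with symmetric weights.

    ``W`` has shape (visible_dim, hidden_dim); ``a`` is the hidden bias,
    ``b`` the visible bias.
    """

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (visible_dim x hidden_dim)")
        if self.a.shape != (self.W.shape[1],):
            raise ValueError(
                f"hidden bias length {self.a.shape} != hidden_dim {self.W.shape[1]}"
            )
        if self.b.shape != (self.W.shape[0],):
            raise ValueError(
                f"visible bias length {self.b.shape} != visible_dim {self.W.shape[0]}"
            )
        for name, arr in (("W", self.W), ("a", self.a), ("b", self.b)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in {name}")

    @property
    def visible_dim(self) -> int:
        return self.W.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.W.shape[1]

    @classmethod
    def initialize(
        cls, visible_dim: int, hidden_dim: int, rng: np.random.Generator, scale: float = 0.01
    ) -> "RBM":
        return cls(
            W=rng.normal(0.0, scale, size=(visible_dim, hidden_dim)),
            a=np.zeros(hidden_dim),
            b=np.zeros(visible_dim),
        )


def hidden_given_visible(rbm: RBM, V: np.ndarray) -> np.ndarray:
    """P(h_j = 1 | V) = g(V @ W + a), rows independent for 2-D input."""
    V = np.asarray(V, dtype=float)
    if V.shape[-1] != rbm.visible_dim:
        raise ValueError(
            f"visible vector length {V.shape[-1]} != visible_dim {rbm.visible_dim}"
        )
    return sigmoid(V @ rbm.W + rbm.a)


def visible_given_hidden(rbm: RBM, h: np.ndarray) -> np.ndarray:
    """P(V_i = 1 | h) = g(h @ W.T + b)."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != rbm.hidden_dim:
        raise ValueError(
            f"hidden vector length {h.shape[-1]} != hidden_dim {rbm.hidden_dim}"
        )
    return sigmoid(h @ rbm.W.T + rbm.b)


def cd_gradient_estimate(
    rbm: RBM, batch: np.ndarray, rng: np.random.Generator, cd_steps: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One contrastive-divergence gradient estimate on ``batch``.

    Returns ``(grad_W, grad_a, grad_b, v_recon)`` where the gradients are
    batch means of the positive-phase minus negative-phase statistics.
    Hidden states are sampled; visible reconstructions use probabilities.
    """
    v0 = np.atleast_2d(np.asarray(batch, dtype=float))
    ph0 = hidden_given_visible(rbm, v0)
    h = (rng.uniform(size=ph0.shape) < ph0).astype(float)
    v = v0
    for _ in range(cd_steps):
        v = visible_given_hidden(rbm, h)
        ph = hidden_given_visible(rbm, v)
        h = (rng.uniform(size=ph.shape) < ph).astype(float)
    b = v0.shape[0]
    grad_W = (v0.T @ ph0 - v.T @ ph) / b
    grad_a = (ph0 - ph).mean(axis=0)
    grad_b = (v0 - v).mean(axis=0)
    return grad_W, grad_a, grad_b, v


def cd_train_rbm(
    rbm: RBM,
    data: np.ndarray,
    epochs: int = 100,
    learning_rate: float = 0.1,
    batch_size: int = 10,
    cd_steps: int = 1,
    seed: int | None = 0,
    row_order: np.ndarray | None = None,
) -> tuple[RBM, list[float]]:
    """Train an RBM by mini-batch CD-``cd_steps``.

    Returns the trained copy and the per-epoch mean squared reconstruction
    error.  Deterministic given ``seed``.  ``row_order`` optionally fixes
    the visitation order for every epoch (used to test row-order
    invariance); by default rows are reshuffled per epoch.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("empty training data")
    if data.shape[1] != rbm.visible_dim:
        raise ValueError(
            f"data has {data.shape[1]} columns, RBM expects {rbm.visible_dim}"
        )
    rbm = copy.deepcopy(rbm)
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    log: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n) if row_order is None else np.asarray(row_order)
        err_sum = 0.0
        for start in range(0, n, batch_size):
            batch = data[order[start : start + batch_size]]
            gW, ga, gb, v_recon = cd_gradient_estimate(rbm, batch, rng, cd_steps)
            if not (
                np.all(np.isfinite(gW))
                and np.all(np.isfinite(ga))
                and np.all(np.isfinite(gb))
            ):
                raise FloatingPointError(
                    f"non-finite CD update at epoch {epoch}, batch row {start}"
                )
            rbm.W += learning_rate * gW
            rbm.a += learning_rate * ga
            rbm.b += learning_rate * gb
            err_sum += float(np.sum((batch - v_recon) ** 2))
        log.append(err_sum / data.size)
    return rbm, log


@dataclass
class DBNModel:
    """Greedily pretrained RBM stack plus a discardable supervised head."""

    rbms: list[RBM]
    head_w: np.ndarray | None = None
    head_b: float = 0.0
    training_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lower, upper in zip(self.rbms, self.rbms[1:]):
            if lower.hidden_dim != upper.visible_dim:
                raise ValueError(
                    f"layer dims do not chain: {lower.hidden_dim} -> {upper.visible_dim}"
                )

    @property
    def layer_sizes(self) -> list[int]:
        return [self.rbms[0].visible_dim] + [r.hidden_dim for r in self.rbms]

    @property
    def output_dim(self) -> int:
        return self.rbms[-1].hidden_dim

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, r in enumerate(self.rbms):
            arrays[f"W{i}"] = r.W
            arrays[f"a{i}"] = r.a
            arrays[f"b{i}"] = r.b
        arrays["n_layers"] = np.array(len(self.rbms))
        if self.head_w is not None:
            arrays["head_w"] = self.head_w
            arrays["head_b"] = np.array(self.head_b)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DBNModel":
        with np.load(path) as z:
            n_layers = int(z["n_layers"])
            rbms = [
                RBM(W=z[f"W{i}"], a=z[f"a{i}"], b=z[f"b{i}"]) for i in range(n_layers)
            ]
            head_w = z["head_w"] if "head_w" in z else None
            head_b = float(z["head_b"]) if "head_b" in z else 0.0
        return cls(rbms=rbms, head_w=head_w, head_b=head_b)


def dbn_pretrain(
    X1_train: np.ndarray,
    layer_sizes: Sequence[int],
    epochs: int = 100,
    learning_rate: float = 0.1,
    batch_size: int = 10,
    cd_steps: int = 1,
    seed: int | None = 0,
) -> DBNModel:
    """Greedy layer-wise unsupervised pretraining.

    Each RBM is trained on the previous layer's mean-field hidden
    probabilities of the training set.  ``layer_sizes[0]`` must equal the
    input width.
    """
    X = np.atleast_2d(np.asarray(X1_train, dtype=float))
    layer_sizes = list(layer_sizes)
    if len(layer_sizes) < 2:
        raise ValueError("need at least one hidden layer")
    if layer_sizes[0] != X.shape[1]:
        raise ValueError(
            f"layer_sizes[0]={layer_sizes[0]} != input width {X.shape[1]}"
        )
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(layer_sizes) - 1)
    rbms: list[RBM] = []
    recon_logs: list[list[float]] = []
    layer_input = X
    for depth, (vis, hid) in enumerate(zip(layer_sizes, layer_sizes[1:])):
        init_rng = np.random.default_rng(children[depth])
        rbm = RBM.initialize(vis, hid, init_rng)
        train_seed = int(init_rng.integers(2**31))
        rbm, log = cd_train_rbm(
            rbm,
            layer_input,
            epochs=epochs,
            learning_rate=learning_rate,
            batch_size=batch_size,
            cd_steps=cd_steps,
            seed=train_seed,
        )
        rbms.append(rbm)
        recon_logs.append(log)
        layer_input = hidden_given_visible(rbm, layer_input)
    return DBNModel(rbms=rbms, training_log={"reconstruction_error": recon_logs})


def _forward(model: DBNModel, X: np.ndarray) -> list[np.ndarray]:
    """Mean-field activations per layer, input included."""
    acts = [np.atleast_2d(np.asarray(X, dtype=float))]
    for rbm in model.rbms:
        acts.append(hidden_given_visible(rbm, acts[-1]))
    return acts


def finetune_loss(model: DBNModel, X: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy of the sigmoid head on (X, y)."""
    if model.head_w is None:
        raise ValueError("model has no supervised head (not fine-tuned yet)")
    top = _forward(model, X)[-1]
    p = sigmoid(top @ model.head_w + model.head_b)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def head_gradient(
    model: DBNModel, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, float]:
    """Analytic gradient of the mean cross-entropy w.r.t. the head only."""
    top = _forward(model, X)[-1]
    p = sigmoid(top @ model.head_w + model.head_b)
    delta = p - np.asarray(y, dtype=float)
    n = top.shape[0]
    return top.T @ delta / n, float(delta.mean())


def dbn_finetune(
    model: DBNModel,
    X1_train: np.ndarray,
    y_train: np.ndarray,
    epochs: int = 100,
    learning_rate: float = 0.1,
    seed: int | None = 0,
) -> DBNModel:
    """Supervised fine-tuning by full-batch gradient descent.

    A single sigmoid output unit with cross-entropy loss is stacked on the
    top hidden layer; errors back-propagate through every RBM's weights and
    hidden biases.  ``epochs=0`` attaches a head but performs no updates.
    """
    y = np.asarray(y_train)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    y = y.astype(float)
    model = copy.deepcopy(model)
    rng = np.random.default_rng(seed)
    if model.head_w is None:
        model.head_w = rng.normal(0.0, 0.01, size=model.output_dim)
        model.head_b = 0.0
    X = np.atleast_2d(np.asarray(X1_train, dtype=float))
    n = X.shape[0]
    losses: list[float] = []
    for _ in range(epochs):
        acts = _forward(model, X)
        top = acts[-1]
        p = sigmoid(top @ model.head_w + model.head_b)
        pc = np.clip(p, 1e-12, 1.0 - 1e-12)
        losses.append(float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean()))
        delta = (p - y) / n  # (n,)
        grad_head_w = top.T @ delta
        grad_head_b = float(delta.sum())
        # back-propagate through the sigmoid stack
        upstream = np.outer(delta, model.head_w)  # dL/d(top activations)
        grads = []
        for depth in range(len(model.rbms) - 1, -1, -1):
            h = acts[depth + 1]
            v = acts[depth]
            dz = upstream * h * (1.0 - h)
            grads.append((dz.sum(axis=0), v.T @ dz))  # (da, dW)
            upstream = dz @ model.rbms[depth].W.T
        model.head_w -= learning_rate * grad_head_w
        model.head_b -= learning_rate * grad_head_b
        for depth, (da, dW) in zip(range(len(model.rbms) - 1, -1, -1), grads):
            model.rbms[depth].a -= learning_rate * da
            model.rbms[depth].W -= learning_rate * dW
    model.training_log = dict(model.training_log)
    model.training_log["finetune_loss"] = losses
    return model


def dbn_transform(model: DBNModel, X1: np.ndarray) -> np.ndarray:
    """Deterministic feature extraction: top-layer mean-field probabilities."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    if X1.shape[1] != model.rbms[0].visible_dim:
        raise ValueError(
            f"input width {X1.shape[1]} != model input {model.rbms[0].visible_dim}"
        )
    return _forward(model, X1)[-1]
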