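"""Graph convolutional network for brain-graph classification.

Implements the Kipf-Welling propagation rule

    H^(l+1) = sigma(D~^{-1/2} (A + I) D~^{-1/2} H^(l) W^(l) + b^(l))

with ReLU sigma, on the weighted adjacency produced by the graph builder
(self-loop weight fixed at 1, edge weights the raw dissimilarities). The
classifier is three 64-channel GCN layers, global mean pooling over nodes,
dropout 0.3 on the pooled vector, and a single affine head to C class
logits — 8835 trainable parameters for C = 3:
(4*64 + 64) + 2*(64*64 + 64) + (64*3 + 3) = 320 + 8320 + 195.

Training (softmax cross-entropy, Adam) and the backward pass are written
directly in numpy: the model is tiny, and a closed-form implementation
keeps every run bit-deterministic on one CPU given a seed. Gradients are
validated against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .graphs import BrainGraph

__all__ = [
    "TrainingConfig",
    "GCNClassifier",
    "normalize_adjacency",
    "gcn_layer_forward",
    "count_parameters",
    "train",
    "predict",
    "stack_graphs",
]


def normalize_adjacency(G: Union[BrainGraph, np.ndarray]) -> np.ndarray:
    """Symmetrically normalized adjacency A^ = D~^{-1/2}(A + I)D~^{-1/2}.

    Accepts a BrainGraph (dense adjacency reconstructed from its edge
    list) or a dense non-negative weighted adjacency. The self-loop added
    by A + I guarantees every degree is >= 1, so the normalization is
    always defined; an edgeless graph maps to the identity.
    """
    A = G.to_dense_adjacency() if isinstance(G, BrainGraph) else np.asarray(G, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(A < 0):
        raise ValueError("adjacency weights must be non-negative")
    At = A + np.eye(A.shape[0])
    d = At.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return At * inv_sqrt[:, None] * inv_sqrt[None, :]


def gcn_layer_forward(H: np.ndarray, A_hat: np.ndarray, W: np.ndarray,
                      b: np.ndarray) -> np.ndarray:
    """One graph-convolution layer: ReLU(A^ H W + b)."""
    H, A_hat, W, b = (np.asarray(x, float) for x in (H, A_hat, W, b))
    if A_hat.shape[0] != A_hat.shape[1] or A_hat.shape[1] != H.shape[0]:
        raise ValueError(
            f"shape mismatch: A_hat {A_hat.shape} vs H {H.shape}"
        )
    if H.shape[1] != W.shape[0] or W.shape[1] != b.shape[0]:
        raise ValueError(
            f"shape mismatch: H {H.shape}, W {W.shape}, b {b.shape}"
        )
    return np.maximum(A_hat @ H @ W + b, 0.0)


@dataclass
class TrainingConfig:
    """Optimization hyperparameters (Adam, lr 0.001 by default)."""

    learning_rate: float = 0.001
    epochs: int = 300
    batch_size: int = 16
    seed: int = 0
    #: early-stopping patience in epochs; generous because the validation
    #: holdout is small (a few patients) and its loss is noisy.
    patience: int = 60
    class_weights: bool = False
    #: fraction of the training set held out (grouped by patient when
    #: groups are given) for early stopping; 0 disables the split.
    val_fraction: float = 0.25
    #: restore the best-validation-loss weights at the end instead of
    #: keeping the final ones. Off by default: the grouped holdout is a
    #: handful of patients, and snapping back to a far-past state on such
    #: a noisy signal is brittle.
    restore_best: bool = False
    #: compute dtype for training; float32 halves the matmul cost and is
    #: ample for a model this size.
    dtype: str = "float32"


def stack_graphs(graphs: Sequence[BrainGraph]):
    """Stack same-size graphs into (B,N,N) normalized adjacencies and
    (B,N,d) node-feature arrays."""
    if not graphs:
        raise ValueError("no graphs")
    N = graphs[0].n_nodes
    for g in graphs:
        if g.n_nodes != N:
            raise ValueError(
                f"all graphs must share the node count; got {g.n_nodes} and {N}"
            )
        if g.node_features is None:
            raise ValueError(f"graph {g.scan_id!r} carries no node features")
    A = np.stack([normalize_adjacency(g) for g in graphs])
    X = np.stack([g.node_features for g in graphs])
    return A, X


class GCNClassifier:
    """Three GCN layers (64 channels), global mean pooling, dropout, and an
    affine head to C logits.

    ``two_layer_head=True`` inserts a hidden fully connected layer before
    the logits (this breaks the 8835-parameter total and exists only for
    architecture ablations).
    """

    def __init__(
        self,
        n_classes: int,
        in_features: int = 4,
        hidden: int = 64,
        n_layers: int = 3,
        dropout: float = 0.3,
        seed: int = 0,
        two_layer_head: bool = False,
        head_hidden: int = 64,
    ):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.n_classes = n_classes
        self.in_features = in_features
        self.hidden = hidden
        self.n_layers = n_layers
        self.dropout = dropout
        self.seed = seed
        self.two_layer_head = two_layer_head
        self.head_hidden = head_hidden
        rng = np.random.default_rng(seed)
        self.params: dict = {}
        dims = [in_features] + [hidden] * n_layers
        for l in range(n_layers):
            self.params[f"W{l + 1}"] = self._glorot(rng, dims[l], dims[l + 1])
            self.params[f"b{l + 1}"] = np.zeros(dims[l + 1])
        if two_layer_head:
            self.params["Wh0"] = self._glorot(rng, hidden, head_hidden)
            self.params["bh0"] = np.zeros(head_hidden)
            self.params["Wh"] = self._glorot(rng, head_hidden, n_classes)
        else:
            self.params["Wh"] = self._glorot(rng, hidden, n_classes)
        self.params["bh"] = np.zeros(n_classes)

    @staticmethod
    def _glorot(rng, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        A_hat: np.ndarray,
        X: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
        cache: Optional[dict] = None,
    ) -> np.ndarray:
        """Batched forward pass: A_hat (B,N,N), X (B,N,in) -> logits (B,C).

        Dropout is active only with ``training=True`` (then ``rng`` drives
        the mask). ``cache`` collects intermediates for backward().
        """
        A_hat = np.asarray(A_hat)
        X = np.asarray(X)
        if A_hat.ndim == 2:  # single graph
            A_hat, X = A_hat[None], X[None]
        if X.shape[-1] != self.in_features:
            raise ValueError(
                f"expected {self.in_features} node features, got {X.shape[-1]}"
            )
        B, N = X.shape[0], X.shape[1]
        H = X
        Zs, Hs, Ms = [], [H], []
        for l in range(1, self.n_layers + 1):
            M = A_hat @ H  # (B,N,d)
            Z = M @ self.params[f"W{l}"] + self.params[f"b{l}"]
            H = np.maximum(Z, 0.0)
            Ms.append(M)
            Zs.append(Z)
            Hs.append(H)
        p = H.mean(axis=1)  # (B,hidden) global mean pooling
        if training and self.dropout > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = 1.0 - self.dropout
            mask = (rng.random(p.shape) < keep) / keep
            p_drop = p * mask
        else:
            mask = np.ones_like(p)
            p_drop = p
        if self.two_layer_head:
            Zh0 = p_drop @ self.params["Wh0"] + self.params["bh0"]
            h0 = np.maximum(Zh0, 0.0)
            logits = h0 @ self.params["Wh"] + self.params["bh"]
        else:
            Zh0 = h0 = None
            logits = p_drop @ self.params["Wh"] + self.params["bh"]
        if cache is not None:
            cache.update(
                A_hat=A_hat, Zs=Zs, Hs=Hs, Ms=Ms, mask=mask, p=p,
                p_drop=p_drop, Zh0=Zh0, h0=h0, N=N, B=B,
            )
        return logits

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict:
        """Gradients of the loss w.r.t. every parameter, given d(loss)/d(logits)."""
        grads = {}
        if self.two_layer_head:
            grads["Wh"] = cache["h0"].T @ dlogits
            grads["bh"] = dlogits.sum(axis=0)
            dh0 = dlogits @ self.params["Wh"].T
            dZh0 = dh0 * (cache["Zh0"] > 0)
            grads["Wh0"] = cache["p_drop"].T @ dZh0
            grads["bh0"] = dZh0.sum(axis=0)
            dp_drop = dZh0 @ self.params["Wh0"].T
        else:
            grads["Wh"] = cache["p_drop"].T @ dlogits
            grads["bh"] = dlogits.sum(axis=0)
            dp_drop = dlogits @ self.params["Wh"].T
        dp = dp_drop * cache["mask"]
        N = cache["N"]
        dH = np.repeat(dp[:, None, :] / N, N, axis=1)  # (B,N,hidden)
        for l in range(self.n_layers, 0, -1):
            dZ = dH * (cache["Zs"][l - 1] > 0)
            M = cache["Ms"][l - 1]
            grads[f"W{l}"] = np.einsum("bnd,bne->de", M, dZ)
            grads[f"b{l}"] = dZ.sum(axis=(0, 1))
            if l > 1:
                dM = dZ @ self.params[f"W{l}"].T
                dH = cache["A_hat"].transpose(0, 2, 1) @ dM
        return grads

    # -- utilities ----------------------------------------------------------

    def astype(self, dtype) -> "GCNClassifier":
        """Cast all parameters in place to ``dtype``; returns self."""
        dtype = np.dtype(dtype)
        for k in self.params:
            self.params[k] = self.params[k].astype(dtype)
        return self

    def count_parameters(self, include_head: bool = True) -> int:
        """Total number of trainable scalars (8835 for the default C=3
        model; 8640 for the GCN stack alone)."""
        head_keys = {"Wh", "bh", "Wh0", "bh0"}
        return int(
            sum(
                v.size
                for k, v in self.params.items()
                if include_head or k not in head_keys
            )
        )

    def get_flat_params(self) -> np.ndarray:
        return np.concatenate([self.params[k].ravel() for k in sorted(self.params)])

    def set_flat_params(self, flat: np.ndarray) -> None:
        off = 0
        for k in sorted(self.params):
            n = self.params[k].size
            self.params[k] = flat[off:off + n].reshape(self.params[k].shape).copy()
            off += n

    def save(self, path) -> None:
        state = {
            "config": {
                "n_classes": self.n_classes, "in_features": self.in_features,
                "hidden": self.hidden, "n_layers": self.n_layers,
                "dropout": self.dropout, "seed": self.seed,
                "two_layer_head": self.two_layer_head,
                "head_hidden": self.head_hidden,
            },
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def load(cls, path) -> "GCNClassifier":
        state = json.loads(Path(path).read_text())
        model = cls(**state["config"])
        for k, v in state["params"].items():
            model.params[k] = np.asarray(v, float)
        return model


def count_parameters(model: GCNClassifier, include_head: bool = True) -> int:
    return model.count_parameters(include_head=include_head)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _ce_loss_and_grad(logits, y, sample_w):
    """Weighted softmax cross-entropy; returns (mean loss, dlogits)."""
    probs = _softmax(logits)
    n = logits.shape[0]
    wsum = sample_w.sum()
    ll = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None))
    loss = float((sample_w * ll).sum() / wsum)
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (sample_w / wsum)[:, None]
    return loss, dlogits


def _grouped_holdout(y, groups, frac, rng):
    """Deterministic per-class grouped holdout of ~frac of the groups."""
    groups = np.asarray(groups)
    y = np.asarray(y)
    val_groups = set()
    for cls in np.unique(y):
        gs = np.unique(groups[y == cls])
        gs = gs[rng.permutation(len(gs))]
        n_val = max(1, int(round(frac * len(gs))))
        if n_val >= len(gs):
            n_val = len(gs) - 1
        val_groups.update(gs[:n_val].tolist())
    val_mask = np.array([g in val_groups for g in groups])
    if val_mask.all() or not val_mask.any():
        return None
    return ~val_mask, val_mask


def train(
    model: GCNClassifier,
    graphs: Sequence[BrainGraph],
    labels: Sequence[int],
    config: TrainingConfig,
    groups: Optional[Sequence] = None,
    val_graphs: Optional[Sequence[BrainGraph]] = None,
    val_labels: Optional[Sequence[int]] = None,
):
    """Train with Adam on softmax cross-entropy.

    Early stopping monitors validation loss (explicit validation set, or a
    grouped holdout carved from the training set when ``groups`` and
    ``config.val_fraction`` are given); the best-validation weights are
    restored. All randomness (holdout, shuffling, dropout) derives from
    ``config.seed``. Returns the per-epoch history as a list of dicts.
    """
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    if y.max() >= model.n_classes:
        raise ValueError("label exceeds model's class count")
    A, X = stack_graphs(graphs)
    dtype = np.dtype(config.dtype)
    A = A.astype(dtype)
    X = X.astype(dtype)
    model.astype(dtype)
    rng = np.random.default_rng(config.seed)

    Av = Xv = yv = None
    if val_graphs is not None:
        Av, Xv = stack_graphs(val_graphs)
        Av, Xv = Av.astype(dtype), Xv.astype(dtype)
        yv = np.asarray(val_labels, dtype=int)
    elif config.val_fraction > 0 and groups is not None:
        split = _grouped_holdout(y, groups, config.val_fraction, rng)
        if split is not None:
            tr, va = split
            if np.unique(y[tr]).size == classes.size:
                Av, Xv, yv = A[va], X[va], y[va]
                A, X, y = A[tr], X[tr], y[tr]

    if config.class_weights:
        counts = np.bincount(y, minlength=model.n_classes).astype(float)
        cw = np.where(counts > 0, y.size / np.maximum(counts, 1) / classes.size, 0.0)
        sample_w = cw[y]
    else:
        sample_w = np.ones(y.size)

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v2 = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = []
    best_val = np.inf
    best_params = {k: p.copy() for k, p in model.params.items()}
    stale = 0
    n = y.size
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            cache: dict = {}
            logits = model.forward(A[idx], X[idx], training=True, rng=rng,
                                   cache=cache)
            loss, dlogits = _ce_loss_and_grad(logits, y[idx], sample_w[idx])
            grads = model.backward(cache, dlogits)
            t += 1
            for k in model.params:
                g = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v2[k] = beta2 * v2[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**t)
                vhat = v2[k] / (1 - beta2**t)
                model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += loss * idx.size
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        rec = {
            "epoch": epoch,
            "train_loss": epoch_loss / n,
            "train_acc": correct / n,
        }
        if yv is not None:
            vlogits = model.forward(Av, Xv, training=False)
            vloss, _ = _ce_loss_and_grad(
                vlogits, yv, np.ones(yv.size)
            )
            rec["val_loss"] = vloss
            rec["val_acc"] = float((vlogits.argmax(axis=1) == yv).mean())
            if vloss < best_val - 1e-6:
                best_val = vloss
                if config.restore_best:
                    best_params = {k: p.copy() for k, p in model.params.items()}
                stale = 0
            else:
                stale += 1
            history.append(rec)
            if stale > config.patience:
                break
        else:
            history.append(rec)
    if yv is not None and config.restore_best:
        model.params = best_params
    return model, history


def predict(model: GCNClassifier, graphs: Sequence[BrainGraph]):
    """Eval-mode prediction: (argmax labels, softmax probabilities)."""
    A, X = stack_graphs(graphs)
    logits = model.forward(A, X, training=False)
    probs = _softmax(logits)
    return logits.argmax(axis=1), probs
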