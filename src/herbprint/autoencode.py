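"""Mirrored feed-forward autoencoder for fingerprint compression.

The encoder shrinks the 1600-dimensional peak-area vector by a factor of 4
per layer (1600 -> 400 -> 100 -> 25 by default); the decoder mirrors the
encoder widths.  Hidden layers use the logistic sigmoid; the output layer
uses ReLU so reconstructions are non-negative like the data.  Training
minimizes the Huber (smoothed l1) reconstruction loss with Adam, using
layer-wise pretraining: a depth-1 model is trained first, its layers seed
the depth-2 model, and so on to the target depth, each stage fine-tuning
all layers end to end.

Implemented directly on numpy (forward pass, backpropagation and the Adam
update rule), which is ample for fingerprint-sized data on a CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def huber_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Smoothed-l1 reconstruction loss, summed over components.

    Per component: 0.5 d^2 when ``|d| < 1`` else ``|d| - 0.5``, with
    d the reconstruction error.  The threshold is fixed at 1.
    """
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    d = np.abs(x - x_hat)
    return float(np.sum(np.where(d < 1.0, 0.5 * d * d, d - 0.5)))


def _huber_grad(x_hat: np.ndarray, x: np.ndarray) -> np.ndarray:
    """d loss / d x_hat, elementwise: clip(x_hat - x, -1, 1)."""
    return np.clip(x_hat - x, -1.0, 1.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class AutoencoderNet:
    """Weight container for the mirrored network.

    ``widths`` lists layer sizes from input through bottleneck back to
    output, e.g. [1600, 400, 100, 25, 100, 400, 1600].  Layer i maps
    widths[i] -> widths[i+1]; all layers apply sigmoid except the last,
    which applies ReLU.
    """

    widths: list[int]
    W: list[np.ndarray] = field(default_factory=list)
    b: list[np.ndarray] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.widths) - 1

    @property
    def n_encoding_layers(self) -> int:
        return self.n_layers // 2

    @property
    def bottleneck(self) -> int:
        return self.widths[self.n_encoding_layers]

    def init_weights(self, rng: np.random.Generator) -> None:
        self.W, self.b = [], []
        for i, (fan_in, fan_out) in enumerate(zip(self.widths[:-1], self.widths[1:])):
            s = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-s, s, size=(fan_out, fan_in)))
            # small positive bias on the ReLU output layer so no unit starts dead
            last = i == len(self.widths) - 2
            self.b.append(np.full(fan_out, 0.1) if last else np.zeros(fan_out))

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations per layer; [0] is the input, [-1] the reconstruction."""
        acts = [X]
        a = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W.T + b
            a = np.maximum(z, 0.0) if i == self.n_layers - 1 else _sigmoid(z)
            acts.append(a)
        return acts

    def encode(self, X: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(X, dtype=float))
        if a.shape[1] != self.widths[0]:
            raise ValueError(f"expected input width {self.widths[0]}, got {a.shape[1]}")
        for i in range(self.n_encoding_layers):
            a = _sigmoid(a @ self.W[i].T + self.b[i])
        return a[0] if np.asarray(X).ndim == 1 else a

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.forward(np.atleast_2d(np.asarray(X, dtype=float)))[-1]

    def backward(self, acts: list[np.ndarray]) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of mean per-sample Huber loss w.r.t. weights and biases."""
        X = acts[0]
        n = X.shape[0]
        delta = _huber_grad(acts[-1], X) / n          # d mean-loss / d output
        gW: list[np.ndarray] = [None] * self.n_layers
        gb: list[np.ndarray] = [None] * self.n_layers
        for i in range(self.n_layers - 1, -1, -1):
            a = acts[i + 1]
            dz = delta * (a > 0) if i == self.n_layers - 1 else delta * a * (1.0 - a)
            gW[i] = dz.T @ acts[i]
            gb[i] = dz.sum(axis=0)
            if i > 0:
                delta = dz @ self.W[i]
        return gW, gb

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps({"widths": self.widths}))

    @classmethod
    def load(cls, path: str | Path) -> "AutoencoderNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        net = cls(widths=list(meta["widths"]))
        arr = np.load(path.with_suffix(".npz"))
        n = net.n_layers
        net.W = [arr[f"W{i}"] for i in range(n)]
        net.b = [arr[f"b{i}"] for i in range(n)]
        return net


def build_autoencoder(
    input_dim: int = 1600,
    n_encoding_layers: int = 3,
    factor: int = 4,
    seed: int = 0,
) -> AutoencoderNet:
    """Initialize a mirrored net whose encoder shrinks by `factor` per layer."""
    if n_encoding_layers < 1:
        raise ValueError("need at least one encoding layer")
    enc = [input_dim]
    for _ in range(n_encoding_layers):
        nxt = enc[-1] / factor
        if nxt != int(nxt) or nxt < 1:
            raise ValueError(
                f"layer width {enc[-1]} is not divisible by factor {factor}: "
                f"first illegal width would be {nxt}"
            )
        enc.append(int(nxt))
    widths = enc + enc[-2::-1]
    net = AutoencoderNet(widths=widths)
    net.init_weights(np.random.default_rng(seed))
    return net


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _train_net(
    net: AutoencoderNet,
    X: np.ndarray,
    epochs: int,
    lr: float,
    batch_size: int,
    rng: np.random.Generator,
    patience: int,
) -> list[float]:
    """Mini-batch Adam on mean per-sample Huber loss; returns epoch losses."""
    n = X.shape[0]
    params = net.W + net.b
    opt = _Adam(params, lr)
    history: list[float] = []
    best = np.inf
    stale = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            batch = X[order[start:start + batch_size]]
            acts = net.forward(batch)
            losses.append(huber_loss(batch, acts[-1]) / batch.shape[0])
            gW, gb = net.backward(acts)
            opt.step(params, gW + gb)
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if epoch_loss < best - 1e-12:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    return history


def train_layerwise(
    X: np.ndarray,
    n_encoding_layers: int = 3,
    factor: int = 4,
    epochs: int = 200,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
    patience: int = 20,
) -> tuple[AutoencoderNet, dict[int, list[float]]]:
    """Layer-wise pretraining schedule ending in full fine-tuning.

    Stage k trains the depth-k mirrored model; its encoder layers 1..k-1
    and decoder layers are warm-started from stage k-1 and nothing is
    frozen — every stage fine-tunes all layers.  Returns the final net and
    per-stage epoch-loss histories.
    """
    if lr <= 0:
        raise ValueError("lr must be positive")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need a 2-d data matrix with at least one sample")
    input_dim = X.shape[1]
    rng = np.random.default_rng(seed)
    history: dict[int, list[float]] = {}
    prev: AutoencoderNet | None = None
    for depth in range(1, n_encoding_layers + 1):
        net = build_autoencoder(input_dim, depth, factor, seed=seed + depth)
        if prev is not None:
            # encoder layers 1..depth-1 and decoder layers shifted by one
            for i in range(depth - 1):
                net.W[i] = prev.W[i].copy()
                net.b[i] = prev.b[i].copy()
            for j in range(prev.n_layers - (depth - 1), prev.n_layers):
                off = net.n_layers - prev.n_layers
                net.W[j + off] = prev.W[j].copy()
                net.b[j + off] = prev.b[j].copy()
        history[depth] = _train_net(net, X, epochs, lr, batch_size, rng, patience)
        prev = net
    return prev, history


class Autoencoder(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer wrapping the mirrored autoencoder.

    ``fit`` expects data scaled into [0, 1] (per-sample max normalization,
    see :func:`herbprint.featurize.build_dataset`); ``transform`` returns
    the bottleneck encoding, whose entries lie in (0, 1).

    Parameters default to the standard configuration: 3 encoding layers
    with factor-4 shrinkage (1600 inputs -> 25 encoded variables).
    """

    def __init__(
        self,
        n_encoding_layers: int = 3,
        factor: int = 4,
        epochs: int = 200,
        lr: float = 1e-3,
        batch_size: int = 32,
        patience: int = 20,
        seed: int = 0,
    ):
        self.n_encoding_layers = n_encoding_layers
        self.factor = factor
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.patience = patience
        self.seed = seed

    def fit(self, X: np.ndarray, y=None) -> "Autoencoder":
        X = np.asarray(X, dtype=float)
        self.net_, self.history_ = train_layerwise(
            X,
            n_encoding_layers=self.n_encoding_layers,
            factor=self.factor,
            epochs=self.epochs,
            lr=self.lr,
            batch_size=self.batch_size,
            seed=self.seed,
            patience=self.patience,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "net_")
        return np.atleast_2d(self.net_.encode(X))

    def inverse_transform_loss(self, X: np.ndarray) -> float:
        """Mean per-sample Huber reconstruction loss on `X`."""
        check_is_fitted(self, "net_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return huber_loss(X, self.net_.reconstruct(X)) / X.shape[0]

    def first_layer_importance(self) -> np.ndarray:
        """Euclidean norm of each input variable's first-layer weight column,
        the variable-importance score used for feature ranking."""
        check_is_fitted(self, "net_")
        return np.linalg.norm(self.net_.W[0], axis=0)
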