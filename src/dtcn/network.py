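"""Deep temporal convolution network: forward pass, gradient routing, training.

The network is a fully connected sigmoid net whose hidden-layer outputs are
rearranged by a *concatenation sublayer*: TS consecutive activation rows of a
mini-batch (kept in natural time order) are joined horizontally into one new
instance, so temporal context reaches the deeper layers.  Per-class label
counts are pooled in lockstep with every concatenation and majority voting is
deferred to the final softmax classifier.

Concatenation is not differentiable, so the backward pass routes the error
through it with the "split-slide-add" rule: the delta attributed to a
concatenation sublayer is split into its TS pre-concatenation column blocks,
the blocks are slid into temporal alignment, and the aligned values are added.
That rule is exactly the linear adjoint of the concatenation operator — it
conserves the total delta and learns nothing itself.

At ``TS = 1`` every operation reduces to the plain DBN-DNN / MLP computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .data_prep import MiniBatch

__all__ = [
    "NetworkParams",
    "LayerState",
    "TrainConfig",
    "concatenate",
    "pool_label_counts",
    "majority_vote",
    "vote_rows",
    "forward",
    "gradient_route",
    "backprop_update",
    "train_network",
    "evaluate",
    "param_count",
    "equivalent_dbn_config",
    "connection_shapes",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


def sigmoid(x: np.ndarray) -> np.ndarray:
    # expit-equivalent, written out so the whole forward pass is in one place
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(y: np.ndarray) -> np.ndarray:
    z = np.exp(y - y.max(axis=1, keepdims=True))
    return z / z.sum(axis=1, keepdims=True)


def connection_shapes(
    layer_sizes: Sequence[int], ts: int
) -> list[tuple[int, int]]:
    """Weight-matrix shapes ``(fan_in, fan_out)`` for each inter-layer connection.

    The first connection consumes the raw time-delay input (no concatenation
    at the input layer); every later connection, including the softmax one,
    attaches to a concatenation sublayer and so has fan-in ``ts * n_i``.
    """
    sizes = list(layer_sizes)
    if len(sizes) < 2:
        raise ValueError("need at least an input and an output layer")
    if any(n < 1 for n in sizes):
        raise ValueError("layer sizes must be positive")
    if ts < 1:
        raise ValueError("time steps TS must be >= 1")
    shapes = [(sizes[0], sizes[1])]
    for i in range(1, len(sizes) - 1):
        shapes.append((ts * sizes[i], sizes[i + 1]))
    return shapes


@dataclass
class NetworkParams:
    """Layer sizes, time steps and all connection weights/biases.

    ``layer_sizes`` is ``(n0, h1, ..., hL, K)``: time-delay input width,
    hidden widths, softmax classes.  ``ts`` (time steps) is the number of
    consecutive instances each concatenation sublayer joins.  Weight matrix
    ``i`` has shape :func:`connection_shapes`\\ ``(layer_sizes, ts)[i]``.
    """

    layer_sizes: tuple[int, ...]
    ts: int
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(n) for n in self.layer_sizes)
        expected = connection_shapes(self.layer_sizes, self.ts)
        if len(self.weights) != len(expected) or len(self.biases) != len(expected):
            raise ValueError(f"expected {len(expected)} connections")
        for i, ((fi, fo), W, b) in enumerate(zip(expected, self.weights, self.biases)):
            if W.shape != (fi, fo) or b.shape != (fo,):
                raise ValueError(
                    f"connection {i}: expected W {(fi, fo)} / b {(fo,)}, "
                    f"got {W.shape} / {b.shape}"
                )
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError(f"connection {i}: non-finite parameters")

    @classmethod
    def initialize(
        cls, layer_sizes: Sequence[int], ts: int, seed: int | np.random.Generator = 0
    ) -> "NetworkParams":
        """Random small-weight initialization, deterministic in ``seed``."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        weights, biases = [], []
        for fi, fo in connection_shapes(layer_sizes, ts):
            weights.append(rng.normal(0.0, 1.0 / np.sqrt(fi), size=(fi, fo)))
            biases.append(np.zeros(fo))
        return cls(tuple(layer_sizes), ts, weights, biases)

    @property
    def n_hidden(self) -> int:
        return len(self.layer_sizes) - 2

    @property
    def n_classes(self) -> int:
        return self.layer_sizes[-1]

    @property
    def min_batch_size(self) -> int:
        """Smallest mini-batch that survives all concatenations with one row."""
        return self.n_hidden * (self.ts - 1) + 1

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.layer_sizes,
            self.ts,
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
        )


@dataclass
class TrainConfig:
    """Fine-tuning hyperparameters for mini-batch gradient descent.

    ``learning_rate`` is the step size of the weight update
    ``W <- W - lr * dE/dW`` on the mean cross-entropy of a mini-batch;
    ``momentum`` adds a classical-momentum velocity term.  ``soft_targets``
    replaces the voted one-hot targets with count-proportional distributions.
    When ``ts > 1``, mini-batches smaller than ``min_batch_size`` are refused
    during training unless ``allow_small_batches`` is set (concatenation needs
    enough rows to be meaningful).
    """

    learning_rate: float = 0.2
    epochs: int = 30
    momentum: float = 0.0
    seed: int = 0
    soft_targets: bool = False
    allow_small_batches: bool = False
    min_batch_size: int = 8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class LayerState:
    """Per-layer tensors of one forward pass through a mini-batch.

    ``linear[i]`` / ``hidden[i]`` are the linear output and sigmoid activation
    of hidden layer ``i``; ``hidden_concat[i]`` its concatenation sublayer;
    ``pooled_counts[i]`` the label counts pooled in lockstep (row-aligned with
    ``hidden_concat[i]``).  ``output`` holds the softmax rows and
    ``final_counts`` the terminal pooled counts the vote is taken on.
    """

    linear: list[np.ndarray]
    hidden: list[np.ndarray]
    hidden_concat: list[np.ndarray]
    pooled_counts: list[np.ndarray]
    output: np.ndarray
    final_counts: np.ndarray
    inputs: np.ndarray


def concatenate(activations: np.ndarray, ts: int) -> np.ndarray:
    """Join each run of ``ts`` consecutive rows into one wider row.

    Output row ``r`` is the horizontal join of input rows ``r .. r+ts-1``;
    an input of ``R`` rows and ``H`` columns becomes ``R - ts + 1`` rows of
    ``ts * H`` columns.  Rows must be in natural time order for the join to
    carry temporal context.  ``ts = 1`` is the identity.
    """
    a = np.asarray(activations, dtype=float)
    if a.ndim != 2:
        raise ValueError("activations must be a 2-D instance-major matrix")
    rows, H = a.shape
    if ts < 1:
        raise ValueError("time steps TS must be >= 1")
    if rows < ts:
        raise ValueError(
            f"mini-batch too small to concatenate: {rows} rows < TS={ts}"
        )
    # (R, H, ts) view with [r, h, j] = a[r + j, h]; reorder blocks time-major
    view = sliding_window_view(a, ts, axis=0)
    return view.transpose(0, 2, 1).reshape(rows - ts + 1, ts * H)


def pool_label_counts(counts: np.ndarray, ts: int) -> np.ndarray:
    """Sum the label counts of each run of ``ts`` consecutive instances.

    Pooling accompanies every concatenation so class-distribution information
    is accumulated, not summarised: each output row sum is ``ts`` times the
    input row sum, and voting waits until the final classifier.
    """
    c = np.asarray(counts)
    if c.ndim != 2:
        raise ValueError("counts must be a 2-D (instances x classes) matrix")
    rows = c.shape[0]
    if ts < 1:
        raise ValueError("time steps TS must be >= 1")
    if rows < ts:
        raise ValueError(f"too few instances to pool: {rows} rows < TS={ts}")
    view = sliding_window_view(c, ts, axis=0)
    return view.sum(axis=2)


def majority_vote(counts: np.ndarray, rng_seed: int) -> int:
    """Class with the largest pooled count; ties broken by a seeded generator.

    Same ``rng_seed`` and counts always give the same class.
    """
    c = np.asarray(counts).ravel()
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if not np.any(c > 0):
        raise ValueError("cannot vote on all-zero counts")
    tied = np.flatnonzero(c == c.max())
    if len(tied) == 1:
        return int(tied[0])
    return int(np.random.default_rng(rng_seed).choice(tied))


def vote_rows(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise majority vote over a counts matrix, ties broken via ``rng``."""
    c = np.asarray(counts)
    out = np.empty(c.shape[0], dtype=np.int64)
    for r in range(c.shape[0]):
        row = c[r]
        if not np.any(row > 0):
            raise ValueError(f"row {r}: cannot vote on all-zero counts")
        tied = np.flatnonzero(row == row.max())
        out[r] = tied[0] if len(tied) == 1 else rng.choice(tied)
    return out


def forward(params: NetworkParams, batch: MiniBatch | np.ndarray,
            label_counts: np.ndarray | None = None) -> LayerState:
    """Run one mini-batch through the network.

    The time-delay input passes through the first connection directly (the
    windowed representation already encodes input-level context); after every
    hidden layer's sigmoid activation the rows are concatenated with TS and
    label counts pooled alongside, then the next connection applies.  The
    final connection ends in a softmax.  With L hidden layers,
    ``B - L*(TS-1)`` instances survive to the output.
    """
    if isinstance(batch, MiniBatch):
        X = batch.features
        counts = batch.label_counts
    else:
        X = np.asarray(batch, dtype=float)
        if label_counts is None:
            raise ValueError("label_counts required when passing a raw matrix")
        counts = np.asarray(label_counts)
    B = X.shape[0]
    if B < params.min_batch_size:
        raise ValueError(
            f"mini-batch of {B} instances cannot survive "
            f"{params.n_hidden} concatenations at TS={params.ts}; "
            f"need at least B={params.min_batch_size}"
        )
    linear, hidden, hidden_concat, pooled = [], [], [], []
    h = X
    for i, (W, b) in enumerate(zip(params.weights, params.biases)):
        y = h @ W + b
        if i == len(params.weights) - 1:
            probs = softmax(y)
            return LayerState(
                linear, hidden, hidden_concat, pooled, probs, counts, X
            )
        a = sigmoid(y)
        linear.append(y)
        hidden.append(a)
        ac = concatenate(a, params.ts)
        counts = pool_label_counts(counts, params.ts)
        hidden_concat.append(ac)
        pooled.append(counts)
        h = ac
    raise AssertionError("unreachable")


def gradient_route(table: np.ndarray, ts: int, pre_rows: int) -> np.ndarray:
    """Split-slide-add: route a concatenation sublayer's delta back to rows.

    ``table`` holds one row per concatenated instance (``pre_rows - ts + 1``
    rows, ``ts * H`` columns).  It is *split* into its ts pre-concatenation
    column blocks of width H, the blocks are *slid* into temporal alignment
    (block j, row r belongs to pre-concatenation row ``r + j``), and aligned
    values are *added*.  This is the linear adjoint of :func:`concatenate`:
    it redistributes — and exactly conserves — the incoming delta without any
    learnable parameters.
    """
    t = np.asarray(table, dtype=float)
    if ts < 1:
        raise ValueError("time steps TS must be >= 1")
    if t.ndim != 2 or t.shape[1] % ts != 0:
        raise ValueError("table width must be a multiple of TS")
    H = t.shape[1] // ts
    R = pre_rows - ts + 1
    if t.shape[0] != R:
        raise ValueError(
            f"table has {t.shape[0]} rows; expected {R} for pre_rows={pre_rows}, TS={ts}"
        )
    out = np.zeros((pre_rows, H))
    for j in range(ts):
        out[j : j + R] += t[:, j * H : (j + 1) * H]
    return out


def _targets(state: LayerState, config: TrainConfig,
             rng: np.random.Generator) -> np.ndarray:
    """One-hot (or count-proportional) target rows from the final pooled counts."""
    counts = state.final_counts
    K = counts.shape[1]
    if config.soft_targets:
        return counts / counts.sum(axis=1, keepdims=True)
    voted = vote_rows(counts, rng)
    T = np.zeros((counts.shape[0], K))
    T[np.arange(counts.shape[0]), voted] = 1.0
    return T


def _gradients(
    params: NetworkParams, state: LayerState, targets: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Backward pass: cross-entropy deltas with split-slide-add routing."""
    probs = state.output
    R = probs.shape[0]
    # cross-entropy over (possibly soft) targets; clip guards log underflow
    loss = float(-np.sum(targets * np.log(np.clip(probs, 1e-12, None))) / R)
    grads_W: list[np.ndarray] = [None] * len(params.weights)  # type: ignore
    grads_b: list[np.ndarray] = [None] * len(params.weights)  # type: ignore
    delta = (probs - targets) / R
    for i in range(len(params.weights) - 1, -1, -1):
        a_in = state.inputs if i == 0 else state.hidden_concat[i - 1]
        grads_W[i] = a_in.T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i == 0:
            break
        d_concat = delta @ params.weights[i].T
        a = state.hidden[i - 1]
        d_act = gradient_route(d_concat, params.ts, a.shape[0])
        delta = d_act * a * (1 - a)
    return grads_W, grads_b, loss


def backprop_update(
    params: NetworkParams,
    batch: MiniBatch,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
    velocity: tuple[list[np.ndarray], list[np.ndarray]] | None = None,
) -> tuple[NetworkParams, float]:
    """One gradient-descent step on a mini-batch; returns loss before update.

    Targets are hard one-hot labels voted from the terminal pooled counts
    (count-proportional soft targets behind ``config.soft_targets``).  Deltas
    flow back through upper-layer weights, are routed across each
    concatenation by split-slide-add, and are multiplied elementwise by the
    sigmoid derivative.  ``params`` is updated in place and returned.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = forward(params, batch)
    targets = _targets(state, config, rng)
    grads_W, grads_b, loss = _gradients(params, state, targets)
    if not np.isfinite(loss):
        raise FloatingPointError(
            "non-finite training loss; reduce the learning rate"
        )
    lr, mom = config.learning_rate, config.momentum
    for i in range(len(params.weights)):
        if velocity is not None and mom > 0:
            vW, vb = velocity
            vW[i] = mom * vW[i] - lr * grads_W[i]
            vb[i] = mom * vb[i] - lr * grads_b[i]
            params.weights[i] += vW[i]
            params.biases[i] += vb[i]
        else:
            params.weights[i] -= lr * grads_W[i]
            params.biases[i] -= lr * grads_b[i]
    return params, loss


def train_network(
    params: NetworkParams,
    batches: Sequence[MiniBatch],
    config: TrainConfig,
) -> tuple[NetworkParams, list[float]]:
    """Fine-tune over epochs of shuffled mini-batches; returns per-epoch losses.

    Mini-batches are re-shuffled (whole batches only) every epoch; a dedicated
    tie-break generator is derived from ``config.seed`` so voting randomness
    is independent of the shuffling stream.
    """
    if not batches:
        raise ValueError("no mini-batches to train on")
    if params.ts > 1 and not config.allow_small_batches:
        smallest = min(b.size for b in batches)
        if smallest < config.min_batch_size:
            raise ValueError(
                f"mini-batch of {smallest} instances is below the minimum of "
                f"{config.min_batch_size} required for concatenation (TS="
                f"{params.ts}); set allow_small_batches to override"
            )
    shuffle_rng = np.random.default_rng([config.seed, 1])
    tie_rng = np.random.default_rng([config.seed, 2])
    velocity = (
        [np.zeros_like(W) for W in params.weights],
        [np.zeros_like(b) for b in params.biases],
    )
    losses = []
    order = np.arange(len(batches))
    for _ in range(config.epochs):
        shuffle_rng.shuffle(order)
        epoch_loss = 0.0
        for idx in order:
            _, loss = backprop_update(
                params, batches[idx], config, rng=tie_rng, velocity=velocity
            )
            epoch_loss += loss
        losses.append(epoch_loss / len(batches))
    return params, losses


def evaluate(
    params: NetworkParams,
    batches: Sequence[MiniBatch],
    rng_seed: int = 0,
) -> float:
    """Accuracy (%) over surviving terminal rows of all mini-batches.

    A row counts as correct when the softmax argmax equals the class voted
    from its terminal pooled label counts.
    """
    rng = np.random.default_rng(rng_seed)
    correct = 0
    total = 0
    for batch in batches:
        state = forward(params, batch)
        preds = state.output.argmax(axis=1)
        truth = vote_rows(state.final_counts, rng)
        correct += int((preds == truth).sum())
        total += len(truth)
    if total == 0:
        raise ValueError("no surviving instances to evaluate")
    return 100.0 * correct / total


def param_count(layer_sizes: Sequence[int], ts: int) -> int:
    """Number of connection weights (biases excluded from the complexity metric)."""
    return sum(fi * fo for fi, fo in connection_shapes(layer_sizes, ts))


def equivalent_dbn_config(
    dtcn_sizes: Sequence[int], ts: int
) -> tuple[int, ...]:
    """Hidden widths of the plain (TS=1) network of matched complexity.

    All hidden layers but the last are widened to a common width, the last is
    kept, and the width whose weights-only parameter count is closest to the
    DTCN's is returned (ties toward the smaller count).  Isolates the effect
    of temporal-context concatenation from raw capacity.
    """
    sizes = list(dtcn_sizes)
    hidden = tuple(sizes[1:-1])
    if ts == 1:
        return hidden
    target = param_count(sizes, ts)
    n0, K = sizes[0], sizes[-1]
    L = len(hidden)
    best: tuple[int, int, int] | None = None  # (|diff|, count, m)
    for m in range(1, max(8 * max(hidden), 64) + 1):
        widths = (m,) * (L - 1) + (hidden[-1],) if L >= 2 else (m,)
        count = param_count([n0, *widths, K], 1)
        key = (abs(count - target), count, m)
        if best is None or key < best:
            best = key
    assert best is not None
    m = best[2]
    return (m,) * (L - 1) + (hidden[-1],) if L >= 2 else (m,)


def save_model(params: NetworkParams, path: str | Path) -> None:
    """Serialize layer sizes, TS and parameters to a versioned JSON container."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "layer_sizes": list(params.layer_sizes),
        "ts": params.ts,
        "weights": [W.tolist() for W in params.weights],
        "biases": [b.tolist() for b in params.biases],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> NetworkParams:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {version!r}")
    return NetworkParams(
        tuple(payload["layer_sizes"]),
        int(payload["ts"]),
        [np.asarray(W, dtype=float) for W in payload["weights"]],
        [np.asarray(b, dtype=float) for b in payload["biases"]],
    )
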