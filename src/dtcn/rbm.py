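"""Greedy layer-wise pretraining of the network as a stack of RBMs.

Pretraining is pair-wise, unsupervised and forward-only: the first restricted
Boltzmann machine sits between the (standardized, Gaussian-visible) time-delay
input and hidden layer 1; every deeper RBM sits between a *concatenation
sublayer* — Bernoulli visibles formed by joining TS consecutive hidden
probability rows — and the next hidden layer, because that is where the
network's weights actually live.  Contrastive divergence (CD-k, default k=1)
trains each RBM; label counts are never read.  The softmax connection is not
pretrained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_prep import MiniBatch
from .network import NetworkParams, concatenate, sigmoid

__all__ = ["RBMParams", "PretrainConfig", "cd_step", "pretrain_stack"]


@dataclass
class RBMParams:
    """One restricted Boltzmann machine.

    ``visible_type`` is ``"gaussian"`` (linear visible reconstruction, assumes
    unit-variance standardized inputs) or ``"bernoulli"`` (sigmoid visible
    reconstruction, for probabilities in [0, 1]).
    """

    W: np.ndarray
    b_vis: np.ndarray
    b_hid: np.ndarray
    visible_type: str = "bernoulli"

    def __post_init__(self) -> None:
        nv, nh = self.W.shape
        if self.b_vis.shape != (nv,) or self.b_hid.shape != (nh,):
            raise ValueError("bias shapes inconsistent with weight matrix")
        if self.visible_type not in ("gaussian", "bernoulli"):
            raise ValueError("visible_type must be 'gaussian' or 'bernoulli'")

    @classmethod
    def initialize(
        cls,
        n_visible: int,
        n_hidden: int,
        visible_type: str,
        rng: np.random.Generator,
    ) -> "RBMParams":
        W = rng.normal(0.0, 0.01, size=(n_visible, n_hidden))
        return cls(W, np.zeros(n_visible), np.zeros(n_hidden), visible_type)


@dataclass
class PretrainConfig:
    """Schedule for greedy CD pretraining (per connection)."""

    epochs: int = 5
    learning_rate: float = 0.05
    k: int = 1
    seed: int = 0
    enabled: bool = True


def _hidden_probs(rbm: RBMParams, v: np.ndarray) -> np.ndarray:
    return sigmoid(v @ rbm.W + rbm.b_hid)


def _visible_recon(rbm: RBMParams, h: np.ndarray) -> np.ndarray:
    lin = h @ rbm.W.T + rbm.b_vis
    return lin if rbm.visible_type == "gaussian" else sigmoid(lin)


def cd_step(
    rbm: RBMParams,
    visible_batch: np.ndarray,
    k: int = 1,
    lr: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[RBMParams, float]:
    """One contrastive-divergence (CD-k) update on a visible mini-batch.

    Positive statistics come from the data; negative statistics from the
    reconstruction after k alternating Gibbs steps (hidden units sampled,
    visible units reconstructed as means).  Returns the updated RBM and the
    mean squared reconstruction error of the batch.
    """
    if k < 1:
        raise ValueError("CD order k must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    v0 = np.asarray(visible_batch, dtype=float)
    n = v0.shape[0]
    h0 = _hidden_probs(rbm, v0)
    h_sample = (rng.random(h0.shape) < h0).astype(float)
    for _ in range(k):
        v_recon = _visible_recon(rbm, h_sample)
        h_recon = _hidden_probs(rbm, v_recon)
        h_sample = (rng.random(h_recon.shape) < h_recon).astype(float)
    dW = (v0.T @ h0 - v_recon.T @ h_recon) / n
    dbv = (v0 - v_recon).mean(axis=0)
    dbh = (h0 - h_recon).mean(axis=0)
    rbm.W += lr * dW
    rbm.b_vis += lr * dbv
    rbm.b_hid += lr * dbh
    if not (np.all(np.isfinite(rbm.W)) and np.all(np.isfinite(rbm.b_vis))
            and np.all(np.isfinite(rbm.b_hid))):
        raise FloatingPointError("non-finite RBM update; reduce the learning rate")
    err = float(np.mean((v0 - v_recon) ** 2))
    return rbm, err


def pretrain_stack(
    params: NetworkParams,
    batches: Sequence[MiniBatch],
    config: PretrainConfig | None = None,
) -> NetworkParams:
    """Greedily pretrain every non-softmax connection of the network.

    Connection 0 is trained as a Gaussian-visible RBM on the raw (standardized)
    input features; connection i>0 as a Bernoulli-visible RBM whose visible
    data are the concatenated mean-field hidden probabilities of the layer
    below, computed with the weights already pretrained.  Propagation between
    levels uses activation probabilities, never samples.  Weights and hidden
    biases are transferred into ``params`` in place and returned; the softmax
    connection keeps its initialization.
    """
    if config is None:
        config = PretrainConfig()
    if not config.enabled:
        return params
    if not batches:
        raise ValueError("no mini-batches to pretrain on")
    if min(b.size for b in batches) < params.min_batch_size:
        raise ValueError(
            f"mini-batches too small for {params.n_hidden} concatenations at "
            f"TS={params.ts}; need at least {params.min_batch_size} instances"
        )
    rng = np.random.default_rng([config.seed, 3])
    # visible data per level; labels are never consulted
    visibles = [b.features for b in batches]
    n_pretrain = len(params.weights) - 1
    for i in range(n_pretrain):
        n_vis, n_hid = params.weights[i].shape
        rbm = RBMParams(
            params.weights[i].copy(),
            np.zeros(n_vis),
            params.biases[i].copy(),
            "gaussian" if i == 0 else "bernoulli",
        )
        for _ in range(config.epochs):
            for v in visibles:
                cd_step(rbm, v, k=config.k, lr=config.learning_rate, rng=rng)
        params.weights[i] = rbm.W
        params.biases[i] = rbm.b_hid
        if i < n_pretrain - 1:
            visibles = [
                concatenate(sigmoid(v @ rbm.W + rbm.b_hid), params.ts)
                for v in visibles
            ]
    return params
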