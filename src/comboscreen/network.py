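"""Two-level residual feedforward network for drug-pair growth regression.

The architecture has two stages trained jointly end-to-end on mean squared
error:

* feature-encoding submodels — one fully connected block per molecular
  feature type (gene expression, microRNA, proteome, ...), plus a single
  drug-descriptor block whose weights and layers are shared between the two
  drug slots (the slots are chemically symmetric, so the mechanism encoding
  the first drug is reused for the second);
* a growth-prediction tower — a deeper fully connected block over the
  concatenated encodings, ending in a linear unit that outputs the predicted
  minimum growth fraction.

Adjacent layers of equal width are optionally linked by an additive residual
skip, which eases optimization of deeper stacks.  Single-agent measurements
are handled by replicating the same descriptor vector into both drug slots.

Everything here is plain NumPy with hand-written backpropagation; all
randomness (initialization, shuffling, dropout) flows from one Generator so
runs are repeatable from a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid architecture configuration."""


def _relu(z):
    return np.maximum(z, 0.0)


class MLPBlock:
    """A fully connected stack with ReLU units and optional residual skips.

    A skip connects the input and output of a layer whenever their dimensions
    match; with ``residual=True`` all hidden widths in the block must be equal
    so every adjacent hidden pair is skip-connected (a pyramid-shaped block
    cannot carry skips and is rejected).

    Forward/backward are functional in the activations: ``forward`` returns
    ``(out, cache)`` and ``backward`` consumes the cache, so one block can be
    applied to several inputs in the same pass (weight sharing).
    """

    def __init__(self, n_in, widths, residual, rng, dropout=0.0):
        widths = list(widths)
        if not widths:
            raise ConfigurationError("a block needs at least one hidden layer")
        if residual and len(set(widths)) > 1:
            raise ConfigurationError(
                f"residual skips require equal adjacent widths, got {widths}"
            )
        self.residual = residual
        self.dropout = dropout
        self.widths = widths
        self.params = []  # list of [W, b]
        prev = n_in
        for w in widths:
            # He initialization, suited to ReLU units; skip-carrying layers
            # start small so the block begins near the identity and the
            # activation variance does not compound with depth
            W = rng.normal(0.0, np.sqrt(2.0 / prev), size=(prev, w))
            if residual and prev == w:
                W *= 0.25
            b = np.zeros(w)
            self.params.append([W, b])
            prev = w
        self.n_out = prev

    def forward(self, x, train=False, rng=None):
        h = x
        cache = []
        for W, b in self.params:
            z = h @ W + b
            a = _relu(z)
            mask = None
            if train and self.dropout > 0.0:
                mask = (rng.uniform(size=a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * mask
            skip = self.residual and W.shape[0] == W.shape[1]
            out = a + h if skip else a
            cache.append((h, z, mask, skip))
            h = out
        return h, cache

    def backward(self, dh, cache):
        """Return (d_input, grads) where grads parallels ``self.params``."""
        grads = [None] * len(self.params)
        for li in range(len(self.params) - 1, -1, -1):
            W, _b = self.params[li]
            h, z, mask, skip = cache[li]
            da = dh * mask if mask is not None else dh
            dz = da * (z > 0)
            grads[li] = [h.T @ dz, dz.sum(axis=0)]
            dh = dz @ W.T + (dh if skip else 0.0)
        return dh, grads


class PairResponseNetwork:
    """The assembled two-level network.

    Parameters
    ----------
    cell_dims : ordered mapping of feature-type name -> input width
    drug_dim : descriptor width for each drug slot
    encoder_layers : mapping name -> widths, or one widths tuple for all
        cell encoders
    drug_encoder_layers : widths of the shared drug encoder
    tower_layers : widths of the growth-prediction tower
    residual : link equal-width adjacent layers with additive skips
    merge : "concat" keeps the two drug encodings in slot order (the literal
        design, order-sensitive); "sum" adds them, making the network
        structurally symmetric in the drug slots
    """

    def __init__(
        self,
        cell_dims: dict,
        drug_dim: int,
        encoder_layers,
        drug_encoder_layers,
        tower_layers,
        residual: bool,
        merge: str,
        dropout: float,
        rng: np.random.Generator,
    ):
        if drug_dim < 1:
            raise ConfigurationError("drug_dim must be >= 1")
        if not cell_dims and drug_dim < 1:
            raise ConfigurationError("at least one feature type must be configured")
        if merge not in ("concat", "sum"):
            raise ConfigurationError("merge must be 'concat' or 'sum'")
        self.cell_names = list(cell_dims)
        self.cell_dims = dict(cell_dims)
        self.drug_dim = drug_dim
        self.merge = merge
        if not isinstance(encoder_layers, dict):
            encoder_layers = {name: encoder_layers for name in self.cell_names}
        self.cell_encoders = {
            name: MLPBlock(self.cell_dims[name], encoder_layers[name], residual, rng, dropout)
            for name in self.cell_names
        }
        # exactly one drug encoder instance serves both slots
        self.drug_encoder = MLPBlock(drug_dim, drug_encoder_layers, residual, rng, dropout)
        tower_in = sum(e.n_out for e in self.cell_encoders.values())
        tower_in += self.drug_encoder.n_out * (2 if merge == "concat" else 1)
        if tower_in == 0:
            raise ConfigurationError("no feature types configured")
        self.tower = MLPBlock(tower_in, tower_layers, residual, rng, dropout)
        self.head = [
            rng.normal(0.0, np.sqrt(1.0 / self.tower.n_out), size=(self.tower.n_out, 1)),
            np.zeros(1),
        ]

    # --- parameter plumbing -------------------------------------------------
    def parameters(self):
        """Flat list of parameter arrays; shared drug weights appear once."""
        out = []
        for name in self.cell_names:
            for p in self.cell_encoders[name].params:
                out.extend(p)
        for p in self.drug_encoder.params:
            out.extend(p)
        for p in self.tower.params:
            out.extend(p)
        out.extend(self.head)
        return out

    def n_parameters(self):
        return int(sum(p.size for p in self.parameters()))

    # --- forward / backward -------------------------------------------------
    def forward(self, cell_blocks, drug_a, drug_b, train=False, rng=None):
        caches = {"cells": {}}
        encs = []
        for name in self.cell_names:
            e, c = self.cell_encoders[name].forward(cell_blocks[name], train, rng)
            caches["cells"][name] = c
            encs.append(e)
        ea, ca = self.drug_encoder.forward(drug_a, train, rng)
        eb, cb = self.drug_encoder.forward(drug_b, train, rng)
        caches["drug_a"], caches["drug_b"] = ca, cb
        if self.merge == "concat":
            h = np.concatenate(encs + [ea, eb], axis=1)
        else:
            h = np.concatenate(encs + [ea + eb], axis=1)
        t, ct = self.tower.forward(h, train, rng)
        caches["tower"] = ct
        caches["tower_in"] = h
        pred = (t @ self.head[0] + self.head[1]).ravel()
        caches["t"] = t
        return pred, caches

    def backward(self, dpred, caches):
        """Gradients in the same order as :meth:`parameters`.

        The shared drug encoder receives the sum of the gradients flowing
        through the two slots.
        """
        t = caches["t"]
        dpred = dpred[:, None]
        g_head = [t.T @ dpred, dpred.sum(axis=0)]
        dt = dpred @ self.head[0].T
        dh, g_tower = self.tower.backward(dt, caches["tower"])

        # split tower-input gradient back into the encoder segments
        grads = []
        offset = 0
        for name in self.cell_names:
            enc = self.cell_encoders[name]
            seg = dh[:, offset:offset + enc.n_out]
            offset += enc.n_out
            _, g = enc.backward(seg, caches["cells"][name])
            for p in g:
                grads.extend(p)
        d = self.drug_encoder.n_out
        if self.merge == "concat":
            seg_a = dh[:, offset:offset + d]
            seg_b = dh[:, offset + d:offset + 2 * d]
        else:
            seg_a = seg_b = dh[:, offset:offset + d]
        _, ga = self.drug_encoder.backward(seg_a, caches["drug_a"])
        _, gb = self.drug_encoder.backward(seg_b, caches["drug_b"])
        for pa, pb in zip(ga, gb):
            grads.extend([pa[0] + pb[0], pa[1] + pb[1]])
        for p in g_tower:
            grads.extend(p)
        grads.extend(g_head)
        return grads


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, params, lr=1e-2):
        self.params = params
        self.lr = lr

    def step(self, grads):
        for p, g in zip(self.params, grads):
            p -= self.lr * g


@dataclass
class TrainingHistory:
    epochs: list = field(default_factory=list)
    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    lr: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"EPOCH": self.epochs, "TRAIN_MSE": self.train_mse,
             "VAL_MSE": self.val_mse, "LR": self.lr}
        )


def _batches(n, batch_size, rng):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


def train_network(
    net: PairResponseNetwork,
    train_data,
    y,
    epochs=50,
    batch_size=32,
    learning_rate=1e-3,
    optimizer="adam",
    reduce_on_plateau=(0.5, 5),
    warmup_epochs=0,
    shuffle_slots=False,
    val_data=None,
    y_val=None,
    rng=None,
) -> TrainingHistory:
    """Train on MSE with Adam, optional LR warm-up and reduce-on-plateau.

    ``train_data`` is ``(cell_blocks: dict, drug_a, drug_b)``.  The plateau
    schedule multiplies the learning rate by ``factor`` after ``patience``
    epochs without improvement of the monitored loss (validation if provided,
    else training).  ``warmup_epochs`` linearly ramps the rate from 0 over the
    first epochs, which stabilizes large-batch / large-rate training.
    ``shuffle_slots`` randomly swaps the two drug slots of half of each batch,
    a train-time symmetrization.
    """
    rng = np.random.default_rng() if rng is None else rng
    cell_blocks, drug_a, drug_b = train_data
    n = len(y)
    params = net.parameters()
    if optimizer == "adam":
        opt = Adam(params, lr=learning_rate)
    elif optimizer == "sgd":
        opt = SGD(params, lr=learning_rate)
    else:
        raise ConfigurationError(f"unknown optimizer {optimizer!r}")

    factor, patience = reduce_on_plateau if reduce_on_plateau else (1.0, np.inf)
    base_lr = learning_rate
    best = np.inf
    stale = 0
    history = TrainingHistory()

    for epoch in range(epochs):
        if warmup_epochs and epoch < warmup_epochs:
            opt.lr = base_lr * (epoch + 1) / warmup_epochs
        mse_accum = 0.0
        for idx in _batches(n, batch_size, rng):
            blocks = {k: v[idx] for k, v in cell_blocks.items()}
            da, db = drug_a[idx], drug_b[idx]
            if shuffle_slots:
                swap = rng.uniform(size=len(idx)) < 0.5
                da, db = np.where(swap[:, None], db, da), np.where(swap[:, None], da, db)
            pred, caches = net.forward(blocks, da, db, train=True, rng=rng)
            err = pred - y[idx]
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or check the inputs"
                )
            mse_accum += loss * len(idx)
            grads = net.backward(2.0 * err / len(idx), caches)
            opt.step(grads)
        train_mse = mse_accum / n

        if val_data is not None:
            vb, vda, vdb = val_data
            vpred, _ = net.forward(vb, vda, vdb, train=False)
            val_mse = float(np.mean((vpred - y_val) ** 2))
        else:
            val_mse = np.nan
        monitored = val_mse if val_data is not None else train_mse

        history.epochs.append(epoch)
        history.train_mse.append(train_mse)
        history.val_mse.append(val_mse)
        history.lr.append(opt.lr)

        if monitored < best - 1e-8:
            best = monitored
            stale = 0
        else:
            stale += 1
            if reduce_on_plateau and stale >= patience and not (
                warmup_epochs and epoch < warmup_epochs
            ):
                opt.lr *= factor
                stale = 0
                logger.debug("epoch %d: reducing learning rate to %g", epoch, opt.lr)
    return history
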