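"""scikit-learn estimator interface to the pair-response network.

:class:`PairResponseRegressor` is a standard sklearn regressor: the design
matrix ``X`` lays the feature blocks side by side in a fixed column order —
the cell-line feature types in the order of ``cell_dims``, then the
descriptor vector of drug A, then the descriptor vector of drug B.  Targets
are minimum growth fractions in [-1, 1].  Single-agent rows simply repeat
the same descriptor vector in both drug slots (see
:meth:`PairResponseRegressor.predict_single`).

The drug encoder weights are shared between the two slots, but ordered
concatenation of the two encodings is still order-sensitive; ``symmetrize``
controls how slot symmetry is obtained (see the parameter docs).
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .network import (
    ConfigurationError,
    PairResponseNetwork,
    train_network,
)

_SYMMETRIZE_MODES = ("none", "average", "sum", "shuffle")


class PairResponseRegressor(RegressorMixin, BaseEstimator):
    """Two-level residual network regressor for (cell, drug A, drug B) growth.

    Parameters
    ----------
    cell_dims : dict of str -> int
        Ordered input widths of the cell-line feature blocks, e.g.
        ``{"expression": 50, "microrna": 20}``.  Column order in ``X`` must
        match.
    drug_dim : int
        Width of each drug-descriptor slot.
    encoder_layers : tuple of int, or dict name -> tuple
        Hidden widths of each cell-feature encoding submodel.
    drug_encoder_layers : tuple of int
        Hidden widths of the shared drug encoder.
    tower_layers : tuple of int
        Hidden widths of the growth-prediction tower (typically deeper than
        the encoders).
    residual : bool
        Link adjacent equal-width layers with additive skips; requires equal
        widths within each block.
    symmetrize : {"average", "none", "sum", "shuffle"}
        How drug-slot symmetry is achieved.  ``"average"`` (default) trains on
        the slots as given and averages the predictions of both orderings at
        inference.  ``"none"`` is the literal ordered design.  ``"sum"`` adds
        the two drug encodings before the tower (structurally symmetric).
        ``"shuffle"`` randomly swaps slots during training and averages at
        inference.
    dropout : float in [0, 1)
        Dropout rate on hidden activations (0 disables).
    epochs, batch_size, learning_rate, optimizer : training schedule.
        The loss is mean squared error; ``optimizer`` is "adam" (recommended)
        or "sgd".
    reduce_on_plateau : (factor, patience) or None
        Multiply the learning rate by ``factor`` after ``patience`` epochs
        without improvement.
    warmup_epochs : int
        Linear learning-rate ramp over the first epochs (0 disables).
    validation_fraction : float
        Fraction of the training rows held out to monitor validation loss
        (0 monitors training loss instead).
    n_ensemble : int
        Number of independently initialized networks whose predictions are
        averaged.  1 is a single network; a small ensemble (3) substantially
        reduces the run-to-run variance of short training budgets.
    single_agent_weight : int
        Replication factor for single-agent rows (detected as rows whose two
        drug slots carry identical descriptors) during training.  Pair rows
        outnumber singles by the pair grid's combinatorics, and the response
        surface is discontinuous across the replicated-slot diagonal, so
        upweighting singles reduces their systematic underprediction.
    random_state : int or None
        Seed for initialization, shuffling and dropout; fixed seed gives a
        repeatable run.

    Attributes
    ----------
    network_ : the first trained :class:`PairResponseNetwork`
    networks_ : all ensemble members
    history_ : per-epoch train/validation MSE and learning rate (first member)
    n_parameters_ : trainable parameter count of one member
    """

    def __init__(
        self,
        cell_dims=None,
        drug_dim=1,
        encoder_layers=(64, 64),
        drug_encoder_layers=(64, 64),
        tower_layers=(64, 64, 64),
        residual=True,
        symmetrize="average",
        dropout=0.0,
        epochs=50,
        batch_size=32,
        learning_rate=1e-3,
        optimizer="adam",
        reduce_on_plateau=(0.5, 5),
        warmup_epochs=0,
        validation_fraction=0.1,
        n_ensemble=1,
        single_agent_weight=1,
        random_state=None,
    ):
        self.cell_dims = cell_dims
        self.drug_dim = drug_dim
        self.encoder_layers = encoder_layers
        self.drug_encoder_layers = drug_encoder_layers
        self.tower_layers = tower_layers
        self.residual = residual
        self.symmetrize = symmetrize
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.reduce_on_plateau = reduce_on_plateau
        self.warmup_epochs = warmup_epochs
        self.validation_fraction = validation_fraction
        self.n_ensemble = n_ensemble
        self.single_agent_weight = single_agent_weight
        self.random_state = random_state

    # --- column bookkeeping -------------------------------------------------
    def _layout(self):
        cell_dims = dict(self.cell_dims or {})
        if not cell_dims:
            raise ConfigurationError("cell_dims must configure at least one feature type")
        if self.drug_dim < 1:
            raise ConfigurationError("drug_dim must be >= 1")
        n_cell = sum(cell_dims.values())
        return cell_dims, n_cell, n_cell + 2 * self.drug_dim

    def _split(self, X, cell_dims):
        blocks = {}
        offset = 0
        for name, width in cell_dims.items():
            blocks[name] = X[:, offset:offset + width]
            offset += width
        drug_a = X[:, offset:offset + self.drug_dim]
        drug_b = X[:, offset + self.drug_dim:offset + 2 * self.drug_dim]
        return blocks, drug_a, drug_b

    # --- sklearn API --------------------------------------------------------
    def fit(self, X, y):
        if self.symmetrize not in _SYMMETRIZE_MODES:
            raise ConfigurationError(
                f"symmetrize must be one of {_SYMMETRIZE_MODES}"
            )
        cell_dims, _, n_features = self._layout()
        X, y = check_X_y(X, y, dtype=float)
        if X.shape[1] != n_features:
            raise ValueError(
                f"X has {X.shape[1]} columns; expected {n_features} "
                "(cell blocks + two drug slots)"
            )
        self.n_features_in_ = n_features
        if self.n_ensemble < 1:
            raise ConfigurationError("n_ensemble must be >= 1")
        root = np.random.default_rng(self.random_state)
        member_rngs = [np.random.default_rng(s)
                       for s in np.random.SeedSequence(
                           root.integers(2**31)).spawn(self.n_ensemble)]

        n = len(y)
        blocks_all, da_all, db_all = self._split(X, cell_dims)
        self.networks_ = []
        self.histories_ = []
        for rng in member_rngs:
            net = PairResponseNetwork(
                cell_dims=cell_dims,
                drug_dim=self.drug_dim,
                encoder_layers=self.encoder_layers,
                drug_encoder_layers=self.drug_encoder_layers,
                tower_layers=self.tower_layers,
                residual=self.residual,
                merge="sum" if self.symmetrize == "sum" else "concat",
                dropout=self.dropout,
                rng=rng,
            )

            if self.validation_fraction and n >= 10:
                n_val = max(1, int(round(self.validation_fraction * n)))
                perm = rng.permutation(n)
                val_idx, tr_idx = perm[:n_val], perm[n_val:]
            else:
                tr_idx, val_idx = np.arange(n), None
            if self.single_agent_weight > 1:
                is_single = np.all(da_all[tr_idx] == db_all[tr_idx], axis=1)
                extra = np.tile(tr_idx[is_single], self.single_agent_weight - 1)
                tr_idx = np.concatenate([tr_idx, extra])
            tr = ({k: v[tr_idx] for k, v in blocks_all.items()},
                  da_all[tr_idx], db_all[tr_idx])
            if val_idx is not None:
                val = ({k: v[val_idx] for k, v in blocks_all.items()},
                       da_all[val_idx], db_all[val_idx])
                y_val = y[val_idx]
            else:
                val, y_val = None, None

            history = train_network(
                net,
                tr,
                y[tr_idx],
                epochs=self.epochs,
                batch_size=self.batch_size,
                learning_rate=self.learning_rate,
                optimizer=self.optimizer,
                reduce_on_plateau=self.reduce_on_plateau,
                warmup_epochs=self.warmup_epochs,
                shuffle_slots=self.symmetrize == "shuffle",
                val_data=val,
                y_val=y_val,
                rng=rng,
            )
            self.networks_.append(net)
            self.histories_.append(history)
        self.network_ = self.networks_[0]
        self.history_ = self.histories_[0]
        self.n_parameters_ = self.network_.n_parameters()
        return self

    def predict(self, X):
        """Predicted minimum growth fraction per row.

        Under ``symmetrize in ("average", "shuffle")`` the prediction is the
        mean of both drug-slot orderings, which makes it order-invariant.
        Batch-order invariant and finite for any valid input.
        """
        check_is_fitted(self, "network_")
        cell_dims, _, n_features = self._layout()
        X = check_array(X, dtype=float)
        if X.shape[1] != n_features:
            raise ValueError(f"X has {X.shape[1]} columns; expected {n_features}")
        blocks, da, db = self._split(X, cell_dims)
        preds = []
        for net in self.networks_:
            pred, _ = net.forward(blocks, da, db, train=False)
            if self.symmetrize in ("average", "shuffle"):
                pred_rev, _ = net.forward(blocks, db, da, train=False)
                pred = 0.5 * (pred + pred_rev)
            preds.append(pred)
        return preds[0] if len(preds) == 1 else np.mean(preds, axis=0)

    def predict_single(self, X):
        """Single-agent prediction: one cell + one drug block.

        ``X`` columns are the cell blocks followed by one descriptor vector;
        the vector is replicated into both drug slots, so the result equals
        ``predict`` with the same descriptors twice, exactly.
        """
        check_is_fitted(self, "network_")
        cell_dims, n_cell, _ = self._layout()
        X = check_array(X, dtype=float)
        if X.shape[1] != n_cell + self.drug_dim:
            raise ValueError(
                f"X has {X.shape[1]} columns; expected {n_cell + self.drug_dim} "
                "(cell blocks + one drug slot)"
            )
        drug = X[:, n_cell:]
        return self.predict(np.hstack([X, drug]))

    # --- persistence --------------------------------------------------------
    def save(self, path):
        """Checkpoint weights + configuration to a single ``.npz`` archive."""
        check_is_fitted(self, "network_")
        arrays = {}
        for mi, net in enumerate(self.networks_):
            for pi, p in enumerate(net.parameters()):
                arrays[f"m{mi}_p{pi}"] = p
        arrays["config"] = np.frombuffer(
            json.dumps(self.get_params()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path) as archive:
            config = json.loads(bytes(archive["config"].tobytes()).decode())
            members = {}
            for name in archive.files:
                if name == "config":
                    continue
                mi, pi = (int(x[1:]) for x in name.split("_"))
                members.setdefault(mi, {})[pi] = archive[name]
        for key in ("encoder_layers", "drug_encoder_layers", "tower_layers",
                    "reduce_on_plateau"):
            if isinstance(config.get(key), list):
                config[key] = tuple(config[key])
        est = cls(**config)
        cell_dims, _, _ = est._layout()
        est.networks_ = []
        for mi in sorted(members):
            net = PairResponseNetwork(
                cell_dims=cell_dims,
                drug_dim=est.drug_dim,
                encoder_layers=est.encoder_layers,
                drug_encoder_layers=est.drug_encoder_layers,
                tower_layers=est.tower_layers,
                residual=est.residual,
                merge="sum" if est.symmetrize == "sum" else "concat",
                dropout=est.dropout,
                rng=np.random.default_rng(0),
            )
            weights = members[mi]
            for pi, p in enumerate(net.parameters()):
                p[...] = weights[pi]
            est.networks_.append(net)
        est.network_ = est.networks_[0]
        est.n_parameters_ = est.network_.n_parameters()
        est.n_features_in_ = sum(dict(est.cell_dims).values()) + 2 * est.drug_dim
        return est


def scaled_estimator(dataset, random_state=None, n_ensemble=3, **overrides):
    """The scaled-down reference configuration used in examples and tests.

    Width-64 encoders and a four-layer width-64 residual tower trained for 50
    epochs with Adam (rate 6e-3, six warm-up epochs, reduce-on-plateau),
    train-time slot shuffling with slot-averaged inference, single-agent rows
    upweighted to match the pair grid's combinatorics (about 7:1 on the
    default screen), and a small ensemble of independent initializations.
    Takes a :class:`~comboscreen.dataset.PairDataset` for the block layout;
    keyword overrides pass through to the constructor.
    """
    params = dict(
        cell_dims=dataset.cell_dims,
        drug_dim=dataset.drug_dim,
        encoder_layers=(64, 64),
        drug_encoder_layers=(64, 64),
        tower_layers=(64, 64, 64, 64),
        residual=True,
        symmetrize="shuffle",
        epochs=50,
        batch_size=32,
        learning_rate=6e-3,
        warmup_epochs=6,
        reduce_on_plateau=(0.6, 4),
        validation_fraction=0.0,
        n_ensemble=n_ensemble,
        single_agent_weight=7,
        random_state=random_state,
    )
    params.update(overrides)
    return PairResponseRegressor(**params)
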