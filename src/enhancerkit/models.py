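"""Compact CNN for accessibility regression and activity classification.

The architecture is a small sequence-to-scalar CNN: four 1D convolutional
blocks (conv -> batch-norm -> ReLU -> max-pool) followed by two dense
blocks (dense -> batch-norm -> ReLU -> dropout) and a single output unit.
The same trunk is used for both tasks; the activity classifier is obtained
by transfer learning — re-initializing a sigmoid-headed copy with the
trained regression weights and fine-tuning every layer with a small
learning rate.

Each model is trained in replicates on several held-out test folds and the
resulting members are averaged at prediction time (``ModelEnsemble``).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .dataprep import EncodedDataset, HOLDOUT, WINDOW
from .genome import Genome
from .sequences import one_hot
from .tracks import write_per_base_bedgraph


class TransferError(ValueError):
    """Pretrained weights do not match the requested architecture."""


@dataclass
class ArchitectureSpec:
    """Hyperparameters of the CNN trunk.

    The default is the full-size architecture; :meth:`compact` returns a
    desk-scale variant used on the small synthetic genome, where the full
    stack would be needlessly slow to train on one CPU.
    """

    conv_filters: list[int] = field(default_factory=lambda: [256, 120, 60, 60])
    conv_kernels: list[int] = field(default_factory=lambda: [7, 3, 3, 3])
    pool_size: int = 3
    pool_type: str = "max"  # 'max' or 'avg' after each conv block
    global_pool: bool = False  # average over positions before the dense head
    dense_units: list[int] = field(default_factory=lambda: [64, 256])
    dropout: float = 0.5
    batch_norm: bool = True
    conv_bias_init: float = 0.0  # negative values start activations sparse
    input_length: int = WINDOW

    def __post_init__(self):
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ValueError("conv_filters and conv_kernels must have equal length")
        if self.pool_size <= 0 or any(k <= 0 for k in self.conv_kernels):
            raise ValueError("pool size and kernels must be positive")
        if self.pool_type not in ("max", "avg"):
            raise ValueError("pool_type must be 'max' or 'avg'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def compact(cls) -> "ArchitectureSpec":
        """Desk-scale variant: a wide-kernel motif-detector layer, local max
        pooling (winner-take-all within 10 bp keeps instance counts), a
        kernel-1 thresholding layer that suppresses near-miss background
        responses, and a global average pool feeding a linear readout.  The
        readout sees only per-filter occupancy sums, so a few hundred
        training regions cannot be memorized — the network is forced to
        learn motifs.  Batch norm is dropped and the conv biases start
        negative: sparse activations make rare-motif filters emerge much
        faster at this data scale."""
        return cls(conv_filters=[32, 16], conv_kernels=[8, 1], pool_size=10, pool_type="max",
                   global_pool=True, dense_units=[], dropout=0.0,
                   batch_norm=False, conv_bias_init=-0.5)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(**d)


@dataclass
class TrainingConfig:
    learning_rate: float = 0.005
    loss: str = "mse"  # 'mse' or 'bce'
    batch_size: int = 128
    patience: int = 5
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    @classmethod
    def accessibility(cls, **kw) -> "TrainingConfig":
        return cls(**{"learning_rate": 0.005, "loss": "mse", "patience": 5, **kw})

    @classmethod
    def activity(cls, **kw) -> "TrainingConfig":
        return cls(**{"learning_rate": 1e-4, "loss": "bce", "patience": 20, **kw})

    def to_dict(self) -> dict:
        return asdict(self)


def build_model(spec: ArchitectureSpec, head: str = "linear", seed: int = 0) -> nn.Model:
    """Assemble the CNN; ``head`` is 'linear' (regression) or 'sigmoid'."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    length, channels = spec.input_length, 4
    pool_cls = nn.MaxPool1D if spec.pool_type == "max" else nn.AvgPool1D
    for filters, kernel in zip(spec.conv_filters, spec.conv_kernels):
        conv = nn.Conv1D(channels, filters, kernel, rng)
        conv.b[:] = spec.conv_bias_init
        layers.append(conv)
        if spec.batch_norm:
            layers.append(nn.BatchNorm(filters))
        layers += [nn.ReLU(), pool_cls(spec.pool_size)]
        channels = filters
        length //= spec.pool_size
    if length < 1:
        raise ValueError("architecture pools the sequence away entirely")
    if spec.global_pool and length > 1:
        layers.append(nn.AvgPool1D(length))
        length = 1
    layers.append(nn.Flatten())
    units = length * channels
    for out_units in spec.dense_units:
        layers.append(nn.Dense(units, out_units, rng))
        if spec.batch_norm:
            layers.append(nn.BatchNorm(out_units))
        layers += [nn.ReLU(), nn.Dropout(spec.dropout, np.random.default_rng(seed + 7919))]
        units = out_units
    layers.append(nn.Dense(units, 1, rng))
    model = nn.Model(layers, head=head)
    model.spec = spec
    return model


def _loss_fn(name: str):
    if name == "mse":
        return nn.mse_loss
    if name == "bce":
        return nn.bce_with_logits_loss
    raise ValueError(f"unknown loss {name!r}")


def fit(
    model: nn.Model,
    data: EncodedDataset,
    cfg: TrainingConfig,
    val_fold: int,
    test_fold: int | None = None,
) -> dict:
    """Minibatch training with early stopping on validation loss.

    Trains on every fold except ``val_fold``, ``test_fold`` and the holdout
    chromosome; stops after ``cfg.patience`` epochs without validation
    improvement and restores the best-validation weights.
    """
    folds = data.folds
    excluded = {val_fold, test_fold, HOLDOUT}
    train_mask = np.array([f not in excluded for f in folds])
    val_mask = np.array([f == val_fold for f in folds])
    if train_mask.sum() == 0:
        raise ValueError("no training data after excluding validation/test/holdout folds")
    if val_mask.sum() == 0:
        raise ValueError(f"validation fold {val_fold} is empty")
    Xtr, ytr = data.X[train_mask], data.y[train_mask]
    Xval, yval = data.X[val_mask], data.y[val_mask]

    loss_fn = _loss_fn(cfg.loss)
    rng = np.random.default_rng(cfg.seed)
    adam = nn.Adam(model, lr=cfg.learning_rate)
    best_val, best_weights, wait = np.inf, model.get_weights(), 0
    history = {"train_loss": [], "val_loss": []}
    for _epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(Xtr))
        epoch_losses = []
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            out = model.forward(Xtr[idx], training=True)
            loss, dout = loss_fn(out, ytr[idx])
            model.backward(dout, need_input_grad=False)
            adam.step()
            epoch_losses.append(loss)
        val_loss, _ = loss_fn(model.predict(Xval, output="logit"), yval)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val:
            best_val, best_weights, wait = val_loss, model.get_weights(), 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    model.set_weights(best_weights)
    history["best_val_loss"] = float(best_val)
    return history


def train_accessibility(
    model: nn.Model, data: EncodedDataset, cfg: TrainingConfig, val_fold: int, test_fold: int | None = None
) -> tuple[nn.Model, dict]:
    if cfg.loss != "mse":
        raise ValueError("accessibility training uses MSE loss")
    history = fit(model, data, cfg, val_fold, test_fold)
    return model, history


def transfer_learn_activity(
    pretrained: nn.Model,
    data: EncodedDataset,
    cfg: TrainingConfig,
    val_fold: int,
    test_fold: int | None = None,
    spec: ArchitectureSpec | None = None,
) -> tuple[nn.Model, dict]:
    """Fine-tune a sigmoid-headed copy of a trained regression model."""
    if cfg.loss != "bce":
        raise ValueError("activity training uses binary cross-entropy")
    spec = spec or getattr(pretrained, "spec", None)
    if spec is None:
        raise TransferError("need an ArchitectureSpec to rebuild the classifier")
    model = build_model(spec, head="sigmoid", seed=cfg.seed)
    try:
        model.set_weights(pretrained.get_weights())
    except (KeyError, ValueError) as exc:
        raise TransferError(f"pretrained weights do not match architecture: {exc}") from exc
    history = fit(model, data, cfg, val_fold, test_fold)
    return model, history


@dataclass
class ModelEnsemble:
    """Replicate x test-fold model collection with an averaged prediction."""

    members: list[nn.Model]
    task: str  # 'accessibility' or 'activity'
    tissue: str
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        heads = {m.head for m in self.members}
        if len(heads) > 1:
            raise ValueError("ensemble members disagree on head type")

    def predict(self, X: np.ndarray, output: str = "response", batch_size: int = 256) -> np.ndarray:
        """Arithmetic mean over members.

        For classifiers, ``output='logit'`` averages pre-sigmoid logits
        (the quantity the design stage optimizes) while ``'response'``
        averages the members' sigmoid outputs.
        """
        if X.ndim == 2:
            X = X[None]
        per_member = [m.predict(X, output=output, batch_size=batch_size) for m in self.members]
        return np.mean(per_member, axis=0)

    def member_predictions(self, X: np.ndarray, output: str = "response") -> np.ndarray:
        if X.ndim == 2:
            X = X[None]
        return np.stack([m.predict(X, output=output) for m in self.members])

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """Mean over members of d(raw output)/d(input)."""
        if X.ndim == 2:
            X = X[None]
        return np.mean([m.input_gradient(X) for m in self.members], axis=0)

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Raw-output value and input gradient for a single (L, 4) input,
        averaged over members (one forward + one backward pass per member)."""
        values, grads = [], []
        for m in self.members:
            values.append(float(m.forward(x[None], training=False)[0]))
            grads.append(m.backward(np.ones(1, dtype=np.float32))[0])
        return float(np.mean(values)), np.mean(grads, axis=0)

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        spec = getattr(self.members[0], "spec", None)
        sidecar = {
            "task": self.task,
            "tissue": self.tissue,
            "n_members": len(self.members),
            "head": self.members[0].head,
            "architecture": spec.to_dict() if spec else None,
            "provenance": self.provenance,
        }
        with open(os.path.join(directory, "ensemble.json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)
        for i, member in enumerate(self.members):
            member.save(os.path.join(directory, f"member_{i}.npz"))

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "ModelEnsemble":
        with open(os.path.join(directory, "ensemble.json")) as fh:
            sidecar = json.load(fh)
        spec = ArchitectureSpec.from_dict(sidecar["architecture"])
        members = []
        for i in range(sidecar["n_members"]):
            model = build_model(spec, head=sidecar["head"], seed=0)
            model.load(os.path.join(directory, f"member_{i}.npz"))
            members.append(model)
        return cls(members=members, task=sidecar["task"], tissue=sidecar["tissue"], provenance=sidecar["provenance"])


def train_ensemble(
    spec: ArchitectureSpec,
    data: EncodedDataset,
    cfg: TrainingConfig,
    tissue: str,
    task: str,
    test_folds: list[int],
    replicates: int = 2,
    pretrained_members: list[nn.Model] | None = None,
) -> ModelEnsemble:
    """Train ``replicates`` models per held-out test fold and bundle them.

    For the activity task, ``pretrained_members`` (cycled over) provide the
    transfer-learning initialization; without them the classifier is trained
    directly from random weights (the no-pretraining baseline).
    """
    present = sorted({f for f in data.folds if f != HOLDOUT})
    members, provenance = [], []
    i = 0
    for test_fold in test_folds:
        val_fold = present[(present.index(test_fold) + 1) % len(present)]
        for rep in range(replicates):
            seed = cfg.seed + 1000 * i + rep
            run_cfg = TrainingConfig(**{**cfg.to_dict(), "seed": seed})
            if task == "accessibility":
                model = build_model(spec, head="linear", seed=seed)
                model, history = train_accessibility(model, data, run_cfg, val_fold, test_fold)
            elif pretrained_members is not None:
                base = pretrained_members[i % len(pretrained_members)]
                model, history = transfer_learn_activity(base, data, run_cfg, val_fold, test_fold, spec=spec)
            else:
                model = build_model(spec, head="sigmoid", seed=seed)
                history = fit(model, data, run_cfg, val_fold, test_fold)
            members.append(model)
            provenance.append(
                {"test_fold": test_fold, "val_fold": val_fold, "replicate": rep, "seed": seed,
                 "epochs": len(history["val_loss"]), "best_val_loss": history["best_val_loss"]}
            )
            i += 1
    return ModelEnsemble(members=members, task=task, tissue=tissue, provenance=provenance)


def predict_track(
    ensemble: ModelEnsemble,
    genome: Genome,
    chrom: str,
    stride: int = 200,
    window: int = WINDOW,
    out_bedgraph: str | os.PathLike | None = None,
    batch_size: int = 128,
) -> np.ndarray:
    """Sliding-window predictions averaged per base over overlapping windows.

    Returns a per-base vector for ``chrom`` (NaN where no window covers);
    optionally writes it as bedGraph.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    length = genome.length(chrom)
    if length < window:
        raise ValueError(f"{chrom} is shorter than one window")
    starts = list(range(0, length - window + 1, stride))
    sums = np.zeros(length)
    counts = np.zeros(length)
    for i in range(0, len(starts), batch_size):
        batch = starts[i : i + batch_size]
        X = np.stack([one_hot(genome.fetch_codes(chrom, s, s + window)) for s in batch])
        preds = ensemble.predict(X)
        for s, p in zip(batch, preds):
            sums[s : s + window] += p
            counts[s : s + window] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if out_bedgraph is not None:
        write_per_base_bedgraph(out_bedgraph, chrom, values)
    return values
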