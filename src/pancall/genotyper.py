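"""CNN genotyper: train on labelled pileup tensors, predict genotype
probabilities over {REF, HET, HOM_ALT}.

The classifier is intentionally compact — three strided conv blocks, a
row-mean pool that preserves the column axis, and a small dense head —
sized for CPU training on desk-scale example sets in minutes. Class
imbalance (REF candidates dominate) is handled with inverse-frequency
sample weights. Early stopping monitors holdout loss.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .nn import ConvNet, softmax
from .pileup import CHANNELS, PileupExample

__all__ = [
    "ModelConfig",
    "GenotypeProbabilities",
    "TrainedModel",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

N_CLASSES = 3  # REF, HET, HOM_ALT


@dataclass(frozen=True)
class ModelConfig:
    conv_layers: tuple[tuple[int, int, int], ...] = (
        (8, 3, 3),
        (16, 3, 2),
        (32, 3, 2),
    )  # (filters, kernel, stride); stride-3 first layer keeps CPU cost low
    dense_units: tuple[int, ...] = (64,)
    dropout: float = 0.0
    learning_rate: float = 3e-3
    batch_size: int = 64
    epochs: int = 10
    patience: int = 3
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(
            f <= 0 or k <= 0 or s <= 0 for f, k, s in self.conv_layers
        ) or any(u <= 0 for u in self.dense_units):
            raise ValueError("all layer sizes must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass(frozen=True)
class GenotypeProbabilities:
    p_ref: float
    p_het: float
    p_hom: float

    def __post_init__(self) -> None:
        total = self.p_ref + self.p_het + self.p_hom
        if not (abs(total - 1.0) < 1e-6):
            raise ValueError(f"probabilities sum to {total}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_ref, self.p_het, self.p_hom])


@dataclass
class TrainedModel:
    net: ConvNet
    config: ModelConfig
    input_shape: tuple[int, int, int]
    channels: tuple[str, ...]
    log: list[dict] = field(default_factory=list)


def _check_shapes(examples: Sequence[PileupExample]) -> tuple[int, int, int]:
    shapes = {ex.tensor.shape for ex in examples}
    if len(shapes) > 1:
        raise ValueError(f"examples have mismatched tensor shapes: {shapes}")
    return next(iter(shapes))


def _labels(examples: Sequence[PileupExample]) -> np.ndarray:
    return np.array(
        [ex.label if ex.label is not None else -1 for ex in examples],
        dtype=np.int64,
    )


def _batched_proba(net: ConvNet, examples: Sequence[PileupExample],
                   batch_size: int = 64) -> np.ndarray:
    """Predict probabilities without materializing one big float32 stack;
    tensors are stored compactly (float16) and cast per batch."""
    out = []
    for i in range(0, len(examples), batch_size):
        xb = np.stack(
            [ex.tensor for ex in examples[i : i + batch_size]]
        ).astype(np.float32)
        logits, _ = net.forward(xb, train=False)
        out.append(softmax(logits))
    return (
        np.concatenate(out, axis=0)
        if out
        else np.zeros((0, N_CLASSES), dtype=np.float32)
    )


def train(
    examples: Sequence[PileupExample],
    model_config: ModelConfig = ModelConfig(),
    holdout_contigs: Sequence[str] = (),
) -> TrainedModel:
    """Train the genotyper.

    Examples on ``holdout_contigs`` are excluded from gradient updates and
    used as the validation set for early stopping and the reported holdout
    accuracy (the held-out-chromosome convention). Without holdout contigs
    a seeded 10% split of the training examples is used instead. All
    randomness (init, shuffling, dropout) derives from ``model_config.seed``.
    """
    if not examples:
        raise ValueError("no training examples")
    if any(ex.label is None for ex in examples):
        raise ValueError("all training examples must be labelled")
    holdout_contigs = set(holdout_contigs)
    contigs = {ex.candidate.contig for ex in examples}
    train_ex = [ex for ex in examples if ex.candidate.contig not in holdout_contigs]
    val_ex = [ex for ex in examples if ex.candidate.contig in holdout_contigs]
    if not train_ex:
        raise ValueError(
            "holdout contigs cover every training contig "
            f"({sorted(contigs)}); nothing left to train on"
        )
    rng = np.random.default_rng(model_config.seed)
    if not val_ex:
        idx = rng.permutation(len(train_ex))
        n_val = max(1, len(train_ex) // 10)
        val_ex = [train_ex[i] for i in idx[:n_val]]
        train_ex = [train_ex[i] for i in idx[n_val:]]

    input_shape = _check_shapes(list(train_ex) + list(val_ex))
    y_train = _labels(train_ex)
    y_val = _labels(val_ex)
    classes = np.unique(y_train)
    if len(classes) < 2:
        raise ValueError(
            f"training set contains a single label class ({classes.tolist()}); "
            "need at least two"
        )

    if model_config.class_weighting:
        counts = np.bincount(y_train, minlength=N_CLASSES).astype(np.float64)
        inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
        weights_by_class = inv / inv[counts > 0].mean()
        sample_weight = weights_by_class[y_train].astype(np.float32)
    else:
        sample_weight = np.ones(len(y_train), dtype=np.float32)

    net = ConvNet(
        input_shape=input_shape,
        conv_layers=model_config.conv_layers,
        dense_units=model_config.dense_units,
        n_classes=N_CLASSES,
        seed=model_config.seed,
        dropout=model_config.dropout,
    )
    log: list[dict] = []
    best_state = net.state_dict()
    best_val = np.inf
    stale = 0
    n = len(train_ex)
    for epoch in range(model_config.epochs):
        order = rng.permutation(n)
        epoch_loss, nb = 0.0, 0
        for i in range(0, n, model_config.batch_size):
            sel = order[i : i + model_config.batch_size]
            xb = np.stack([train_ex[j].tensor for j in sel]).astype(np.float32)
            loss, grads = net.loss_and_grads(
                xb, y_train[sel], sample_weight[sel], rng=rng
            )
            net.adam_step(grads, model_config.learning_rate)
            epoch_loss += loss
            nb += 1
        val_probs = _batched_proba(net, val_ex, model_config.batch_size)
        eps = 1e-12
        val_loss = float(
            -np.log(val_probs[np.arange(len(y_val)), y_val] + eps).mean()
        )
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        log.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(nb, 1),
                "holdout_loss": val_loss,
                "holdout_accuracy": val_acc,
            }
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = net.state_dict()
            stale = 0
        else:
            stale += 1
            if stale > model_config.patience:
                break
    net.load_state_dict(best_state)
    return TrainedModel(
        net=net,
        config=model_config,
        input_shape=tuple(input_shape),
        channels=CHANNELS,
        log=log,
    )


def predict(
    model: TrainedModel, examples: Sequence[PileupExample]
) -> list[GenotypeProbabilities]:
    """Genotype probabilities for each example, order preserved."""
    if not examples:
        return []
    shape = _check_shapes(examples)
    if tuple(shape) != tuple(model.input_shape):
        raise ValueError(
            f"example tensor shape {tuple(shape)} does not match model "
            f"input shape {tuple(model.input_shape)}"
        )
    probs = _batched_proba(model.net, examples).astype(np.float64)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return [GenotypeProbabilities(*row) for row in probs]


def save_checkpoint(model: TrainedModel, path: str | os.PathLike) -> None:
    """Checkpoint = weights container + JSON of config + shape/channel
    descriptor. Predicting from a reloaded checkpoint is bitwise identical."""
    path = os.fspath(path)
    meta = {
        "config": {
            **asdict(model.config),
            "conv_layers": [list(l) for l in model.config.conv_layers],
            "dense_units": list(model.config.dense_units),
        },
        "input_shape": list(model.input_shape),
        "channels": list(model.channels),
        "log": model.log,
    }
    np.savez(
        path if path.endswith(".npz") else path + ".npz",
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.net.state_dict(),
    )


def load_checkpoint(path: str | os.PathLike) -> TrainedModel:
    path = os.fspath(path)
    if not path.endswith(".npz"):
        path = path + ".npz"
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg_dict = dict(meta["config"])
    cfg_dict["conv_layers"] = tuple(tuple(l) for l in cfg_dict["conv_layers"])
    cfg_dict["dense_units"] = tuple(cfg_dict["dense_units"])
    config = ModelConfig(**cfg_dict)
    input_shape = tuple(meta["input_shape"])
    net = ConvNet(
        input_shape=input_shape,
        conv_layers=config.conv_layers,
        dense_units=config.dense_units,
        n_classes=N_CLASSES,
        seed=config.seed,
        dropout=config.dropout,
    )
    net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return TrainedModel(
        net=net,
        config=config,
        input_shape=input_shape,
        channels=tuple(meta["channels"]),
        log=list(meta["log"]),
    )
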