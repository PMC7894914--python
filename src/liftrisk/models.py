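"""Model zoo and training protocol.

Five classifiers over the three risk levels:

``proposed_avgpool``
    The headline model: a slimmed VGGNet-B variant on the 95x95x3 image
    encoding, with 2x2 *average* pooling in place of max pooling and a
    32/64/64/128/128 filter ladder.  Layer stack:
    conv32-3x3 / avgpool / drop / conv64 / conv64 / avgpool / drop /
    conv128 / conv128 / avgpool / drop / flatten / dense1024 / batch-norm /
    drop / softmax(3).  All convolutions are size-preserving with ReLU, so
    pooling alone downsamples: 95 -> 47 -> 23 -> 11.
``vggb_maxpool``
    Identical except every pooling layer is max pooling.
``simple_cnn``
    Convolutional layers and a softmax output only (no pooling, no hidden
    dense layer): three size-preserving 3x3 conv blocks (32/64/128, ReLU).
``mlp``
    flatten / dense1024 ReLU / dropout / softmax(3).
``cnn_lstm``
    Sequence model on the 12x750x3 stream tensor: each frame's 12x1x3
    column becomes a 36-feature step; 1-D convolutions over time feed
    stacked LSTM layers and a softmax head (DeepConvLSTM family).

All models train identically: Adam at learning rate alpha, categorical
cross-entropy, L2 regularisation (lambda) on the final softmax dense layer
only, and early stopping that monitors the *training* loss (no internal
validation split) with min_delta 0 and patience 10, restoring the
best-loss weights.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .dataset import N_CLASSES, make_folds, one_hot
from .preprocessing import (
    IMAGE_SIDE,
    MAX_FRAMES,
    N_STREAMS,
    ChannelScaler,
    encode_image,
    rezero_padding,
)

__all__ = [
    "MODEL_NAMES",
    "IMAGE_INPUT_SHAPE",
    "SEQUENCE_INPUT_SHAPE",
    "ModelSpec",
    "TrainingConfig",
    "TrainedModel",
    "build_model",
    "build_cnn_lstm",
    "train_model",
    "predict",
    "cross_validate",
    "hyperparameter_sweep",
    "select_setting",
    "save_model",
    "load_model",
]

MODEL_NAMES = ("proposed_avgpool", "vggb_maxpool", "simple_cnn", "mlp", "cnn_lstm")
IMAGE_INPUT_SHAPE = (IMAGE_SIDE, IMAGE_SIDE, 3)
SEQUENCE_INPUT_SHAPE = (N_STREAMS, MAX_FRAMES, 3)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the shared training protocol.

    The selected operating point: lambda = 1e-5, alpha = 1e-3, dropout 25%,
    patience 10 with min_delta 0.  Batch size and the epoch ceiling are not
    part of the protocol definition and default to 32 and 500.
    """

    learning_rate: float = 1e-3
    l2_lambda: float = 1e-5
    dropout: float = 0.25
    patience: int = 10
    min_delta: float = 0.0
    batch_size: int = 32
    max_epochs: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture selector plus the structural knobs that are open.

    ``dense_units`` and the cnn_lstm fields allow scaled-down instantiations
    for quick experiments; defaults are the full-size models.
    """

    name: str = "proposed_avgpool"
    dropout: float = 0.25
    l2_lambda: float = 1e-5
    dense_units: int = 1024
    lstm_units: int = 128
    lstm_conv_filters: int = 64
    lstm_n_conv: int = 4
    lstm_kernel: int = 5
    lstm_conv_stride: int = 2  # each conv halves the 750-step sequence

    def validate(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")

    @property
    def input_shape(self):
        return SEQUENCE_INPUT_SHAPE if self.name == "cnn_lstm" else IMAGE_INPUT_SHAPE


def _vgg_variant(spec: ModelSpec, pool_cls, rng, dtype):
    side = IMAGE_SIDE
    layers = []
    c_in = 3
    for filters in ((32,), (64, 64), (128, 128)):
        for c_out in filters:
            layers += [nn.Conv2D(c_in, c_out, 3, rng=rng, dtype=dtype), nn.ReLU()]
            c_in = c_out
        layers += [pool_cls(2), nn.Dropout(spec.dropout)]
        side //= 2
    flat = side * side * c_in  # 11 * 11 * 128 = 15,488 at full size
    layers += [
        nn.Flatten(),
        nn.Dense(flat, spec.dense_units, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.BatchNorm(spec.dense_units, dtype=dtype),
        nn.Dropout(spec.dropout),
        nn.Dense(spec.dense_units, N_CLASSES, l2=spec.l2_lambda, rng=rng, dtype=dtype),
    ]
    return layers


def build_model(spec: ModelSpec | str, seed: int = 0, dtype=np.float32) -> nn.Sequential:
    """Instantiate an untrained model for a spec (or a model name)."""
    if isinstance(spec, str):
        spec = ModelSpec(name=spec)
    spec.validate()
    rng = np.random.default_rng(seed)
    name = spec.name
    if name == "cnn_lstm":
        return build_cnn_lstm(spec, seed=seed, dtype=dtype)
    if name in ("proposed_avgpool", "vggb_maxpool"):
        pool = nn.AvgPool2D if name == "proposed_avgpool" else nn.MaxPool2D
        layers = _vgg_variant(spec, pool, rng, dtype)
    elif name == "simple_cnn":
        layers = []
        c_in = 3
        for c_out in (32, 64, 128):
            layers += [nn.Conv2D(c_in, c_out, 3, rng=rng, dtype=dtype), nn.ReLU()]
            c_in = c_out
        flat = IMAGE_SIDE * IMAGE_SIDE * c_in
        layers += [
            nn.Flatten(),
            nn.Dense(flat, N_CLASSES, l2=spec.l2_lambda, rng=rng, dtype=dtype),
        ]
    elif name == "mlp":
        flat = IMAGE_SIDE * IMAGE_SIDE * 3
        layers = [
            nn.Flatten(),
            nn.Dense(flat, spec.dense_units, rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.Dropout(spec.dropout),
            nn.Dense(spec.dense_units, N_CLASSES, l2=spec.l2_lambda, rng=rng, dtype=dtype),
        ]
    else:  # pragma: no cover - guarded by validate
        raise ValueError(name)
    return nn.Sequential(layers, input_shape=spec.input_shape)


def build_cnn_lstm(spec: ModelSpec | None = None, seed: int = 0, dtype=np.float32) -> nn.Sequential:
    """Sequence classifier on the 12x750x3 stream tensor.

    The tensor is unrolled frame-by-frame (a 12x1x3 column per step, 36
    features), run through ``lstm_n_conv`` strided 1-D convolutions over
    time (each stride-2 conv halves the sequence: 750 -> 375 -> 188 -> 94
    -> 47 at the defaults, keeping gradients alive across the whole lift),
    then two LSTM layers; the final hidden state feeds the softmax head.
    """
    spec = spec or ModelSpec(name="cnn_lstm")
    rng = np.random.default_rng(seed)
    layers = [nn.SensorToSequence()]
    c_in = N_STREAMS * 3
    for _ in range(spec.lstm_n_conv):
        layers += [
            nn.Conv1D(
                c_in,
                spec.lstm_conv_filters,
                spec.lstm_kernel,
                stride=spec.lstm_conv_stride,
                rng=rng,
                dtype=dtype,
            ),
            nn.ReLU(),
        ]
        c_in = spec.lstm_conv_filters
    layers += [
        nn.LSTM(c_in, spec.lstm_units, return_sequences=True, rng=rng, dtype=dtype),
        nn.LSTM(spec.lstm_units, spec.lstm_units, return_sequences=False, rng=rng, dtype=dtype),
        nn.Dense(spec.lstm_units, N_CLASSES, l2=spec.l2_lambda, rng=rng, dtype=dtype),
    ]
    return nn.Sequential(layers, input_shape=SEQUENCE_INPUT_SHAPE)


@dataclass
class TrainedModel:
    """A fitted model plus its training history.

    ``best_epoch`` indexes the epoch whose monitored loss was lowest; the
    stored weights are that epoch's (restored after early stopping).
    """

    model: nn.Sequential
    history: pd.DataFrame
    best_epoch: int
    stopped_epoch: int
    config: TrainingConfig
    spec: ModelSpec | None = None


def train_model(
    model: nn.Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainingConfig,
    verbose: bool = False,
) -> TrainedModel:
    """Fit with Adam + categorical cross-entropy + early stopping.

    ``y_train`` may be integer labels or one-hot rows.  The monitored loss
    is the mean training loss of each epoch.  Raises
    :class:`~liftrisk.nn.TrainingDivergedError` on a non-finite loss (the
    unstable high-learning-rate regime).
    """
    config.validate()
    if y_train.ndim == 1:
        y_train = one_hot(y_train)
    y_train = y_train.astype(np.float32)
    rng = np.random.default_rng(config.seed)
    optimiser = nn.Adam(model.params(), lr=config.learning_rate)
    stopper = nn.EarlyStopping(patience=config.patience, min_delta=config.min_delta)
    history = {"epoch": [], "loss": [], "accuracy": []}
    best_weights = model.get_weights()
    n = len(x_train)
    stopped = -1
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        loss_sum = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            model.zero_grad()
            loss, n_ok = model.loss_and_backward(x_train[idx], y_train[idx], rng)
            if not np.isfinite(loss):
                raise nn.TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}; "
                    "learning rate is likely in the unstable regime"
                )
            optimiser.step()
            loss_sum += loss * len(idx)
            correct += n_ok
        epoch_loss = loss_sum / n
        history["epoch"].append(epoch)
        history["loss"].append(epoch_loss)
        history["accuracy"].append(correct / n)
        if verbose:
            print(f"epoch {epoch:3d}  loss {epoch_loss:.4f}  acc {correct / n:.3f}")
        stop = stopper.update(epoch_loss)
        if stopper.best_epoch == epoch:
            best_weights = model.get_weights()
        stopped = epoch
        if stop:
            break
    model.set_weights(best_weights)
    return TrainedModel(
        model=model,
        history=pd.DataFrame(history),
        best_epoch=stopper.best_epoch,
        stopped_epoch=stopped,
        config=config,
    )


def predict(model: nn.Sequential, x: np.ndarray, batch_size: int = 64):
    """Class probabilities and hard labels; probability ties break toward
    the higher risk class (conservative for a safety application)."""
    probs = model.predict_proba(x, batch_size=batch_size)
    k = probs.shape[1]
    labels = (k - 1) - np.argmax(probs[:, ::-1], axis=1)
    return probs, labels


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------


def _fold_arrays(tensors, fold, spec: ModelSpec, scaler_mode: str):
    """Scale on the training side only, re-zero padding, build input arrays."""
    train = [tensors[i] for i in fold.train_indices]
    test = [tensors[i] for i in fold.test_indices]
    scaler = ChannelScaler(mode=scaler_mode).fit(train)
    train = [rezero_padding(t) for t in scaler.transform_all(train)]
    test = [rezero_padding(t) for t in scaler.transform_all(test)]
    if spec.name == "cnn_lstm":
        xtr = np.stack([t.data for t in train]).astype(np.float32)
        xte = np.stack([t.data for t in test]).astype(np.float32)
    else:
        xtr = np.stack([encode_image(t).data for t in train]).astype(np.float32)
        xte = np.stack([encode_image(t).data for t in test]).astype(np.float32)
    ytr = np.array([t.label for t in train])
    yte = np.array([t.label for t in test])
    return xtr, ytr, xte, yte


def cross_validate(
    tensors,
    folds,
    spec: ModelSpec | str,
    config: TrainingConfig,
    scaler_mode: str = "zscore",
    keep_models: bool = False,
):
    """Train and evaluate one model spec across the given folds.

    ``tensors`` are filtered + padded (unscaled) :class:`LiftTensor` objects
    with labels.  Returns a list of per-fold dicts with the confusion
    matrix, true/predicted labels and optionally the trained model.
    """
    from .metrics import confusion

    if isinstance(spec, str):
        spec = ModelSpec(name=spec)
    results = []
    for fold in folds:
        xtr, ytr, xte, yte = _fold_arrays(tensors, fold, spec, scaler_mode)
        seed = (config.seed + 7919 * (fold.fold_id + 1)) % (2**31)
        model = build_model(spec, seed=seed)
        trained = train_model(model, xtr, ytr, replace(config, seed=seed))
        _, pred = predict(trained.model, xte)
        entry = {
            "fold_id": fold.fold_id,
            "confusion": confusion(yte, pred),
            "y_true": yte,
            "y_pred": pred,
            "history": trained.history,
            "best_epoch": trained.best_epoch,
        }
        if keep_models:
            entry["trained"] = trained
            entry["x_test"] = xte
        results.append(entry)
    return results


def hyperparameter_sweep(
    tensors,
    zones,
    settings,
    base_config: TrainingConfig,
    spec: ModelSpec | str = "proposed_avgpool",
    n_folds: int = 4,
    test_fraction: float = 0.25,
    fold_seed: int = 0,
    scaler_mode: str = "zscore",
) -> pd.DataFrame:
    """Grid evaluation of (l2_lambda, learning_rate, dropout) settings.

    ``settings`` is an iterable of dicts with any subset of those keys.
    Fold definitions are fixed across settings so rows are comparable.
    Returns one row per setting with the mean cross-validated R_K and
    accuracy; callers select the highest R_K (or apply their own stability
    preference, e.g. rejecting learning rates that terminate at high loss).
    """
    from .metrics import accuracy as acc_fn
    from .metrics import r_k as rk_fn

    settings = list(settings)
    if not settings:
        raise ValueError("empty hyperparameter grid")
    if isinstance(spec, str):
        spec = ModelSpec(name=spec)
    folds = make_folds(zones, n_folds=n_folds, test_fraction=test_fraction, seed=fold_seed)
    rows = []
    for setting in settings:
        unknown = set(setting) - {"l2_lambda", "learning_rate", "dropout"}
        if unknown:
            raise ValueError(f"unknown hyperparameter(s): {sorted(unknown)}")
        cfg = replace(base_config, **setting)
        sp = replace(
            spec,
            dropout=cfg.dropout,
            l2_lambda=cfg.l2_lambda,
        )
        fold_results = cross_validate(tensors, folds, sp, cfg, scaler_mode=scaler_mode)
        rks = [rk_fn(r["confusion"]) for r in fold_results]
        accs = [acc_fn(r["confusion"]) for r in fold_results]
        rows.append(
            {
                "l2_lambda": cfg.l2_lambda,
                "learning_rate": cfg.learning_rate,
                "dropout": cfg.dropout,
                "mean_r_k": float(np.mean(rks)),
                "mean_accuracy": float(np.mean(accs)),
                "fold_r_k": rks,
                "fold_accuracy": accs,
            }
        )
    return pd.DataFrame(rows)


def select_setting(table: pd.DataFrame, rule=None) -> dict:
    """Pick a hyperparameter setting from a sweep table.

    Default rule: highest mean cross-validated R_K.  ``rule`` overrides the
    selection — e.g. a stability preference that rejects learning rates
    whose runs terminate at high loss and takes the runner-up — and must
    map the table to the index of the chosen row.
    """
    if table.empty:
        raise ValueError("empty sweep table")
    idx = int(table["mean_r_k"].idxmax()) if rule is None else int(rule(table))
    row = table.loc[idx]
    return {
        "l2_lambda": float(row["l2_lambda"]),
        "learning_rate": float(row["learning_rate"]),
        "dropout": float(row["dropout"]),
    }


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_model(spec: ModelSpec, model: nn.Sequential, path) -> None:
    """Write a checkpoint: all parameter arrays plus the spec needed to
    rebuild the architecture."""
    path = Path(path)
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(dataclasses.asdict(spec)) + "\n")


def load_model(path) -> tuple[ModelSpec, nn.Sequential]:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    path = Path(path)
    spec = ModelSpec(**json.loads(path.with_suffix(".json").read_text()))
    model = build_model(spec, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        weights = [data[f"param_{i}"] for i in range(len(model.params()))]
    model.set_weights(weights)
    return spec, model
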