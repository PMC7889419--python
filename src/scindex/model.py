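"""The CNN pain scorer and the 0-100 spectrogram-CNN index.

The network takes a 124 x 124 spectrogram patch and emits two softmax
probabilities (no-pain, pain).  Three Conv-Maxpool stages with 32, 64
and 128 filters (2x2 kernels, stride 1, size-preserving padding; 2x2
stride-2 max pooling) reduce the input 124 -> 62 -> 31 -> 15, so the
flattened feature vector has 15 * 15 * 128 = 28,800 entries.  Batch
normalisation and ReLU follow each convolution; two fully connected
hidden layers with ReLU and dropout precede the 2-node softmax output.
Training minimises cross-entropy with Adam and early-stops on
validation loss; dropout is active only during training.

The spectrogram-CNN index of a patch is 100 times the pain-node
probability; a recording's summary value is the mean index over its
10-s patches.

Usage follows the model/results idiom::

    model = SpectrogramCNN(X_train, y_train, subject_ids=train_subjects)
    res = model.fit(TrainConfig(max_epochs=10, seed=0),
                    validation=(X_val, y_val, val_subjects))
    print(res.summary())
    idx = res.pain_index(X_test)          # one value in [0, 100] per patch
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .errors import ConfigError, DegenerateLabelsError, InvalidParameterError, LeakageError
from .preprocess import FilterSpec, preprocess_recording
from .spectrogram import SpectrogramParams, make_patches, patches_to_arrays
from .synth import PPGRecording

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "PainIndexSeries",
    "SpectrogramCNN",
    "SpectrogramCNNResults",
    "build_model",
    "train_model",
    "predict_proba",
    "compute_index",
    "score_recording",
]


@dataclass(frozen=True)
class CNNConfig:
    """Architecture hyperparameters.

    The spatial trace on the default 124 x 124 input must be
    124 -> 62 -> 31 -> 15; configurations that break it are rejected at
    build time with the computed trace in the message.
    """

    conv_filters: tuple[int, ...] = (32, 64, 128)
    conv_kernel: int = 2
    conv_stride: int = 1
    conv_padding: str = "same"
    pool_size: int = 2
    pool_stride: int = 2
    use_batch_norm: bool = True
    fc_hidden: tuple[int, ...] = (256, 64)
    dropout_rate: float = 0.5
    n_classes: int = 2
    input_size: int = 124

    def __post_init__(self):
        if self.conv_padding != "same" or self.conv_stride != 1:
            raise ConfigError("only stride-1 'same' convolutions are supported")
        if self.pool_size != 2 or self.pool_stride != 2:
            raise ConfigError("only 2x2 stride-2 max pooling is supported")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.n_classes != 2:
            raise ConfigError("the pain scorer is a two-class model")

    def spatial_trace(self) -> list[int]:
        """Spatial size after each Conv-Maxpool stage, starting at the input."""
        sizes = [self.input_size]
        s = self.input_size
        for _ in self.conv_filters:
            s = s // 2  # 'same' conv preserves size; 2x2/2 pool floors
            sizes.append(s)
        return sizes

    def flatten_width(self) -> int:
        s = self.spatial_trace()[-1]
        return s * s * self.conv_filters[-1]

    def validate(self) -> None:
        trace = self.spatial_trace()
        if any(s < 1 for s in trace):
            raise ConfigError(f"spatial trace collapses below 1 pixel: {trace}")
        if self.input_size == 124 and trace != [124, 62, 31, 15]:
            raise ConfigError(
                f"a 124x124 input must trace 124->62->31->15 through three "
                f"Conv-Maxpool stages; this configuration gives {trace}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; cross-entropy loss and Adam are fixed."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "max_epochs", "early_stop_patience"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class PainIndexSeries:
    """Per-10-s spectrogram-CNN index values and their recording mean."""

    values: np.ndarray
    start_times_s: np.ndarray
    subject_id: str = "S000"
    condition: str = "baseline"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if np.any((v < 0) | (v > 100)):
            raise InvalidParameterError("index values must lie in [0, 100]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "start_times_s",
                           np.asarray(self.start_times_s, dtype=np.float64))

    @property
    def mean_index(self) -> float:
        return float(self.values.mean())


def _build_layers(config: CNNConfig, rng: np.random.Generator) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    c_in = 1
    for c_out in config.conv_filters:
        layers.append(nn.Conv2D(c_in, c_out, kernel=config.conv_kernel, rng=rng))
        if config.use_batch_norm:
            layers.append(nn.BatchNorm2D(c_out))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2D())
        c_in = c_out
    layers.append(nn.Flatten())
    width = config.flatten_width()
    for h in config.fc_hidden:
        layers.append(nn.Dense(width, h, rng=rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(config.dropout_rate))
        width = h
    head = nn.Dense(width, config.n_classes, rng=rng)
    # small-scale classifier head: initial logits near zero, so the first
    # cross-entropy sits at ln(2) instead of exploding through the ReLU stack
    head.params["W"] *= 0.05
    layers.append(head)
    return layers


def _as_input(x: np.ndarray, input_size: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[..., None]
    if x.ndim != 4 or x.shape[1] != input_size or x.shape[2] != input_size:
        raise ConfigError(
            f"expected patches of shape ({input_size}, {input_size}), got {x.shape[1:]}")
    return x


class SpectrogramCNN:
    """Pain-scorer model bound to its training patches.

    Parameters
    ----------
    patches : (n, 124, 124) array (or a sequence of SpectrogramPatch)
    labels : (n,) array of {0, 1}
    subject_ids : optional (n,) array, used for leakage checks against
        the validation set.
    config : CNNConfig
    """

    def __init__(self, patches, labels=None, subject_ids=None,
                 config: CNNConfig = CNNConfig()):
        config.validate()
        self.config = config
        if labels is None and patches and hasattr(patches[0], "matrix"):
            patches, labels, subject_ids, _, _ = patches_to_arrays(patches)
        self.exog = _as_input(patches, config.input_size)
        self.endog = np.asarray(labels, dtype=np.int64)
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ConfigError("patches and labels disagree in length")
        self.subject_ids = None if subject_ids is None else np.asarray(subject_ids)

    @classmethod
    def from_patches(cls, patches, config: CNNConfig = CNNConfig()):
        x, y, subjects, _, _ = patches_to_arrays(patches)
        return cls(x, y, subject_ids=subjects, config=config)

    def fit(self, train_config: TrainConfig = TrainConfig(),
            validation=None) -> "SpectrogramCNNResults":
        """Train with Adam on cross-entropy; return the parameter state
        with the best validation loss (or final state without validation).

        ``validation`` is ``(patches, labels)`` or
        ``(patches, labels, subject_ids)`` from subjects disjoint with
        the training subjects.
        """
        classes = np.unique(self.endog)
        if classes.size < 2:
            raise DegenerateLabelsError(
                f"training labels contain a single class {classes.tolist()}")
        x_val = y_val = None
        if validation is not None:
            x_val = _as_input(validation[0], self.config.input_size)
            y_val = np.asarray(validation[1], dtype=np.int64)
            if len(validation) > 2 and validation[2] is not None and self.subject_ids is not None:
                overlap = set(np.asarray(validation[2]).tolist()) & set(self.subject_ids.tolist())
                if overlap:
                    raise LeakageError(
                        f"subjects appear in both train and validation: {sorted(overlap)[:5]}")
        rng = np.random.default_rng(train_config.seed)
        layers = _build_layers(self.config, rng)
        opt = nn.Adam(layers, lr=train_config.learning_rate)
        n = self.exog.shape[0]
        bs = train_config.batch_size
        history = {"train_loss": [], "val_loss": []}
        best_val = np.inf
        best_state = None
        best_epoch = -1
        patience = 0
        for epoch in range(train_config.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                h = self.exog[idx]
                for layer in layers:
                    h = layer.forward(h, train=True, rng=rng)
                loss, d = nn.softmax_cross_entropy(h, self.endog[idx])
                for layer in reversed(layers):
                    d = layer.backward(d)
                opt.step()
                losses.append(loss)
            history["train_loss"].append(float(np.mean(losses)))
            if x_val is not None:
                logits = _forward_eval(layers, x_val)
                val_loss, _ = nn.softmax_cross_entropy(logits, y_val)
                history["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = _snapshot(layers)
                    best_epoch = epoch
                    patience = 0
                else:
                    patience += 1
                    if patience >= train_config.early_stop_patience:
                        break
            else:
                best_state = _snapshot(layers)
                best_epoch = epoch
        if best_state is not None:
            _restore(layers, best_state)
        return SpectrogramCNNResults(self, layers, train_config, history, best_epoch)


class SpectrogramCNNResults:
    """Fitted pain scorer: learned parameters, training history and the
    scoring interface."""

    def __init__(self, model: SpectrogramCNN, layers, train_config: TrainConfig,
                 history: dict, best_epoch: int, stft_config_hash: str = ""):
        self.model = model
        self.config = model.config
        self.layers = layers
        self.train_config = train_config
        self.history = history
        self.best_epoch = best_epoch
        self.stft_config_hash = stft_config_hash

    # -- scoring --------------------------------------------------------
    def predict_proba(self, patches) -> np.ndarray:
        """(n, 2) array of (p_nopain, p_pain); deterministic (no dropout)."""
        x = _as_input(patches, self.config.input_size)
        return nn.softmax(_forward_eval(self.layers, x))

    def pain_index(self, patches) -> np.ndarray:
        """Spectrogram-CNN index: 100 * p(pain) per patch."""
        return compute_index(self.predict_proba(patches)[:, 1])

    def score_recording(self, rec: PPGRecording,
                        filter_spec: FilterSpec = FilterSpec(),
                        stft_params: SpectrogramParams = SpectrogramParams(),
                        preprocess: bool = True) -> PainIndexSeries:
        """Run the full pipeline on a raw recording: one index per 10-s patch."""
        conditioned = preprocess_recording(rec, filter_spec) if preprocess else rec
        patches = make_patches(conditioned, stft_params)
        x, _, _, _, t0 = patches_to_arrays(patches)
        return PainIndexSeries(values=self.pain_index(x), start_times_s=t0,
                               subject_id=rec.subject_id, condition=rec.condition)

    # -- reporting ------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for l in self.layers for p in l.params.values()))

    def summary(self) -> str:
        cfg = self.config
        trace = cfg.spatial_trace()
        buf = io.StringIO()
        w = buf.write
        w("                     Spectrogram-CNN pain scorer\n")
        w("=" * 64 + "\n")
        w(f"{'Input patch:':<28}{cfg.input_size} x {cfg.input_size}\n")
        w(f"{'Conv filters:':<28}{', '.join(map(str, cfg.conv_filters))}"
          f"  (kernel {cfg.conv_kernel}x{cfg.conv_kernel}, stride 1, same)\n")
        w(f"{'Spatial trace:':<28}{' -> '.join(map(str, trace))}\n")
        w(f"{'Flatten width:':<28}{cfg.flatten_width():,}\n")
        w(f"{'FC hidden:':<28}{', '.join(map(str, cfg.fc_hidden))}"
          f"  (dropout {cfg.dropout_rate})\n")
        w(f"{'Parameters:':<28}{self.n_parameters:,}\n")
        w(f"{'Training patches:':<28}{self.model.exog.shape[0]}\n")
        w(f"{'Epochs run:':<28}{len(self.history['train_loss'])}"
          f"  (best epoch {self.best_epoch})\n")
        if self.history["train_loss"]:
            w(f"{'Final train loss:':<28}{self.history['train_loss'][-1]:.4f}\n")
        if self.history["val_loss"]:
            w(f"{'Best validation loss:':<28}{min(self.history['val_loss']):.4f}\n")
        w("=" * 64 + "\n")
        return buf.getvalue()

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        """Self-describing checkpoint: architecture, parameters, running
        batch-norm moments and the hash of the spectrogram configuration
        the scorer was trained under."""
        arrays = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                arrays[f"layer{i}.{k}"] = v
            if isinstance(layer, nn.BatchNorm2D):
                arrays[f"layer{i}.running_mean"] = layer.running_mean
                arrays[f"layer{i}.running_var"] = layer.running_var
        meta = {
            "cnn_config": asdict(self.config),
            "train_config": asdict(self.train_config),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "stft_config_hash": self.stft_config_hash,
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, expected_stft_hash: str | None = None) -> "SpectrogramCNNResults":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        meta["cnn_config"]["conv_filters"] = tuple(meta["cnn_config"]["conv_filters"])
        meta["cnn_config"]["fc_hidden"] = tuple(meta["cnn_config"]["fc_hidden"])
        config = CNNConfig(**meta["cnn_config"])
        if expected_stft_hash is not None and meta["stft_config_hash"] and \
                meta["stft_config_hash"] != expected_stft_hash:
            raise ConfigError(
                "checkpoint was trained under a different spectrogram "
                f"configuration (hash {meta['stft_config_hash'][:12]}... != "
                f"{expected_stft_hash[:12]}...)")
        layers = _build_layers(config, np.random.default_rng(0))
        for i, layer in enumerate(layers):
            for k in list(layer.params):
                layer.params[k][...] = arrays[f"layer{i}.{k}"]
            if isinstance(layer, nn.BatchNorm2D):
                layer.running_mean = arrays[f"layer{i}.running_mean"]
                layer.running_var = arrays[f"layer{i}.running_var"]
        dummy = SpectrogramCNN(np.zeros((1, config.input_size, config.input_size),
                                        dtype=np.float32), [0], config=config)
        # single-patch placeholder only anchors config; labels unused
        res = cls(dummy, layers, TrainConfig(**meta["train_config"]),
                  meta["history"], meta["best_epoch"], meta["stft_config_hash"])
        return res


def _forward_eval(layers, x: np.ndarray, batch: int = 16) -> np.ndarray:
    outs = []
    for start in range(0, x.shape[0], batch):
        h = x[start:start + batch]
        for layer in layers:
            h = layer.forward(h, train=False)
        outs.append(h)
    return np.concatenate(outs, axis=0)


def _snapshot(layers):
    state = []
    for layer in layers:
        entry = {k: v.copy() for k, v in layer.params.items()}
        if isinstance(layer, nn.BatchNorm2D):
            entry["__rm__"] = layer.running_mean.copy()
            entry["__rv__"] = layer.running_var.copy()
        state.append(entry)
    return state


def _restore(layers, state):
    for layer, entry in zip(layers, state):
        for k in layer.params:
            layer.params[k][...] = entry[k]
        if isinstance(layer, nn.BatchNorm2D):
            layer.running_mean = entry["__rm__"].copy()
            layer.running_var = entry["__rv__"].copy()


# -- functional wrappers ------------------------------------------------

def build_model(config: CNNConfig = CNNConfig()) -> SpectrogramCNN:
    """Untrained model shell with a validated architecture."""
    config.validate()
    placeholder = np.zeros((1, config.input_size, config.input_size), dtype=np.float32)
    return SpectrogramCNN(placeholder, [0], config=config)


def train_model(model: SpectrogramCNN, train_patches, train_labels,
                val_patches=None, val_labels=None,
                train_config: TrainConfig = TrainConfig(),
                train_subjects=None, val_subjects=None) -> SpectrogramCNNResults:
    bound = SpectrogramCNN(train_patches, train_labels,
                           subject_ids=train_subjects, config=model.config)
    validation = None
    if val_patches is not None:
        validation = (val_patches, val_labels, val_subjects)
    return bound.fit(train_config, validation=validation)


def predict_proba(results: SpectrogramCNNResults, patch) -> np.ndarray:
    return results.predict_proba(patch)


def compute_index(p_pain) -> np.ndarray:
    """Spectrogram-CNN index: 100 * pain probability."""
    p = np.asarray(p_pain, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("pain probability must be in [0, 1]")
    return 100.0 * p


def score_recording(results: SpectrogramCNNResults, rec: PPGRecording,
                    filter_spec: FilterSpec = FilterSpec(),
                    stft_params: SpectrogramParams = SpectrogramParams()) -> PainIndexSeries:
    return results.score_recording(rec, filter_spec, stft_params)
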