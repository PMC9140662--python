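"""Model families and the cost-sensitive training protocol.

Three classifier families perform the per-second binary decisions:

* FFNN — one tanh hidden layer over engineered features;
* 1D-CNN — a stack of "GofLayer" groups (convolution with kernel 2 and unit
  stride + ReLU, max-pool 2/2, 10% dropout) over raw overlapping windows,
  then a ReLU dense layer and the 2-unit soft-max output;
* LSTM — one or more (optionally bidirectional) recurrent layers over
  time-step sequences, 10% dropout, an optional dense layer, soft-max out.

Training uses Adam (lr 0.001, batch 1024), class-weighted cross-entropy for
the A-phase imbalance, at most 50 epochs, and early stopping once the
validation AUC has not improved by 0.01 within five consecutive epochs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .preprocess import EPOCH_SAMPLES, WindowSpec

DENSE_OPTIONS = ("half", "same", "twice", "none")


@dataclass(frozen=True)
class FfnnSpec:
    n_inputs: int
    hidden_units: int

    def __post_init__(self):
        if self.n_inputs < 1 or self.hidden_units < 1:
            raise ValueError("layer sizes must be positive")


@dataclass(frozen=True)
class CnnSpec:
    """GofLayer stack; ``goflayers[k]`` is the kernel count of group k."""

    goflayers: tuple
    dense_units: int
    window: WindowSpec = field(default_factory=lambda: WindowSpec(0))
    group_dropout: float = 0.10

    def __post_init__(self):
        object.__setattr__(self, "goflayers", tuple(self.goflayers))
        if not self.goflayers:
            raise ValueError("at least one group of layers required")

    @property
    def input_len(self) -> int:
        return self.window.window_w * EPOCH_SAMPLES


@dataclass(frozen=True)
class LstmSpec:
    n_inputs: int            # features per time step
    hidden_units: int        # Nh, shared by all recurrent layers
    time_steps: int          # T
    depth: int = 1           # number of recurrent layers (Gr)
    bidirectional: bool = False
    dense_option: str = "half"
    inter_dropout: float = 0.10

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("at least one recurrent layer required")
        if self.dense_option not in DENSE_OPTIONS:
            raise ValueError(f"dense_option must be one of {DENSE_OPTIONS}")

    @property
    def dense_units(self):
        """Units of the pre-output dense layer (None for option 'none')."""
        if self.dense_option == "half":
            return int(np.floor(self.hidden_units / 2 + 0.5))
        if self.dense_option == "same":
            return self.hidden_units
        if self.dense_option == "twice":
            return 2 * self.hidden_units
        return None


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 1024
    max_epochs: int = 50
    early_stop_delta: float = 0.01   # minimum AUC improvement that counts
    early_stop_patience: int = 5     # consecutive epochs without it
    seed: int = 0


class EarlyStopper:
    """Stop when validation AUC fails to improve by ``delta`` for
    ``patience`` consecutive epochs."""

    def __init__(self, delta: float = 0.01, patience: int = 5):
        self.delta = delta
        self.patience = patience
        self.best = -np.inf
        self.stale = 0

    def update(self, auc: float) -> bool:
        """Record one epoch's AUC; True means training should stop."""
        if auc >= self.best + self.delta:
            self.best = auc
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class _AddChannel(nn.Layer):
    """(B, L) -> (B, L, 1) so raw windows feed the convolution stack."""

    def forward(self, x, training=False, rng=None):
        return x[:, :, None]

    def backward(self, grad):
        return grad[:, :, 0]


def spec_to_dict(spec) -> dict:
    d = asdict(spec)
    d["family"] = type(spec).__name__
    if isinstance(spec, CnnSpec):
        d["window"] = {"overlap_o": spec.window.overlap_o,
                       "scenario": spec.window.scenario}
    return d


def spec_from_dict(d: dict):
    d = dict(d)
    family = d.pop("family")
    if family == "FfnnSpec":
        return FfnnSpec(**d)
    if family == "CnnSpec":
        d["window"] = WindowSpec(**d["window"])
        d["goflayers"] = tuple(d["goflayers"])
        return CnnSpec(**d)
    if family == "LstmSpec":
        return LstmSpec(**d)
    raise ValueError(f"unknown spec family {family!r}")


def build_model(spec, seed: int = 0) -> nn.Sequential:
    """Construct an untrained, seeded network from a declarative spec."""
    rng = np.random.default_rng(seed)
    if isinstance(spec, FfnnSpec):
        return nn.Sequential([
            nn.Dense(spec.n_inputs, spec.hidden_units, activation="tanh", rng=rng),
            nn.Dense(spec.hidden_units, 2, rng=rng),
        ])
    if isinstance(spec, CnnSpec):
        layers = [_AddChannel()]
        length, channels = spec.input_len, 1
        for kernels in spec.goflayers:
            layers.append(nn.Conv1D(channels, kernels, rng=rng))
            length -= 1
            layers.append(nn.MaxPool1D())
            length //= 2
            layers.append(nn.Dropout(spec.group_dropout))
            channels = kernels
            if length < 2:
                raise ValueError("window too short for this GofLayer stack")
        layers.append(nn.Flatten())
        layers.append(nn.Dense(length * channels, spec.dense_units,
                               activation="relu", rng=rng))
        layers.append(nn.Dense(spec.dense_units, 2, rng=rng))
        return nn.Sequential(layers)
    if isinstance(spec, LstmSpec):
        layers = []
        d_in = spec.n_inputs
        for k in range(spec.depth):
            last = k == spec.depth - 1
            layer = nn.LSTM(d_in, spec.hidden_units,
                            return_sequences=not last,
                            bidirectional=spec.bidirectional, rng=rng)
            layers.append(layer)
            d_in = layer.output_dim
        layers.append(nn.Dropout(spec.inter_dropout))
        if spec.dense_units is not None:
            layers.append(nn.Dense(d_in, spec.dense_units, activation="relu",
                                   rng=rng))
            d_in = spec.dense_units
        layers.append(nn.Dense(d_in, 2, rng=rng))
        return nn.Sequential(layers)
    raise TypeError(f"unknown spec type {type(spec).__name__}")


def class_weights(labels) -> np.ndarray:
    """Inverse-frequency cost multipliers: w_c = n_total / (2 * n_c)."""
    labels = np.asarray(labels).astype(int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    return len(labels) / (2.0 * counts)


def train(model, train_data, val_data, config: TrainConfig,
          cost_sensitive: bool = True):
    """Fit ``model`` in place; returns a history dict.

    ``train_data``/``val_data`` are (X, y) pairs with y in {0, 1}. History
    records the per-epoch validation AUC and the stopping epoch.
    """
    x_train, y_train = train_data
    x_val, y_val = val_data
    y_train = np.asarray(y_train).astype(int)
    y_val = np.asarray(y_val).astype(int)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty training or validation data")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")

    weights = class_weights(y_train) if cost_sensitive else np.ones(2)
    sample_w = weights[y_train]

    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.params(), lr=config.learning_rate)
    history = {"val_auc": [], "train_loss": [], "stopped_epoch": None}
    stopper = EarlyStopper(config.early_stop_delta, config.early_stop_patience)

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start: start + config.batch_size]
            loss = model.loss_and_grad(x_train[idx], y_train[idx],
                                       sample_w[idx], rng=rng)
            optimizer.step(model.grads())
            losses.append(loss)
        scores = model.predict_proba(x_val)
        auc = roc_auc_score(y_val, scores)
        history["val_auc"].append(float(auc))
        history["train_loss"].append(float(np.mean(losses)))
        if stopper.update(auc):
            history["stopped_epoch"] = epoch + 1
            break
    if history["stopped_epoch"] is None:
        history["stopped_epoch"] = len(history["val_auc"])
    return history


def predict_proba(model, data) -> np.ndarray:
    return model.predict_proba(np.asarray(data, dtype=np.float64))


def predict_labels(probabilities) -> np.ndarray:
    """Highest-score decision; a tie at exactly 0.5 goes to the positive."""
    return np.asarray(probabilities) >= 0.5


# ---------------------------------------------------------------------------
# Reference presets (the tuned architectures the pipeline defaults to)
# ---------------------------------------------------------------------------

def preset(name: str, n_features: int | None = None):
    """Build a named reference architecture spec.

    ``n_features`` overrides the feature count for the feature-fed presets
    (defaults: 14 for the FFNN, 12 for the feature-fed LSTM).
    """
    if name == "ffnn":
        return FfnnSpec(n_inputs=n_features or 14, hidden_units=400)
    if name == "cnn-afc":
        return CnnSpec(goflayers=(64, 128), dense_units=100,
                       window=WindowSpec(9, "central"))  # W = 19 s, central
    if name == "cnn-nrem":
        return CnnSpec(goflayers=(32, 64), dense_units=100,
                       window=WindowSpec(9, "central"))
    if name == "lstm-afc":
        return LstmSpec(n_inputs=EPOCH_SAMPLES, hidden_units=100,
                        time_steps=25, dense_option="half")
    if name == "lstm-features":
        return LstmSpec(n_inputs=n_features or 12, hidden_units=100,
                        time_steps=25, dense_option="half")
    if name == "lstm-nrem":
        return LstmSpec(n_inputs=n_features or 12, hidden_units=300,
                        time_steps=25, dense_option="half")
    raise KeyError(f"unknown preset {name!r}")


def save_checkpoint(path, model, spec, config: TrainConfig | None = None):
    """Write weights (.npz) and a JSON sidecar describing the architecture."""
    np.savez(path, **model.state_dict())
    sidecar = {"spec": spec_to_dict(spec)}
    if config is not None:
        sidecar["train_config"] = asdict(config)
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path, seed: int = 0):
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    spec = spec_from_dict(sidecar["spec"])
    model = build_model(spec, seed=seed)
    with np.load(str(path) if str(path).endswith(".npz") else str(path)) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, spec
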