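"""Feed-forward softmax classifier: forward pass, training, persistence.

The architecture is fixed at the published dimensions: a 4-vector of phase
enhancements passes through two 50-node rectified-linear hidden layers and
a 4-way softmax output,

    y1 = ReLU(W1 x + b1),  y2 = ReLU(W2 y1 + b2),  z = softmax(W3 y2 + b3),

for 50x4, 50x50 and 4x50 weight matrices — 3,004 trainable parameters in
all (50*4+50 + 50*50+50 + 4*50+4).  Training minimizes mean categorical cross-entropy against one-hot
subtype targets by mini-batch gradient descent with adaptive-moment (Adam)
updates; forward pass, backpropagation and the optimizer are implemented
here directly in NumPy, with no external learning framework.

Softmax is evaluated with max-subtraction and the loss floors probabilities
at 1e-12 inside the log; both are numerically-stable rewrites that leave
the mathematics unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np

from . import __version__ as _pkg_version
from .generative import LabeledCohort
from .subtypes import N_PHASES, N_SUBTYPES, SUBTYPES, Subtype

__all__ = [
    "NetworkParams",
    "TrainingConfig",
    "TrainingReport",
    "TrainingError",
    "ModelFormatError",
    "FeatureScaler",
    "PARAMETER_COUNT",
    "init_network",
    "forward",
    "loss_and_gradients",
    "train",
    "predict",
    "predict_labels",
    "save_model",
    "load_model",
]

_HIDDEN = 50
_SHAPES = {
    "W1": (_HIDDEN, N_PHASES),
    "b1": (_HIDDEN,),
    "W2": (_HIDDEN, _HIDDEN),
    "b2": (_HIDDEN,),
    "W3": (N_SUBTYPES, _HIDDEN),
    "b3": (N_SUBTYPES,),
}
#: 50*4+50 + 50*50+50 + 4*50+4
PARAMETER_COUNT = sum(int(np.prod(s)) for s in _SHAPES.values())

_PROB_FLOOR = 1e-12


class TrainingError(RuntimeError):
    """Raised when optimization produces a non-finite loss."""


class ModelFormatError(ValueError):
    """Raised for malformed or shape-mismatched model files."""


@dataclasses.dataclass
class NetworkParams:
    """The six weight/bias arrays of the classifier."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray

    def __post_init__(self) -> None:
        for name, shape in _SHAPES.items():
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {a.shape}")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, a)

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in _SHAPES}

    def copy(self) -> "NetworkParams":
        return NetworkParams(**{k: v.copy() for k, v in self.arrays().items()})

    @property
    def n_parameters(self) -> int:
        return PARAMETER_COUNT


@dataclasses.dataclass(frozen=True)
class FeatureScaler:
    """Optional per-phase standardization (train-set mean/SD), persisted
    with the model so prediction applies the identical transform."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mean.shape != (N_PHASES,) or sd.shape != (N_PHASES,):
            raise ValueError("scaler mean/sd must be length-4 vectors")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", np.where(sd > 0, sd, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the cross-entropy training loop.

    Defaults: Adam at learning rate 1e-3, batch 256, up to 50 epochs with
    early stopping (patience 5) on a 10% validation split.  Features are
    standardized by default (train-set per-phase mean/SD, persisted with
    the model, so a trained classifier is still a pure function of raw HU
    input); set ``standardize=False`` to feed raw HU directly.
    """

    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 50
    patience: int = 5
    validation_fraction: float = 0.1
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be a positive integer")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be a positive integer")
        if self.patience < 0:
            raise ValueError("patience must be non-negative")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class TrainingReport:
    """Per-epoch loss/accuracy trace and the final validation scores."""

    train_loss: list[float]
    train_accuracy: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    epochs_run: int
    config: TrainingConfig

    @property
    def final_val_accuracy(self) -> float:
        return self.val_accuracy[-1] if self.val_accuracy else float("nan")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["config"] = self.config.to_dict()
        return d


def init_network(seed: int) -> NetworkParams:
    """He-uniform weight initialization with zero biases.

    Each weight matrix is drawn uniformly on ±sqrt(6 / fan_in), the
    variance scaling appropriate for rectified-linear layers; biases start
    at exactly zero.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    params = {}
    for name, shape in _SHAPES.items():
        if name.startswith("W"):
            limit = np.sqrt(6.0 / shape[1])
            params[name] = rng.uniform(-limit, limit, size=shape)
        else:
            params[name] = np.zeros(shape)
    return NetworkParams(**params)


def _softmax(logits: np.ndarray) -> np.ndarray:
    # max-subtraction: identical result, no overflow
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _forward_batch(X: np.ndarray, net: NetworkParams):
    y1 = np.maximum(X @ net.W1.T + net.b1, 0.0)
    y2 = np.maximum(y1 @ net.W2.T + net.b2, 0.0)
    z = _softmax(y2 @ net.W3.T + net.b3)
    return y1, y2, z


def forward(x: np.ndarray, net: NetworkParams) -> np.ndarray:
    """Confidence vector z for one phase vector or a batch of them.

    Computes y1 = ReLU(W1 x + b1), y2 = ReLU(W2 y1 + b2) and
    z = softmax(W3 y2 + b3).  Returns shape (4,) for a single vector or
    (n, 4) for an (n, 4) batch; every output row is a probability vector.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != N_PHASES:
        raise ValueError(f"expected 4 phase values per record, got {X.shape[1]}")
    z = _forward_batch(X, net)[2]
    return z[0] if single else z


def loss_and_gradients(
    X: np.ndarray, T: np.ndarray, net: NetworkParams
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy over a batch and its analytic gradients.

    ``T`` holds one-hot targets, shape (n, 4).  Returns the scalar loss
    -mean(sum(T log z)) (with the probability floor) and a dict of
    gradients keyed like :meth:`NetworkParams.arrays`.
    """
    n = X.shape[0]
    y1, y2, z = _forward_batch(X, net)
    loss = -float(np.mean(np.sum(T * np.log(np.maximum(z, _PROB_FLOOR)), axis=1)))

    # softmax + cross-entropy: d(loss)/d(logits3) = (z - T)/n
    d3 = (z - T) / n
    gW3 = d3.T @ y2
    gb3 = d3.sum(axis=0)
    d2 = (d3 @ net.W3) * (y2 > 0)
    gW2 = d2.T @ y1
    gb2 = d2.sum(axis=0)
    d1 = (d2 @ net.W2) * (y1 > 0)
    gW1 = d1.T @ X
    gb1 = d1.sum(axis=0)
    grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2, "W3": gW3, "b3": gb3}
    return loss, grads


def _accuracy(X: np.ndarray, y: np.ndarray, net: NetworkParams) -> float:
    z = _forward_batch(X, net)[2]
    return float(np.mean(z.argmax(axis=1) == y))


def train(
    cohort: LabeledCohort,
    config: TrainingConfig | None = None,
) -> tuple[NetworkParams, TrainingReport, FeatureScaler | None]:
    """Train the classifier on a labeled cohort.

    Minimizes mean categorical cross-entropy with mini-batch Adam; an
    optional validation split drives early stopping (the parameters from
    the best validation epoch are returned).  Fully deterministic given
    ``config.seed``, which controls initialization, the train/validation
    split and the per-epoch shuffles.

    Returns ``(params, report, scaler)``; ``scaler`` is None unless
    ``config.standardize`` is set.

    Raises
    ------
    ValueError
        If fewer than two classes are present.
    TrainingError
        If the loss becomes non-finite, naming the epoch.
    """
    if config is None:
        config = TrainingConfig()
    X, y = cohort.X, cohort.y
    if len(np.unique(y)) < 2:
        raise ValueError("training requires a cohort with at least two classes")

    rng = np.random.default_rng(config.seed)
    net = init_network(int(rng.integers(2**31)))

    scaler = None
    if config.standardize:
        scaler = FeatureScaler(mean=X.mean(axis=0), sd=X.std(axis=0))
        X = scaler.transform(X)

    n = len(y)
    perm = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_tr, y_tr = X[tr_idx], y[tr_idx]
    X_val, y_val = X[val_idx], y[val_idx]
    T_tr = np.eye(N_SUBTYPES)[y_tr]

    # Adam state
    m = {k: np.zeros_like(v) for k, v in net.arrays().items()}
    v = {k: np.zeros_like(vv) for k, vv in net.arrays().items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    tr_loss_hist: list[float] = []
    tr_acc_hist: list[float] = []
    val_loss_hist: list[float] = []
    val_acc_hist: list[float] = []
    best_val = np.inf
    best_net = net.copy()
    bad_epochs = 0
    epochs_run = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(y_tr))
        epoch_loss = 0.0
        for start in range(0, len(y_tr), config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = loss_and_gradients(X_tr[idx], T_tr[idx], net)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            step += 1
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                m_hat = m[k] / (1 - beta1**step)
                v_hat = v[k] / (1 - beta2**step)
                arr = getattr(net, k)
                arr -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        epochs_run = epoch
        tr_loss_hist.append(epoch_loss / len(y_tr))
        tr_acc_hist.append(_accuracy(X_tr, y_tr, net))
        if n_val:
            vl, _ = loss_and_gradients(X_val, np.eye(N_SUBTYPES)[y_val], net)
            val_loss_hist.append(vl)
            val_acc_hist.append(_accuracy(X_val, y_val, net))
            if vl < best_val - 1e-6:
                best_val = vl
                best_net = net.copy()
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > config.patience:
                    net = best_net
                    break
        else:
            best_net = net

    if n_val and np.isfinite(best_val):
        net = best_net

    report = TrainingReport(
        train_loss=tr_loss_hist,
        train_accuracy=tr_acc_hist,
        val_loss=val_loss_hist,
        val_accuracy=val_acc_hist,
        epochs_run=epochs_run,
        config=config,
    )
    return net, report, scaler


def predict(
    x: np.ndarray, net: NetworkParams, scaler: FeatureScaler | None = None
) -> tuple[Subtype, float, np.ndarray]:
    """Classify one phase vector.

    Returns ``(label, confidence, z)`` where the label is the argmax of
    the softmax output (ties broken toward the lowest class index, PPC
    first) and confidence is ``100 * max(z)`` in percent.
    """
    x = np.asarray(x, dtype=float)
    if scaler is not None:
        x = scaler.transform(x)
    z = forward(x, net)
    label = Subtype(int(np.argmax(z)))  # argmax returns the first maximum
    return label, 100.0 * float(z[label]), z


def predict_labels(
    X: np.ndarray, net: NetworkParams, scaler: FeatureScaler | None = None
) -> np.ndarray:
    """Vectorized argmax labels (subtype indices) for an (n, 4) batch."""
    X = np.asarray(X, dtype=float)
    if scaler is not None:
        X = scaler.transform(X)
    return forward(X, net).argmax(axis=1)


# -- persistence ----------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def save_model(
    net: NetworkParams,
    path: str | Path,
    *,
    scaler: FeatureScaler | None = None,
    training_config: TrainingConfig | None = None,
    params_fingerprint: str | None = None,
    extra_metadata: dict | None = None,
) -> None:
    """Write the model to a versioned JSON text file.

    The file records the six arrays row-major at full precision (hex
    floats, so the round trip is bit-exact), the immutable class order,
    the optional feature scaler, the training configuration and the
    generative-parameter fingerprint.
    """
    doc = {
        "format_version": _MODEL_FORMAT_VERSION,
        "package_version": _pkg_version,
        "class_order": [s.name for s in SUBTYPES],
        "arrays": {
            k: {"shape": list(a.shape), "data": [fl.hex() for fl in a.ravel()]}
            for k, a in net.arrays().items()
        },
        "scaler": None
        if scaler is None
        else {
            "mean": [fl.hex() for fl in scaler.mean],
            "sd": [fl.hex() for fl in scaler.sd],
        },
        "training_config": None if training_config is None else training_config.to_dict(),
        "generative_params_fingerprint": params_fingerprint,
        "metadata": extra_metadata or {},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _floats(hexes: Iterable[str], field: str) -> np.ndarray:
    try:
        return np.array([float.fromhex(h) for h in hexes], dtype=float)
    except (TypeError, ValueError):
        raise ModelFormatError(f"field {field!r} holds malformed float data") from None


def load_model(path: str | Path) -> tuple[NetworkParams, FeatureScaler | None, dict]:
    """Read a model file written by :func:`save_model`.

    Returns ``(net, scaler, metadata)``.  Refuses files whose class order
    differs from the package's fixed PPC, CPC, OCC, CCC order, and names
    the offending field on any shape or format mismatch.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ModelFormatError(f"not a valid model file: {e}") from None
    if not isinstance(doc, dict) or "arrays" not in doc:
        raise ModelFormatError("field 'arrays' missing")
    if "class_order" not in doc:
        raise ModelFormatError("field 'class_order' missing; refusing to assume one")
    expected_order = [s.name for s in SUBTYPES]
    if doc["class_order"] != expected_order:
        raise ModelFormatError(
            f"field 'class_order' is {doc['class_order']}, expected {expected_order}"
        )
    arrays = {}
    for name, shape in _SHAPES.items():
        if name not in doc["arrays"]:
            raise ModelFormatError(f"field 'arrays.{name}' missing")
        entry = doc["arrays"][name]
        a = _floats(entry.get("data", []), f"arrays.{name}")
        if tuple(entry.get("shape", [])) != shape or a.size != int(np.prod(shape)):
            raise ModelFormatError(
                f"field 'arrays.{name}' has shape {entry.get('shape')}, expected {list(shape)}"
            )
        arrays[name] = a.reshape(shape)
    scaler = None
    if doc.get("scaler") is not None:
        scaler = FeatureScaler(
            mean=_floats(doc["scaler"]["mean"], "scaler.mean"),
            sd=_floats(doc["scaler"]["sd"], "scaler.sd"),
        )
    meta = {
        k: doc.get(k)
        for k in (
            "package_version",
            "training_config",
            "generative_params_fingerprint",
            "metadata",
        )
    }
    return NetworkParams(**arrays), scaler, meta
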