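"""The patch classifier: texture -> structure label.

A patch of side p is area-downsampled to d x d, standardized, and mapped to
one of c structure classes. The ``lightweight`` backbone is a compact
multilayer perceptron (two ReLU hidden layers with dropout before the c-way
softmax head) trained with Adam on cross-entropy, the learning rate halved
every ``lr_halving_period`` epochs, and early stopping when the validation
loss fails to improve for ``early_stop_patience`` epochs. That recipe — and
the 100 x 100 input resolution, batch size 100, 50-epoch cap, 1e-4 learning
rate defaults — is the operating point the surrounding pipeline was designed
for; the backbone itself is deliberately swappable behind
:class:`PatchClassifier`, because the pipeline is classifier-agnostic.

Normalization is (x - mean) / sd with an sd = 0 guard. At training time the
mean and sd are computed over all downsampled training patches and frozen
into the model (``normalization_stats``), so inference sees the same scale;
called standalone (no stats), :func:`preprocess_patch` standardizes with the
patch's own statistics.
"""

from __future__ import annotations

import dataclasses
import io
import json
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .sampling import PatchSample

__all__ = [
    "ClassifierConfig",
    "PatchClassifier",
    "ClassifierModel",
    "preprocess_patch",
    "preprocess_batch",
    "train_classifier",
    "predict_one_hot",
    "predict_batch",
    "early_stopping_triggered",
    "save_model",
    "load_model",
]


@dataclasses.dataclass
class ClassifierConfig:
    c: int = 10
    input_downsample_d: int = 100
    dropout_rate: float = 0.5
    architecture: str = "lightweight"
    hidden_sizes: tuple[int, ...] = (128, 64)
    batch_size: int = 100
    max_epochs: int = 50
    learning_rate: float = 1e-4
    early_stop_patience: int = 5
    lr_halving_period: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.input_downsample_d < 8:
            raise ValueError("input_downsample_d must be >= 8")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.architecture != "lightweight":
            raise ValueError(
                f"unsupported architecture {self.architecture!r}; "
                "this build ships the 'lightweight' backbone"
            )
        self.hidden_sizes = tuple(self.hidden_sizes)


# ---------------------------------------------------------------------------
# preprocessing


def _downsample_area(patch: np.ndarray, d: int) -> np.ndarray:
    """Area-style downsampling of a square patch to d x d."""
    p = patch.shape[0]
    if p == d:
        return patch.astype(np.float64)
    if p % d == 0:
        k = p // d
        return patch.reshape(d, k, d, k).mean(axis=(1, 3))
    return _sk_resize(patch.astype(np.float64), (d, d),
                      anti_aliasing=p > d, preserve_range=True)


def preprocess_patch(patch: np.ndarray, config: ClassifierConfig,
                     stats: dict[str, float] | None = None) -> np.ndarray:
    """Downsample to d x d and normalize.

    With ``stats`` (a trained model's ``normalization_stats``), normalization
    is ``(x - stats['mean']) / stats['sd']``. Without, the patch is
    standardized by its own mean/sd; in either case a zero sd is guarded and
    yields an all-zero output.
    """
    patch = np.asarray(patch)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"patch must be square 2D, got shape {patch.shape}")
    small = _downsample_area(patch, config.input_downsample_d)
    if stats is None:
        mean, sd = small.mean(), small.std()
    else:
        mean, sd = stats["mean"], stats["sd"]
    if sd == 0:
        return np.zeros_like(small)
    return (small - mean) / sd


def _downsample_batch(patches: np.ndarray, d: int) -> np.ndarray:
    m, p, q = patches.shape
    if p != q:
        raise ValueError("patches must be square")
    if p % d == 0:
        k = p // d
        return patches.reshape(m, d, k, d, k).astype(np.float32).mean(axis=(2, 4))
    return np.stack([_downsample_area(patches[i], d)
                     for i in range(m)]).astype(np.float32)


def preprocess_batch(patches: np.ndarray, config: ClassifierConfig,
                     stats: dict[str, float] | None = None) -> np.ndarray:
    """Vectorized :func:`preprocess_patch`; returns flattened (m, d*d) floats."""
    small = _downsample_batch(np.asarray(patches), config.input_downsample_d)
    if stats is None:
        mean = small.mean(axis=(1, 2), keepdims=True)
        sd = small.std(axis=(1, 2), keepdims=True)
        sd_safe = np.where(sd == 0, 1.0, sd)
        out = (small - mean) / sd_safe
        out[np.broadcast_to(sd == 0, out.shape)] = 0.0
    elif stats["sd"] == 0:
        out = np.zeros_like(small)
    else:
        out = (small - stats["mean"]) / stats["sd"]
    m = small.shape[0]
    return out.reshape(m, -1)


# ---------------------------------------------------------------------------
# model


class PatchClassifier:
    """Anything that maps raw (m, p, p) patches to (m, c) one-hot rows."""

    c: int

    def predict_proba_batch(self, patches: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_one_hot_batch(self, patches: np.ndarray) -> np.ndarray:
        proba = self.predict_proba_batch(patches)
        return one_hot_from_proba(proba)

    def predict_one_hot_samples(self, samples: Sequence[PatchSample]) -> np.ndarray:
        return self.predict_one_hot_batch(np.stack([s.pixels for s in samples]))


class CenterLabelOracle(PatchClassifier):
    """Stub classifier that returns the ground-truth label of each patch
    center — the reconstruction stage's upper bound.

    Useful for testing the sparse-map / density / post-processing chain in
    isolation from classifier error. ``labels`` is a 2D label map (applied
    to every slice) or a 3D label volume indexed by ``slice_index``; centers
    must fall on labeled (nonzero) pixels.
    """

    def __init__(self, labels: np.ndarray, c: int):
        self.labels = np.asarray(labels)
        self.c = c

    def predict_one_hot_samples(self, samples: Sequence[PatchSample]) -> np.ndarray:
        out = np.zeros((len(samples), self.c), dtype=np.uint8)
        for i, s in enumerate(samples):
            lab_map = (self.labels if self.labels.ndim == 2
                       else self.labels[s.slice_index])
            label = int(lab_map[s.center_yx])
            if not 1 <= label <= self.c:
                raise ValueError(
                    f"oracle center {s.center_yx} has label {label}, not a structure")
            out[i, label - 1] = 1
        return out


def one_hot_from_proba(proba: np.ndarray) -> np.ndarray:
    """Argmax rows to one-hot; ties break toward the lowest class index."""
    proba = np.atleast_2d(proba)
    out = np.zeros_like(proba, dtype=np.uint8)
    out[np.arange(proba.shape[0]), np.argmax(proba, axis=1)] = 1
    return out


@dataclasses.dataclass
class ClassifierModel(PatchClassifier):
    """Trained patch classifier: parameters + config + training provenance."""

    weights: dict[str, np.ndarray]
    config: ClassifierConfig
    normalization_stats: dict[str, float]
    training_history: list[dict[str, float]]

    @property
    def c(self) -> int:
        return self.config.c

    def _forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for standardized flattened inputs (no dropout at inference)."""
        h = x
        n_hidden = len(self.config.hidden_sizes)
        for i in range(n_hidden):
            h = np.maximum(h @ self.weights[f"W{i}"] + self.weights[f"b{i}"], 0.0)
        return h @ self.weights[f"W{n_hidden}"] + self.weights[f"b{n_hidden}"]

    def predict_proba_batch(self, patches: np.ndarray,
                            chunk: int = 8192) -> np.ndarray:
        patches = np.asarray(patches)
        if patches.ndim == 2:
            patches = patches[None]
        out = np.empty((patches.shape[0], self.c), dtype=np.float64)
        for lo in range(0, patches.shape[0], chunk):
            x = preprocess_batch(patches[lo:lo + chunk], self.config,
                                 self.normalization_stats)
            out[lo:lo + x.shape[0]] = _softmax(self._forward(x))
        return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_weights(config: ClassifierConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    sizes = (config.input_downsample_d ** 2, *config.hidden_sizes, config.c)
    weights: dict[str, np.ndarray] = {}
    for i, (fan_in, fan_out) in enumerate(zip(sizes, sizes[1:])):
        weights[f"W{i}"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)
        ).astype(np.float64)
        weights[f"b{i}"] = np.zeros(fan_out)
    return weights


def early_stopping_triggered(val_losses: Sequence[float], patience: int) -> bool:
    """True once the best validation loss is ``patience`` or more epochs old."""
    if len(val_losses) <= patience:
        return False
    best = int(np.argmin(val_losses))
    return (len(val_losses) - 1 - best) >= patience


class _Adam:
    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _labels_to_index(samples: Sequence[PatchSample], c: int) -> np.ndarray:
    labels = np.array([s.label if s.label is not None else -1 for s in samples])
    if labels.min() < 1 or labels.max() > c:
        bad = labels[(labels < 1) | (labels > c)][0]
        raise ValueError(f"sample label {bad} outside 1..{c}")
    return labels - 1


def _forward_backward(weights: dict[str, np.ndarray], x: np.ndarray,
                      y: np.ndarray, config: ClassifierConfig,
                      rng: np.random.Generator | None
                      ) -> tuple[float, dict[str, np.ndarray]]:
    """Cross-entropy loss and gradients for one mini-batch.

    ``rng`` enables inverted dropout on the last hidden activation.
    """
    n_hidden = len(config.hidden_sizes)
    acts = [x]
    h = x
    for i in range(n_hidden):
        h = np.maximum(h @ weights[f"W{i}"] + weights[f"b{i}"], 0.0)
        acts.append(h)
    drop_mask = None
    if rng is not None and config.dropout_rate > 0:
        keep = 1.0 - config.dropout_rate
        drop_mask = (rng.random(h.shape) < keep) / keep
        h = h * drop_mask
    logits = h @ weights[f"W{n_hidden}"] + weights[f"b{n_hidden}"]
    proba = _softmax(logits)
    n = x.shape[0]
    loss = -np.log(np.clip(proba[np.arange(n), y], 1e-12, None)).mean()

    grads: dict[str, np.ndarray] = {}
    dlogits = proba.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    grads[f"W{n_hidden}"] = h.T @ dlogits
    grads[f"b{n_hidden}"] = dlogits.sum(axis=0)
    dh = dlogits @ weights[f"W{n_hidden}"].T
    if drop_mask is not None:
        dh = dh * drop_mask
    for i in range(n_hidden - 1, -1, -1):
        dh = dh * (acts[i + 1] > 0)
        grads[f"W{i}"] = acts[i].T @ dh
        grads[f"b{i}"] = dh.sum(axis=0)
        if i > 0:
            dh = dh @ weights[f"W{i}"].T
    return float(loss), grads


def _eval_loss_acc(weights: dict[str, np.ndarray], x: np.ndarray,
                   y: np.ndarray, config: ClassifierConfig) -> tuple[float, float]:
    n_hidden = len(config.hidden_sizes)
    h = x
    for i in range(n_hidden):
        h = np.maximum(h @ weights[f"W{i}"] + weights[f"b{i}"], 0.0)
    logits = h @ weights[f"W{n_hidden}"] + weights[f"b{n_hidden}"]
    proba = _softmax(logits)
    loss = -np.log(np.clip(proba[np.arange(len(y)), y], 1e-12, None)).mean()
    acc = float((proba.argmax(axis=1) == y).mean())
    return float(loss), acc


def train_classifier(train: Sequence[PatchSample], val: Sequence[PatchSample],
                     config: ClassifierConfig) -> ClassifierModel:
    """Train the patch classifier; returns the best-validation-loss model.

    Mini-batch Adam on cross-entropy; the learning rate is halved every
    ``lr_halving_period`` epochs and training stops early once the validation
    loss has not improved for ``early_stop_patience`` epochs. The per-epoch
    history (losses, accuracies, learning rate) is kept on the model.
    """
    if not train or not val:
        raise ValueError("train and val sets must both be nonempty")
    y_train = _labels_to_index(train, config.c)
    y_val = _labels_to_index(val, config.c)
    small_train = _downsample_batch(np.stack([s.pixels for s in train]),
                                    config.input_downsample_d)
    norm_stats = {"mean": float(small_train.mean()),
                  "sd": float(small_train.std())}
    x_train = preprocess_batch(np.stack([s.pixels for s in train]), config,
                               norm_stats)
    x_val = preprocess_batch(np.stack([s.pixels for s in val]), config,
                             norm_stats)

    rng = np.random.default_rng(config.seed)
    weights = _init_weights(config, rng)
    adam = _Adam(weights)
    history: list[dict[str, float]] = []
    best_weights = {k: v.copy() for k, v in weights.items()}
    best_val = np.inf
    val_losses: list[float] = []
    for epoch in range(config.max_epochs):
        lr = config.learning_rate * 0.5 ** (epoch // config.lr_halving_period)
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, len(train), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            loss, grads = _forward_backward(
                weights, x_train[idx], y_train[idx], config, rng)
            adam.step(weights, grads, lr)
            epoch_loss += loss
            n_batches += 1
        train_loss, train_acc = _eval_loss_acc(weights, x_train, y_train, config)
        val_loss, val_acc = _eval_loss_acc(weights, x_val, y_val, config)
        history.append({
            "epoch": epoch, "lr": lr,
            "batch_loss": epoch_loss / max(n_batches, 1),
            "train_loss": train_loss, "train_acc": train_acc,
            "val_loss": val_loss, "val_acc": val_acc,
        })
        val_losses.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = {k: v.copy() for k, v in weights.items()}
        if early_stopping_triggered(val_losses, config.early_stop_patience):
            break
    return ClassifierModel(best_weights, config, norm_stats, history)


# ---------------------------------------------------------------------------
# prediction


def predict_one_hot(model: PatchClassifier, patch: np.ndarray) -> np.ndarray:
    """c-bit one-hot prediction for one patch (argmax, ties to lowest class)."""
    proba = model.predict_proba_batch(np.asarray(patch)[None])
    return one_hot_from_proba(proba)[0]


def predict_batch(model: PatchClassifier, patches: Sequence[PatchSample]
                  ) -> list[tuple[tuple[int, int], int, np.ndarray]]:
    """Order-preserving batch prediction.

    Returns ``(center_yx, slice_index, one_hot)`` per input patch so the
    sparse map can be filled downstream.
    """
    if not patches:
        raise ValueError("empty patch list")
    one_hot = model.predict_one_hot_samples(patches)
    return [
        (patches[i].center_yx, patches[i].slice_index, one_hot[i])
        for i in range(len(patches))
    ]


# ---------------------------------------------------------------------------
# persistence


def save_model(model: ClassifierModel, path) -> None:
    """Single-archive save: npz with weights + JSON metadata."""
    meta = {
        "config": dataclasses.asdict(model.config),
        "normalization_stats": model.normalization_stats,
        "training_history": model.training_history,
    }
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.weights)


def load_model(path) -> ClassifierModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        weights = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = meta["config"]
    cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
    return ClassifierModel(weights, ClassifierConfig(**cfg),
                           meta["normalization_stats"], meta["training_history"])
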