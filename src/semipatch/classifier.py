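"""The final patch classifier: a three-convolution CNN plus evaluation tools.

The architecture is a fixed ladder for square inputs divisible by 8 (default
32 px): batch normalisation before each of three 64-kernel convolutions at
feature-map sizes 32x32, 16x16 and 8x8, each followed by 2x2 max pooling
(the first two pooling outputs pass through ReLU; the last pooling output is
4x4), then global average pooling, dropout, a hidden fully connected layer
with ReLU and a final two-way layer whose softmax gives the class
memberships. Training is plain SGD with per-step learning-rate decay.

Evaluation reports accuracy, balanced accuracy (mean of sensitivity and
specificity), F-measure and rank-statistic AUC, and a Wilcoxon signed-rank
test compares paired per-run metrics between two systems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import zoom as _ndzoom
from sklearn.metrics import roc_auc_score

from .errors import ArchitectureError, ConfigurationError, DataError, DegenerateError, DivergenceError
from .nn import (
    SGD,
    BatchNorm,
    Conv2d,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool2d,
    ReLU,
    Sequential,
    Softmax,
    nll_loss,
)
from .patchio import PatchDataset

logger = logging.getLogger("semipatch.classifier")

__all__ = [
    "CnnConfig",
    "EvalReport",
    "build_cnn",
    "train_cnn",
    "predict_proba",
    "evaluate",
    "wilcoxon_compare",
]


@dataclass
class CnnConfig:
    input_size: int = 32
    conv_kernels: int = 64          # kernels per convolution layer
    conv_kernel_size: int = 3
    learning_rate: float = 0.01
    epochs: int = 80
    batch_size: int = 32
    decay: float = 1e-5             # per-step learning-rate decay (weight-decay variant via `decay_mode`)
    decay_mode: str = "lr"          # 'lr' or 'weight'
    dropout_rate: float = 0.5
    fc_widths: tuple[int, int] = (256, 2)
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 8 != 0:
            raise ArchitectureError(
                f"input_size must be divisible by 8 (three 2x poolings), got {self.input_size}"
            )
        if self.conv_kernels < 1 or any(w < 1 for w in self.fc_widths):
            raise ConfigurationError("layer widths must be positive")
        if self.decay_mode not in ("lr", "weight"):
            raise ConfigurationError("decay_mode must be 'lr' or 'weight'")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")


def build_cnn(config: CnnConfig) -> Sequential:
    """Build the CNN and verify the feature-map ladder with a dummy forward."""
    rng = np.random.default_rng(config.seed)
    k = config.conv_kernels
    ks = config.conv_kernel_size
    layers = [
        BatchNorm(3, name="bn1"),
        Conv2d(3, k, ks, rng, padding="same", name="conv1"),
        MaxPool2d(2, name="pool1"),
        ReLU(name="relu1"),
        BatchNorm(k, name="bn2"),
        Conv2d(k, k, ks, rng, padding="same", name="conv2"),
        MaxPool2d(2, name="pool2"),
        ReLU(name="relu2"),
        BatchNorm(k, name="bn3"),
        Conv2d(k, k, ks, rng, padding="same", name="conv3"),
        MaxPool2d(2, name="pool3"),
        GlobalAvgPool(name="gap"),
        Dropout(config.dropout_rate, np.random.default_rng(config.seed + 1), name="dropout"),
        Dense(k, config.fc_widths[0], rng, name="fc1"),
        ReLU(name="relu_fc"),
        Dense(config.fc_widths[0], config.fc_widths[1], rng, name="fc2"),
        Softmax(name="softmax"),
    ]
    model = Sequential(layers, name="idc_cnn")
    s = config.input_size
    dummy = np.zeros((1, 3, s, s))
    model.forward(dummy, record=True)
    ladder = {
        "conv1": (s, s),
        "conv2": (s // 2, s // 2),
        "conv3": (s // 4, s // 4),
        "pool3": (s // 8, s // 8),
    }
    for name, expected in ladder.items():
        got = model.activation(name).shape[2:]
        if tuple(got) != expected:
            raise ArchitectureError(f"{name} feature map is {got}, expected {expected}")
    model.config = config  # type: ignore[attr-defined]
    return model


def _to_nchw(images: np.ndarray, size: int) -> np.ndarray:
    h, w = images.shape[1:3]
    if (h, w) != (size, size):
        images = _ndzoom(images, (1, size / h, size / w, 1), order=1)
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2))


def train_cnn(
    model: Sequential, data: PatchDataset, config: CnnConfig
) -> tuple[Sequential, list[float]]:
    """Train with SGD (stated learning rate / batch size / decay); returns the
    fitted model and the per-epoch mean loss trace."""
    mask = data.labelled_mask
    if not mask.all():
        logger.warning("dropping %d unlabelled patches from CNN training", int((~mask).sum()))
    y = data.labels[mask]
    if len(np.unique(y)) < 2:
        raise DataError("CNN training requires both classes")
    X = _to_nchw(data.images[mask], config.input_size)
    if config.epochs == 0:
        return model, []
    opt = SGD(
        model,
        lr=config.learning_rate,
        decay=config.decay if config.decay_mode == "lr" else 0.0,
    )
    wd = config.decay if config.decay_mode == "weight" else 0.0
    rng = np.random.default_rng(config.seed + 2)
    trace: list[float] = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            probs = model.forward(X[idx], training=True)
            loss, grad = nll_loss(probs, y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}", epoch=epoch)
            model.backward(grad)
            if wd:
                for layer, key, param in model.parameters():
                    if key == "w" and key in layer.grads:
                        layer.grads[key] = layer.grads[key] + wd * param
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return model, trace


def predict_proba(model: Sequential, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
    """Class-membership probabilities for (N, H, W, 3) images in [0, 1]."""
    size = model.config.input_size  # type: ignore[attr-defined]
    X = _to_nchw(images, size)
    return np.concatenate(
        [model.forward(X[i : i + batch_size], training=False) for i in range(0, len(X), batch_size)]
    )


@dataclass
class EvalReport:
    accuracy: float
    balanced_accuracy: float
    f_measure: float
    auc: float | None
    confusion: dict = field(default_factory=dict)  # tp / fp / fn / tn
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "f_measure": self.f_measure,
            "auc": self.auc,
            "confusion": self.confusion,
            "n": self.n,
        }


def report_from_counts(tp: int, fp: int, fn: int, tn: int, auc: float | None = None) -> EvalReport:
    """Metrics from confusion counts: balanced accuracy is the mean of
    sensitivity and specificity; F is the harmonic precision/recall mean."""
    n = tp + fp + fn + tn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return EvalReport(
        accuracy=(tp + tn) / n if n else 0.0,
        balanced_accuracy=(sens + spec) / 2.0,
        f_measure=f,
        auc=auc,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        n=n,
    )


def evaluate(model: Sequential, test: PatchDataset) -> EvalReport:
    """Evaluate on a labelled test set; AUC is the rank statistic over the
    positive-class membership scores (undefined, hence None, for a
    single-class test set)."""
    if not test.labelled_mask.all():
        raise DataError("test set must be fully labelled")
    probs = predict_proba(model, test.images)
    scores = probs[:, 1]
    preds = (scores >= 0.5).astype(int)
    y = test.labels
    tp = int(((preds == 1) & (y == 1)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    if len(np.unique(y)) < 2:
        logger.warning("single-class test set: AUC undefined, reported as None")
        auc = None
    else:
        auc = float(roc_auc_score(y, scores))
    return report_from_counts(tp, fp, fn, tn, auc=auc)


def wilcoxon_compare(scores_a: np.ndarray, scores_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired run metrics.

    Exact null distribution for small samples (n <= 25 after discarding zero
    differences), normal approximation with tie correction otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired samples must be equal-length 1-D arrays")
    if len(a) < 5:
        raise DataError(f"need at least 5 paired values, got {len(a)}")
    d = a - b
    if np.all(d == 0):
        raise DegenerateError("all paired differences are zero; test undefined")
    res = stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


def save_cnn(model: Sequential, path: str) -> None:
    """Model checkpoint: .npz of parameters plus a JSON architecture echo."""
    import dataclasses
    import json

    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    np.savez_compressed(base + ".npz", **model.state_dict())
    with open(base + ".json", "w") as fh:
        json.dump({"config": dataclasses.asdict(model.config), "layers": model.layer_names()}, fh, indent=1)


def load_cnn(path: str) -> Sequential:
    import json

    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        meta = json.load(fh)
    cfg = meta["config"]
    cfg["fc_widths"] = tuple(cfg["fc_widths"])
    model = build_cnn(CnnConfig(**cfg))
    with np.load(base + ".npz") as arch:
        model.load_state_dict(dict(arch))
    return model
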