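"""Fixed-length patch representations for the labelling stage.

The primary representation is the VGG-16 GAP concatenation: run the VGG-16
convolutional stack (the fully connected head is never built), apply global
average pooling at the four internal tap layers with 128, 256, 512 and 512
channels, and concatenate in network order into one vector of length
128 + 256 + 512 + 512 = 1408. The tap layers are the final convolutions of
blocks 2-5 — the unique layers with those channel counts directly before
each pooling.

The backbone accepts pretrained weights from an ``.npz`` file; by default it
is randomly initialised from a fixed seed, which preserves every
dimensionality and determinism contract without a weight download. PCA and
LDA alternatives are provided for the comparison experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import zoom as _ndzoom
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, DataError, DimensionError
from .nn import Conv2d, MaxPool2d, ReLU
from .patchio import PatchDataset

logger = logging.getLogger("semipatch.features")

__all__ = [
    "FeatureMatrix",
    "VGG16Backbone",
    "vgg_gap_features",
    "pca_features",
    "lda_features",
    "standardize_features",
]

VGG16_BLOCKS = ([64, 64], [128, 128], [256, 256, 256], [512, 512, 512], [512, 512, 512])
TAP_CHANNELS = (128, 256, 512, 512)
GAP_DIM = sum(TAP_CHANNELS)  # 1408


@dataclass
class FeatureMatrix:
    """Per-patch feature vectors with an extraction-method record."""

    vectors: np.ndarray
    method: str
    patch_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise DimensionError(f"feature vectors must be 2-D, got shape {self.vectors.shape}")
        if len(self.patch_ids) != len(self.vectors):
            raise DimensionError("patch_ids must align one-to-one with feature rows")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.vectors)


class VGG16Backbone:
    """The 13-layer VGG-16 convolutional stack with named GAP tap points.

    Only the forward pass exists; the network is a frozen feature extractor.
    Weights are float32. ``weights_npz`` may point to an ``.npz`` archive with
    arrays ``block{i}_conv{j}.w`` (shape (C_out, C_in, 3, 3)) and ``.b``.
    """

    MIN_INPUT = 16  # four poolings precede the last tap layer

    def __init__(self, seed: int = 0, weights_npz: str | None = None):
        rng = np.random.default_rng(seed)
        self.layers: list[tuple[str, object]] = []
        self.tap_names: list[str] = []
        c_in = 3
        for bi, widths in enumerate(VGG16_BLOCKS, start=1):
            for ci, width in enumerate(widths, start=1):
                name = f"block{bi}_conv{ci}"
                conv = Conv2d(c_in, width, 3, rng, padding="same", name=name)
                conv.params = {k: v.astype(np.float32) for k, v in conv.params.items()}
                self.layers.append((name, conv))
                self.layers.append((f"{name}_relu", ReLU()))
                c_in = width
            self.tap_names.append(f"block{bi}_conv{len(widths)}_relu")
            if bi < len(VGG16_BLOCKS):
                self.layers.append((f"pool{bi}", MaxPool2d(2)))
        # the four designated taps are the block-final convolutions of blocks 2..5
        self.tap_names = self.tap_names[1:]
        if weights_npz is not None:
            self._load_weights(weights_npz)
        tap_widths = tuple(
            next(l for n, l in self.layers if n == t.replace("_relu", "")).params["w"].shape[0]
            for t in self.tap_names
        )
        if tap_widths != TAP_CHANNELS:
            raise ConfigurationError(
                f"backbone tap layers must have channels {TAP_CHANNELS}, found {tap_widths}"
            )

    def _load_weights(self, path: str) -> None:
        with np.load(path) as arch:
            for name, layer in self.layers:
                if not isinstance(layer, Conv2d):
                    continue
                for key in ("w", "b"):
                    full = f"{name}.{key}"
                    if full not in arch:
                        raise ConfigurationError(f"weights file missing array {full}")
                    if arch[full].shape != layer.params[key].shape:
                        raise ConfigurationError(
                            f"{full}: expected shape {layer.params[key].shape}, got {arch[full].shape}"
                        )
                    layer.params[key] = arch[full].astype(np.float32)

    def gap_features(self, batch: np.ndarray) -> np.ndarray:
        """(N, H, W, 3) in [0,1] -> (N, 1408) GAP-concatenated features."""
        h, w = batch.shape[1:3]
        if h < self.MIN_INPUT or w < self.MIN_INPUT:
            raise ConfigurationError(
                f"input spatial size {(h, w)} below backbone minimum {self.MIN_INPUT}"
            )
        x = np.ascontiguousarray(batch.transpose(0, 3, 1, 2), dtype=np.float32)
        taps: list[np.ndarray] = []
        remaining = set(self.tap_names)
        for name, layer in self.layers:
            x = layer.forward(x)
            if name in remaining:
                taps.append(x.mean(axis=(2, 3)))
                remaining.discard(name)
                if not remaining:
                    break
        return np.concatenate(taps, axis=1).astype(float)


def _resize_batch(images: np.ndarray, size: int) -> np.ndarray:
    h, w = images.shape[1:3]
    if (h, w) == (size, size):
        return images
    factors = (1, size / h, size / w, 1)
    return _ndzoom(images, factors, order=1)


def vgg_gap_features(
    ds: PatchDataset,
    backbone: VGG16Backbone | None = None,
    resize: int | None = 224,
    batch_size: int = 16,
) -> FeatureMatrix:
    """Extract the length-1408 GAP concatenation for every patch.

    ``resize`` rescales patches bilinearly before the backbone (canonical
    VGG preprocessing is 224); ``resize=None`` runs fully convolutionally at
    the native patch size (minimum 16 px).
    """
    if backbone is None:
        backbone = VGG16Backbone(seed=0)
    images = ds.images if resize is None else _resize_batch(ds.images, resize)
    chunks = [
        backbone.gap_features(images[i : i + batch_size])
        for i in range(0, len(images), batch_size)
    ]
    return FeatureMatrix(np.concatenate(chunks), "vgg_gap", list(ds.ids))


def pca_features(X: FeatureMatrix, n_components: int, seed: int = 0) -> FeatureMatrix:
    """PCA reduction fit on the given matrix; explained-variance ratios in meta."""
    if n_components > min(X.vectors.shape):
        raise DimensionError(
            f"n_components={n_components} exceeds min(n_samples, dim)={min(X.vectors.shape)}"
        )
    model = PCA(n_components=n_components, random_state=seed)
    reduced = model.fit_transform(X.vectors)
    return FeatureMatrix(
        reduced,
        "pca",
        list(X.patch_ids),
        meta={"explained_variance_ratio": model.explained_variance_ratio_, "model": model},
    )


def lda_features(X: FeatureMatrix, labels: np.ndarray, n_components_requested: int) -> FeatureMatrix:
    """LDA projection; the output dimension is capped at n_classes - 1."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DataError("LDA requires at least two classes")
    actual = min(n_components_requested, len(classes) - 1)
    if actual < n_components_requested:
        logger.warning(
            "LDA output truncated from %d to %d components (n_classes - 1)",
            n_components_requested,
            actual,
        )
    model = LinearDiscriminantAnalysis(n_components=actual)
    reduced = model.fit_transform(X.vectors, labels)
    return FeatureMatrix(reduced, "lda", list(X.patch_ids), meta={"model": model, "requested": n_components_requested})


def standardize_features(train: FeatureMatrix, *others: FeatureMatrix) -> list[FeatureMatrix]:
    """Zero-mean unit-variance columns, fit on the (labelled) training matrix."""
    scaler = StandardScaler().fit(train.vectors)
    out = []
    for fm in (train, *others):
        out.append(
            FeatureMatrix(
                scaler.transform(fm.vectors), fm.method, list(fm.patch_ids), meta={**fm.meta, "standardized": True}
            )
        )
    return out


def save_features(fm: FeatureMatrix, path: str) -> None:
    """Persist a feature matrix as a compressed .npz plus a TSV header sidecar."""
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    np.savez_compressed(base + ".npz", vectors=fm.vectors)
    with open(base + ".tsv", "w") as fh:
        fh.write(f"# method={fm.method}\tdim={fm.dim}\n")
        fh.write("patch_id\n")
        for pid in fm.patch_ids:
            fh.write(f"{pid}\n")


def load_features(path: str) -> FeatureMatrix:
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with np.load(base + ".npz") as arch:
        vectors = arch["vectors"]
    with open(base + ".tsv") as fh:
        header = fh.readline().strip().lstrip("# ")
        method = dict(kv.split("=") for kv in header.split("\t"))["method"]
        fh.readline()
        ids = [line.strip() for line in fh if line.strip()]
    return FeatureMatrix(vectors, method, ids)
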