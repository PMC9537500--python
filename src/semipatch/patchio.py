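"""Patch dataset container plus on-disk I/O (PNG patches, TSV manifests, YAML configs).

The on-disk layout mirrors the public IDC patch release: PNG tiles either
sorted into ``class0/`` / ``class1/`` / ``unlabelled/`` sub-directories or
carrying a trailing ``classK`` token in the filename
(``8863_idx5_x51_y1251_class0.png``). Intensities are normalised to [0, 1]
floats at load time so every downstream stage shares one convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .errors import ConfigurationError, DataError, FormatError

logger = logging.getLogger("semipatch.patchio")

UNLABELLED = -1
PROVENANCES = ("original", "gan", "pseudo")

_CLASS_TOKEN = re.compile(r"class([01])(?:\.[A-Za-z]+)?$")

__all__ = [
    "UNLABELLED",
    "PatchDataset",
    "RunConfig",
    "load_patch_dir",
    "write_patch_dir",
    "split_dataset",
    "load_run_config",
]


@dataclass
class PatchDataset:
    """Images with optional binary labels and provenance tags.

    images : float array (n, H, W, 3) in [0, 1]
    labels : int array (n,), 0/1 or UNLABELLED (-1)
    provenance : object array of {'original', 'gan', 'pseudo'}
    ids : unique string identifiers, aligned with rows
    """

    images: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise FormatError(f"images must be (n, H, W, 3); got {self.images.shape}")
        n = len(self.images)
        if not self.ids:
            self.ids = [f"patch_{i:06d}" for i in range(n)]
        if len(self.labels) != n or len(self.provenance) != n or len(self.ids) != n:
            raise FormatError("images, labels, provenance and ids must align")
        if len(set(self.ids)) != n:
            raise FormatError("patch ids must be unique")
        bad = set(np.unique(self.labels)) - {0, 1, UNLABELLED}
        if bad:
            raise FormatError(f"labels must be 0, 1 or unlabelled; got {sorted(bad)}")
        bad_prov = set(self.provenance) - set(PROVENANCES)
        if bad_prov:
            raise FormatError(f"unknown provenance tags {sorted(bad_prov)}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labelled_mask(self) -> np.ndarray:
        return self.labels != UNLABELLED

    def subset(self, index: np.ndarray) -> "PatchDataset":
        index = np.asarray(index)
        return PatchDataset(
            self.images[index],
            self.labels[index],
            self.provenance[index],
            [self.ids[i] for i in np.flatnonzero(index)] if index.dtype == bool
            else [self.ids[i] for i in index],
        )

    @staticmethod
    def concatenate(parts: list["PatchDataset"]) -> "PatchDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise DataError("cannot concatenate zero non-empty datasets")
        return PatchDataset(
            np.concatenate([p.images for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.provenance for p in parts]),
            [i for p in parts for i in p.ids],
        )

    @staticmethod
    def from_images(images, labels=None, provenance="original", ids=None) -> "PatchDataset":
        images = np.asarray(images, dtype=float)
        n = len(images)
        if labels is None:
            labels = np.full(n, UNLABELLED)
        labels = np.broadcast_to(np.asarray(labels, dtype=int), (n,)).copy()
        prov = np.array([provenance] * n, dtype=object) if isinstance(provenance, str) else np.asarray(provenance, dtype=object)
        return PatchDataset(images, labels, prov, list(ids) if ids is not None else [])


# ---------------------------------------------------------------------------
# Reading / writing patch directories
# ---------------------------------------------------------------------------

def _decode(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"), dtype=float) / 255.0
    except Exception as exc:  # pillow raises a zoo of exceptions
        raise FormatError(f"cannot decode image file {path}") from exc


def _label_from_filename(name: str) -> int:
    m = _CLASS_TOKEN.search(name)
    return int(m.group(1)) if m else UNLABELLED


def load_patch_dir(path: str | Path, label_rule: str = "subdir") -> PatchDataset:
    """Load every PNG under ``path`` into a dataset.

    label_rule='subdir' reads labels from ``class0``/``class1`` parent
    directories (anything else, e.g. ``unlabelled/``, loads unlabelled);
    label_rule='filename_token' parses a trailing ``classK`` filename token.
    Files with no deducible label load as unlabelled.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"{path} is not a directory")
    if label_rule not in ("subdir", "filename_token"):
        raise ConfigurationError(f"unknown label_rule {label_rule!r}")
    files = sorted(p for p in path.rglob("*.png"))
    if not files:
        logger.warning("no PNG files under %s; returning empty dataset", path)
        return PatchDataset(np.empty((0, 1, 1, 3)), np.empty(0, int), np.empty(0, object), [])
    images, labels, ids = [], [], []
    for f in files:
        img = _decode(f)
        if label_rule == "subdir":
            parent = f.parent.name
            label = {"class0": 0, "class1": 1}.get(parent, UNLABELLED)
        else:
            label = _label_from_filename(f.name)
        images.append(img)
        labels.append(label)
        ids.append(str(f.relative_to(path)))
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise FormatError(f"mixed image dimensions under {path}: {sorted(shapes)}")
    prov = np.array(["original"] * len(images), dtype=object)
    return PatchDataset(np.stack(images), np.array(labels), prov, ids)


def write_patch_dir(ds: PatchDataset, path: str | Path, manifest: str = "manifest.tsv") -> Path:
    """Write patches as 8-bit PNGs into class0/ class1/ unlabelled/ plus a TSV manifest."""
    path = Path(path)
    rows = []
    for i in range(len(ds)):
        sub = {0: "class0", 1: "class1"}.get(int(ds.labels[i]), "unlabelled")
        out = path / sub
        out.mkdir(parents=True, exist_ok=True)
        fname = Path(ds.ids[i]).name
        if not fname.endswith(".png"):
            fname += ".png"
        arr = np.clip(np.round(ds.images[i] * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out / fname)
        rows.append((f"{sub}/{fname}", int(ds.labels[i]), str(ds.provenance[i])))
    with open(path / manifest, "w") as fh:
        fh.write("filename\tlabel\tprovenance\n")
        for fname, label, prov in rows:
            fh.write(f"{fname}\t{label}\t{prov}\n")
    return path


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_dataset(
    ds: PatchDataset,
    fractions: tuple[float, float, float],
    stratified: bool = False,
    seed: int = 0,
) -> tuple[PatchDataset, PatchDataset, PatchDataset]:
    """Random, disjoint, exhaustive three-way split.

    A stratified split preserves the class ratio of each part to within one
    patch; it requires every item to be labelled.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ConfigurationError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(ds)
    rng = np.random.default_rng(seed)

    def cut(indices: np.ndarray) -> list[np.ndarray]:
        indices = rng.permutation(indices)
        m = len(indices)
        n0 = int(round(fractions[0] * m))
        n1 = int(round((fractions[0] + fractions[1]) * m))
        return [indices[:n0], indices[n0:n1], indices[n1:]]

    if stratified:
        if not ds.labelled_mask.all():
            raise DataError("stratified split requires labels on every patch")
        parts = [[], [], []]
        for c in np.unique(ds.labels):
            for k, chunk in enumerate(cut(np.flatnonzero(ds.labels == c))):
                parts[k].append(chunk)
        groups = [np.sort(np.concatenate(p)) if p else np.empty(0, int) for p in parts]
    else:
        groups = [np.sort(g) for g in cut(np.arange(n))]
    return tuple(ds.subset(g) for g in groups)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_KNOWN_BLOCKS = ("synthesis", "gan", "features", "labelling", "classifier", "interpretability")


@dataclass
class RunConfig:
    """Stage-keyed parameter blocks parsed from a YAML file.

    Unknown top-level keys are rejected; each block defaults to {} and is
    interpreted by the owning stage's config dataclass.
    """

    seed: int = 0
    out_dir: str = "runs"
    blocks: dict = field(default_factory=dict)

    def block(self, name: str) -> dict:
        if name not in _KNOWN_BLOCKS:
            raise ConfigurationError(f"unknown stage block {name!r}")
        return dict(self.blocks.get(name, {}))


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    known = set(_KNOWN_BLOCKS) | {"seed", "out_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys {sorted(unknown)}; expected {sorted(known)}")
    blocks = {k: v for k, v in raw.items() if k in _KNOWN_BLOCKS}
    return RunConfig(seed=int(raw.get("seed", 0)), out_dir=str(raw.get("out_dir", "runs")), blocks=blocks)
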