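"""Patch I/O: PNG round-trips, label rules, manifest, splitting, run config."""

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from semipatch.errors import ConfigurationError, DataError, FormatError
from semipatch.patchio import (
    UNLABELLED,
    PatchDataset,
    load_patch_dir,
    load_run_config,
    split_dataset,
    write_patch_dir,
)


def _quantized_dataset(n=9, size=16, seed=0):
    rng = np.random.default_rng(seed)
    images = rng.integers(0, 256, size=(n, size, size, 3)).astype(float) / 255.0
    labels = rng.integers(0, 2, n)
    return PatchDataset.from_images(images, labels=labels)


def test_write_then_load_round_trips_images_and_labels(tmp_path):
    ds = _quantized_dataset()
    write_patch_dir(ds, tmp_path)
    back = load_patch_dir(tmp_path, label_rule="subdir")
    # PNG is lossless, so 8-bit-quantized intensities survive bit-exactly
    from pathlib import Path

    back_by = {Path(pid).stem: i for i, pid in enumerate(back.ids)}
    for i, pid in enumerate(ds.ids):
        j = back_by[pid]
        assert np.array_equal(back.images[j], ds.images[i])
        assert back.labels[j] == ds.labels[i]
    assert (tmp_path / "manifest.tsv").exists()


def test_subdir_label_rule(tmp_path):
    (tmp_path / "class1").mkdir()
    img = Image.fromarray(np.zeros((8, 8, 3), dtype=np.uint8))
    for i in range(3):
        img.save(tmp_path / "class1" / f"p{i}.png")
    ds = load_patch_dir(tmp_path, label_rule="subdir")
    assert len(ds) == 3 and (ds.labels == 1).all()


def test_filename_token_label_rule(tmp_path):
    img = Image.fromarray(np.zeros((8, 8, 3), dtype=np.uint8))
    img.save(tmp_path / "8863_idx5_x51_y1251_class0.png")
    img.save(tmp_path / "8863_idx5_x52_y1251_class1.png")
    img.save(tmp_path / "no_token_here.png")
    ds = load_patch_dir(tmp_path, label_rule="filename_token")
    by_id = dict(zip(ds.ids, ds.labels))
    assert by_id["8863_idx5_x51_y1251_class0.png"] == 0
    assert by_id["8863_idx5_x52_y1251_class1.png"] == 1
    assert by_id["no_token_here.png"] == UNLABELLED


def test_empty_directory_loads_empty_dataset_with_warning(tmp_path, caplog):
    with caplog.at_level("WARNING", logger="semipatch.patchio"):
        ds = load_patch_dir(tmp_path)
    assert len(ds) == 0
    assert any("no PNG files" in r.message for r in caplog.records)


def test_mixed_dimensions_raise_format_error(tmp_path):
    Image.fromarray(np.zeros((8, 8, 3), dtype=np.uint8)).save(tmp_path / "a.png")
    Image.fromarray(np.zeros((9, 8, 3), dtype=np.uint8)).save(tmp_path / "b.png")
    with pytest.raises(FormatError, match="mixed image dimensions"):
        load_patch_dir(tmp_path)


def test_stratified_split_exact_proportions():
    ds = _quantized_dataset(n=100, seed=1)
    ds.labels[:50] = 0
    ds.labels[50:] = 1
    a, b, c = split_dataset(ds, (0.6, 0.2, 0.2), stratified=True, seed=0)
    assert (len(a), len(b), len(c)) == (60, 20, 20)
    for part, n1 in ((a, 30), (b, 10), (c, 10)):
        assert (part.labels == 1).sum() == n1


def test_degenerate_split_puts_everything_first():
    ds = _quantized_dataset(n=10)
    a, b, c = split_dataset(ds, (1.0, 0.0, 0.0), seed=0)
    assert len(a) == 10 and len(b) == 0 and len(c) == 0


def test_split_is_deterministic_under_seed():
    ds = _quantized_dataset(n=30)
    first = split_dataset(ds, (0.5, 0.3, 0.2), seed=9)
    second = split_dataset(ds, (0.5, 0.3, 0.2), seed=9)
    for p, q in zip(first, second):
        assert p.ids == q.ids


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    f0=st.floats(0.05, 0.9),
    f1=st.floats(0.05, 0.9),
    seed=st.integers(0, 100),
)
def test_split_disjoint_and_exhaustive(f0, f1, seed):
    if f0 + f1 >= 0.999:
        return
    ds = _quantized_dataset(n=37, seed=3)
    parts = split_dataset(ds, (f0, f1, 1.0 - f0 - f1), seed=seed)
    all_ids = [i for p in parts for i in p.ids]
    assert len(all_ids) == len(ds)
    assert set(all_ids) == set(ds.ids)


def test_bad_fraction_sum_rejected():
    ds = _quantized_dataset(n=10)
    with pytest.raises(ConfigurationError, match="sum to 1"):
        split_dataset(ds, (0.5, 0.3, 0.3))


def test_stratified_split_requires_labels():
    ds = _quantized_dataset(n=10)
    ds.labels[0] = UNLABELLED
    with pytest.raises(DataError):
        split_dataset(ds, (0.5, 0.25, 0.25), stratified=True)


def test_run_config_rejects_unknown_keys(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.dump({"seed": 3, "labelling": {"k_shuffles": 5}, "bogus": 1}))
    with pytest.raises(ConfigurationError, match="bogus"):
        load_run_config(path)
    path.write_text(yaml.dump({"seed": 3, "labelling": {"k_shuffles": 5}}))
    cfg = load_run_config(path)
    assert cfg.seed == 3
    assert cfg.block("labelling") == {"k_shuffles": 5}
    assert cfg.block("gan") == {}


def test_duplicate_ids_rejected():
    images = np.zeros((2, 8, 8, 3))
    with pytest.raises(FormatError, match="unique"):
        PatchDataset.from_images(images, labels=[0, 1], ids=["a", "a"])
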