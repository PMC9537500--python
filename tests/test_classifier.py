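"""The final CNN: architecture ladder, training behaviour, metrics, Wilcoxon."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semipatch.classifier import (
    CnnConfig,
    build_cnn,
    evaluate,
    load_cnn,
    predict_proba,
    report_from_counts,
    save_cnn,
    train_cnn,
    wilcoxon_compare,
)
from semipatch.errors import ArchitectureError, DataError, DegenerateError
from semipatch.patchio import PatchDataset
from semipatch.synthio import ClassParams, SynthConfig, generate_patch_dataset

FAST = dict(conv_kernels=8, fc_widths=(16, 2))


def test_feature_map_ladder_32_16_8_4(tiny_cnn):
    x = np.random.default_rng(0).random((5, 3, 32, 32))
    out = tiny_cnn.forward(x, record=True)
    assert tiny_cnn.activation("conv1").shape[2:] == (32, 32)
    assert tiny_cnn.activation("conv2").shape[2:] == (16, 16)
    assert tiny_cnn.activation("conv3").shape[2:] == (8, 8)
    assert tiny_cnn.activation("pool3").shape[2:] == (4, 4)
    assert out.shape == (5, 2)
    assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)


def test_default_architecture_has_64_kernels_per_conv():
    model = build_cnn(CnnConfig())
    for name in ("conv1", "conv2", "conv3"):
        conv = model.layers[model._index(name)]
        assert conv.params["w"].shape[0] == 64


def test_input_size_must_fit_the_pooling_ladder():
    with pytest.raises(ArchitectureError):
        CnnConfig(input_size=20)


def test_zero_epochs_returns_model_unchanged(small_patches):
    cfg = CnnConfig(epochs=0, seed=0, **FAST)
    model = build_cnn(cfg)
    before = model.state_dict()
    model2, trace = train_cnn(model, small_patches, cfg)
    assert trace == [] and model2 is model
    after = model.state_dict()
    assert all(np.array_equal(before[k], after[k]) for k in before)


def test_training_is_deterministic_under_seed(small_patches):
    cfg = CnnConfig(epochs=2, seed=3, **FAST)
    m1, t1 = train_cnn(build_cnn(cfg), small_patches, cfg)
    m2, t2 = train_cnn(build_cnn(cfg), small_patches, cfg)
    assert t1 == t2
    s1, s2 = m1.state_dict(), m2.state_dict()
    assert all(np.array_equal(s1[k], s2[k]) for k in s1)


def test_training_fits_a_separable_patch_set():
    """200 well-separated patches, 20 epochs: training accuracy >= 0.95 and a
    decreasing loss trace."""
    params = {
        0: ClassParams(blob_density=2.0, contrast=0.15),
        1: ClassParams(blob_density=10.0, contrast=0.55),
    }
    ds = generate_patch_dataset(SynthConfig(n_per_class=100, class_params=params, seed=21))
    cfg = CnnConfig(conv_kernels=16, fc_widths=(64, 2), epochs=20, seed=0)
    model, trace = train_cnn(build_cnn(cfg), ds, cfg)
    assert trace[-1] < trace[0]
    report = evaluate(model, ds)
    assert report.accuracy >= 0.95


def test_training_requires_both_classes():
    ds = PatchDataset.from_images(np.random.default_rng(0).random((10, 32, 32, 3)), labels=1)
    cfg = CnnConfig(epochs=1, **FAST)
    with pytest.raises(DataError):
        train_cnn(build_cnn(cfg), ds, cfg)


def test_checkpoint_round_trip(tmp_path, tiny_cnn, small_patches):
    save_cnn(tiny_cnn, str(tmp_path / "cnn"))
    back = load_cnn(str(tmp_path / "cnn"))
    a = predict_proba(tiny_cnn, small_patches.images[:4])
    b = predict_proba(back, small_patches.images[:4])
    assert np.allclose(a, b)


# -- metrics ----------------------------------------------------------------

def test_perfect_predictions_score_one():
    r = report_from_counts(tp=10, fp=0, fn=0, tn=10, auc=1.0)
    assert r.accuracy == r.balanced_accuracy == r.f_measure == r.auc == 1.0


def test_f_measure_from_hand_confusion():
    r = report_from_counts(tp=2, fp=1, fn=1, tn=6)
    assert r.f_measure == pytest.approx(2 * 2 / (2 * 2 + 1 + 1), abs=1e-4)
    assert r.f_measure == pytest.approx(0.6667, abs=1e-4)


def test_all_positive_predictor_has_chance_balanced_accuracy():
    # 30/70 split, everything predicted positive
    r = report_from_counts(tp=30, fp=70, fn=0, tn=0)
    assert r.balanced_accuracy == 0.5
    assert r.accuracy == 0.3


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    tp=st.integers(1, 40),
    fp=st.integers(0, 40),
    fn=st.integers(0, 40),
    tn=st.integers(1, 40),
)
def test_balanced_accuracy_identity(tp, fp, fn, tn):
    r = report_from_counts(tp, fp, fn, tn)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    assert r.balanced_accuracy == pytest.approx((sens + spec) / 2)


def test_single_class_test_set_has_undefined_auc(tiny_cnn, caplog):
    images = np.random.default_rng(0).random((6, 32, 32, 3))
    ds = PatchDataset.from_images(images, labels=1)
    with caplog.at_level("WARNING", logger="semipatch.classifier"):
        report = evaluate(tiny_cnn, ds)
    assert report.auc is None
    assert report.accuracy is not None


# -- Wilcoxon ---------------------------------------------------------------

def test_constant_shift_is_significant():
    rng = np.random.default_rng(0)
    b = rng.uniform(0.7, 0.9, 10)
    a = b + 0.1
    _, p = wilcoxon_compare(a, b)
    assert p < 0.01


def test_symmetric_differences_are_not_significant():
    rng = np.random.default_rng(1)
    b = rng.uniform(0.7, 0.9, 10)
    deltas = np.array([0.01, -0.01, 0.02, -0.02, 0.03, -0.03, 0.04, -0.04, 0.05, -0.05])
    a = b + rng.permutation(deltas)
    _, p = wilcoxon_compare(a, b)
    assert p > 0.05


def test_identical_samples_are_degenerate():
    x = np.linspace(0, 1, 8)
    with pytest.raises(DegenerateError):
        wilcoxon_compare(x, x.copy())


def test_too_few_pairs_rejected():
    with pytest.raises(DataError):
        wilcoxon_compare(np.ones(4), np.zeros(4))
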