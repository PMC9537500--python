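"""Co-training pseudo-labelling: the agreement rule, pool bookkeeping, oracles."""

import numpy as np
import pytest

from semipatch.cotrain import (
    LabellingConfig,
    _self_training_base,
    bootstrap_halves,
    cotrain,
    label_round,
    self_training_baseline,
    sweep_labelling,
)
from semipatch.errors import ConfigurationError, DataError


class FakeModel:
    """Stand-in classifier emitting fixed class-1 probabilities."""

    classes_ = [0, 1]

    def __init__(self, p1):
        self.p1 = float(p1)

    def predict_proba(self, X):
        p1 = np.full(len(X), self.p1)
        return np.column_stack([1 - p1, p1])


# -- configuration ----------------------------------------------------------

def test_labelling_config_validation():
    LabellingConfig()  # defaults are valid: k=5, threshold 5, cutoff 0.9
    with pytest.raises(ConfigurationError):
        LabellingConfig(k_shuffles=2, agreement_threshold=5)
    with pytest.raises(ConfigurationError):
        LabellingConfig(confidence_cutoff=0.5)
    with pytest.raises(ConfigurationError):
        LabellingConfig(base_learner="mlp")


# -- bootstrap halves -------------------------------------------------------

def test_k_shuffles_give_2k_subsets():
    rng = np.random.default_rng(0)
    X, y = rng.normal(size=(20, 3)), rng.integers(0, 2, 20)
    subsets = bootstrap_halves(X, y, X, y, k=5, seed=0)
    assert len(subsets) == 10


def test_half_split_sizes_with_four_rows_each():
    X = np.arange(8, dtype=float).reshape(4, 2)
    y = np.array([0, 1, 0, 1])
    subsets = bootstrap_halves(X, y, X + 100, y, k=1, seed=1)
    assert len(subsets) == 2
    for Xs, ys in subsets:
        assert len(Xs) == 4  # 2 train rows + 2 gan rows
        assert (Xs[:, 0] < 50).sum() == 2 and (Xs[:, 0] > 50).sum() == 2


def test_each_train_row_appears_in_exactly_k_subsets():
    rng = np.random.default_rng(2)
    X = np.arange(30, dtype=float).reshape(30, 1)  # identifiable rows
    y = rng.integers(0, 2, 30)
    k = 4
    subsets = bootstrap_halves(X, y, None, None, k=k, seed=3)
    counts = np.zeros(30, int)
    for Xs, _ in subsets:
        for val in Xs[:, 0]:
            counts[int(val)] += 1
    assert (counts == k).all()


def test_too_small_pools_rejected():
    X = np.zeros((1, 2))
    with pytest.raises(DataError):
        bootstrap_halves(X, np.zeros(1, int), None, None, k=1)
    good = np.zeros((4, 2))
    with pytest.raises(DataError):
        bootstrap_halves(good, np.zeros(4, int), X, np.zeros(1, int), k=1)


# -- the agreement rule -----------------------------------------------------

def test_unanimous_confident_models_label_the_row():
    models = [FakeModel(0.99)] * 10
    idx, labels, agree, rem = label_round(models, np.zeros((1, 2)), threshold=5, cutoff=0.9)
    assert list(idx) == [0] and list(labels) == [1] and list(agree) == [10]
    assert len(rem) == 0


def test_confident_conflict_leaves_row_unlabelled():
    models = [FakeModel(0.99)] * 5 + [FakeModel(0.01)] * 5
    idx, _, _, rem = label_round(models, np.zeros((1, 2)), threshold=5, cutoff=0.9)
    assert len(idx) == 0 and list(rem) == [0]


def test_below_threshold_agreement_leaves_row_unlabelled():
    models = [FakeModel(0.99)] * 4 + [FakeModel(0.6)] * 6
    idx, _, _, rem = label_round(models, np.zeros((1, 2)), threshold=5, cutoff=0.9)
    assert len(idx) == 0 and list(rem) == [0]


def test_cutoff_is_inclusive():
    models = [FakeModel(0.9)] * 5 + [FakeModel(0.6)] * 5
    idx, labels, _, _ = label_round(models, np.zeros((1, 2)), threshold=5, cutoff=0.9)
    assert list(idx) == [0] and list(labels) == [1]


def test_raising_threshold_never_labels_more_rows():
    rng = np.random.default_rng(4)
    models = [FakeModel(p) for p in rng.uniform(0, 1, 10)]
    X = np.zeros((6, 2))
    counts = [len(label_round(models, X, threshold=t, cutoff=0.8)[0]) for t in range(1, 11)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# -- the full loop ----------------------------------------------------------

def test_cotrain_reaches_bayes_level_accuracy_on_separated_gaussians(gaussian_scenario):
    s = gaussian_scenario
    res = cotrain(s["X_lab"], s["y_lab"], s["X_unlab"], LabellingConfig(seed=0))
    assert res.rounds[0]["n_models"] == 10
    acc = (res.pseudo_labels == s["y_unlab"][res.confident_idx]).mean()
    assert acc >= 0.95
    # against the Bayes rule itself the agreement is at least as high
    bayes_agree = (res.pseudo_labels == s["bayes"][res.confident_idx]).mean()
    assert bayes_agree >= 0.95


def test_cotrain_bookkeeping_invariants(gaussian_scenario):
    s = gaussian_scenario
    pick = np.r_[0:20, 50:70]  # 20 per class
    res = cotrain(s["X_lab"][pick], s["y_lab"][pick], s["X_unlab"][:200], LabellingConfig(seed=1))
    # monotone growth and exact conservation
    assert len(res.final_train_X) >= 40
    assert res.n_confident + len(res.noisy_idx) == 200
    assert len(res.rounds) <= 200
    assert set(res.confident_idx).isdisjoint(res.noisy_idx)
    assert res.n_confident == sum(r["n_newly_labelled"] for r in res.rounds)


def test_cotrain_requires_both_classes():
    X = np.random.default_rng(0).normal(size=(10, 2))
    with pytest.raises(DataError):
        cotrain(X, np.zeros(10, int), X, LabellingConfig())


def test_cotrain_empty_unlabelled_pool_is_a_fixpoint(gaussian_scenario):
    s = gaussian_scenario
    res = cotrain(s["X_lab"], s["y_lab"], np.empty((0, 2)), LabellingConfig())
    assert res.rounds == [] and res.n_confident == 0
    assert np.array_equal(res.final_train_X, s["X_lab"])


def test_gan_rows_never_enter_the_final_training_pool(gaussian_scenario):
    s = gaussian_scenario
    rng = np.random.default_rng(5)
    X_gan = s["X_lab"] + rng.normal(0, 0.1, s["X_lab"].shape)
    res = cotrain(s["X_lab"], s["y_lab"], s["X_unlab"][:300], LabellingConfig(seed=2), X_gan=X_gan, y_gan=s["y_lab"])
    assert "gan" not in set(res.final_train_provenance)
    assert len(res.final_train_X) == len(s["X_lab"]) + res.n_confident
    n_pseudo = (res.final_train_provenance == "pseudo").sum()
    assert n_pseudo == res.n_confident


def test_self_training_identity_on_empty_pool(gaussian_scenario):
    s = gaussian_scenario
    res = self_training_baseline(s["X_lab"], s["y_lab"], np.empty((0, 2)), base="naive_bayes")
    assert res.n_confident == 0
    assert np.array_equal(res.final_train_X, s["X_lab"])


def test_self_training_accuracy_on_separated_gaussians(gaussian_scenario):
    s = gaussian_scenario
    res = self_training_baseline(s["X_lab"], s["y_lab"], s["X_unlab"], base="svm", cutoff=0.9, seed=0)
    assert res.n_confident > 0
    acc = (res.pseudo_labels == s["y_unlab"][res.confident_idx]).mean()
    assert acc >= 0.90


def test_self_training_svm_base_configuration():
    svm = _self_training_base("svm", seed=0)
    assert svm.C == 1.0 and svm.kernel == "poly" and svm.degree == 1 and svm.tol == 1e-3
    dt = _self_training_base("decision_tree", seed=0)
    assert dt.min_samples_leaf == 2


def test_sweep_emits_one_row_per_setting(gaussian_scenario):
    s = gaussian_scenario
    frame = sweep_labelling(
        s["X_lab"],
        s["y_lab"],
        s["X_unlab"][:100],
        y_unlabelled_truth=s["y_unlab"][:100],
        ks=(1, 2),
        base_learners=("decision_tree", "naive_bayes"),
        seed=0,
    )
    assert len(frame) == 4
    assert set(frame["n_models"]) == {2, 4}
    assert (frame["n_pseudo_labelled"] + frame["n_noisy"] == 100).all()
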