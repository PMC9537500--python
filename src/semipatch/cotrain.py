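"""Bootstrapped-agreement co-training pseudo-labelling.

The labelled pool ``D_train`` and the GAN-generated pool ``D_GAN`` are each
shuffled into two equal halves ``k`` times (default 5); pairing the i-th
train half with the i-th GAN half gives 2k training subsets, on which 2k
base learners (gradient boosting by default) are fitted. An unlabelled row
receives a pseudo-label c when at least ``agreement_threshold`` learners
predict c with probability at least ``confidence_cutoff`` and no learner is
equally confident in the opposite class. Confident rows are appended to both
pools and the procedure repeats until a round labels nothing. Rows never
labelled are treated as noise, and GAN-provenance rows are excluded from the
final training pool: the grown pool is D_train united with D_conf only.

A single-classifier self-training baseline with the same stopping rule is
provided for comparison experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, DataError

logger = logging.getLogger("semipatch.cotrain")

__all__ = [
    "LabellingConfig",
    "LabellingResult",
    "make_base_learner",
    "bootstrap_halves",
    "label_round",
    "cotrain",
    "self_training_baseline",
    "sweep_labelling",
]

BASE_LEARNERS = ("gradient_boost", "random_forest", "decision_tree", "naive_bayes", "svm")


@dataclass
class LabellingConfig:
    k_shuffles: int = 5                 # 2k base learners; 5 -> 10 classifiers
    agreement_threshold: int = 5        # minimum number of confidently agreeing learners
    confidence_cutoff: float = 0.90     # per-learner probability needed to count as confident
    base_learner: str = "gradient_boost"
    max_rounds: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.k_shuffles < 1:
            raise ConfigurationError("k_shuffles must be >= 1")
        if not 1 <= self.agreement_threshold <= 2 * self.k_shuffles:
            raise ConfigurationError(
                f"agreement_threshold must be in [1, {2 * self.k_shuffles}], got {self.agreement_threshold}"
            )
        if not 0.5 < self.confidence_cutoff < 1.0:
            raise ConfigurationError("confidence_cutoff must lie in (0.5, 1)")
        if self.base_learner not in BASE_LEARNERS:
            raise ConfigurationError(f"base_learner must be one of {BASE_LEARNERS}")
        if self.max_rounds < 1:
            raise ConfigurationError("max_rounds must be >= 1")


@dataclass
class LabellingResult:
    """Outcome of a labelling run, with row-level provenance.

    ``confident_idx`` indexes the original unlabelled matrix; ``noisy_idx``
    is its never-labelled complement. ``final_train`` is D_train united with
    the pseudo-labelled confident rows — GAN rows never enter it.
    """

    confident_idx: np.ndarray
    pseudo_labels: np.ndarray
    round_assigned: np.ndarray
    n_agreeing: np.ndarray
    noisy_idx: np.ndarray
    final_train_X: np.ndarray
    final_train_y: np.ndarray
    final_train_provenance: np.ndarray
    rounds: list[dict] = field(default_factory=list)

    @property
    def n_confident(self) -> int:
        return len(self.confident_idx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": self.confident_idx,
                "pseudo_label": self.pseudo_labels,
                "round": self.round_assigned,
                "n_agreeing": self.n_agreeing,
            }
        )


def make_base_learner(name: str, seed: int):
    """Instantiate a base learner with the conventions used by the pipeline.

    Gradient boosting uses 100 trees of depth 3 at learning rate 0.1.
    """
    if name == "gradient_boost":
        return GradientBoostingClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "svm":
        return SVC(probability=True, random_state=seed)
    raise ConfigurationError(f"unknown base learner {name!r}")


def bootstrap_halves(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_gan: np.ndarray | None,
    y_gan: np.ndarray | None,
    k: int,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffle train and GAN pools into halves ``k`` times -> 2k subsets.

    Subset 2i is the union of the i-th shuffle's first train half and first
    GAN half; subset 2i+1 pairs the second halves. With no GAN pool the
    subsets are the train halves alone (logged as a warning).
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train)
    if len(X_train) < 2:
        raise DataError(f"need at least 2 training instances, got {len(X_train)}")
    have_gan = X_gan is not None and len(X_gan) > 0
    if X_gan is not None and 0 < len(X_gan) < 2:
        raise DataError(f"need at least 2 GAN instances, got {len(X_gan)}")
    if not have_gan:
        logger.warning("no GAN pool supplied; bootstrap halves use the train pool only")
    elif len(X_gan) != len(X_train):
        logger.warning(
            "GAN pool size %d differs from train pool size %d (equal sizes recommended)",
            len(X_gan),
            len(X_train),
        )
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(k):
        t_perm = rng.permutation(len(X_train))
        t_halves = (t_perm[: len(t_perm) // 2], t_perm[len(t_perm) // 2 :])
        if have_gan:
            g_perm = rng.permutation(len(X_gan))
            g_halves = (g_perm[: len(g_perm) // 2], g_perm[len(g_perm) // 2 :])
        for h in range(2):
            Xs = [X_train[t_halves[h]]]
            ys = [y_train[t_halves[h]]]
            if have_gan:
                Xs.append(np.asarray(X_gan)[g_halves[h]])
                ys.append(np.asarray(y_gan)[g_halves[h]])
            subsets.append((np.concatenate(Xs), np.concatenate(ys)))
    return subsets


def label_round(
    models: list,
    X_unlabelled: np.ndarray,
    threshold: int,
    cutoff: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Apply the agreement rule to one round of predictions.

    Returns (confident row indices, their labels, their agreeing-model
    counts, remaining row indices). A row is labelled c iff >= threshold
    models give class c probability >= cutoff and no model gives the
    opposite class probability >= cutoff; counting is inclusive at the
    cutoff. An empty confident set is a valid outcome.
    """
    if len(X_unlabelled) == 0:
        raise DataError("label_round requires a non-empty unlabelled pool")
    proba1 = np.stack([m.predict_proba(X_unlabelled)[:, list(m.classes_).index(1)] for m in models])
    conf1 = (proba1 >= cutoff).sum(axis=0)
    conf0 = ((1.0 - proba1) >= cutoff).sum(axis=0)
    take1 = (conf1 >= threshold) & (conf0 == 0)
    take0 = (conf0 >= threshold) & (conf1 == 0)
    confident = take1 | take0
    idx = np.flatnonzero(confident)
    labels = np.where(take1[idx], 1, 0)
    agree = np.where(take1[idx], conf1[idx], conf0[idx])
    remaining = np.flatnonzero(~confident)
    return idx, labels, agree, remaining


def cotrain(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_unlabelled: np.ndarray,
    config: LabellingConfig,
    X_gan: np.ndarray | None = None,
    y_gan: np.ndarray | None = None,
) -> LabellingResult:
    """Run the co-training loop to its fixpoint (or ``max_rounds``).

    Each round re-shuffles the grown pools into halves, fits 2k fresh base
    learners and applies the agreement rule to the still-unlabelled rows;
    confident rows join both the train-side and GAN-side pools with
    provenance 'pseudo'.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    X_unlabelled = np.asarray(X_unlabelled, dtype=float)
    if len(np.unique(y_train)) < 2:
        raise DataError("training pool must contain both classes")
    cur_tX, cur_ty = X_train, y_train
    cur_prov = np.array(["original"] * len(X_train), dtype=object)
    have_gan = X_gan is not None and len(X_gan) > 0
    cur_gX = np.asarray(X_gan, dtype=float) if have_gan else None
    cur_gy = np.asarray(y_gan) if have_gan else None

    remaining = np.arange(len(X_unlabelled))
    conf_idx: list[int] = []
    conf_labels: list[int] = []
    conf_round: list[int] = []
    conf_agree: list[int] = []
    rounds: list[dict] = []

    for rnd in range(1, config.max_rounds + 1):
        if len(remaining) == 0:
            break
        subsets = bootstrap_halves(cur_tX, cur_ty, cur_gX, cur_gy, config.k_shuffles, seed=config.seed + rnd)
        models = []
        for i, (Xs, ys) in enumerate(subsets):
            rs = int((config.seed + 7919 * rnd + 104729 * i) % (2**31))
            models.append(make_base_learner(config.base_learner, rs).fit(Xs, ys))
        idx, labels, agree, rem = label_round(
            models, X_unlabelled[remaining], config.agreement_threshold, config.confidence_cutoff
        )
        rounds.append(
            {
                "round": rnd,
                "n_models": len(models),
                "n_newly_labelled": int(len(idx)),
                "n_remaining": int(len(rem)),
            }
        )
        if len(idx) == 0:
            break
        new_global = remaining[idx]
        conf_idx.extend(new_global.tolist())
        conf_labels.extend(labels.tolist())
        conf_round.extend([rnd] * len(idx))
        conf_agree.extend(agree.tolist())
        new_X = X_unlabelled[new_global]
        cur_tX = np.concatenate([cur_tX, new_X])
        cur_ty = np.concatenate([cur_ty, labels])
        cur_prov = np.concatenate([cur_prov, np.array(["pseudo"] * len(idx), dtype=object)])
        if have_gan:
            cur_gX = np.concatenate([cur_gX, new_X])
            cur_gy = np.concatenate([cur_gy, labels])
        remaining = remaining[rem]

    return LabellingResult(
        confident_idx=np.array(conf_idx, dtype=int),
        pseudo_labels=np.array(conf_labels, dtype=int),
        round_assigned=np.array(conf_round, dtype=int),
        n_agreeing=np.array(conf_agree, dtype=int),
        noisy_idx=np.asarray(remaining, dtype=int),
        final_train_X=cur_tX,
        final_train_y=cur_ty,
        final_train_provenance=cur_prov,
        rounds=rounds,
    )


def _self_training_base(name: str, seed: int):
    """Base learners for the self-training baseline (classic configurations:
    pruned-style decision tree with >= 2 items per leaf; degree-1 polynomial
    SVM with C = 1 and logistic probability fitting; plain Gaussian NB)."""
    if name == "decision_tree":
        return DecisionTreeClassifier(min_samples_leaf=2, random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "svm":
        return SVC(C=1.0, kernel="poly", degree=1, tol=1e-3, probability=True, random_state=seed)
    raise ConfigurationError(f"self-training base must be decision_tree, naive_bayes or svm; got {name!r}")


def self_training_baseline(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_unlabelled: np.ndarray,
    base: str = "decision_tree",
    cutoff: float = 0.90,
    max_rounds: int = 20,
    seed: int = 0,
) -> LabellingResult:
    """Iterative single-classifier self-training with a confidence cutoff."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    X_unlabelled = np.asarray(X_unlabelled, dtype=float)
    if len(np.unique(y_train)) < 2:
        raise DataError("training pool must contain both classes")
    cur_X, cur_y = X_train, y_train
    cur_prov = np.array(["original"] * len(X_train), dtype=object)
    remaining = np.arange(len(X_unlabelled))
    conf_idx, conf_labels, conf_round, conf_agree = [], [], [], []
    rounds = []
    for rnd in range(1, max_rounds + 1):
        if len(remaining) == 0:
            break
        model = _self_training_base(base, int((seed + 7919 * rnd) % (2**31))).fit(cur_X, cur_y)
        proba = model.predict_proba(X_unlabelled[remaining])
        best = proba.max(axis=1)
        take = best >= cutoff
        rounds.append(
            {"round": rnd, "n_models": 1, "n_newly_labelled": int(take.sum()), "n_remaining": int((~take).sum())}
        )
        if not take.any():
            break
        new_global = remaining[take]
        labels = np.asarray(model.classes_)[proba[take].argmax(axis=1)]
        conf_idx.extend(new_global.tolist())
        conf_labels.extend(labels.tolist())
        conf_round.extend([rnd] * len(new_global))
        conf_agree.extend([1] * len(new_global))
        cur_X = np.concatenate([cur_X, X_unlabelled[new_global]])
        cur_y = np.concatenate([cur_y, labels])
        cur_prov = np.concatenate([cur_prov, np.array(["pseudo"] * len(new_global), dtype=object)])
        remaining = remaining[~take]
    return LabellingResult(
        confident_idx=np.array(conf_idx, dtype=int),
        pseudo_labels=np.array(conf_labels, dtype=int),
        round_assigned=np.array(conf_round, dtype=int),
        n_agreeing=np.array(conf_agree, dtype=int),
        noisy_idx=np.asarray(remaining, dtype=int),
        final_train_X=cur_X,
        final_train_y=cur_y,
        final_train_provenance=cur_prov,
        rounds=rounds,
    )


def sweep_labelling(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_unlabelled: np.ndarray,
    y_unlabelled_truth: np.ndarray | None = None,
    X_gan: np.ndarray | None = None,
    y_gan: np.ndarray | None = None,
    ks: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    base_learners: tuple[str, ...] = BASE_LEARNERS,
    confidence_cutoff: float = 0.90,
    seed: int = 0,
) -> pd.DataFrame:
    """Ablation harness: sweep the shuffle count k and the base learner.

    In the k sweep the agreement threshold is set to k (half the learners),
    matching how the number-of-bootstraps experiment is run. Returns one row
    per setting with the pseudo-label count and, when the ground truth of the
    unlabelled pool is supplied, the pseudo-label accuracy.
    """
    records = []
    for learner in base_learners:
        for k in ks:
            cfg = LabellingConfig(
                k_shuffles=k,
                agreement_threshold=k,
                confidence_cutoff=confidence_cutoff,
                base_learner=learner,
                seed=seed,
            )
            res = cotrain(X_train, y_train, X_unlabelled, cfg, X_gan=X_gan, y_gan=y_gan)
            rec = {
                "base_learner": learner,
                "k": k,
                "n_models": 2 * k,
                "n_pseudo_labelled": res.n_confident,
                "n_noisy": len(res.noisy_idx),
            }
            if y_unlabelled_truth is not None and res.n_confident:
                truth = np.asarray(y_unlabelled_truth)[res.confident_idx]
                rec["pseudo_label_accuracy"] = float((truth == res.pseudo_labels).mean())
            records.append(rec)
    return pd.DataFrame.from_records(records)
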