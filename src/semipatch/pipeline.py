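"""End-to-end orchestration of the five pipeline stages at desk scale.

``run_semisupervised_study`` reproduces the core experimental contrast: the
final CNN trained on the grown pool (labelled patches plus confidently
pseudo-labelled ones) versus the identical CNN trained on the small labelled
pool alone, on synthetic two-class patches with a known ground truth for
every unlabelled row. Feature extraction for the labelling stage follows the
pipeline convention — VGG-16 GAP concatenation, standardised on the labelled
rows — followed by a PCA reduction that keeps the classical base learners
fast on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment_gan import GanConfig, sample_synthetic, train_dcgan
from .classifier import CnnConfig, EvalReport, build_cnn, evaluate, train_cnn
from .cotrain import LabellingConfig, LabellingResult, cotrain
from .features import VGG16Backbone, pca_features, standardize_features, vgg_gap_features
from .patchio import PatchDataset, split_dataset
from .synthio import SynthConfig, generate_patch_dataset

__all__ = ["StudyConfig", "StudyOutcome", "run_semisupervised_study"]


@dataclass
class StudyConfig:
    """Desk-scale study: 10% of the training pool labelled, the rest unlabelled."""

    n_labelled_per_class: int = 20
    n_unlabelled_per_class: int = 180
    n_test_per_class: int = 100
    pca_components: int = 50
    use_gan: bool = False
    gan_samples_per_class: int = 0
    seed: int = 0

    @property
    def labelled_fraction(self) -> float:
        pool = self.n_labelled_per_class + self.n_unlabelled_per_class
        return self.n_labelled_per_class / pool


@dataclass
class StudyOutcome:
    semi: EvalReport
    baseline: EvalReport
    labelling: LabellingResult
    pseudo_label_accuracy: float
    n_confident: int
    n_labelled: int
    n_unlabelled: int


def run_semisupervised_study(
    study: StudyConfig,
    cnn_config: CnnConfig | None = None,
    labelling_config: LabellingConfig | None = None,
    gan_config: GanConfig | None = None,
    synth_config: SynthConfig | None = None,
) -> StudyOutcome:
    seed = study.seed
    per_class = study.n_labelled_per_class + study.n_unlabelled_per_class + study.n_test_per_class
    synth = synth_config or SynthConfig(n_per_class=per_class, seed=seed)
    full = generate_patch_dataset(synth)
    total = len(full)
    fracs = (
        2 * study.n_labelled_per_class / total,
        2 * study.n_unlabelled_per_class / total,
        2 * study.n_test_per_class / total,
    )
    labelled, unlab, test = split_dataset(full, fracs, stratified=True, seed=seed)
    truth_unlab = unlab.labels.copy()  # generator ground truth, hidden from the labeller

    gan_ds = None
    if study.use_gan and study.gan_samples_per_class > 0:
        gcfg = gan_config or GanConfig(seed=seed)
        parts = []
        for label in (0, 1):
            state = train_dcgan(labelled, label, gcfg)
            parts.append(sample_synthetic(state, study.gan_samples_per_class, seed=seed + label))
        gan_ds = PatchDataset.concatenate(parts)

    # features: VGG-GAP at native size, standardised on labelled rows, PCA-reduced
    backbone = VGG16Backbone(seed=0)
    stack = [labelled, unlab] + ([gan_ds] if gan_ds is not None else [])
    feats = [vgg_gap_features(ds, backbone=backbone, resize=None) for ds in stack]
    feats = standardize_features(*feats)
    all_fm = feats[0]
    pooled = np.concatenate([f.vectors for f in feats])
    from .features import FeatureMatrix

    pca_fit = pca_features(
        FeatureMatrix(pooled, "vgg_gap", [f"row{i}" for i in range(len(pooled))]),
        n_components=min(study.pca_components, *pooled.shape),
        seed=seed,
    )
    model = pca_fit.meta["model"]
    X_lab = model.transform(feats[0].vectors)
    X_unlab = model.transform(feats[1].vectors)
    X_gan = model.transform(feats[2].vectors) if gan_ds is not None else None
    y_gan = gan_ds.labels if gan_ds is not None else None

    lcfg = labelling_config or LabellingConfig(seed=seed)
    result = cotrain(X_lab, labelled.labels, X_unlab, lcfg, X_gan=X_gan, y_gan=y_gan)
    if result.n_confident:
        pseudo_acc = float((truth_unlab[result.confident_idx] == result.pseudo_labels).mean())
    else:
        pseudo_acc = float("nan")

    # the final CNN sees raw patches: labelled + confidently pseudo-labelled
    pseudo_ds = unlab.subset(result.confident_idx) if result.n_confident else None
    if pseudo_ds is not None:
        pseudo_ds.labels[:] = result.pseudo_labels
        pseudo_ds.provenance[:] = "pseudo"
        semi_train = PatchDataset.concatenate([labelled, pseudo_ds])
    else:
        semi_train = labelled

    ccfg = cnn_config or CnnConfig(seed=seed)
    semi_model, _ = train_cnn(build_cnn(ccfg), semi_train, ccfg)
    base_model, _ = train_cnn(build_cnn(ccfg), labelled, ccfg)
    return StudyOutcome(
        semi=evaluate(semi_model, test),
        baseline=evaluate(base_model, test),
        labelling=result,
        pseudo_label_accuracy=pseudo_acc,
        n_confident=result.n_confident,
        n_labelled=len(labelled),
        n_unlabelled=len(unlab),
    )
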