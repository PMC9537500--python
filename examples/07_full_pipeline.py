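"""Run the whole semi-supervised study at desk scale.

10% of the training pool is labelled; the rest is pseudo-labelled by
co-training on VGG-GAP features, and the CNN trained on the grown pool is
compared with the same CNN trained on the labelled patches alone. The
balanced-accuracy gap is the benefit of the unlabelled data.
"""

from semipatch import CnnConfig
from semipatch.pipeline import StudyConfig, run_semisupervised_study

study = StudyConfig(n_labelled_per_class=20, n_unlabelled_per_class=180, n_test_per_class=100, seed=0)
cnn = CnnConfig(conv_kernels=16, epochs=20, fc_widths=(64, 2), seed=0)
out = run_semisupervised_study(study, cnn_config=cnn)

print(f"labelled pool: {out.n_labelled}, unlabelled pool: {out.n_unlabelled}")
print(f"confidently pseudo-labelled: {out.n_confident} "
      f"(accuracy vs generative truth: {out.pseudo_label_accuracy:.3f})")
print(f"balanced accuracy, labelled-only CNN: {out.baseline.balanced_accuracy:.3f}")
print(f"balanced accuracy, labelled + pseudo: {out.semi.balanced_accuracy:.3f}")
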