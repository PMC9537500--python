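"""Train the compact CNN on synthetic patches and evaluate it.

The network is the fixed ladder (feature maps 32 -> 16 -> 8 -> 4, three
64-kernel convolutions by default; a 16-kernel variant is used here for
speed) trained with SGD. The report prints accuracy, balanced accuracy
(mean of sensitivity and specificity), F-measure and rank-based AUC.
"""

from semipatch import CnnConfig, SynthConfig, build_cnn, evaluate, generate_patch_dataset, train_cnn
from semipatch.patchio import split_dataset

ds = generate_patch_dataset(SynthConfig(n_per_class=150, seed=0))
train, _, test = split_dataset(ds, (0.7, 0.0, 0.3), stratified=True, seed=0)

config = CnnConfig(conv_kernels=16, epochs=20, fc_widths=(64, 2), seed=0)
model, trace = train_cnn(build_cnn(config), train, config)
print(f"trained {config.epochs} epochs; loss {trace[0]:.3f} -> {trace[-1]:.3f}")

report = evaluate(model, test)
print(f"test accuracy          {report.accuracy:.3f}")
print(f"test balanced accuracy {report.balanced_accuracy:.3f}")
print(f"test F-measure         {report.f_measure:.3f}")
print(f"test AUC               {report.auc:.3f}")
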