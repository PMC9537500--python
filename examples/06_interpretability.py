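"""Explain a trained CNN globally with regression concept vectors.

Concept measures (here the three Haralick texture statistics) are computed
on nuclei-annotated concept patches; each concept's direction is fitted in
the last pooling layer's activation space, and the Br score summarises how
strongly the IDC membership moves along that direction over a test set.
The concept with the most positive (negative) influence is scaled to
+1 (-1).
"""

from semipatch import (
    CnnConfig,
    SynthConfig,
    build_cnn,
    generate_concept_dataset,
    generate_patch_dataset,
    global_interpretability,
    train_cnn,
)

train = generate_patch_dataset(SynthConfig(n_per_class=60, seed=0))
test = generate_patch_dataset(SynthConfig(n_per_class=40, seed=1))
config = CnnConfig(conv_kernels=16, epochs=15, fc_widths=(64, 2), seed=0)
model, _ = train_cnn(build_cnn(config), train, config)

concepts = generate_concept_dataset(SynthConfig(seed=2), 80)
report = global_interpretability(model, concepts, test.images, layer="pool3")
print(report.frame[["concept", "rho", "r2", "br_raw", "br_scaled", "t_p"]].round(4).to_string(index=False))
best = report.frame.loc[report.frame["br_scaled"].idxmax(), "concept"]
print(f"\nmost positively relevant concept at the last pooling layer: {best}")
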