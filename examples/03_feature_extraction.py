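"""Extract VGG-GAP features and compare with PCA and LDA reductions.

The GAP concatenation over the four designated VGG-16 layers is always 1408
numbers per patch regardless of patch size; LDA collapses binary-labelled
data to a single dimension (number of classes minus one).
"""

from semipatch import SynthConfig, generate_patch_dataset, lda_features, pca_features, vgg_gap_features
from semipatch.features import VGG16Backbone, standardize_features

ds = generate_patch_dataset(SynthConfig(n_per_class=40, seed=0))
backbone = VGG16Backbone(seed=0)  # random init; pass weights_npz= for pretrained weights
fm = vgg_gap_features(ds, backbone=backbone, resize=None)
print(f"vgg_gap: {len(fm)} patches x {fm.dim} features")

[fm_std] = standardize_features(fm)
reduced = pca_features(fm_std, n_components=50, seed=0)
evr = reduced.meta["explained_variance_ratio"]
print(f"pca:     dim {reduced.dim}, top-5 explained variance {evr[:5].round(3)}")

proj = lda_features(fm_std, ds.labels, n_components_requested=50)
print(f"lda:     requested 50, got dim {proj.dim} (binary labels -> classes - 1)")
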