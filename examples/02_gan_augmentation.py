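"""Train a small per-class DCGAN and sample synthetic patches.

The trace printed each 10th epoch is the mean absolute difference between a
fixed-noise generated batch's mean image and the real mean image — it should
drift downward as the generator locks onto the class appearance.
"""

from semipatch import GanConfig, SynthConfig, generate_patch_dataset, sample_synthetic, train_dcgan

ds = generate_patch_dataset(SynthConfig(patch_size=32, n_per_class=32, seed=0))
config = GanConfig(generator_filters=(64, 32, 16, 8), epochs=40, learning_rate=1e-2, seed=0)
state = train_dcgan(ds, target_label=1, config=config)
for i in range(0, config.epochs, 10):
    print(f"epoch {i + 1:3d}: d_loss={state.loss_trace['d_loss'][i]:.3f} "
          f"g_loss={state.loss_trace['g_loss'][i]:.3f} "
          f"mean-image error={state.loss_trace['mean_abs_err'][i]:.3f}")

synthetic = sample_synthetic(state, n=50, seed=1)
print(f"sampled {len(synthetic)} patches, provenance={synthetic.provenance[0]}, "
      f"label={synthetic.labels[0]}, intensity range "
      f"[{synthetic.images.min():.2f}, {synthetic.images.max():.2f}]")
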