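"""Per-class DCGAN augmentation of the labelled pool.

One generator/discriminator pair is trained per class label. The generator
projects a 100-dimensional uniform noise vector through a fully connected
layer into four successively wider feature stages of 256, 128, 64 and 32
channels (5x5 kernels, stride-2 transposed convolutions, ReLU everywhere
except the tanh output, batch normalisation on every layer but the last).
The discriminator mirrors that capacity with four stride-2 convolutions of
32, 64, 128 and 256 filters and LeakyReLU activations. Both are trained
with SGD on the binary cross-entropy GAN objective; patches are scaled to
[-1, 1] for training and de-scaled to [0, 1] on sampling.

Because the DCGAN is trained separately per class, the label is constant
within each training run; an optional flag appends a constant label channel
to the discriminator input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError, DivergenceError
from .nn import (
    SGD,
    BatchNorm,
    Conv2d,
    ConvTranspose2d,
    Dense,
    Flatten,
    LeakyReLU,
    ReLU,
    Reshape,
    Sequential,
    Sigmoid,
    Tanh,
    bce_loss,
)
from .patchio import PatchDataset

logger = logging.getLogger("semipatch.augment_gan")

__all__ = ["GanConfig", "GeneratorState", "build_generator", "build_discriminator", "train_dcgan", "sample_synthetic"]


@dataclass
class GanConfig:
    noise_dim: int = 100
    generator_filters: tuple[int, int, int, int] = (256, 128, 64, 32)
    kernel: int = 5
    epochs: int = 50            # desk-scale default; the full-scale setting is 1200 epochs
    batch_size: int = 16
    learning_rate: float = 3e-4
    momentum: float = 0.0       # SGD momentum (0 unless configured)
    label_channel: bool = False
    discriminator_batchnorm: bool = False  # batch stats of low-diversity real batches degenerate
    seed: int = 0

    def __post_init__(self):
        if self.noise_dim < 1:
            raise ConfigurationError("noise_dim must be >= 1")
        if len(self.generator_filters) != 4 or any(f < 1 for f in self.generator_filters):
            raise ConfigurationError("generator_filters must be four positive widths")
        if self.kernel < 2:
            raise ConfigurationError("kernel must be >= 2")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigurationError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class GeneratorState:
    """A trained generator with its class label and training diagnostics."""

    generator: Sequential
    config: GanConfig
    class_label: int
    patch_shape: tuple[int, int, int]  # (H, W, C)
    loss_trace: dict[str, list[float]] = field(default_factory=dict)


def build_generator(config: GanConfig, patch_size: int, rng: np.random.Generator) -> Sequential:
    """Noise vector -> (3, P, P) tanh image; P must be divisible by 16."""
    if patch_size % 16 != 0:
        raise ConfigurationError(f"patch size must be divisible by 16, got {patch_size}")
    f1, f2, f3, f4 = config.generator_filters
    s0 = patch_size // 16
    k = config.kernel
    return Sequential(
        [
            Dense(config.noise_dim, f1 * s0 * s0, rng, name="project"),
            Reshape((f1, s0, s0), name="reshape"),
            BatchNorm(f1, name="g_bn1"),
            ReLU(name="g_relu1"),
            ConvTranspose2d(f1, f2, k, rng, stride=2, name="g_tconv1"),
            BatchNorm(f2, name="g_bn2"),
            ReLU(name="g_relu2"),
            ConvTranspose2d(f2, f3, k, rng, stride=2, name="g_tconv2"),
            BatchNorm(f3, name="g_bn3"),
            ReLU(name="g_relu3"),
            ConvTranspose2d(f3, f4, k, rng, stride=2, name="g_tconv3"),
            BatchNorm(f4, name="g_bn4"),
            ReLU(name="g_relu4"),
            ConvTranspose2d(f4, 3, k, rng, stride=2, name="g_out"),
            Tanh(name="g_tanh"),
        ],
        name="generator",
    )


def build_discriminator(config: GanConfig, patch_size: int, rng: np.random.Generator) -> Sequential:
    """Image -> real/fake probability; capacity mirrors the generator."""
    d_filters = tuple(reversed(config.generator_filters))
    k = config.kernel
    pad = k // 2
    c_in = 3 + (1 if config.label_channel else 0)
    layers = []
    size = patch_size
    for i, f in enumerate(d_filters, start=1):
        layers.append(Conv2d(c_in, f, k, rng, stride=2, padding=pad, name=f"d_conv{i}"))
        if config.discriminator_batchnorm and i > 1:
            layers.append(BatchNorm(f, name=f"d_bn{i}"))
        layers.append(LeakyReLU(0.2, name=f"d_lrelu{i}"))
        c_in = f
        size = (size + 2 * pad - k) // 2 + 1
    layers += [
        Flatten(name="d_flatten"),
        Dense(c_in * size * size, 1, rng, name="d_out"),
        Sigmoid(name="d_sigmoid"),
    ]
    return Sequential(layers, name="discriminator")


def _with_label_channel(x: np.ndarray, label: int, enabled: bool) -> np.ndarray:
    if not enabled:
        return x
    chan = np.full((x.shape[0], 1) + x.shape[2:], float(label))
    return np.concatenate([x, chan], axis=1)


def train_dcgan(ds: PatchDataset, target_label: int, config: GanConfig) -> GeneratorState:
    """Train a DCGAN on the patches of one class and return the generator.

    Per epoch the trace records the discriminator loss, the generator loss
    and the mean absolute difference between a fixed-noise generated batch's
    mean image and the real mean image (a cheap convergence diagnostic).
    """
    mask = ds.labels == target_label
    X = ds.images[mask]
    if len(X) < config.batch_size:
        raise DataError(
            f"need at least batch_size={config.batch_size} patches of class {target_label}, got {len(X)}"
        )
    patch_size = X.shape[1]
    if X.shape[1] != X.shape[2]:
        raise DataError("DCGAN expects square patches")
    rng = np.random.default_rng(config.seed)
    gen = build_generator(config, patch_size, rng)
    disc = build_discriminator(config, patch_size, rng)
    g_opt = SGD(gen, lr=config.learning_rate, momentum=config.momentum)
    d_opt = SGD(disc, lr=config.learning_rate, momentum=config.momentum)

    real_all = np.ascontiguousarray(X.transpose(0, 3, 1, 2)) * 2.0 - 1.0  # [-1, 1]
    real_mean_img = real_all.mean(axis=0)
    fixed_noise = rng.uniform(-1, 1, size=(config.batch_size, config.noise_dim))
    trace: dict[str, list[float]] = {"d_loss": [], "g_loss": [], "mean_abs_err": []}

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(real_all))
        d_losses, g_losses = [], []
        for start in range(0, len(real_all), config.batch_size):
            idx = order[start : start + config.batch_size]
            real = real_all[idx]
            m = len(real)
            noise = rng.uniform(-1, 1, size=(m, config.noise_dim))
            fake = gen.forward(noise, training=True)

            # discriminator step: real -> 1, fake (held constant) -> 0
            p_real = disc.forward(_with_label_channel(real, target_label, config.label_channel), training=True)
            loss_real, grad = bce_loss(p_real[:, 0], np.ones(m))
            disc.backward(grad[:, None])
            d_opt.step()
            p_fake = disc.forward(
                _with_label_channel(fake, target_label, config.label_channel), training=True
            )
            loss_fake, grad = bce_loss(p_fake[:, 0], np.zeros(m))
            disc.backward(grad[:, None])
            d_opt.step()
            d_loss = loss_real + loss_fake

            # generator step: fool the discriminator (fake -> 1)
            fake = gen.forward(noise, training=True)
            p = disc.forward(_with_label_channel(fake, target_label, config.label_channel), training=True)
            g_loss, grad = bce_loss(p[:, 0], np.ones(m))
            dfake = disc.backward(grad[:, None])
            if config.label_channel:
                dfake = dfake[:, :3]
            gen.backward(dfake)
            g_opt.step()

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise DivergenceError(f"non-finite GAN loss at epoch {epoch}", epoch=epoch)
            d_losses.append(d_loss)
            g_losses.append(g_loss)
        sample = gen.forward(fixed_noise, training=False)
        trace["d_loss"].append(float(np.mean(d_losses)))
        trace["g_loss"].append(float(np.mean(g_losses)))
        trace["mean_abs_err"].append(float(np.abs(sample.mean(axis=0) - real_mean_img).mean()))

    return GeneratorState(
        generator=gen,
        config=config,
        class_label=int(target_label),
        patch_shape=(patch_size, patch_size, 3),
        loss_trace=trace,
    )


def sample_synthetic(gen: GeneratorState, n: int, seed: int = 0) -> PatchDataset:
    """Draw ``n`` synthetic patches; values de-scaled to [0, 1], provenance 'gan'."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    batches = []
    for start in range(0, n, 256):
        m = min(256, n - start)
        noise = rng.uniform(-1, 1, size=(m, gen.config.noise_dim))
        out = gen.generator.forward(noise, training=False)
        batches.append((out.transpose(0, 2, 3, 1) + 1.0) / 2.0)
    images = np.clip(np.concatenate(batches), 0.0, 1.0)
    return PatchDataset.from_images(
        images,
        labels=np.full(n, gen.class_label),
        provenance="gan",
        ids=[f"gan_class{gen.class_label}_{seed}_{i:06d}" for i in range(n)],
    )


def save_generator(state: GeneratorState, path: str) -> None:
    """Generator checkpoint: .npz parameters plus a JSON sidecar (config, trace)."""
    import dataclasses
    import json

    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    np.savez_compressed(base + ".npz", **state.generator.state_dict())
    with open(base + ".json", "w") as fh:
        json.dump(
            {
                "config": dataclasses.asdict(state.config),
                "class_label": state.class_label,
                "patch_shape": list(state.patch_shape),
                "loss_trace": state.loss_trace,
            },
            fh,
            indent=1,
        )


def load_generator(path: str) -> GeneratorState:
    import json

    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        meta = json.load(fh)
    cfg = meta["config"]
    cfg["generator_filters"] = tuple(cfg["generator_filters"])
    config = GanConfig(**cfg)
    patch_shape = tuple(meta["patch_shape"])
    gen = build_generator(config, patch_shape[0], np.random.default_rng(config.seed))
    with np.load(base + ".npz") as arch:
        gen.load_state_dict(dict(arch))
    return GeneratorState(
        generator=gen,
        config=config,
        class_label=int(meta["class_label"]),
        patch_shape=patch_shape,  # type: ignore[arg-type]
        loss_trace=meta["loss_trace"],
    )
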