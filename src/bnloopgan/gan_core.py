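"""Generator, patch critic and classifier for connectivity matrices.

The three networks are declared as layer tables (kernel / stride /
padding / channels / activation) and compiled onto the NumPy autodiff
stack.  At the full 164-region geometry the tables reproduce the
published architecture exactly: a seven-layer transposed-convolution
generator mapping a length-100·n latent vector to a 164×164×n matrix in
[0, 1], a six-layer convolutional critic ending in an unbounded 5×5×n
patch map (PatchGAN-style local realness scores), and a six-layer
classifier ending in a 2×2×1 map whose mean is the class logit.

Training follows the Wasserstein-GAN-with-gradient-penalty objective:

    L_D = E[D(x_fake)] - E[D(x_real)]
          + lambda * E[(||grad_xhat D(xhat)||_2 - 1)^2]

with xhat drawn uniformly on the segment between paired real and fake
samples, and L_G = -E[D(x_fake)].  Class conditioning appends a one-hot
label to the generator's latent vector and a constant label channel to
the critic's input.

A reduced geometry (any spatial size 5·2^m with a channel-width factor)
is provided for desk-scale experiments; it is not the published
architecture and is labeled as such wherever it appears.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import autodiff as ad
from .nn.autodiff import Tensor

logger = logging.getLogger(__name__)

PAPER_IMAGE_SIZE = 164
LATENT_PER_MODALITY = 100
N_CLASSES = 2


@dataclass(frozen=True)
class LayerSpec:
    kind: str                 # 'conv' | 'transposed_conv'
    kernel: int
    stride: int
    padding: int
    out_channels: int
    activation: str = "none"  # 'relu' | 'leaky_relu' | 'sigmoid' | 'none'
    normalization: str = "none"   # 'batch' | 'instance' | 'none'
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("conv", "transposed_conv"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kernel < 1 or self.stride < 1 or self.padding < 0:
            raise ValueError(f"invalid geometry in layer {self.name or self.kind}")
        if self.out_channels < 1:
            raise ValueError("out_channels must be positive")


@dataclass(frozen=True)
class NetworkSpec:
    role: str                 # 'generator' | 'discriminator' | 'classifier'
    layers: tuple[LayerSpec, ...]
    n_modalities: int
    input_shape: tuple[int, int, int]     # (height, width, channels)

    def shape_trace(self) -> list[tuple[int, int, int]]:
        """(H, W, C) after each layer, starting from the input shape."""
        trace = [self.input_shape]
        shape = self.input_shape
        for layer in self.layers:
            shape = output_shape(layer, shape)
            trace.append(shape)
        return trace


def output_shape(layer: LayerSpec, in_shape: tuple[int, int, int]
                 ) -> tuple[int, int, int]:
    """Spatial/channel shape produced by one layer.

    conv:            out = floor((in + 2p - k) / s) + 1
    transposed conv: out = (in - 1) * s - 2p + k
    """
    h, w, _ = in_shape
    if layer.kind == "conv":
        oh = (h + 2 * layer.padding - layer.kernel) // layer.stride + 1
        ow = (w + 2 * layer.padding - layer.kernel) // layer.stride + 1
    else:
        oh = (h - 1) * layer.stride - 2 * layer.padding + layer.kernel
        ow = (w - 1) * layer.stride - 2 * layer.padding + layer.kernel
    if oh <= 0 or ow <= 0:
        raise ValueError(
            f"layer {layer.name or layer.kind} yields non-positive size "
            f"{oh}x{ow} from input {h}x{w}")
    return (oh, ow, layer.out_channels)


def _scaled(c: int, width: float) -> int:
    return max(1, int(round(c * width)))


def _check_n(n: int):
    if n < 1:
        raise ValueError("number of modalities must be >= 1")


def _desk_levels(image_size: int) -> int:
    m = image_size / 5.0
    levels = int(round(math.log2(m))) if m > 0 else -1
    if levels < 1 or 5 * 2 ** levels != image_size:
        raise ValueError(
            f"reduced geometry needs a spatial size of 5*2^m, got {image_size}")
    return levels


def build_generator(n: int, image_size: int = PAPER_IMAGE_SIZE,
                    width: float = 1.0, conditional: bool = False
                    ) -> NetworkSpec:
    """Generator spec: latent (1×1 map, 100·n channels) -> size×size×n."""
    _check_n(n)
    latent = LATENT_PER_MODALITY * n + (N_CLASSES if conditional else 0)
    if image_size == PAPER_IMAGE_SIZE:
        rows = [(4, 1, 0, 512), (4, 2, 1, 256), (4, 2, 1, 128), (4, 2, 1, 64),
                (12, 1, 1, 32), (4, 2, 1, 16)]
    else:
        levels = _desk_levels(image_size)
        chans = [16 * 2 ** (levels - 1 - i) for i in range(levels)]
        rows = [(5, 1, 0, chans[0])] + [(4, 2, 1, c) for c in chans[1:]]
    layers = [LayerSpec("transposed_conv", k, s, p, _scaled(c, width),
                        "relu", "none" if i == 0 else "batch",
                        name=f"ConvT {i + 1}")
              for i, (k, s, p, c) in enumerate(rows)]
    layers.append(LayerSpec("transposed_conv", 4, 2, 1, n, "sigmoid", "none",
                            name=f"ConvT {len(rows) + 1}"))
    return NetworkSpec("generator", tuple(layers), n, (1, 1, latent))


def _critic_like(role: str, n: int, image_size: int, width: float,
                 conditional: bool, final: tuple, norm: str) -> NetworkSpec:
    _check_n(n)
    in_channels = n + (1 if conditional and role == "discriminator" else 0)
    if image_size == PAPER_IMAGE_SIZE:
        rows = [(4, 2, 1, 16), (4, 2, 1, 64), (10, 1, 0, 128),
                (4, 2, 1, 256), (4, 2, 1, 512)]
    else:
        levels = _desk_levels(image_size)
        rows = [(4, 2, 1, 16 * 2 ** i) for i in range(levels)]
    start = 1 if role == "discriminator" else 7
    layers = [LayerSpec("conv", k, s, p, _scaled(c, width), "leaky_relu",
                        "none" if i == 0 else norm,
                        name=f"Conv {start + i}")
              for i, (k, s, p, c) in enumerate(rows)]
    fk, fs, fp, fc = final
    layers.append(LayerSpec("conv", fk, fs, fp, fc, "none", "none",
                            name=f"Conv {start + len(rows)}"))
    return NetworkSpec(role, tuple(layers), n, (image_size, image_size, in_channels))


def build_discriminator(n: int, image_size: int = PAPER_IMAGE_SIZE,
                        width: float = 1.0, conditional: bool = False,
                        norm: str = "batch") -> NetworkSpec:
    """Patch critic spec: size×size×n (+label channel) -> 5×5×n patch map."""
    final = (4, 1, 0, n) if image_size == PAPER_IMAGE_SIZE else (3, 1, 1, n)
    return _critic_like("discriminator", n, image_size, width, conditional,
                        final, norm)


def build_classifier(n: int, image_size: int = PAPER_IMAGE_SIZE,
                     width: float = 1.0, norm: str = "batch") -> NetworkSpec:
    """Classifier spec: size×size×n -> 2×2×1 map (mean = class logit)."""
    final = (8, 2, 1, 1) if image_size == PAPER_IMAGE_SIZE else (4, 1, 0, 1)
    return _critic_like("classifier", n, image_size, width, False, final, norm)


# ---------------------------------------------------------------------
# compilation onto the autodiff stack

_ACTIVATIONS = {"relu": nn.ReLU, "leaky_relu": lambda: nn.LeakyReLU(0.2),
                "sigmoid": nn.Sigmoid}


class Network(nn.Module):
    """A NetworkSpec compiled to runnable layers."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        mods: list[nn.Module] = []
        in_c = spec.input_shape[2]
        for layer in spec.layers:
            cls = nn.Conv2d if layer.kind == "conv" else nn.ConvTranspose2d
            mods.append(cls(in_c, layer.out_channels, layer.kernel,
                            layer.stride, layer.padding, rng=rng))
            if layer.normalization == "batch":
                mods.append(nn.BatchNorm2d(layer.out_channels))
            elif layer.normalization == "instance":
                mods.append(nn.InstanceNorm2d(layer.out_channels))
            if layer.activation != "none":
                mods.append(_ACTIVATIONS[layer.activation]())
            in_c = layer.out_channels
        self.net = self.add_child("net", nn.Sequential(*mods))

    def forward(self, x: Tensor) -> Tensor:
        if self.spec.role == "generator" and x.ndim == 2:
            x = ad.reshape(x, (x.shape[0], x.shape[1], 1, 1))
        return self.net(x)


def condition_inputs(x, labels):
    """Attach class information to a generator latent or a critic input.

    Rank-2 input (N, latent): append a one-hot label pair.  Rank-4 input
    (N, C, H, W): append one constant-valued channel equal to the label.
    """
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    xd = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)
    if xd.ndim == 2:
        onehot = np.eye(N_CLASSES)[labels.astype(int)]
        out = np.concatenate([xd, onehot], axis=1)
        return Tensor(out) if isinstance(x, Tensor) else out
    if xd.ndim == 4:
        chan = np.broadcast_to(
            labels.astype(float)[:, None, None, None],
            (xd.shape[0], 1, xd.shape[2], xd.shape[3])).copy()
        if isinstance(x, Tensor):
            return ad.concat([x, Tensor(chan)], axis=1)
        return np.concatenate([xd, chan], axis=1)
    raise ValueError("expected a rank-2 latent or rank-4 image input")


def critic_scores(critic: Network, x: Tensor, labels=None,
                  conditional: bool = False) -> Tensor:
    """Per-sample critic scalar: mean over the patch map."""
    if conditional:
        x = condition_inputs(x, labels)
    patch = critic(x)
    return ad.mean(patch, axis=(1, 2, 3))


def gradient_penalty(real_batch, fake_batch, critic: Network,
                     rng: np.random.Generator, labels=None,
                     conditional: bool = False) -> Tensor:
    """E[(||grad_xhat D(xhat)||_2 - 1)^2] on real/fake interpolates.

    xhat = eps*real + (1-eps)*fake with eps ~ U(0,1) per sample; the
    gradient is taken over every input coordinate of each sample,
    flowing through the per-sample patch-map mean.
    """
    real = np.asarray(real_batch, dtype=float)
    fake = np.asarray(fake_batch, dtype=float)
    if real.shape != fake.shape:
        raise ValueError(f"batch shape mismatch: {real.shape} vs {fake.shape}")
    eps = rng.uniform(size=(real.shape[0], 1, 1, 1))
    xhat = Tensor(eps * real + (1 - eps) * fake, requires_grad=True)
    scores = critic_scores(critic, xhat, labels, conditional)
    g = ad.grad(ad.sum_(scores), [xhat])[0]
    g2 = ad.reshape(g * g, (real.shape[0], int(np.prod(real.shape[1:]))))
    norms = ad.sqrt(ad.sum_(g2, axis=1) + Tensor(1e-12))
    return ad.mean((norms - Tensor(1.0)) ** 2)


def discriminator_loss(d_real: Tensor, d_fake: Tensor, gp, lambda_gp: float):
    """Critic objective: E[D(fake)] - E[D(real)] + lambda * penalty."""
    if lambda_gp < 0:
        raise ValueError("gradient-penalty coefficient must be non-negative")
    gp_t = gp if isinstance(gp, Tensor) else Tensor(float(gp))
    return ad.mean(d_fake) - ad.mean(d_real) + Tensor(float(lambda_gp)) * gp_t


def generator_loss(d_fake: Tensor):
    """Generator objective: -E[D(fake)]."""
    if d_fake.data.size == 0:
        raise ValueError("empty critic-score batch")
    return -ad.mean(d_fake)


def classifier_logit(class_map: Tensor) -> Tensor:
    """Scalar logit per sample: mean of the final 2×2 map."""
    return ad.mean(class_map, axis=(1, 2, 3))


def classifier_loss(logits: Tensor, labels) -> Tensor:
    """Binary cross-entropy with logits: mean softplus(z) - y*z."""
    y = np.asarray(labels, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    return ad.mean(ad.softplus(logits) - Tensor(y) * logits)


# ---------------------------------------------------------------------
# training

@dataclass
class TrainingConfig:
    """Hyperparameters of adversarial pre-training.

    The gradient-penalty coefficient defaults to 10 and the optimizer to
    Adam(1e-4, betas 0.5/0.9) with 5 critic steps per generator step —
    the standard WGAN-GP recipe.  ``critic_norm`` may be 'batch',
    'instance' or 'none'; batch statistics couple samples within a batch
    and so interact with the per-sample gradient penalty, hence the
    switch.
    """

    n_modalities: int = 2
    image_size: int = PAPER_IMAGE_SIZE
    width: float = 1.0
    lambda_gp: float = 10.0
    lr: float = 1e-4
    betas: tuple[float, float] = (0.5, 0.9)
    n_critic: int = 5
    epochs: int = 1
    batch_size: int = 16
    conditional: bool = True
    critic_norm: str = "batch"
    seed: int = 0

    def __post_init__(self):
        if self.lambda_gp <= 0:
            raise ValueError("lambda_gp must be positive")
        if self.n_critic < 1 or self.batch_size < 2 or self.epochs < 0:
            raise ValueError("invalid training configuration")


@dataclass
class GanBundle:
    """Pre-trained generator + critic with their config and training log."""

    generator: Network
    critic: Network
    config: TrainingConfig
    log: list[dict] = field(default_factory=list)

    @property
    def latent_dim(self) -> int:
        return LATENT_PER_MODALITY * self.config.n_modalities

    def sample(self, labels, rng: np.random.Generator) -> np.ndarray:
        """Generate fake matrices conditioned on ``labels`` (eval mode)."""
        labels = np.asarray(labels, dtype=int)
        z = rng.normal(size=(labels.size, self.latent_dim))
        if self.config.conditional:
            z = condition_inputs(z, labels)
        self.generator.eval()
        out = self.generator(Tensor(z)).data
        self.generator.train()
        return out


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple):
        x, y = dataset
        return np.asarray(x, dtype=float), np.asarray(y, dtype=int)
    x = np.stack([s.tensor.transpose(2, 0, 1) for s in dataset])
    y = np.array([s.label for s in dataset], dtype=int)
    return x, y


def pretrain_gan(dataset, config: TrainingConfig) -> GanBundle:
    """Alternating WGAN-GP training of the conditional generator/critic.

    ``dataset`` is either a list of multi-modal samples (values already
    scaled to [0, 1]) or an ``(X, y)`` pair with X in NCHW layout.  One
    generator update is taken per ``n_critic`` critic updates.  The run
    is deterministic given the config seed.
    """
    x, y = _as_arrays(dataset)
    n, c, h, _ = x.shape
    if c != config.n_modalities or h != config.image_size:
        raise ValueError(
            f"dataset shape {x.shape[1:]} does not match config "
            f"({config.n_modalities} modalities, size {config.image_size})")
    rng = np.random.default_rng(config.seed)
    g_spec = build_generator(config.n_modalities, config.image_size,
                             config.width, config.conditional)
    d_spec = build_discriminator(config.n_modalities, config.image_size,
                                 config.width, config.conditional,
                                 norm=config.critic_norm)
    gen = Network(g_spec, rng)
    critic = Network(d_spec, rng)
    opt_g = nn.Adam(gen.parameters(), lr=config.lr, betas=config.betas)
    opt_d = nn.Adam(critic.parameters(), lr=config.lr, betas=config.betas)
    bundle = GanBundle(gen, critic, config)

    bs = min(config.batch_size, n)
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for lo in range(0, n - bs + 1, bs):
            idx = order[lo:lo + bs]
            xb, yb = x[idx], y[idx]
            fake = bundle.sample(yb, rng)

            d_real = critic_scores(critic, Tensor(xb), yb, config.conditional)
            d_fake = critic_scores(critic, Tensor(fake), yb, config.conditional)
            gp = gradient_penalty(xb, fake, critic, rng, yb, config.conditional)
            l_d = discriminator_loss(d_real, d_fake, gp, config.lambda_gp)
            if not np.isfinite(l_d.data):
                raise RuntimeError(
                    f"non-finite critic loss at epoch {epoch}, step {step}")
            opt_d.step(ad.grad(l_d, critic.parameters()))

            l_g_val = np.nan
            if step % config.n_critic == config.n_critic - 1:
                z = rng.normal(size=(bs, bundle.latent_dim))
                if config.conditional:
                    z = condition_inputs(z, yb)
                fake_t = gen(Tensor(z, requires_grad=False))
                d_fake_g = critic_scores(critic, fake_t, yb, config.conditional)
                l_g = generator_loss(d_fake_g)
                if not np.isfinite(l_g.data):
                    raise RuntimeError(
                        f"non-finite generator loss at epoch {epoch}, step {step}")
                opt_g.step(ad.grad(l_g, gen.parameters()))
                l_g_val = float(l_g.data)

            bundle.log.append({"step": step, "epoch": epoch,
                               "L_D": float(l_d.data), "L_G": l_g_val,
                               "gp": float(gp.data)})
            step += 1
    logger.info("pre-trained GAN: %d steps on %d samples", step, n)
    return bundle


def gan_refresh_steps(bundle: GanBundle, x: np.ndarray, y: np.ndarray,
                      steps: int, rng: np.random.Generator):
    """A few extra adversarial updates (used by the loop's refresh flag)."""
    cfg = bundle.config
    opt_g = nn.Adam(bundle.generator.parameters(), lr=cfg.lr, betas=cfg.betas)
    opt_d = nn.Adam(bundle.critic.parameters(), lr=cfg.lr, betas=cfg.betas)
    bs = min(cfg.batch_size, x.shape[0])
    for _ in range(steps):
        idx = rng.permutation(x.shape[0])[:bs]
        xb, yb = x[idx], y[idx]
        fake = bundle.sample(yb, rng)
        d_real = critic_scores(bundle.critic, Tensor(xb), yb, cfg.conditional)
        d_fake = critic_scores(bundle.critic, Tensor(fake), yb, cfg.conditional)
        gp = gradient_penalty(xb, fake, bundle.critic, rng, yb, cfg.conditional)
        opt_d.step(ad.grad(discriminator_loss(d_real, d_fake, gp, cfg.lambda_gp),
                           bundle.critic.parameters()))
        z = rng.normal(size=(bs, bundle.latent_dim))
        if cfg.conditional:
            z = condition_inputs(z, yb)
        d_fake_g = critic_scores(bundle.critic, bundle.generator(Tensor(z)),
                                 yb, cfg.conditional)
        opt_g.step(ad.grad(generator_loss(d_fake_g),
                           bundle.generator.parameters()))
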