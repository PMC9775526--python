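"""Progressive 1D Wasserstein-divergence GAN for sleep-EEG epochs.

One independent generator/discriminator pair is trained per sleep stage on
mean-normalized 30 s epochs.  Training is progressive: the generator maps
a length-100 latent vector to a length-100 trace at stage 0, then grows by
appending blocks of three convolutional layers, each stage linearly
upsampling the previous features towards the 3000-sample target.  The
per-stage output lengths follow a geometric-style schedule fixed by the
rescaling factor

    r = (S_n / S_r)^(1/(N-1))

which for the defaults (S_n=100, S_r=3000, N=4) yields lengths
[100, 230, 965, 3000].

The adversarial objective is the Wasserstein divergence:

    L_D = E[D(x_f)] - E[D(x_r)] + k * E[ ||grad_{x_hat} D(x_hat)||_2^p ]
    L_G = E[D(x_r)] - E[D(G(z))]

with k=2, p=6 and x_hat random per-sample interpolates between real and
fake batches.  The discriminator is piecewise linear (conv + leaky ReLU,
no normalization), so its input gradient is computed exactly by a
transposed-convolution chain with the activation masks held fixed; that
chain is built over the live weight tensors, which makes the penalty's
parameter gradient exact without second-order autodiff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .signal import STAGES, NormalizedEpoch


# ------------------------------------------------------------------ schedule
@dataclass(frozen=True)
class ResolutionSchedule:
    """Per-stage output lengths of the progressive generator."""

    latent_size: int
    target_size: int
    n_stages: int
    rescale_factor: float
    sizes: tuple[int, ...]


def build_schedule(S_n: int = 100, S_r: int = 3000, N: int = 4) -> ResolutionSchedule:
    """Compute the progressive resolution schedule.

    ``r = (S_n/S_r)^(1/(N-1))``; intermediate sizes are
    ``floor(S_r * r^(((M-1)/ln M) * ln(M-i) + 1))`` for ``i = 0..M-1`` with
    ``M = N-1``, and the final stage is exactly ``S_r``.  The exponent
    interpolates from ``N-1`` (giving ``S_n`` exactly at stage 0) down to
    1, so the defaults reproduce [100, 230, 965, 3000].
    """
    if N < 2:
        raise ValueError(f"need at least 2 stages, got {N}")
    if not 0 < S_n < S_r:
        raise ValueError(f"need 0 < latent size < target size, got {S_n}, {S_r}")
    r = (S_n / S_r) ** (1.0 / (N - 1))
    M = N - 1
    sizes: list[int] = []
    if M == 1:
        sizes = [S_n]
    else:
        for i in range(M):
            expo = (M - 1) / math.log(M) * math.log(M - i) + 1.0
            sizes.append(int(math.floor(S_r * r**expo + 1e-9)))
    sizes.append(S_r)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError(f"schedule is not strictly increasing: {sizes}")
    return ResolutionSchedule(S_n, S_r, N, r, tuple(sizes))


# -------------------------------------------------------------------- config
@dataclass(frozen=True)
class GanConfig:
    """Hyperparameters of the generators, discriminators and training loop.

    Defaults are the full-scale settings; smoke-scale runs shrink
    ``channels``, ``epochs_per_scale`` and ``batch_size`` (see
    docs/methods.md for the sizes used by the test suite).
    """

    k: float = 2.0                      # gradient-penalty weight
    p: float = 6.0                      # gradient-penalty exponent
    base_lr: float = 5e-4
    lr_decay: float = 0.1               # per stage below the current top
    adam_betas: tuple[float, float] = (0.5, 0.999)
    epochs_per_scale: int = 2000
    scheduler_gamma: float = 0.1
    scheduler_milestone: int = 1600
    batch_size: int = 64
    noise_amplitude: float = 0.1        # additive noise on upsampled features
    concurrent_stages: int = 3          # only the last stages receive updates
    inner_steps_G: int = 3
    inner_steps_D: int = 3
    channels: int = 32
    kernel: int = 9
    conv_per_stage: int = 3
    lrelu_alpha: float = 0.05
    latent_size: int = 100
    target_size: int = 3000
    n_stages: int = 4

    def __post_init__(self):
        if self.k <= 0 or self.p < 1:
            raise ValueError("penalty needs k > 0 and p >= 1")
        if not 1 <= self.concurrent_stages <= self.n_stages:
            raise ValueError("concurrent_stages must be in [1, n_stages]")

    def schedule(self) -> ResolutionSchedule:
        return build_schedule(self.latent_size, self.target_size, self.n_stages)

    def with_overrides(self, **kw) -> "GanConfig":
        return replace(self, **kw)


# -------------------------------------------------------------------- losses
def _values(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
    if t.data.size == 0:
        raise ValueError("empty batch")
    return t


def discriminator_loss(d_fake, d_real, grad_norms, config: GanConfig) -> Tensor:
    """Wasserstein-divergence critic loss.

    ``mean(D(x_f)) - mean(D(x_r)) + k * mean(||grad||^p)`` where
    ``grad_norms`` are the full-input L2 norms of the critic's gradient at
    the interpolates.  Accepts plain arrays (returns a constant tensor) or
    graph tensors (differentiable).
    """
    d_fake, d_real, grad_norms = _values(d_fake), _values(d_real), _values(grad_norms)
    penalty = config.k * ad.mean(ad.power(grad_norms, config.p))
    return ad.mean(d_fake) - ad.mean(d_real) + penalty


def generator_loss(d_real, d_gen) -> Tensor:
    """``mean(D(x_r)) - mean(D(G(z)))``."""
    d_real, d_gen = _values(d_real), _values(d_gen)
    return ad.mean(d_real) - ad.mean(d_gen)


def make_interpolates(x_r: np.ndarray, x_f: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Per-sample convex combinations ``u*x_r + (1-u)*x_f`` (one scalar u
    per sample)."""
    x_r, x_f = np.asarray(x_r), np.asarray(x_f)
    if x_r.shape != x_f.shape:
        raise ValueError(f"shape mismatch: {x_r.shape} vs {x_f.shape}")
    u = np.asarray(u, dtype=np.float64).reshape(-1, *([1] * (x_r.ndim - 1)))
    if u.shape[0] != x_r.shape[0]:
        raise ValueError("need one interpolation scalar per sample")
    return u * x_r + (1.0 - u) * x_f


# --------------------------------------------------------------------- model
class ConvBlock(nn.Module):
    """Conv -> BatchNorm -> leaky ReLU."""

    def __init__(self, c_in, c_out, kernel, alpha, rng):
        super().__init__()
        self.conv = nn.Conv1d(c_in, c_out, kernel, rng)
        self.bn = nn.BatchNorm1d(c_out)
        self.alpha = alpha

    def __call__(self, x):
        return ad.leaky_relu(self.bn(self.conv(x)), self.alpha)


class GeneratorStage(nn.Module):
    """Three conv blocks; stage 0 maps the 1-channel latent up to
    ``channels``, later stages keep the channel count."""

    def __init__(self, c_in, channels, config: GanConfig, rng):
        super().__init__()
        self.blocks = [
            ConvBlock(c_in if i == 0 else channels, channels, config.kernel, config.lrelu_alpha, rng)
            for i in range(config.conv_per_stage)
        ]

    def __call__(self, x):
        for b in self.blocks:
            x = b(x)
        return x


class Generator(nn.Module):
    """Progressive generator for one sleep stage.

    Holds a list of :class:`GeneratorStage` blocks (grown with
    :meth:`grow`), plus a shared tanh output head.  ``forward`` runs the
    blocks up to the current top stage, linearly upsampling between
    stages, adding Gaussian feature noise on the upsampled features, and
    applying the residual connection around each grown block.
    """

    def __init__(self, stage_label: str, config: GanConfig, rng: np.random.Generator):
        super().__init__()
        if stage_label not in STAGES:
            raise ValueError(f"unknown sleep stage {stage_label!r}")
        self.stage_label = stage_label
        self.config = config
        self.schedule = config.schedule()
        self.stages = [GeneratorStage(1, config.channels, config, rng)]
        self.head = nn.Conv1d(config.channels, 1, config.kernel, rng)

    @property
    def top(self) -> int:
        return len(self.stages) - 1

    @property
    def is_final(self) -> bool:
        return self.top == self.schedule.n_stages - 1

    def grow(self, rng: np.random.Generator) -> None:
        """Append the next stage's three conv blocks.  Earlier stages'
        parameters are untouched (preserved bit-exact)."""
        if self.is_final:
            raise ValueError("generator is already at the final stage")
        cfg = self.config
        self.stages.append(GeneratorStage(cfg.channels, cfg.channels, cfg, rng))

    def features(self, z, rng: np.random.Generator | None = None) -> Tensor:
        """Feature maps at the top stage (before the output head)."""
        f = self.stages[0](z if isinstance(z, Tensor) else Tensor(z))
        for j in range(1, self.top + 1):
            up = ad.upsample_linear(f, self.schedule.sizes[j])
            branch_in = up
            if self.config.noise_amplitude > 0 and rng is not None:
                noise = rng.standard_normal(up.data.shape) * self.config.noise_amplitude
                branch_in = up + Tensor(noise)
            f = up + self.stages[j](branch_in)
        return f

    def __call__(self, z, rng: np.random.Generator | None = None) -> Tensor:
        """Generated traces at the current stage's resolution, in [-1, 1]."""
        return ad.tanh(self.head(self.features(z, rng)))

    def trained_stage_indices(self) -> list[int]:
        lo = max(0, self.top - (self.config.concurrent_stages - 1))
        return list(range(lo, self.top + 1))

    def set_stage_modes(self) -> None:
        """Trained stages in train mode, frozen stages (and their batch-norm
        statistics) in eval mode."""
        trained = set(self.trained_stage_indices())
        for j, st in enumerate(self.stages):
            st.train(j in trained)
        self.head.train(True)


class Discriminator(nn.Module):
    """Critic: 3 conv + leaky ReLU blocks then a linear conv head; the
    output map has the input's length and the critic value is its mean.
    Resolution-agnostic, so one parameter set serves every stage (the
    warm-start across stages is literal parameter reuse)."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        super().__init__()
        c = config.channels
        self.convs = [nn.Conv1d(1 if i == 0 else c, c, config.kernel, rng) for i in range(3)]
        self.head = nn.Conv1d(c, 1, config.kernel, rng)
        self.alpha = config.lrelu_alpha

    def __call__(self, x) -> Tensor:
        """Per-sample critic values, shape (B,)."""
        h = x if isinstance(x, Tensor) else Tensor(x)
        for conv in self.convs:
            h = ad.leaky_relu(conv(h), self.alpha)
        return ad.mean(self.head(h), axis=(1, 2))

    def input_gradient_graph(self, x_hat: np.ndarray) -> Tensor:
        """grad of the critic value w.r.t. its input, as a graph over the
        weight tensors.

        Runs a plain NumPy forward pass at ``x_hat`` to record the leaky
        ReLU masks, then assembles the backward chain from transposed
        convolutions of the *live* weight tensors with the masks held as
        constants.  Because leaky ReLU has zero second derivative almost
        everywhere, first-order differentiation of this graph gives the
        exact parameter gradient of any function of the input gradient —
        the same quantity double backprop would produce.
        """
        B, _, L = x_hat.shape
        h = x_hat
        masks = []
        for conv in self.convs:
            a = _np_conv1d(h, conv.weight.data, conv.bias.data)
            masks.append(np.where(a > 0, 1.0, self.alpha))
            h = np.where(a > 0, a, self.alpha * a)
        # critic value = mean over the (1, L) output map => cotangent 1/L
        g = Tensor(np.full((B, 1, L), 1.0 / L))
        g = ad.conv1d(g, ad.conv1d_weight_transposed(self.head.weight))
        for conv, m in zip(reversed(self.convs), reversed(masks)):
            g = g * Tensor(m)
            g = ad.conv1d(g, ad.conv1d_weight_transposed(conv.weight))
        return g


def _np_conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    K = w.shape[2]
    P = K // 2
    L = x.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (P, P)))
    out = np.zeros((x.shape[0], w.shape[0], L), dtype=x.dtype)
    for k in range(K):
        out += np.matmul(w[:, :, k], xp[:, :, k : k + L])
    return out + b[None, :, None]


# ------------------------------------------------------------------ training
def downscale_epochs(x: np.ndarray, length: int) -> np.ndarray:
    """Linearly resample real (n, L) epochs to an intermediate length —
    mirrors the generator's linear upsampling."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] == length:
        return x
    return x @ ad.upsample_matrix(x.shape[1], length)


def stage_learning_rates(top: int, config: GanConfig) -> dict[int, float]:
    """Learning rate per trained generator stage while ``top`` is current:
    ``base_lr * lr_decay^(top - m)``.  The top stage always trains at the
    base rate; at the final stage this reproduces the printed
    ``0.0005 * 0.1^(N-n-1)`` values."""
    lo = max(0, top - (config.concurrent_stages - 1))
    return {m: config.base_lr * config.lr_decay ** (top - m) for m in range(lo, top + 1)}


@dataclass
class StageTrainResult:
    d_losses: list[float] = field(default_factory=list)
    g_losses: list[float] = field(default_factory=list)


def train_stage(
    generator: Generator,
    discriminator: Discriminator,
    real_epochs: np.ndarray,
    config: GanConfig,
    rng: np.random.Generator,
) -> StageTrainResult:
    """Train the current top stage for ``epochs_per_scale`` iterations.

    Per iteration: ``inner_steps_D`` critic updates on fresh batches
    (real, fake, interpolates) followed by ``inner_steps_G`` generator
    updates.  Only the last ``concurrent_stages`` generator stages get
    gradients, at per-stage decayed learning rates; the critic trains at
    the base rate.  Both rates drop by ``scheduler_gamma`` at the
    milestone iteration.  Real epochs are expected already downscaled to
    the current stage length.
    """
    real_epochs = np.atleast_2d(np.asarray(real_epochs, dtype=np.float64))
    if real_epochs.shape[0] < 1:
        raise ValueError("need at least one real epoch")
    top = generator.top
    if real_epochs.shape[1] != generator.schedule.sizes[top]:
        raise ValueError(
            f"real epochs have length {real_epochs.shape[1]}, "
            f"stage {top} expects {generator.schedule.sizes[top]}"
        )

    lrs = stage_learning_rates(top, config)
    g_groups = [
        {"params": generator.stages[m].parameters(), "lr": lr} for m, lr in lrs.items()
    ]
    g_groups.append({"params": generator.head.parameters(), "lr": config.base_lr})
    opt_g = nn.Adam(g_groups, betas=config.adam_betas)
    opt_d = nn.Adam(
        [{"params": discriminator.parameters(), "lr": config.base_lr}], betas=config.adam_betas
    )
    generator.set_stage_modes()
    discriminator.train(True)

    B = config.batch_size
    n_real = real_epochs.shape[0]
    result = StageTrainResult()
    for it in range(config.epochs_per_scale):
        if it == config.scheduler_milestone:
            opt_g.scale_lr(config.scheduler_gamma)
            opt_d.scale_lr(config.scheduler_gamma)
        # ---- critic updates
        for _ in range(config.inner_steps_D):
            x_r = real_epochs[rng.integers(0, n_real, size=B)][:, None, :]
            z = rng.standard_normal((B, 1, config.latent_size))
            with ad.no_grad():
                x_f = generator(z, rng).data
            x_hat = make_interpolates(x_r, x_f, rng.random(B))
            d_real = discriminator(x_r)
            d_fake = discriminator(Tensor(x_f))
            gx = discriminator.input_gradient_graph(x_hat)
            norms = ad.sqrt(ad.sum_(gx * gx, axis=(1, 2)) + 1e-24)
            loss_d = discriminator_loss(d_fake, d_real, norms, config)
            opt_d.zero_grad()
            ad.backward(loss_d)
            opt_d.step()
            d_val = loss_d.item()
        if not np.isfinite(d_val):
            raise FloatingPointError(f"non-finite critic loss at iteration {it}")
        result.d_losses.append(d_val)
        # ---- generator updates
        for _ in range(config.inner_steps_G):
            x_r = real_epochs[rng.integers(0, n_real, size=B)][:, None, :]
            z = rng.standard_normal((B, 1, config.latent_size))
            with ad.no_grad():
                d_real_const = discriminator(x_r).data
            x_f = generator(z, rng)
            d_gen = discriminator(x_f)
            loss_g = generator_loss(Tensor(d_real_const), d_gen)
            opt_g.zero_grad()
            discriminator.zero_grad()  # D appears in the graph but is frozen here
            ad.backward(loss_g)
            opt_g.step()
            g_val = loss_g.item()
        if not np.isfinite(g_val):
            raise FloatingPointError(f"non-finite generator loss at iteration {it}")
        result.g_losses.append(g_val)
    return result


def train_progressive(
    stage_label: str,
    real_epochs,
    config: GanConfig,
    seed: int,
) -> tuple[Generator, Discriminator, list[StageTrainResult]]:
    """Full multistage run: train stage 0, then repeatedly grow and train
    until the final resolution.  ``real_epochs`` is an (n, target_size)
    array of mean-normalized epochs (or a list of
    :class:`~sleepgan.signal.NormalizedEpoch`)."""
    if isinstance(real_epochs, (list, tuple)) and real_epochs and isinstance(real_epochs[0], NormalizedEpoch):
        real_epochs = np.stack([e.samples for e in real_epochs])
    real_epochs = np.atleast_2d(np.asarray(real_epochs, dtype=np.float64))
    rng = np.random.default_rng(seed)
    gen = Generator(stage_label, config, rng)
    disc = Discriminator(config, rng)
    traces = []
    for stage in range(config.n_stages):
        if stage > 0:
            gen.grow(rng)
        x = downscale_epochs(real_epochs, gen.schedule.sizes[stage])
        traces.append(train_stage(gen, disc, x, config, rng))
    return gen, disc, traces


def sample_epochs(generator: Generator, n_samples: int, seed: int) -> list[NormalizedEpoch]:
    """Draw epochs from a fully grown generator.

    Latents are standard Gaussian of the configured length; outputs are
    tanh-bounded, tagged with the generator's stage label.  Rejects a
    generator that has not reached the final resolution.
    """
    if not generator.is_final:
        raise ValueError(
            f"generator is at stage {generator.top} of {generator.schedule.n_stages - 1}; "
            "grow it to the final stage before sampling"
        )
    rng = np.random.default_rng(seed)
    generator.eval()
    with ad.no_grad():
        z = rng.standard_normal((n_samples, 1, generator.config.latent_size))
        out = generator(z, rng).data[:, 0, :]
    return [NormalizedEpoch(samples=row, stage=generator.stage_label) for row in out]
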