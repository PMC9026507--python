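"""Generator and discriminator architectures.

The switchable generator is a 4-level U-net whose nine normalization sites are
AdaIN layers fed by a single style coder: one set of convolutional weights
serves both translation directions, selected by the domain code ``gamma``.
The baseline for comparison experiments is a pair of independent generators
with the same backbone but fixed identity style (plain instance norm) and no
coder. Discriminators are PatchGAN classifiers scoring overlapping patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .adain import StyleCoder, StyleParams, adain_transform, style_code, validate_gamma
from .autograd import Tensor

LRELU_SLOPE = 0.2


@dataclass
class GeneratorConfig:
    base_channels: int = 64
    depth: int = 4
    in_channels: int = 1
    out_channels: int = 1

    @property
    def divisor(self) -> int:
        return 2**self.depth

    @property
    def site_widths(self) -> list[int]:
        c = self.base_channels
        enc = [c, 2 * c, 4 * c, 8 * c]
        dec = [4 * c, 2 * c, c, c]
        return enc + dec + [c]  # 4 encoder + 4 decoder + 1 fusion = 9 sites


def _conv_weight(rng, co, ci, k, dtype=np.float32):
    return Tensor((rng.standard_normal((co, ci, k, k)) * 0.02).astype(dtype),
                  requires_grad=True)


def _convT_weight(rng, ci, co, k, dtype=np.float32):
    return Tensor((rng.standard_normal((ci, co, k, k)) * 0.02).astype(dtype),
                  requires_grad=True)


def _to_nchw(image) -> tuple[Tensor, bool]:
    """Accept (H, W) ndarray or (1, 1, H, W) Tensor; return NCHW Tensor."""
    if isinstance(image, Tensor):
        return image, False
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim != 4:
        raise ValueError(f"expected a 2-D image or NCHW array, got shape {arr.shape}")
    return Tensor(arr), True


class Generator:
    """U-net backbone with nine AdaIN sites and an optional style coder.

    With a coder attached (switchable model) the style at every site is
    F(gamma); without one (baseline CycleGAN generator) the style is fixed at
    the identity (sigma=1, mu=0), i.e. plain instance normalization.
    """

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator,
                 with_coder: bool = True):
        self.config = config
        c = config.base_channels
        ci = config.in_channels
        self.weights: dict[str, Tensor] = {}
        w = self.weights
        # contracting path: k4/s2/p1 convolutions, channels doubling
        w["enc1"] = _conv_weight(rng, c, ci, 4)
        w["enc2"] = _conv_weight(rng, 2 * c, c, 4)
        w["enc3"] = _conv_weight(rng, 4 * c, 2 * c, 4)
        w["enc4"] = _conv_weight(rng, 8 * c, 4 * c, 4)
        # expansive path: transposed k4/s2/p1 convolutions, skip concatenation
        w["dec1"] = _convT_weight(rng, 8 * c, 4 * c, 4)
        w["dec2"] = _convT_weight(rng, 8 * c, 2 * c, 4)
        w["dec3"] = _convT_weight(rng, 4 * c, c, 4)
        w["dec4"] = _convT_weight(rng, 2 * c, c, 4)
        # fusion conv (9th AdaIN site) and the final 1x1 projection
        w["fuse"] = _conv_weight(rng, c, c, 3)
        w["out_w"] = _conv_weight(rng, config.out_channels, c, 1)
        w["out_b"] = Tensor(np.zeros(config.out_channels, dtype=np.float32),
                            requires_grad=True)
        self.coder = StyleCoder(config.site_widths, rng) if with_coder else None
        self._identity_style = StyleParams.identity(config.site_widths)

    # -- parameter plumbing ---------------------------------------------------

    def parameters(self, include_coder: bool = True) -> list[Tensor]:
        params = list(self.weights.values())
        if include_coder and self.coder is not None:
            params += self.coder.parameters()
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"g.{k}": v.data.copy() for k, v in self.weights.items()}
        if self.coder is not None:
            names = ["embedding", "w1", "b1", "w2", "b2"]
            for name, p in zip(names, self.coder.parameters()):
                state[f"coder.{name}"] = p.data.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for k, v in self.weights.items():
            v.data = np.asarray(state[f"g.{k}"]).copy()
        if self.coder is not None:
            names = ["embedding", "w1", "b1", "w2", "b2"]
            for name, p in zip(names, self.coder.parameters()):
                p.data = np.asarray(state[f"coder.{name}"]).copy()

    # -- forward --------------------------------------------------------------

    def _style(self, gamma) -> StyleParams:
        if self.coder is None:
            return self._identity_style
        return style_code(gamma, self.coder)

    def forward(self, x: Tensor, gamma: float | None = None) -> Tensor:
        h, w = x.shape[-2:]
        d = self.config.divisor
        if h % d or w % d:
            raise ValueError(
                f"input spatial dims must be divisible by {d}, got {h}x{w}")
        style = self._style(0.0 if gamma is None else gamma).sites
        wt = self.weights

        def site(t, weight, idx, transposed=False):
            if transposed:
                t = ag.conv_transpose2d(t, weight, stride=2, padding=1)
            else:
                t = ag.conv2d(t, weight, stride=2, padding=1)
            sig, mu = style[idx]
            return ag.leaky_relu(adain_transform(t, sig, mu), LRELU_SLOPE)

        e1 = site(x, wt["enc1"], 0)
        e2 = site(e1, wt["enc2"], 1)
        e3 = site(e2, wt["enc3"], 2)
        e4 = site(e3, wt["enc4"], 3)
        u1 = ag.concat([site(e4, wt["dec1"], 4, transposed=True), e3])
        u2 = ag.concat([site(u1, wt["dec2"], 5, transposed=True), e2])
        u3 = ag.concat([site(u2, wt["dec3"], 6, transposed=True), e1])
        u4 = site(u3, wt["dec4"], 7, transposed=True)
        f = ag.conv2d(u4, wt["fuse"], stride=1, padding=1)
        sig, mu = style[8]
        f = ag.leaky_relu(adain_transform(f, sig, mu), LRELU_SLOPE)
        return ag.tanh(ag.conv2d(f, wt["out_w"], wt["out_b"], stride=1, padding=0))


class _BatchNorm:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        c = x.shape[1]
        if training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            sd = Tensor(np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1))
            xhat = (x - mu) / sd
        return self.gamma.reshape((1, c, 1, 1)) * xhat + self.beta.reshape((1, c, 1, 1))


class Discriminator:
    """PatchGAN: 5 convolutions, first stride 2 then stride 1, channels
    1 -> 64 -> 128 -> 256 -> 512 -> 1, batch norm on the middle stages, raw
    (un-sigmoided) patch scores for the least-squares adversarial loss."""

    KERNEL = 4

    def __init__(self, rng: np.random.Generator, base_channels: int = 64,
                 in_channels: int = 1):
        c = base_channels
        k = self.KERNEL
        self.channels = [in_channels, c, 2 * c, 4 * c, 8 * c, 1]
        self.weights = [
            _conv_weight(rng, c, in_channels, k),
            _conv_weight(rng, 2 * c, c, k),
            _conv_weight(rng, 4 * c, 2 * c, k),
            _conv_weight(rng, 8 * c, 4 * c, k),
            _conv_weight(rng, 1, 8 * c, k),
        ]
        self.bias_out = Tensor(np.zeros(1, dtype=np.float32), requires_grad=True)
        self.norms = [_BatchNorm(2 * c), _BatchNorm(4 * c), _BatchNorm(8 * c)]
        self.strides = [2, 1, 1, 1, 1]

    def parameters(self) -> list[Tensor]:
        params = list(self.weights) + [self.bias_out]
        for n in self.norms:
            params += [n.gamma, n.beta]
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"w{i}": w.data.copy() for i, w in enumerate(self.weights)}
        state["bias_out"] = self.bias_out.data.copy()
        for i, n in enumerate(self.norms):
            state[f"bn{i}.gamma"] = n.gamma.data.copy()
            state[f"bn{i}.beta"] = n.beta.data.copy()
            state[f"bn{i}.mean"] = n.running_mean.copy()
            state[f"bn{i}.var"] = n.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, w in enumerate(self.weights):
            w.data = np.asarray(state[f"w{i}"]).copy()
        self.bias_out.data = np.asarray(state["bias_out"]).copy()
        for i, n in enumerate(self.norms):
            n.gamma.data = np.asarray(state[f"bn{i}.gamma"]).copy()
            n.beta.data = np.asarray(state[f"bn{i}.beta"]).copy()
            n.running_mean = np.asarray(state[f"bn{i}.mean"]).copy()
            n.running_var = np.asarray(state[f"bn{i}.var"]).copy()

    def forward(self, x: Tensor, training: bool = True) -> Tensor:
        t = ag.conv2d(x, self.weights[0], stride=2, padding=1)
        t = ag.leaky_relu(t, LRELU_SLOPE)
        for i in (1, 2, 3):
            t = ag.conv2d(t, self.weights[i], stride=1, padding=1)
            t = self.norms[i - 1](t, training=training)
            t = ag.leaky_relu(t, LRELU_SLOPE)
        return ag.conv2d(t, self.weights[4], self.bias_out, stride=1, padding=1)

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        """Patch-map extent from standard convolution arithmetic."""
        k = self.KERNEL
        for s in self.strides:
            h = (h + 2 - k) // s + 1
            w = (w + 2 - k) // s + 1
        return h, w


# -- builders -------------------------------------------------------------------


def build_switchable_generator(config: GeneratorConfig | None = None,
                               seed: int = 0) -> Generator:
    """Single AdaIN-switched generator serving both translation directions."""
    config = config or GeneratorConfig()
    return Generator(config, np.random.default_rng(seed), with_coder=True)


def build_cyclegan_pair(config: GeneratorConfig | None = None,
                        seed: int = 0) -> tuple[Generator, Generator]:
    """Baseline: two independent fixed-style generators (forward, backward)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    g_ab = Generator(config, rng, with_coder=False)
    g_ba = Generator(config, rng, with_coder=False)
    return g_ab, g_ba


def build_discriminator(seed: int = 0, base_channels: int = 64) -> Discriminator:
    return Discriminator(np.random.default_rng(seed), base_channels=base_channels)


def count_parameters(network) -> int:
    """Number of trainable scalars in a generator or discriminator."""
    return int(sum(p.data.size for p in network.parameters()))


def generate(g: Generator, image, gamma: float | None = None) -> np.ndarray:
    """Translate one [-1, 1] grayscale image; gamma selects the output domain.

    gamma=0 synthesizes the contrast-2 (domain B) appearance, gamma=1 the
    contrast-1 (domain A) appearance; baseline generators ignore gamma.
    """
    if gamma is not None:
        validate_gamma(gamma)
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.min() < -1.0 - 1e-6 or arr.max() > 1.0 + 1e-6:
        warnings.warn("input intensities outside [-1, 1]; clamping", stacklevel=2)
        arr = np.clip(arr, -1.0, 1.0)
    with ag.no_grad():
        out = g.forward(Tensor(arr[None, None]), gamma)
    return out.data[0, 0]


def discriminate(d: Discriminator, image) -> np.ndarray:
    """Raw patch score map for one image (inference mode, running BN stats)."""
    x, _ = _to_nchw(image)
    with ag.no_grad():
        out = d.forward(x, training=False)
    return out.data[0, 0]
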