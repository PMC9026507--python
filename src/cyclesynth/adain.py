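"""Adaptive instance normalization (AdaIN) and the switchable style coder.

AdaIN replaces the per-channel spatial mean/std of a feature map with target
moments. The style coder maps a scalar domain code ``gamma`` to one (sigma, mu)
pair per AdaIN site: ``gamma = 0`` yields the identity style (sigma=1, mu=0,
i.e. plain instance normalization) and ``gamma = 1`` yields a learned style,
so a single generator can synthesize either image contrast. Intermediate
``gamma`` linearly interpolates the two styles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, leaky_relu, relu

EPS = 1e-5  # stabilizer under the square root of the spatial std

N_SITES = 9  # AdaIN sites in the generator: 4 encoder + 4 decoder + 1 fusion


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, False
    arr = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature map contains non-finite values")
    return Tensor(arr), True


def instance_moments(x, eps: float = EPS):
    """Per-channel spatial mean and std of a (..., C, H, W) feature map.

    The std uses the population (biased) convention with ``eps`` added under
    the square root, so constant channels give std == sqrt(eps).
    Returns (mean, std) as Tensors, or as numpy arrays when ``x`` is one.
    """
    t, was_array = _as_tensor(x)
    if t.ndim < 3:
        raise ValueError("feature map must have at least (C, H, W) dimensions")
    mean = t.mean(axis=(-2, -1), keepdims=True)
    var = ((t - mean) ** 2).mean(axis=(-2, -1), keepdims=True)
    std = (var + eps).sqrt()
    sq = lambda v: v.reshape(v.shape[:-2])
    mean, std = sq(mean), sq(std)
    if was_array:
        return mean.data, std.data
    return mean, std


def _style_broadcast(v, ref: Tensor):
    """Reshape a per-channel style vector (C,) to broadcast over (..., C, H, W)."""
    t = v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float64))
    c = ref.shape[-3]
    if t.data.size != c:
        raise ValueError(f"style has {t.data.size} channels, feature map has {c}")
    return t.reshape((c, 1, 1))


def adain_transform(x, sigma, mu, eps: float = EPS):
    """AdaIN moment matching: z_n = sigma_n * (x_n - mean(x_n)) / std(x_n) + mu_n.

    ``sigma`` and ``mu`` are per-channel vectors; ``sigma`` must be
    non-negative. Output has the shape of ``x``.
    """
    t, was_array = _as_tensor(x)
    sig = _style_broadcast(sigma, t)
    m = _style_broadcast(mu, t)
    if np.any(sig.data < 0):
        raise ValueError("sigma components must be non-negative")
    mean, std = instance_moments(t, eps=eps)
    mean = mean.reshape(mean.shape + (1, 1))
    std = std.reshape(std.shape + (1, 1))
    out = sig * ((t - mean) / std) + m
    return out.data if was_array else out


@dataclass
class StyleParams:
    """One (sigma, mu) pair per AdaIN site, in generator order."""

    sites: list  # list of (sigma: Tensor, mu: Tensor), each of shape (C_site,)

    def __post_init__(self):
        if len(self.sites) != N_SITES:
            raise ValueError(f"expected {N_SITES} AdaIN sites, got {len(self.sites)}")

    @property
    def widths(self) -> list[int]:
        return [int(s.data.size) for s, _ in self.sites]

    @staticmethod
    def identity(widths) -> "StyleParams":
        """The fixed instance-norm style: sigma=1, mu=0 at every site."""
        return StyleParams(
            [(Tensor(np.ones(w, dtype=np.float32)),
              Tensor(np.zeros(w, dtype=np.float32))) for w in widths]
        )


class StyleCoder:
    """The light-weight coder F: a learnable 128-vector through a two-layer MLP.

    Produces the domain-B style (sigma_B, mu_B) for all sites; the sigma head
    is ReLU-rectified so variance vectors cannot go negative. Output biases
    start at (sigma=1, mu=0) so training begins from the identity style.
    """

    EMBED_DIM = 128

    def __init__(self, site_widths, rng: np.random.Generator,
                 dtype=np.float32):
        self.site_widths = list(site_widths)
        total = 2 * sum(self.site_widths)
        d = self.EMBED_DIM
        self.embedding = Tensor(
            rng.standard_normal((1, d)).astype(dtype), requires_grad=True)
        self.w1 = Tensor((rng.standard_normal((d, d)) * 0.02).astype(dtype),
                         requires_grad=True)
        self.b1 = Tensor(np.zeros((1, d), dtype=dtype), requires_grad=True)
        self.w2 = Tensor((rng.standard_normal((d, total)) * 0.02).astype(dtype),
                         requires_grad=True)
        b2 = np.zeros((1, total), dtype=dtype)
        off = 0
        for w in self.site_widths:  # sigma components start at 1
            b2[0, off : off + w] = 1.0
            off += 2 * w
        self.b2 = Tensor(b2, requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.embedding, self.w1, self.b1, self.w2, self.b2]

    def domain_b_style(self) -> list:
        """Per-site rectified (sigma_B, mu_B) from the embedding MLP."""
        h = leaky_relu(self.embedding @ self.w1 + self.b1, 0.2)
        out = (h @ self.w2 + self.b2).reshape((-1,))
        return _split_sites(out, self.site_widths)


def _split_sites(flat: Tensor, widths) -> list:
    """Split the coder's flat output into per-site (relu(sigma_raw), mu)."""
    pieces = []
    off = 0
    for w in widths:
        sig_raw = _slice1d(flat, off, off + w)
        mu = _slice1d(flat, off + w, off + 2 * w)
        pieces.append((relu(sig_raw), mu))
        off += 2 * w
    return pieces


def _slice1d(t: Tensor, start: int, stop: int) -> Tensor:
    """Differentiable 1-D slice."""
    def backward(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            full[start:stop] = g
            t._accumulate(full)

    return Tensor._make(t.data[start:stop], (t,), backward)


def validate_gamma(gamma: float) -> float:
    g = float(gamma)
    if not (0.0 <= g <= 1.0) or not np.isfinite(g):
        raise ValueError(f"domain code gamma must lie in [0, 1], got {gamma}")
    return g


def style_code(gamma: float, coder: StyleCoder) -> StyleParams:
    """F(gamma) = (1 - gamma) * [1; 0] + gamma * [sigma_B; mu_B] per site.

    gamma = 0 returns exactly the identity style regardless of coder weights;
    gamma = 1 returns the coder's learned, rectified style.
    """
    g = validate_gamma(gamma)
    if g == 0.0:
        return StyleParams.identity(coder.site_widths)
    b_sites = coder.domain_b_style()
    if g == 1.0:
        return StyleParams(list(b_sites))
    sites = []
    for w, (sig_b, mu_b) in zip(coder.site_widths, b_sites):
        one = Tensor(np.ones(w))
        sites.append(((1.0 - g) * one + g * sig_b, g * mu_b))
    return StyleParams(sites)
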