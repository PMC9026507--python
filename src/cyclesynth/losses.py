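"""Least-squares adversarial, cycle-consistency and identity losses.

All losses are means over pixels/patches so the weights are independent of
image resolution. Targets follow the least-squares GAN convention: the
discriminator pushes real patches toward 1 and generated patches toward 0,
while the generator pushes its outputs' scores toward 1. The discriminator
loss is halved, and its fake inputs are detached from the generator tape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor


@dataclass(frozen=True)
class LossWeights:
    lambda_adv: float = 1.0
    lambda_cyc: float = 10.0
    lambda_id: float = 5.0


@dataclass
class LossReport:
    """Per-step loss components (generator side plus both discriminators)."""

    step: int
    epoch: int
    adv_g: float
    adv_d_a: float
    adv_d_b: float
    cyc: float
    id: float
    total: float

    FIELDS = ("step", "epoch", "adv_g", "adv_d_a", "adv_d_b", "cyc", "id", "total")

    def row(self) -> list:
        return [getattr(self, f) for f in self.FIELDS]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _check_shapes(a: Tensor, b: Tensor, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")


def adversarial_loss_d(real_scores, fake_scores) -> Tensor:
    """0.5 * [ mean (D(real) - 1)^2 + mean D(fake)^2 ].

    ``fake_scores`` must come from detached (replay-buffer) images so no
    gradient reaches the generator.
    """
    real, fake = _as_tensor(real_scores), _as_tensor(fake_scores)
    return 0.5 * (((real - 1.0) ** 2).mean() + (fake**2).mean())


def adversarial_loss_g(fake_scores) -> Tensor:
    """mean (D(G(x)) - 1)^2: the generator tries to make fakes score real."""
    fake = _as_tensor(fake_scores)
    return ((fake - 1.0) ** 2).mean()


def _mae(a: Tensor, b: Tensor) -> Tensor:
    return (a - b).abs().mean()


def cycle_loss(x, x_cycled, y, y_cycled) -> Tensor:
    """L1 error of both round trips: A->B->A against x, B->A->B against y."""
    x, xc, y, yc = map(_as_tensor, (x, x_cycled, y, y_cycled))
    _check_shapes(x, xc, "cycle_loss (x)")
    _check_shapes(y, yc, "cycle_loss (y)")
    return _mae(xc, x) + _mae(yc, y)


def identity_loss(y, g_on_y, x, g_on_x) -> Tensor:
    """L1 penalty for changing an image already in the generator's target domain."""
    y, gy, x, gx = map(_as_tensor, (y, g_on_y, x, g_on_x))
    _check_shapes(y, gy, "identity_loss (y)")
    _check_shapes(x, gx, "identity_loss (x)")
    return _mae(gy, y) + _mae(gx, x)


def total_generator_loss(adv_g, cyc, id_, weights: LossWeights = LossWeights()):
    """lambda_adv * L_adv + lambda_cyc * L_cyc + lambda_id * L_id."""
    adv_g, cyc, id_ = map(_as_tensor, (adv_g, cyc, id_))
    return (weights.lambda_adv * adv_g + weights.lambda_cyc * cyc
            + weights.lambda_id * id_)
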