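"""Adversarial training loop: schedule, augmentation, replay buffer, updates.

One iteration draws one image from each domain (independently shuffled, so
pairs arrive unpaired), updates the generator (and style coder) on the
weighted total loss, then updates each discriminator on the least-squares
loss using a replay buffer of previously generated images. The learning rate
is constant for the first half of the schedule and decays linearly to zero
over the second half.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .losses import (LossReport, LossWeights, adversarial_loss_d,
                     adversarial_loss_g, cycle_loss, identity_loss,
                     total_generator_loss)
from .networks import (Discriminator, Generator, GeneratorConfig,
                       build_cyclegan_pair, build_discriminator,
                       build_switchable_generator)
from .optim import Adam
from .phantom import DatasetManifest


@dataclass
class TrainConfig:
    epochs: int = 200
    lr_initial: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 1
    crop: int = 128
    buffer_capacity: int = 50
    seed: int = 0
    decay_start_epoch: int = 100
    weights: LossWeights = field(default_factory=LossWeights)
    checkpoint_every: int = 0  # epochs; 0 disables periodic checkpoints


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Initial rate through ``decay_start_epoch``, then linear decay reaching
    exactly zero at the final epoch (1-based epochs)."""
    if not 1 <= epoch <= config.epochs:
        raise ValueError(f"epoch must be in [1, {config.epochs}], got {epoch}")
    if epoch <= config.decay_start_epoch or config.epochs <= config.decay_start_epoch:
        return config.lr_initial
    span = config.epochs - config.decay_start_epoch
    return config.lr_initial * (1.0 - (epoch - config.decay_start_epoch) / span)


class ImageBuffer:
    """History pool of generated images used to update the discriminators.

    While filling, every query stores and returns its input. Once full, each
    query returns the new image with probability 0.5, otherwise returns a
    uniformly chosen stored image and replaces it with the new one.
    """

    def __init__(self, capacity: int = 50, rng: np.random.Generator | None = None):
        self.capacity = int(capacity)
        self.stored: list[np.ndarray] = []
        self.rng = rng or np.random.default_rng()

    def query(self, new_image: np.ndarray) -> np.ndarray:
        if len(self.stored) < self.capacity:
            self.stored.append(new_image.copy())
            return new_image
        if self.rng.random() < 0.5:
            return new_image
        idx = int(self.rng.integers(self.capacity))
        old = self.stored[idx]
        self.stored[idx] = new_image.copy()
        return old

    def __len__(self) -> int:
        return len(self.stored)


def augment(image: np.ndarray, crop: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random crop to crop x crop, then independent horizontal and
    vertical flips, each with probability 0.5."""
    h, w = image.shape
    if h < crop or w < crop:
        raise ValueError(f"image {h}x{w} smaller than crop {crop}")
    top = int(rng.integers(h - crop + 1))
    left = int(rng.integers(w - crop + 1))
    out = image[top : top + crop, left : left + crop]
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


# -- model adapters ---------------------------------------------------------------


class SwitchableModel:
    """Single generator; the domain code picks the synthesis direction."""

    kind = "switchable"

    def __init__(self, generator: Generator):
        if generator.coder is None:
            raise ValueError("switchable model requires a style coder")
        self.generator = generator

    def to_b(self, x: Tensor) -> Tensor:  # domain A -> B uses F(0)
        return self.generator.forward(x, 0.0)

    def to_a(self, x: Tensor) -> Tensor:  # domain B -> A uses F(1)
        return self.generator.forward(x, 1.0)

    def parameters(self) -> list[Tensor]:
        return self.generator.parameters()

    def a2b(self, image: np.ndarray) -> np.ndarray:
        with ag.no_grad():
            return self.to_b(Tensor(np.asarray(image, np.float32)[None, None])).data[0, 0]

    def b2a(self, image: np.ndarray) -> np.ndarray:
        with ag.no_grad():
            return self.to_a(Tensor(np.asarray(image, np.float32)[None, None])).data[0, 0]

    def state_dict(self) -> dict:
        return {f"model.{k}": v for k, v in self.generator.state_dict().items()}

    def load_state_dict(self, state: dict) -> None:
        self.generator.load_state_dict(
            {k[len("model."):]: v for k, v in state.items()})


class CycleGANModel:
    """Baseline: two independent fixed-style generators."""

    kind = "cyclegan"

    def __init__(self, g_ab: Generator, g_ba: Generator):
        self.g_ab, self.g_ba = g_ab, g_ba

    def to_b(self, x: Tensor) -> Tensor:
        return self.g_ab.forward(x)

    def to_a(self, x: Tensor) -> Tensor:
        return self.g_ba.forward(x)

    def parameters(self) -> list[Tensor]:
        return self.g_ab.parameters() + self.g_ba.parameters()

    def a2b(self, image: np.ndarray) -> np.ndarray:
        with ag.no_grad():
            return self.to_b(Tensor(np.asarray(image, np.float32)[None, None])).data[0, 0]

    def b2a(self, image: np.ndarray) -> np.ndarray:
        with ag.no_grad():
            return self.to_a(Tensor(np.asarray(image, np.float32)[None, None])).data[0, 0]

    def state_dict(self) -> dict:
        state = {f"model.ab.{k}": v for k, v in self.g_ab.state_dict().items()}
        state.update({f"model.ba.{k}": v for k, v in self.g_ba.state_dict().items()})
        return state

    def load_state_dict(self, state: dict) -> None:
        self.g_ab.load_state_dict(
            {k[len("model.ab."):]: v for k, v in state.items()
             if k.startswith("model.ab.")})
        self.g_ba.load_state_dict(
            {k[len("model.ba."):]: v for k, v in state.items()
             if k.startswith("model.ba.")})


def build_model(kind: str, config: GeneratorConfig | None = None, seed: int = 0):
    if kind == "switchable":
        return SwitchableModel(build_switchable_generator(config, seed))
    if kind == "cyclegan":
        return CycleGANModel(*build_cyclegan_pair(config, seed))
    raise ValueError(f"unknown model kind: {kind!r}")


# -- checkpoints -------------------------------------------------------------------


def save_checkpoint(path, model, d_a: Discriminator, d_b: Discriminator,
                    epoch: int, optimizers: dict | None = None) -> None:
    """Single .npz archive: model, both discriminators, epoch, optimizer state."""
    arrays: dict[str, np.ndarray] = {}
    arrays.update(model.state_dict())
    arrays.update({f"d_a.{k}": v for k, v in d_a.state_dict().items()})
    arrays.update({f"d_b.{k}": v for k, v in d_b.state_dict().items()})
    meta = {"epoch": int(epoch), "kind": model.kind, "format_version": 1}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8).copy()
    if optimizers:
        for name, opt in optimizers.items():
            st = opt.state_dict()
            arrays[f"opt.{name}.t"] = np.array([st["t"], st["lr"]])
            for i, (m, v) in enumerate(zip(st["m"], st["v"])):
                arrays[f"opt.{name}.m{i}"] = m
                arrays[f"opt.{name}.v{i}"] = v
    np.savez(path, **arrays)


def load_checkpoint(path, model, d_a: Discriminator, d_b: Discriminator) -> dict:
    """Restore networks in place; returns the checkpoint metadata."""
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(bytes(arrays.pop("meta_json")).decode())
    if meta.get("kind") != model.kind:
        raise ValueError(
            f"checkpoint holds a {meta.get('kind')!r} model, not {model.kind!r}")
    model.load_state_dict({k: v for k, v in arrays.items()
                           if k.startswith("model.")})
    d_a.load_state_dict({k[len("d_a."):]: v for k, v in arrays.items()
                         if k.startswith("d_a.")})
    d_b.load_state_dict({k[len("d_b."):]: v for k, v in arrays.items()
                         if k.startswith("d_b.")})
    return meta


# -- training loop -----------------------------------------------------------------


@dataclass
class TrainResult:
    model: object
    d_a: Discriminator
    d_b: Discriminator
    log: list[LossReport]

    def log_rows(self) -> list[list]:
        return [r.row() for r in self.log]

    def write_log_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(LossReport.FIELDS)
            writer.writerows(self.log_rows())


def train(manifest: DatasetManifest, model, d_a: Discriminator,
          d_b: Discriminator, config: TrainConfig,
          checkpoint_dir=None) -> TrainResult:
    """Alternating optimization of the generator(s) and both discriminators.

    ``model`` is a SwitchableModel or CycleGANModel. An epoch is one pass over
    the smaller domain's training list; both domain streams are reshuffled
    independently every epoch.
    """
    imgs_a = manifest.training_images("a")
    imgs_b = manifest.training_images("b")
    if not imgs_a or not imgs_b:
        raise ValueError("both domains need at least one training image")
    rng = np.random.default_rng(config.seed)
    opt_g = Adam(model.parameters(), config.lr_initial, config.beta1, config.beta2)
    opt_da = Adam(d_a.parameters(), config.lr_initial, config.beta1, config.beta2)
    opt_db = Adam(d_b.parameters(), config.lr_initial, config.beta1, config.beta2)
    buffer_a = ImageBuffer(config.buffer_capacity, rng)
    buffer_b = ImageBuffer(config.buffer_capacity, rng)
    weights = config.weights
    steps_per_epoch = min(len(imgs_a), len(imgs_b))
    log: list[LossReport] = []
    step = 0

    for epoch in range(1, config.epochs + 1):
        lr = lr_at_epoch(epoch, config)
        opt_g.lr = opt_da.lr = opt_db.lr = lr
        order_a = rng.permutation(len(imgs_a))
        order_b = rng.permutation(len(imgs_b))
        for i in range(steps_per_epoch):
            a = augment(imgs_a[order_a[i]], config.crop, rng)
            b = augment(imgs_b[order_b[i]], config.crop, rng)
            xa = Tensor(a[None, None].astype(np.float32))
            xb = Tensor(b[None, None].astype(np.float32))

            # generator (+ coder) update
            fake_b = model.to_b(xa)
            fake_a = model.to_a(xb)
            cyc_a = model.to_a(fake_b)
            cyc_b = model.to_b(fake_a)
            idt_b = model.to_b(xb)
            idt_a = model.to_a(xa)
            adv_g = (adversarial_loss_g(d_b.forward(fake_b))
                     + adversarial_loss_g(d_a.forward(fake_a)))
            cyc = cycle_loss(xa, cyc_a, xb, cyc_b)
            idl = identity_loss(xb, idt_b, xa, idt_a)
            total = total_generator_loss(adv_g, cyc, idl, weights)
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite generator loss at epoch {epoch}, step {i}: "
                    f"adv={adv_g.item()} cyc={cyc.item()} id={idl.item()}")
            for opt in (opt_g, opt_da, opt_db):
                opt.zero_grad()
            total.backward()
            opt_g.step()

            # discriminator updates with replay-buffer (detached) fakes
            fa_hist = buffer_a.query(fake_a.data[0, 0])
            fb_hist = buffer_b.query(fake_b.data[0, 0])
            loss_da = adversarial_loss_d(
                d_a.forward(xa), d_a.forward(Tensor(fa_hist[None, None])))
            opt_da.zero_grad()
            loss_da.backward()
            opt_da.step()
            loss_db = adversarial_loss_d(
                d_b.forward(xb), d_b.forward(Tensor(fb_hist[None, None])))
            opt_db.zero_grad()
            loss_db.backward()
            opt_db.step()

            step += 1
            log.append(LossReport(step=step, epoch=epoch, adv_g=adv_g.item(),
                                  adv_d_a=loss_da.item(), adv_d_b=loss_db.item(),
                                  cyc=cyc.item(), id=idl.item(),
                                  total=total.item()))
        if (checkpoint_dir is not None and config.checkpoint_every
                and epoch % config.checkpoint_every == 0):
            from pathlib import Path

            path = Path(checkpoint_dir) / f"checkpoint_epoch{epoch:04d}.npz"
            save_checkpoint(path, model, d_a, d_b, epoch,
                            {"g": opt_g, "d_a": opt_da, "d_b": opt_db})
    return TrainResult(model=model, d_a=d_a, d_b=d_b, log=log)
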