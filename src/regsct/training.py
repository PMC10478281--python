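"""Adversarial training with registration-corrected noisy labels.

Each step takes one CBCT/planning-CT pair (batch size 1, the regime the
method was designed for): the discriminator is updated first on its
least-squares real/fake term, then the generator and registration network
are updated jointly on the weighted sum of correction, smoothness and
adversarial terms.  Adam with lr 1e-4, betas (0.5, 0.999) and weight decay
1e-4 throughout.  The registration network is a training-time-only device:
inference applies the generator alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import CheckpointError, ConfigurationError
from .losses import LossWeights, adversarial_terms, smoothness_loss, total_loss
from .metrics import mae
from .networks import (DiscriminatorConfig, GeneratorConfig, RegistrationConfig,
                       build_discriminator, build_generator, build_registration)
from .optim import Adam
from .preprocess import HU_WINDOW, HUImage, clip_hu, normalize, resample_to
from .warp import warp_tensor

__all__ = [
    "TrainConfig", "ModelConfigs", "TrainState", "train", "translate",
    "save_checkpoint", "load_checkpoint", "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    adam_betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 1
    weight_decay: float = 1e-4
    epochs: int = 80
    seed: int = 0
    image_size: int = 256

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.image_size < 8 or self.image_size % 8:
            raise ConfigurationError("image_size must be a multiple of 8 and >= 8")


@dataclass(frozen=True)
class ModelConfigs:
    generator: GeneratorConfig = GeneratorConfig()
    registration: RegistrationConfig = RegistrationConfig()
    discriminator: DiscriminatorConfig = DiscriminatorConfig()


@dataclass
class TrainState:
    iteration: int = 0
    epoch_losses: list = field(default_factory=list)  # dicts: corr/smooth/adv_g/adv_d
    val_mae: list = field(default_factory=list)
    best_val_mae: float = float("inf")
    best_epoch: int = -1


def _prepare(img: HUImage, size: int) -> np.ndarray:
    """clip -> resample -> normalize; returns (1, 1, size, size) float32."""
    n = normalize(resample_to(clip_hu(img), size))
    return n.values[None, None].astype(np.float32)


class Checkpoint:
    """In-memory bundle of the three networks plus their configs."""

    def __init__(self, generator, registration, discriminator,
                 model_cfgs: ModelConfigs, image_size: int,
                 window: tuple[float, float] = HU_WINDOW):
        self.generator = generator
        self.registration = registration
        self.discriminator = discriminator
        self.model_cfgs = model_cfgs
        self.image_size = image_size
        self.window = window


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    meta = {
        "version": CHECKPOINT_VERSION,
        "image_size": ckpt.image_size,
        "window": list(ckpt.window),
        "generator": asdict(ckpt.model_cfgs.generator),
        "registration": asdict(ckpt.model_cfgs.registration),
        "discriminator": asdict(ckpt.model_cfgs.discriminator),
    }
    arrays = {}
    for tag, net in (("g", ckpt.generator), ("r", ckpt.registration), ("d", ckpt.discriminator)):
        for i, a in enumerate(net.state_arrays()):
            arrays[f"{tag}_{i}"] = a
    np.savez(path, meta=np.bytes_(json.dumps(meta).encode()), **arrays)


def load_checkpoint(path) -> Checkpoint:
    try:
        data = np.load(path, allow_pickle=False)
    except (OSError, ValueError) as exc:
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if "meta" not in data:
        raise CheckpointError(f"{path} is not a model checkpoint (no meta entry)")
    meta = json.loads(bytes(data["meta"]).decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint version {meta.get('version')} != supported {CHECKPOINT_VERSION}")
    cfgs = ModelConfigs(
        generator=GeneratorConfig(**meta["generator"]),
        registration=RegistrationConfig(**meta["registration"]),
        discriminator=DiscriminatorConfig(**meta["discriminator"]),
    )
    gen = build_generator(cfgs.generator)
    reg = build_registration(cfgs.registration)
    disc = build_discriminator(cfgs.discriminator)
    for tag, net in (("g", gen), ("r", reg), ("d", disc)):
        arrays = []
        i = 0
        while f"{tag}_{i}" in data:
            arrays.append(data[f"{tag}_{i}"])
            i += 1
        net.load_state_arrays(arrays)
    return Checkpoint(gen, reg, disc, cfgs, int(meta["image_size"]),
                      tuple(meta["window"]))


def train(dataset, train_cfg: TrainConfig, weights: LossWeights,
          model_cfgs: ModelConfigs | None = None, val_dataset=None,
          checkpoint_path=None, log_every: int = 0) -> tuple[TrainState, Checkpoint]:
    """Run the alternating D / (G, R) update loop over paired samples.

    Samples are visited in a seeded random order each epoch.  Per-epoch
    validation MAE (HU) is logged when ``val_dataset`` is given, and the
    checkpoint snapshot with the lowest validation MAE is the one returned.
    """
    dataset = list(dataset)
    if not dataset:
        raise ConfigurationError("training dataset is empty")
    train_cfg.validate()
    weights.validate()
    cfgs = model_cfgs or ModelConfigs()

    rng = np.random.default_rng(train_cfg.seed)
    gen = build_generator(cfgs.generator, seed=int(rng.integers(2 ** 31)))
    reg = build_registration(cfgs.registration, seed=int(rng.integers(2 ** 31)))
    disc = build_discriminator(cfgs.discriminator, seed=int(rng.integers(2 ** 31)))

    opt_gr = Adam(gen.parameters() + reg.parameters(), lr=train_cfg.learning_rate,
                  betas=train_cfg.adam_betas, weight_decay=train_cfg.weight_decay)
    opt_d = Adam(disc.parameters(), lr=train_cfg.learning_rate,
                 betas=train_cfg.adam_betas, weight_decay=train_cfg.weight_decay)

    size = train_cfg.image_size
    xs = [_prepare(s.cbct, size) for s in dataset]
    ys = [_prepare(s.pct, size) for s in dataset]

    state = TrainState()
    ckpt = Checkpoint(gen, reg, disc, cfgs, size)
    best_arrays = None

    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(dataset))
        sums = {"corr": 0.0, "smooth": 0.0, "adv_g": 0.0, "adv_d": 0.0}
        for idx in order:
            x = Tensor(xs[idx])
            y = Tensor(ys[idx])

            fake = gen(x)

            # -- discriminator step (fake detached) -----------------------
            if weights.w_adv > 0:
                _, d_term = adversarial_terms(disc(y), disc(fake.detach()))
                disc.zero_grad()
                d_term.backward()
                opt_d.step()
                sums["adv_d"] += d_term.item()

            # -- joint generator + registration step ----------------------
            field_t = reg(fake, y)
            warped = warp_tensor(fake, field_t)
            corr = ad.mean(ad.absolute(y - warped))
            smooth = smoothness_loss(field_t)
            if weights.w_adv > 0:
                g_term = ad.mean(ad.square(disc(fake) - 1.0))
            else:
                g_term = Tensor(np.float32(0.0))
            loss = total_loss((corr, smooth, g_term), weights)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged: non-finite loss at iteration {state.iteration}")
            gen.zero_grad()
            reg.zero_grad()
            disc.zero_grad()
            loss.backward()
            opt_gr.step()

            sums["corr"] += corr.item()
            sums["smooth"] += smooth.item()
            sums["adv_g"] += g_term.item()
            state.iteration += 1

        n = len(dataset)
        state.epoch_losses.append({k: v / n for k, v in sums.items()})
        if log_every and (epoch + 1) % log_every == 0:
            print(f"epoch {epoch + 1}/{train_cfg.epochs}: "
                  + ", ".join(f"{k}={v / n:.4f}" for k, v in sums.items()))

        if val_dataset is not None:
            val = float(np.mean([
                mae(translate(s.cbct, ckpt), s.pct) for s in val_dataset]))
            state.val_mae.append(val)
            if val < state.best_val_mae:
                state.best_val_mae = val
                state.best_epoch = epoch
                best_arrays = [a.copy() for a in gen.state_arrays()]

    if best_arrays is not None:
        gen.load_state_arrays(best_arrays)
    if checkpoint_path is not None:
        save_checkpoint(ckpt, checkpoint_path)
    return state, ckpt


def translate(cbct: HUImage, checkpoint: Checkpoint) -> HUImage:
    """CBCT -> sCT: preprocess, apply the generator alone, restore HU.

    The registration and discriminator networks play no role at inference.
    Output is resampled back onto the input grid.
    """
    original_size = cbct.values.shape[0]
    if cbct.values.shape[0] != cbct.values.shape[1]:
        raise ConfigurationError("translate expects square slices")
    x = _prepare(cbct, checkpoint.image_size)
    out = checkpoint.generator(Tensor(x)).data[0, 0]
    lo, hi = checkpoint.window
    hu = (out.astype(np.float64) + 1.0) / 2.0 * (hi - lo) + lo
    sct = HUImage(hu.astype(np.float32), cbct.spacing)
    return resample_to(sct, original_size)
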