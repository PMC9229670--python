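"""Adversarial training of the segmentation generator.

The generator G maps a normalized slice x (plus noise realized as bottleneck
dropout) to a segmentation map in tanh range; the discriminator D judges
(slice, map) pairs patch-wise.  Objectives:

* G minimizes  BCE(D(x, G(x)), 1) + lambda * L1(G(x), y)   with lambda = 75,
  i.e. the adversarial term plus a strongly weighted mean-absolute-error term
  (class imbalance makes the plain adversarial signal weak).
* D minimizes  pace * 1/2 [BCE(D(x, y), 1) + BCE(D(x, G(x)), 0)]  with
  pace = 0.5 — D's objective is halved so it does not outrun G.

Each step updates D first (G frozen: the generated map is detached), then G
through a frozen D (D's gradients are discarded, its weights untouched).
G uses Adam (lr 2e-4, beta1 0.9, beta2 0.999); D uses RMSProp (same lr,
momentum 0.9).  An optional exponential learning-rate schedule multiplies
the rate by 0.96 each epoch.  After training only the generator is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentConfig, augment_pair
from .evaluate import confusion_counts, dice
from .networks import (
    DiscriminatorConfig,
    GeneratorConfig,
    NetworkHandle,
    build_discriminator,
    build_generator,
)
from .preprocess import (
    BinaryMask,
    PreprocessConfig,
    SliceImage,
    VolumeStack,
    normalize_for_network,
    preprocess_volume,
)


@dataclass
class TrainConfig:
    lambda_l1: float = 75.0
    lr: float = 2e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    rmsprop_rho: float = 0.9
    rmsprop_momentum: float = 0.9
    d_pace_factor: float = 0.5
    batch_size: int = 10
    epochs: int = 100
    lr_schedule_decay: float | None = 0.96  # per-epoch exponential; None disables
    early_stop_patience: int | None = 10    # epochs without val-Dice improvement
    dropout_at_inference: bool = False
    seed: int = 0

    def validate(self) -> "TrainConfig":
        if self.lambda_l1 < 0:
            raise ValueError("train.lambda_l1 must be nonnegative")
        if self.lr < 0:
            raise ValueError("train.lr must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("train.batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("train.epochs must be >= 1")
        if not 0.0 < self.d_pace_factor <= 1.0:
            raise ValueError("train.d_pace_factor must be in (0, 1]")
        if self.lr_schedule_decay is not None and not 0.0 < self.lr_schedule_decay <= 1.0:
            raise ValueError("train.lr_schedule_decay must be in (0, 1]")
        if self.early_stop_patience is not None and self.early_stop_patience < 1:
            raise ValueError("train.early_stop_patience must be >= 1")
        return self


@dataclass
class TrainState:
    generator: NetworkHandle
    discriminator: NetworkHandle
    g_opt: nn.Adam
    d_opt: nn.RMSProp
    cfg: TrainConfig
    epoch: int = 0
    history: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _wrap(x) -> nn.Tensor:
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, dtype=np.float32))


def l1_loss(pred, target) -> nn.Tensor:
    """Mean absolute difference over all pixels in the batch."""
    pred, target = _wrap(pred), _wrap(target)
    if pred.shape != target.shape:
        raise ValueError("l1_loss: shape mismatch")
    return nn.mean(nn.absolute(nn.sub(pred, target)))


def _check_probability_map(d_out) -> None:
    data = d_out.data if isinstance(d_out, nn.Tensor) else np.asarray(d_out)
    if data.min() < 0.0 or data.max() > 1.0:
        raise ValueError("discriminator output must lie in (0, 1)")


def generator_loss(d_on_fake, pred, target, lambda_l1: float = 75.0):
    """(total, adversarial, l1): BCE of D's verdicts against all-ones labels
    plus lambda times the L1 term."""
    _check_probability_map(d_on_fake)
    adv = nn.binary_cross_entropy(_wrap(d_on_fake), 1.0)
    l1 = l1_loss(pred, target)
    total = nn.add(adv, nn.mul(l1, float(lambda_l1)))
    return total, adv, l1


def discriminator_loss(d_on_real, d_on_fake, pace_factor: float = 0.5) -> nn.Tensor:
    """pace * 1/2 [BCE(real, 1) + BCE(fake, 0)]; outputs at exactly 0 or 1 are
    epsilon-clamped inside the BCE."""
    _check_probability_map(d_on_real)
    _check_probability_map(d_on_fake)
    bce_real = nn.binary_cross_entropy(_wrap(d_on_real), 1.0)
    bce_fake = nn.binary_cross_entropy(_wrap(d_on_fake), 0.0)
    return nn.mul(nn.add(bce_real, bce_fake), 0.5 * float(pace_factor))


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def make_train_state(
    train_cfg: TrainConfig | None = None,
    generator_cfg: GeneratorConfig | None = None,
    discriminator_cfg: DiscriminatorConfig | None = None,
) -> TrainState:
    train_cfg = (train_cfg or TrainConfig()).validate()
    seeds = np.random.SeedSequence(train_cfg.seed).generate_state(2)
    gen = build_generator(generator_cfg, seed=int(seeds[0]) % (2**31))
    disc = build_discriminator(discriminator_cfg, seed=int(seeds[1]) % (2**31))
    g_opt = nn.Adam(
        gen.model.parameters(), lr=train_cfg.lr,
        beta1=train_cfg.adam_beta1, beta2=train_cfg.adam_beta2,
    )
    d_opt = nn.RMSProp(
        disc.model.parameters(), lr=train_cfg.lr,
        rho=train_cfg.rmsprop_rho, momentum=train_cfg.rmsprop_momentum,
    )
    return TrainState(gen, disc, g_opt, d_opt, train_cfg)


def train_step(batch_x: np.ndarray, batch_y: np.ndarray, state: TrainState) -> dict:
    """One alternating update: D on (real, detached-fake), then G through a
    frozen D.  ``batch_x``/``batch_y`` are (B, 1, H, W) arrays in tanh range.
    Returns the step's losses."""
    cfg = state.cfg
    g_model, d_model = state.generator.model, state.discriminator.model
    g_model.train()
    d_model.train()
    x = nn.Tensor(batch_x)
    y = np.asarray(batch_y, dtype=np.float32)

    fake = g_model(x)

    # -- discriminator update (generator frozen via detach) -----------------
    d_real = d_model(nn.concat([x, nn.Tensor(y)], axis=1))
    d_fake = d_model(nn.concat([x, fake.detach()], axis=1))
    d_loss = discriminator_loss(d_real, d_fake, cfg.d_pace_factor)
    d_model.zero_grad()
    d_loss.backward()
    state.d_opt.step()

    # -- generator update (discriminator weights untouched) -----------------
    d_on_fake = d_model(nn.concat([x, fake], axis=1))
    g_total, g_adv, g_l1 = generator_loss(d_on_fake, fake, y, cfg.lambda_l1)
    g_model.zero_grad()
    d_model.zero_grad()  # discard any D gradients before G's backward pass
    g_total.backward()
    state.g_opt.step()   # holds only G's parameters
    d_model.zero_grad()

    losses = {
        "g_total": g_total.item(),
        "g_adv": g_adv.item(),
        "g_l1": g_l1.item(),
        "d_loss": d_loss.item(),
    }
    if not all(np.isfinite(v) for v in losses.values()):
        raise FloatingPointError(f"non-finite loss encountered: {losses}")
    return losses


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_volume(
    generator: NetworkHandle,
    volume: VolumeStack,
    preprocess_cfg: PreprocessConfig | None = None,
    batch_size: int = 10,
    dropout_at_inference: bool = False,
) -> VolumeStack:
    """Segment a volume: (optional) preprocessing, forward pass, binarize the
    tanh output at 0.  Returns a {0,1} stack at model resolution."""
    if preprocess_cfg is not None:
        volume = preprocess_volume(volume, preprocess_cfg)
    model = generator.model
    model.train(dropout_at_inference)
    arr = volume.as_array()
    lo, hi = volume.value_range
    net_in = ((arr - lo) / (hi - lo) * 2.0 - 1.0).astype(np.float32)[:, None]
    out = []
    for start in range(0, net_in.shape[0], batch_size):
        y = model(nn.Tensor(net_in[start : start + batch_size]))
        out.append((y.data[:, 0] > 0.0).astype(np.float32))
    model.train(True)
    return VolumeStack.from_array(
        np.concatenate(out, axis=0), value_range=(0.0, 1.0), spacing_mm=volume.spacing_mm
    )


def _volume_pairs_to_slices(
    volumes: list[tuple[VolumeStack, VolumeStack]]
) -> list[tuple[SliceImage, BinaryMask]]:
    pairs = []
    for img_vol, mask_vol in volumes:
        for img_sl, m_sl in zip(img_vol.slices, mask_vol.slices):
            pairs.append((img_sl, BinaryMask(m_sl.pixels)))
    return pairs


def _validation_dice(generator, val_volumes, batch_size) -> float | None:
    vals = []
    for img_vol, mask_vol in val_volumes:
        pred = predict_volume(generator, img_vol, batch_size=batch_size)
        d = dice(confusion_counts(pred, mask_vol.as_array().astype(np.uint8)))
        if d is not None:
            vals.append(d)
    return float(np.mean(vals)) if vals else None


def fit(
    train_volumes: list[tuple[VolumeStack, VolumeStack]],
    val_volumes: list[tuple[VolumeStack, VolumeStack]],
    train_cfg: TrainConfig | None = None,
    generator_cfg: GeneratorConfig | None = None,
    discriminator_cfg: DiscriminatorConfig | None = None,
    augment_cfg: AugmentConfig | None = None,
    verbose: bool = False,
) -> tuple[NetworkHandle, pd.DataFrame]:
    """Train on slice batches with on-the-fly augmentation; validate per epoch
    with the pooled Dice score.  The discriminator is discarded afterwards —
    inference needs only the generator.

    Volumes are (image, mask) stacks on a [0,1]-like declared scale; they are
    normalized to tanh range internally.  Augmented copies are drawn fresh
    each epoch from the run seed and never touch the validation volumes.
    """
    train_cfg = (train_cfg or TrainConfig()).validate()
    augment_cfg = (augment_cfg or AugmentConfig()).validate()
    if not train_volumes:
        raise ValueError("empty training set")
    state = make_train_state(train_cfg, generator_cfg, discriminator_cfg)
    rng = np.random.default_rng(np.random.SeedSequence(train_cfg.seed).spawn(1)[0])

    base_pairs = _volume_pairs_to_slices(train_volumes)
    lr0 = train_cfg.lr
    best_dice, best_epoch, best_weights = -np.inf, -1, None

    for epoch in range(train_cfg.epochs):
        if train_cfg.lr_schedule_decay is not None:
            lr = lr0 * train_cfg.lr_schedule_decay**epoch
            state.g_opt.lr = lr
            state.d_opt.lr = lr
        # on-the-fly expansion: originals + fresh augmented copies
        pairs = list(base_pairs)
        for img, mask in base_pairs:
            for _ in range(augment_cfg.copies_per_sample):
                pairs.append(augment_pair(img, mask, augment_cfg, rng))
        order = rng.permutation(len(pairs))
        sums = {"g_total": 0.0, "g_adv": 0.0, "g_l1": 0.0, "d_loss": 0.0}
        n_batches = 0
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            xb = np.stack(
                [normalize_for_network(pairs[i][0]).pixels for i in idx]
            )[:, None]
            yb = np.stack(
                [pairs[i][1].pixels.astype(np.float32) * 2.0 - 1.0 for i in idx]
            )[:, None]
            losses = train_step(xb, yb, state)
            for k in sums:
                sums[k] += losses[k]
            n_batches += 1
        row = {k: v / n_batches for k, v in sums.items()}
        row["epoch"] = epoch
        row["val_dice"] = _validation_dice(
            state.generator, val_volumes, train_cfg.batch_size
        )
        state.history.append(row)
        state.epoch = epoch + 1
        if verbose:  # pragma: no cover - console feedback only
            print(
                f"epoch {epoch}: g_total={row['g_total']:.4f} "
                f"d_loss={row['d_loss']:.4f} val_dice={row['val_dice']}"
            )
        vd = row["val_dice"]
        if vd is not None and vd > best_dice:
            best_dice, best_epoch = vd, epoch
            best_weights = state.generator.model.state_dict()
        if (
            train_cfg.early_stop_patience is not None
            and best_epoch >= 0
            and epoch - best_epoch >= train_cfg.early_stop_patience
        ):
            break
    if best_weights is not None:
        state.generator.model.load_state_dict(best_weights)
    history = pd.DataFrame(
        state.history, columns=["epoch", "g_total", "g_adv", "g_l1", "d_loss", "val_dice"]
    )
    return state.generator, history
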