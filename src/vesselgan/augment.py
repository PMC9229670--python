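"""Training-set augmentation: mirror flips and random patch-zoom.

Two geometric transforms expand the training slices: a left-right mirror
flip (plausible for the brain's lateral symmetry), and patch extraction — a
random zoom factor between 1x and 2x picks a random sub-window that is
resized back to the full slice size.  Every transform is applied identically
to the image and its mask; masks are resampled nearest-neighbor so they stay
binary.  Augmentation only ever touches training data — the volume-level
split happens before expansion, so validation folds see original slices only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BinaryMask, SliceImage, resize_slice


@dataclass
class AugmentConfig:
    enable_flip: bool = True
    enable_patch: bool = True
    zoom_range: tuple[float, float] = (1.0, 2.0)
    copies_per_sample: int = 2
    seed: int = 0

    def validate(self) -> "AugmentConfig":
        lo, hi = self.zoom_range
        if lo < 1.0 or hi < lo:
            raise ValueError("augment.zoom_range must satisfy 1.0 <= lo <= hi")
        if self.copies_per_sample < 0:
            raise ValueError("augment.copies_per_sample must be nonnegative")
        return self


def mirror_flip(img: SliceImage, mask: BinaryMask) -> tuple[SliceImage, BinaryMask]:
    """Left-right mirror of the slice and its mask (an involution)."""
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    return (
        SliceImage(img.pixels[:, ::-1].copy(), img.value_range),
        BinaryMask(mask.pixels[:, ::-1].copy()),
    )


def random_patch_zoom(
    img: SliceImage,
    mask: BinaryMask,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[SliceImage, BinaryMask]:
    """Crop a random window of side round(side/z), z ~ U(zoom_range), and
    resize it back to the original slice size (bilinear image, nearest mask)."""
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    cfg.validate()
    h, w = img.shape
    z = rng.uniform(*cfg.zoom_range)
    ph, pw = int(round(h / z)), int(round(w / z))
    if ph < 2 or pw < 2:
        raise ValueError("zoomed patch smaller than 2 pixels")
    top = int(rng.integers(0, h - ph + 1))
    left = int(rng.integers(0, w - pw + 1))
    if (ph, pw) == (h, w):
        return (
            SliceImage(img.pixels.copy(), img.value_range),
            BinaryMask(mask.pixels.copy()),
        )
    img_patch = SliceImage(img.pixels[top : top + ph, left : left + pw], img.value_range)
    mask_patch = BinaryMask(mask.pixels[top : top + ph, left : left + pw])
    return (
        resize_slice(img_patch, h),
        resize_slice(mask_patch, h, is_mask=True),
    )


def augment_pair(
    img: SliceImage,
    mask: BinaryMask,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[SliceImage, BinaryMask]:
    """One random augmented variant drawn from the enabled transforms."""
    choices = []
    if cfg.enable_flip:
        choices.append("flip")
    if cfg.enable_patch:
        choices.append("patch")
    if not choices:
        return SliceImage(img.pixels.copy(), img.value_range), BinaryMask(mask.pixels.copy())
    pick = choices[int(rng.integers(0, len(choices)))]
    if pick == "flip":
        return mirror_flip(img, mask)
    return random_patch_zoom(img, mask, cfg, rng)


def expand_dataset(
    pairs: list[tuple[SliceImage, BinaryMask]], cfg: AugmentConfig
) -> list[tuple[SliceImage, BinaryMask]]:
    """All originals plus ``copies_per_sample`` augmented variants per slice."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out = list(pairs)
    for img, mask in pairs:
        for _ in range(cfg.copies_per_sample):
            out.append(augment_pair(img, mask, cfg, rng))
    return out
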