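"""Region-of-interest masking, resizing, normalization and CLAHE.

Angiography slices carry low-level background noise outside the head.  The
ROI step suppresses it: pixels below an intensity threshold (default 10 on a
0-255 scale) are zeroed, the resulting binary map is morphologically closed
with a k x k structuring element (default k = 9) to fill holes, and the mask
multiplies the original slice.  Slices are then resized (default 256 x 256,
bilinear for images / nearest-neighbor for masks so masks stay binary) and
affinely normalized to the network's tanh range [-1, 1].  An optional CLAHE
pass (contrast-limited adaptive histogram equalization) is provided for
low-contrast modalities such as two-photon microscopy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology
from skimage.transform import resize as _sk_resize


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SliceImage:
    """One 2-D grayscale slice with its declared intensity range."""

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("SliceImage.pixels must be 2-D")
        lo, hi = self.value_range
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("SliceImage contains non-finite values")
        if self.pixels.size and (self.pixels.min() < lo or self.pixels.max() > hi):
            raise ValueError("SliceImage values outside the declared range")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A {0,1} segmentation map."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("BinaryMask admits only values 0 and 1")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class VolumeStack:
    """Ordered slices of identical shape forming one subject volume."""

    slices: list[SliceImage]
    spacing_mm: float = 0.5
    value_range: tuple[float, float] = field(default=(0.0, 1.0))

    def __post_init__(self):
        if not self.slices:
            raise ValueError("VolumeStack must contain at least one slice")
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError("all slices in a VolumeStack must share one shape")

    @classmethod
    def from_array(cls, data: np.ndarray, value_range=(0.0, 1.0), spacing_mm: float = 0.5):
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError("expected a (n_slices, height, width) array")
        return cls(
            [SliceImage(sl, value_range) for sl in data],
            spacing_mm=spacing_mm,
            value_range=value_range,
        )

    def as_array(self) -> np.ndarray:
        return np.stack([s.pixels for s in self.slices])

    @property
    def shape(self):
        return (len(self.slices),) + self.slices[0].shape


@dataclass
class PreprocessConfig:
    threshold: float = 10.0          # on the raw intensity scale
    closure_kernel: int = 9          # structuring element side, odd
    kernel_shape: str = "square"     # "square" | "disk"
    target_size: int = 256
    normalize_range: tuple[float, float] = (-1.0, 1.0)
    clahe_enabled: bool = False
    clahe_clip: float = 0.01
    clahe_tiles: int = 8

    def validate(self) -> "PreprocessConfig":
        k = self.closure_kernel
        if k < 1 or k % 2 == 0:
            raise ValueError("preprocess.closure_kernel must be odd and >= 1")
        if self.kernel_shape not in ("square", "disk"):
            raise ValueError("preprocess.kernel_shape must be 'square' or 'disk'")
        if self.target_size < 16:
            raise ValueError("preprocess.target_size must be >= 16")
        lo, hi = self.normalize_range
        if not lo < hi:
            raise ValueError("preprocess.normalize_range must satisfy lo < hi")
        if self.clahe_clip <= 0 or self.clahe_tiles < 1:
            raise ValueError("preprocess CLAHE parameters must be positive")
        return self


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _structuring_element(cfg: PreprocessConfig) -> np.ndarray:
    k = cfg.closure_kernel
    if cfg.kernel_shape == "disk":
        return morphology.disk(k // 2).astype(bool)
    return np.ones((k, k), dtype=bool)


def morphological_closure(binary: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """Dilation then erosion.  Outside the image the dilation sees background
    (zeros, the dark MRA border) while the erosion sees foreground (ones), the
    convention under which a solid image stays solid."""
    dil = ndimage.binary_dilation(binary, structure=selem, border_value=0)
    return ndimage.binary_erosion(dil, structure=selem, border_value=1)


def make_roi_mask(img: SliceImage, cfg: PreprocessConfig | None = None) -> BinaryMask:
    """Threshold-and-close ROI mask: keep pixels >= threshold, then fill holes
    with a morphological closure."""
    cfg = (cfg or PreprocessConfig()).validate()
    lo, hi = img.value_range
    if not lo <= cfg.threshold <= hi:
        warnings.warn(
            f"threshold {cfg.threshold} lies outside the slice's declared "
            f"intensity range [{lo}, {hi}]; the mask may be trivial",
            stacklevel=2,
        )
    binary = img.pixels >= cfg.threshold
    closed = morphological_closure(binary, _structuring_element(cfg))
    return BinaryMask(closed.astype(np.uint8))


def apply_mask(img: SliceImage, mask: BinaryMask) -> SliceImage:
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    return SliceImage(img.pixels * mask.pixels, img.value_range)


def _nearest_indices(src: int, dst: int) -> np.ndarray:
    # top-left sample convention: output i reads source floor(i*src/dst)
    return (np.arange(dst) * src) // dst


def resize_slice(img: SliceImage | BinaryMask, target_size: int, is_mask: bool = False):
    """Resize to target_size x target_size: bilinear for images,
    nearest-neighbor for masks (so they remain strictly binary)."""
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    px = img.pixels
    if is_mask or isinstance(img, BinaryMask):
        rows = _nearest_indices(px.shape[0], target_size)
        cols = _nearest_indices(px.shape[1], target_size)
        out = px[np.ix_(rows, cols)]
        return BinaryMask(out) if isinstance(img, BinaryMask) else SliceImage(out, img.value_range)
    out = _sk_resize(
        px.astype(np.float64),
        (target_size, target_size),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    lo, hi = img.value_range
    return SliceImage(np.clip(out, lo, hi).astype(np.float32), img.value_range)


def clahe_enhance(img: SliceImage, cfg: PreprocessConfig | None = None) -> SliceImage:
    """Contrast-limited adaptive histogram equalization, tile-wise, output on
    the same declared scale as the input."""
    cfg = (cfg or PreprocessConfig()).validate()
    lo, hi = img.value_range
    if hi <= lo:
        raise ValueError("degenerate value range")
    unit = (img.pixels - lo) / (hi - lo)
    if np.ptp(unit) == 0:
        return SliceImage(img.pixels.copy(), img.value_range)
    tile = max(1, int(np.ceil(img.pixels.shape[0] / cfg.clahe_tiles)))
    tile_w = max(1, int(np.ceil(img.pixels.shape[1] / cfg.clahe_tiles)))
    out = exposure.equalize_adapthist(
        unit, kernel_size=(tile, tile_w), clip_limit=cfg.clahe_clip
    )
    return SliceImage((out * (hi - lo) + lo).astype(np.float32), img.value_range)


def normalize_for_network(
    img: SliceImage, normalize_range: tuple[float, float] = (-1.0, 1.0)
) -> SliceImage:
    """Affine map of the declared intensity range onto ``normalize_range``."""
    lo, hi = img.value_range
    if hi == lo:
        raise ValueError("degenerate declared range")
    a, b = normalize_range
    if not a < b:
        raise ValueError("normalize_range must satisfy lo < hi")
    out = (img.pixels - lo) / (hi - lo) * (b - a) + a
    return SliceImage(out.astype(np.float32), (a, b))


def denormalize(img: SliceImage, value_range: tuple[float, float]) -> SliceImage:
    """Inverse of :func:`normalize_for_network`."""
    a, b = img.value_range
    lo, hi = value_range
    out = (img.pixels - a) / (b - a) * (hi - lo) + lo
    return SliceImage(out.astype(np.float32), value_range)


def preprocess_volume(
    vol: VolumeStack, cfg: PreprocessConfig | None = None, is_mask: bool = False
) -> VolumeStack:
    """ROI-mask (images only), optional CLAHE, then resize every slice.
    The ROI mask is computed at native resolution before resizing."""
    cfg = (cfg or PreprocessConfig()).validate()
    out = []
    for sl in vol.slices:
        if is_mask:
            m = resize_slice(BinaryMask(sl.pixels), cfg.target_size, is_mask=True)
            out.append(SliceImage(m.pixels.astype(np.float32), (0.0, 1.0)))
            continue
        roi = apply_mask(sl, make_roi_mask(sl, cfg))
        if cfg.clahe_enabled:
            roi = clahe_enhance(roi, cfg)
        out.append(resize_slice(roi, cfg.target_size))
    rng_ = (0.0, 1.0) if is_mask else vol.value_range
    return VolumeStack(out, spacing_mm=vol.spacing_mm, value_range=rng_)
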