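"""White balance, fruit segmentation and channel-mean extraction.

Images show fruit clusters on a saturated blue background, optionally
with a white reference patch.  The processing chain is:

1. white-balance the image so the reference patch maps to (255, 255, 255);
2. segment fruit from background by thresholding the CIELAB b* channel
   (the blue background has a strongly negative b*, fruit tissue does
   not), followed by a morphological opening and small-object removal;
3. average each channel over the fruit mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, morphology
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "WhiteBalanceGains",
    "FruitMask",
    "ChannelMeans",
    "DegeneratePatchError",
    "NoFruitError",
    "compute_white_balance",
    "apply_white_balance",
    "segment_fruit",
    "extract_channel_means",
]


class DegeneratePatchError(ValueError):
    """The white patch has a zero channel mean; gains are undefined."""


class NoFruitError(ValueError):
    """Segmentation produced an empty mask."""


@dataclass(frozen=True)
class WhiteBalanceGains:
    gain_r: float
    gain_g: float
    gain_b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.gain_r, self.gain_g, self.gain_b], dtype=float)


@dataclass(frozen=True)
class FruitMask:
    mask: np.ndarray  # boolean (H, W)
    n_components: int
    area_px: int


@dataclass(frozen=True)
class ChannelMeans:
    r_mean: float
    g_mean: float
    b_mean: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r_mean, self.g_mean, self.b_mean)


def _patch_slice(patch_region: tuple[int, int, int, int]):
    """Half-open (x, y, w, h) rectangle, origin top-left, as array slices."""
    x, y, w, h = patch_region
    if w <= 0 or h <= 0:
        raise ValueError("patch_region must have positive width and height")
    return slice(y, y + h), slice(x, x + w)


def compute_white_balance(
    image: np.ndarray, patch_region: tuple[int, int, int, int]
) -> WhiteBalanceGains:
    """Per-channel gains mapping the reference-patch mean to pure white."""
    image = _check_image(image)
    ys, xs = _patch_slice(patch_region)
    patch = image[ys, xs]
    if patch.size == 0:
        raise ValueError("patch_region lies outside the image")
    means = patch.reshape(-1, 3).mean(axis=0)
    if np.any(means == 0):
        raise DegeneratePatchError(f"patch channel means {tuple(means)} contain zero")
    gains = 255.0 / means
    return WhiteBalanceGains(*gains)


def apply_white_balance(image: np.ndarray, gains: WhiteBalanceGains) -> np.ndarray:
    """Multiply channels by their gains; clip to [0, 255], round half-up."""
    image = _check_image(image)
    corrected = image.astype(float) * gains.as_array()
    return np.clip(np.floor(corrected + 0.5), 0, 255).astype(np.uint8)


def segment_fruit(
    image: np.ndarray,
    b_star_threshold: float | str = -15.0,
    min_area_px: int = 16,
    patch_region: tuple[int, int, int, int] | None = None,
) -> FruitMask:
    """Segment fruit pixels by thresholding the CIELAB b* channel.

    Pixels with ``b* < b_star_threshold`` are background.  Passing the
    string ``"otsu"`` picks the threshold by Otsu's method on the b*
    channel instead of the fixed default.  The optional white-patch
    rectangle is always forced to background.  A morphological opening
    (disk radius 2) is applied and connected components smaller than
    ``min_area_px`` removed.
    """
    image = _check_image(image)
    lab = color.rgb2lab(image)
    b_star = lab[..., 2]
    if isinstance(b_star_threshold, str):
        if b_star_threshold != "otsu":
            raise ValueError("threshold must be a number or 'otsu'")
        thr = float(threshold_otsu(b_star))
    else:
        thr = float(b_star_threshold)
    mask = b_star >= thr
    if patch_region is not None:
        ys, xs = _patch_slice(patch_region)
        mask[ys, xs] = False
    mask = morphology.opening(mask, morphology.disk(2))
    # drop connected components with area strictly below min_area_px
    mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
    area = int(mask.sum())
    if area == 0:
        raise NoFruitError("no fruit pixels left after thresholding and filtering")
    n_comp = int(label(mask).max())
    return FruitMask(mask=mask, n_components=n_comp, area_px=area)


def extract_channel_means(image: np.ndarray, mask: FruitMask | np.ndarray) -> ChannelMeans:
    """Arithmetic per-channel mean over mask pixels (unrounded)."""
    image = _check_image(image)
    m = mask.mask if isinstance(mask, FruitMask) else np.asarray(mask, dtype=bool)
    if m.shape != image.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not m.any():
        raise ValueError("mask is empty")
    vals = image[m].astype(float)
    r, g, b = vals.mean(axis=0)
    return ChannelMeans(float(r), float(g), float(b))


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    if image.size == 0:
        raise ValueError("image is empty")
    return image
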