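"""ROI cropping, intensity normalization and training-time augmentation.

The instrument's en-face SLO frame is 496x496 px; analysis uses a 156x238 px
window centred on the optic nerve head, min-max normalized per image to
[0, 1].  Augmentation (random flips, shifts up to +/-0.15 of the frame and
rotations up to +/-50 degrees) is applied to training images only and is
resampled every epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

ROI_HEIGHT = 156
ROI_WIDTH = 238


class BoundsError(ValueError):
    """Requested crop window extends past an image edge."""


class DegenerateImageError(ValueError):
    """Operation undefined on a constant image."""


@dataclass(frozen=True)
class AugmentationConfig:
    """Stochastic transform ranges; defaults mirror the training protocol."""

    horizontal_flip: bool = True
    vertical_flip: bool = True
    shift_fraction: float = 0.15
    rotation_range_deg: float = 50.0
    fill_mode: str = "nearest"

    def validate(self) -> None:
        if not 0.0 <= self.shift_fraction < 1.0:
            raise ValueError(f"shift_fraction={self.shift_fraction} outside [0, 1)")
        if not 0.0 <= self.rotation_range_deg <= 180.0:
            raise ValueError(
                f"rotation_range_deg={self.rotation_range_deg} outside [0, 180]"
            )
        if self.fill_mode not in ("nearest", "reflect", "constant"):
            raise ValueError(f"unknown fill_mode {self.fill_mode!r}")


IDENTITY_AUGMENTATION = AugmentationConfig(
    horizontal_flip=False, vertical_flip=False, shift_fraction=0.0,
    rotation_range_deg=0.0,
)


def crop_roi(
    image: np.ndarray,
    center_row: int | None = None,
    center_col: int | None = None,
    height: int = ROI_HEIGHT,
    width: int = ROI_WIDTH,
) -> np.ndarray:
    """Crop a ``height x width`` window centred at (center_row, center_col).

    The centre defaults to the image centre (synthetic discs are centred
    there; on instrument data the overlay centre should be passed
    explicitly).  Output pixel (0, 0) is input pixel
    (center_row - height//2, center_col - width//2).
    """
    h, w = image.shape
    if center_row is None:
        center_row = h // 2
    if center_col is None:
        center_col = w // 2
    top = center_row - height // 2
    left = center_col - width // 2
    if top < 0:
        raise BoundsError(f"crop window exceeds top edge by {-top} px")
    if left < 0:
        raise BoundsError(f"crop window exceeds left edge by {-left} px")
    if top + height > h:
        raise BoundsError(f"crop window exceeds bottom edge by {top + height - h} px")
    if left + width > w:
        raise BoundsError(f"crop window exceeds right edge by {left + width - w} px")
    return image[top: top + height, left: left + width].copy()


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Affine min-max rescale to [0, 1]; raises on constant images."""
    lo = float(image.min())
    hi = float(image.max())
    if hi <= lo:
        raise DegenerateImageError("constant image: min-max rescale undefined")
    return (image - lo) / (hi - lo)


def augment(
    image: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """One random flip/shift/rotate draw from ``config``; shape-preserving.

    Flips are applied independently with probability 0.5 each; the shift is
    drawn uniformly in +/- shift_fraction of the height/width, the rotation
    uniformly in +/- rotation_range_deg.  Bilinear interpolation with the
    configured border fill, clamped back to [0, 1].  The same rng state
    reproduces the same transform.
    """
    config.validate()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = image
    if config.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    if config.vertical_flip and rng.random() < 0.5:
        out = out[::-1, :]
    if config.shift_fraction > 0:
        dy = rng.uniform(-config.shift_fraction, config.shift_fraction) * image.shape[0]
        dx = rng.uniform(-config.shift_fraction, config.shift_fraction) * image.shape[1]
        out = ndimage.shift(out, (dy, dx), order=1, mode=config.fill_mode, cval=0.0)
    if config.rotation_range_deg > 0:
        angle = rng.uniform(-config.rotation_range_deg, config.rotation_range_deg)
        out = ndimage.rotate(
            out, angle, reshape=False, order=1, mode=config.fill_mode, cval=0.0
        )
    return np.clip(np.ascontiguousarray(out, dtype=float), 0.0, 1.0)
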