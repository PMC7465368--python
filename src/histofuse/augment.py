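"""Training-time patch augmentation.

The suite mirrors how pathologists view slides from arbitrary orientations:
horizontal/vertical flips, small rotations, width/height shifts, brightness
scaling, zoom, and slight Gaussian blur. Geometric transforms use reflection
fill and keep the patch size unchanged; labels are never touched. All draws
come from a caller-supplied generator, so a fixed seed reproduces the exact
augmented stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class AugmentConfig:
    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation_max: float = 30.0          # degrees
    width_shift: float = 0.1            # fraction of width
    height_shift: float = 0.1           # fraction of height
    brightness_range: tuple[float, float] = (0.8, 1.2)
    zoom_range: float = 0.1             # fraction around 1.0
    blur_sigma_max: float = 1.0         # pixels
    enabled: bool = True

    def validate(self) -> None:
        lo, hi = self.brightness_range
        if any(v < 0 for v in (self.rotation_max, self.width_shift,
                               self.height_shift, self.zoom_range,
                               self.blur_sigma_max, lo)):
            raise ValueError("augmentation ranges must be non-negative")
        if lo > hi:
            raise ValueError(
                f"brightness_range must be (low, high): {self.brightness_range}")


def augment_patch(patch: np.ndarray, config: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply one random draw of the augmentation suite to a single patch.

    With ``enabled=False`` the input is returned bit-identical. Input is an
    (S, S, 3) array, uint8 or float in [0, 1]; output has the same shape and
    dtype.
    """
    config.validate()
    if not config.enabled:
        return patch
    was_uint8 = patch.dtype == np.uint8
    img = patch.astype(np.float32) / 255.0 if was_uint8 \
        else patch.astype(np.float32)
    h, w = img.shape[:2]

    if config.horizontal_flip and rng.random() < 0.5:
        img = img[:, ::-1]
    if config.vertical_flip and rng.random() < 0.5:
        img = img[::-1]

    angle = rng.uniform(-config.rotation_max, config.rotation_max) \
        if config.rotation_max else 0.0
    zoom = 1.0 + rng.uniform(-config.zoom_range, config.zoom_range) \
        if config.zoom_range else 1.0
    dx = rng.uniform(-config.width_shift, config.width_shift) * w \
        if config.width_shift else 0.0
    dy = rng.uniform(-config.height_shift, config.height_shift) * h \
        if config.height_shift else 0.0
    if angle or zoom != 1.0 or dx or dy:
        theta = np.deg2rad(angle)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]]) / zoom
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        offset = center - rot @ center + np.array([dy, dx])
        img = np.ascontiguousarray(img)
        out = np.empty_like(img)
        for c in range(img.shape[2]):
            ndimage.affine_transform(
                img[:, :, c], rot, offset=offset, output=out[:, :, c],
                order=1, mode="reflect")
        img = out

    lo, hi = config.brightness_range
    if (lo, hi) != (1.0, 1.0):
        img = img * rng.uniform(lo, hi)

    if config.blur_sigma_max:
        sigma = rng.uniform(0.0, config.blur_sigma_max)
        if sigma > 1e-3:
            img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))

    img = np.clip(img, 0.0, 1.0)
    if was_uint8:
        return np.rint(img * 255.0).astype(np.uint8)
    return img.astype(patch.dtype)
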