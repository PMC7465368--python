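"""Input preparation: stain normalization, scale pyramid, quadrant patches.

Every source image is (1) H&E color-normalized, (2) rescaled to the four
pyramid ratios 1x, 0.5x, 0.33x and 0.25x, (3) cut into four contiguous
non-overlapping quadrants per scale, and (4) each quadrant resized to the
network input side (224 px), giving 16 patches per image. Patches inherit
the source image's class label.

Stain normalization defaults to mean/variance matching in the decorrelated
l-alpha-beta color space (Reinhard-style); a stain-vector factorization mode
(Macenko-style, OD-space SVD) is available via ``method="macenko"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image

DEFAULT_RATIOS = (1.0, 0.5, 0.33, 0.25)
PATCH_SIDE = 224
QUADRANT_NAMES = ("TL", "TR", "BL", "BR")

# Ruderman RGB <-> l-alpha-beta transform matrices
_RGB2LMS = np.array([[0.3811, 0.5783, 0.0402],
                     [0.1967, 0.7244, 0.0782],
                     [0.0241, 0.1288, 0.8444]])
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ \
    np.array([[1.0, 1.0, 1.0], [1.0, 1.0, -2.0], [1.0, -1.0, 0.0]])
_LAB2LMS = np.linalg.inv(_LMS2LAB)

_LOG_FLOOR = 1e-6


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _check_rgb(image: np.ndarray) -> None:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an RGB image of shape (H, W, 3), got {image.shape}")


def _to_float(image: np.ndarray) -> tuple[np.ndarray, bool]:
    """Return image in [0, 1] float64 and whether the input was uint8."""
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0, True
    return image.astype(np.float64), False


def _from_float(image: np.ndarray, was_uint8: bool, dtype) -> np.ndarray:
    image = np.clip(image, 0.0, 1.0)
    if was_uint8:
        return np.rint(image * 255.0).astype(np.uint8)
    return image.astype(dtype)


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Float [0,1] RGB -> Ruderman l-alpha-beta (per pixel)."""
    lms = image @ _RGB2LMS.T
    return np.log10(np.maximum(lms, _LOG_FLOOR)) @ _LMS2LAB.T


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    lms = 10.0 ** (lab @ _LAB2LMS.T)
    return lms @ _LMS2RGB.T


@dataclass(frozen=True)
class StainStats:
    """Per-channel mean/std in the decorrelated color space."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    @classmethod
    def from_image(cls, image: np.ndarray) -> "StainStats":
        _check_rgb(image)
        img, _ = _to_float(image)
        lab = rgb_to_lab(img).reshape(-1, 3)
        return cls(tuple(lab.mean(axis=0)), tuple(lab.std(axis=0)))


# typical well-stained H&E field statistics; any reference works, this one
# keeps un-configured pipelines deterministic
DEFAULT_REFERENCE = StainStats(
    mean=(-0.25, -0.022, -0.012), std=(0.16, 0.03, 0.014))


@dataclass(frozen=True)
class MacenkoReference:
    """Reference H/E stain vectors (rows, unit OD) and max concentrations."""

    stain_matrix: tuple = ((0.65, 0.70, 0.29), (0.07, 0.99, 0.11))
    max_concentration: tuple[float, float] = (1.9705, 1.0308)


def _macenko_fit(od: np.ndarray, beta: float = 0.15, alpha: float = 1.0):
    """Estimate the two stain vectors from optical-density pixels."""
    tissue = od[(od > beta).any(axis=1)]
    if len(tissue) < 10:
        raise ValueError("too few stained pixels for stain estimation")
    _, _, v = np.linalg.svd(tissue - tissue.mean(axis=0), full_matrices=False)
    plane = v[:2].T  # (3, 2)
    proj = tissue @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, (alpha, 100 - alpha))
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    stains = np.array([v1, v2])
    stains[stains < 0] = 0
    norm = np.linalg.norm(stains, axis=1, keepdims=True)
    stains = stains / np.where(norm == 0, 1, norm)
    # hematoxylin first (more blue OD)
    if stains[0, 2] < stains[1, 2]:
        stains = stains[::-1]
    return stains


def _normalize_macenko(img: np.ndarray, ref: MacenkoReference) -> np.ndarray:
    h, w, _ = img.shape
    od = -np.log10(np.maximum(img, _LOG_FLOOR)).reshape(-1, 3)
    stains = _macenko_fit(od)
    conc, *_ = np.linalg.lstsq(stains.T, od.T, rcond=None)
    max_c = np.percentile(np.maximum(conc, 0), 99, axis=1)
    max_c = np.where(max_c == 0, 1, max_c)
    conc = conc * (np.asarray(ref.max_concentration) / max_c)[:, None]
    od_norm = (np.asarray(ref.stain_matrix).T @ conc).T
    return (10.0 ** (-od_norm)).reshape(h, w, 3)


def normalize_stain(image: np.ndarray,
                    reference: StainStats | MacenkoReference | None = None,
                    method: str = "reinhard") -> np.ndarray:
    """Match an RGB image's stain appearance to a reference.

    ``reinhard``: shift/scale each channel in l-alpha-beta space to the
    reference mean/std. ``macenko``: re-express the image in reference H/E
    stain vectors with matched maximum concentrations.
    """
    _check_rgb(image)
    img, was_uint8 = _to_float(image)
    if not img.any():
        warnings.warn("all-zero image passed to normalize_stain; "
                      "returned unchanged", stacklevel=2)
        return image
    if method == "reinhard":
        ref = reference or DEFAULT_REFERENCE
        if not isinstance(ref, StainStats):
            raise TypeError("reinhard normalization needs StainStats")
        lab = rgb_to_lab(img)
        mean = lab.reshape(-1, 3).mean(axis=0)
        std = lab.reshape(-1, 3).std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        lab = (lab - mean) * (np.asarray(ref.std) / std) + np.asarray(ref.mean)
        out = lab_to_rgb(lab)
    elif method == "macenko":
        ref = reference or MacenkoReference()
        if not isinstance(ref, MacenkoReference):
            raise TypeError("macenko normalization needs MacenkoReference")
        out = _normalize_macenko(img, ref)
    else:
        raise ValueError(f"unknown stain normalization method {method!r}")
    return _from_float(out, was_uint8, image.dtype)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class ScalePyramid:
    """The four rescaled versions of one image (level 0 = original size)."""

    ratios: tuple[float, ...]
    images: list[np.ndarray]

    def __post_init__(self):
        sides = [im.shape[:2] for im in self.images]
        if any(np.prod(later) >= np.prod(earlier)
               for later, earlier in zip(sides[1:], sides[:-1])):
            raise ValueError("pyramid levels must strictly decrease in size")


def _resize(image: np.ndarray, size_wh: tuple[int, int]) -> np.ndarray:
    """Bilinear resize through Pillow (half-pixel-center convention)."""
    if image.dtype != np.uint8:
        arr = np.clip(image, 0, 1)
        out = _resize(np.rint(arr * 255).astype(np.uint8), size_wh)
        return out.astype(image.dtype) / 255.0
    return np.asarray(Image.fromarray(image).resize(size_wh, Image.BILINEAR))


def build_pyramid(image: np.ndarray,
                  ratios: tuple[float, ...] = DEFAULT_RATIOS) -> ScalePyramid:
    """Rescale to each ratio; level sides are round(ratio * side)."""
    _check_rgb(image)
    h, w = image.shape[:2]
    levels = []
    for r in ratios:
        th, tw = _round_half_up(r * h), _round_half_up(r * w)
        if min(th, tw) < 8:
            raise ValueError(
                f"image {w}x{h} too small for pyramid ratio {r} "
                f"(level would be {tw}x{th}, need >= 8 px)")
        if r == 1.0:
            levels.append(image.copy())
        else:
            levels.append(_resize(image, (tw, th)))
    return ScalePyramid(tuple(ratios), levels)


def quadrant_patches(image: np.ndarray) -> list[np.ndarray]:
    """2x2 grid of floor(side/2) quadrants in row-major order (TL,TR,BL,BR)."""
    h, w = image.shape[:2]
    if h < 2 or w < 2:
        raise ValueError(f"image {w}x{h} too small to cut into quadrants")
    hh, hw = h // 2, w // 2
    return [
        image[:hh, :hw].copy(),
        image[:hh, hw:2 * hw].copy(),
        image[hh:2 * hh, :hw].copy(),
        image[hh:2 * hh, hw:2 * hw].copy(),
    ]


@dataclass
class PatchSet:
    """The 16 resized patches of one image with (scale, quadrant) provenance."""

    patches: list[np.ndarray]
    provenance: list[tuple[int, int]]
    label: str | None = None
    source: str | None = None
    ratios: tuple[float, ...] = DEFAULT_RATIOS

    def __post_init__(self):
        n = len(self.ratios) * 4
        if len(self.patches) != n or len(self.provenance) != n:
            raise ValueError(f"expected {n} patches with provenance")

    def to_array(self, dtype=np.float32) -> np.ndarray:
        """Stack as (N, 3, S, S) in [0, 1]."""
        arr = np.stack(self.patches).astype(dtype)
        if self.patches[0].dtype == np.uint8:
            arr /= 255.0
        return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def build_patchset(image: np.ndarray,
                   ratios: tuple[float, ...] = DEFAULT_RATIOS,
                   out_size: int = PATCH_SIDE,
                   *,
                   normalize: bool = True,
                   reference: StainStats | None = None,
                   stain_method: str = "reinhard",
                   label: str | None = None,
                   source: str | None = None) -> PatchSet:
    """normalize -> pyramid -> quadrants per level -> resize to out_size."""
    if normalize:
        image = normalize_stain(image, reference, method=stain_method)
    pyramid = build_pyramid(image, ratios)
    patches, provenance = [], []
    for si, level in enumerate(pyramid.images):
        for qi, quad in enumerate(quadrant_patches(level)):
            patches.append(_resize(quad, (out_size, out_size)))
            provenance.append((si, qi))
    return PatchSet(patches, provenance, label=label, source=source,
                    ratios=tuple(ratios))


def save_patchset(ps: PatchSet, out_dir, stem: str) -> "pd.DataFrame":
    """Write patches as PNG with provenance-encoding names + manifest rows."""
    import pandas as pd
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for patch, (si, qi) in zip(ps.patches, ps.provenance):
        name = f"{stem}_s{si}_{QUADRANT_NAMES[qi]}.png"
        path = out_dir / name
        arr = patch if patch.dtype == np.uint8 else \
            np.rint(np.clip(patch, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr).save(path)
        rows.append((ps.source, ps.ratios[si], qi, ps.label, str(path)))
    return pd.DataFrame(
        rows, columns=["source", "scale_ratio", "quadrant", "label", "path"])
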