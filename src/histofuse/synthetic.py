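"""Seeded toy histology datasets in both supported directory layouts.

Images emulate low-level H&E statistics: a tinted stroma background with
speckle noise and Poisson-scattered dark Gaussian blobs standing in for
nuclei. Classes differ in blob rate and background tint, spaced so that the
mean blob counts of adjacent classes are separated by well over three
standard deviations — a depth-1 classifier on first-order statistics can
already tell them apart, so end-to-end training checks exercise the
pipeline rather than a hard recognition problem. A per-image multiplicative
tint jitter emulates staining variability and gives stain normalization
something to remove.

Everything is reproducible from the spec seed alone; the same spec writes
bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .data_io import (
    BREAKHIS_CLASSES,
    ICIAR_CLASSES,
    binary_label_for,
)

# background tints (RGB in [0,1]) cycled per class: eosin pink through
# hematoxylin purple
_TINTS = (
    (0.92, 0.72, 0.80),
    (0.72, 0.55, 0.82),
    (0.88, 0.62, 0.66),
    (0.65, 0.62, 0.86),
    (0.90, 0.80, 0.72),
    (0.70, 0.70, 0.78),
    (0.84, 0.66, 0.84),
    (0.78, 0.58, 0.70),
)
_NUCLEUS_COLOR = np.array([0.28, 0.16, 0.45])


def _default_classes(layout: str, n_classes: int) -> tuple[str, ...]:
    if layout == "iciar":
        if n_classes > len(ICIAR_CLASSES):
            raise ValueError("iciar layout supports at most 4 classes")
        return ICIAR_CLASSES[:n_classes]
    if n_classes == 2:
        return ("A", "DC")  # one benign, one malignant subtype
    if n_classes > len(BREAKHIS_CLASSES):
        raise ValueError("breakhis layout supports at most 8 classes")
    return BREAKHIS_CLASSES[:n_classes]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a generated toy dataset."""

    layout: str = "breakhis"
    n_classes: int = 2
    n_patients_per_class: int = 4
    images_per_patient: int = 3
    image_size: tuple[int, int] = (460, 700)  # (height, width) px
    magnification: int = 200
    blob_density: tuple[float, ...] | None = None  # mean blobs per image
    tint_jitter: float = 0.06
    blob_radius: tuple[float, float] = (4.0, 10.0)
    radius_shrink: float = 0.65  # higher-rate classes get smaller nuclei
    noise_sigma: float = 0.02
    seed: int = 0

    @property
    def class_names(self) -> tuple[str, ...]:
        return _default_classes(self.layout, self.n_classes)

    @property
    def densities(self) -> tuple[float, ...]:
        if self.blob_density is not None:
            if len(self.blob_density) != self.n_classes:
                raise ValueError("one blob density per class required")
            return tuple(self.blob_density)
        # spaced so adjacent-class counts differ by >> 3 Poisson sigmas
        return tuple(60.0 + 180.0 * i for i in range(self.n_classes))

    def validate(self) -> None:
        if self.layout not in ("breakhis", "iciar"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.class_names  # raises when the layout vocabulary is too small
        if self.n_patients_per_class < 1 or self.images_per_patient < 1:
            raise ValueError("patients and images per patient must be >= 1")
        if min(self.image_size) < 32:
            raise ValueError("image sides must be >= 32 px")
        d = self.densities
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("blob densities must be strictly increasing")


def render_image(spec: SyntheticSpec, class_index: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Render one image; returns (uint8 HxWx3, sampled blob count)."""
    h, w = spec.image_size
    tint = np.array(_TINTS[class_index % len(_TINTS)])
    jitter = rng.uniform(1 - spec.tint_jitter, 1 + spec.tint_jitter, size=3)
    img = np.empty((h, w, 3), np.float32)
    img[:] = tint * jitter
    img += rng.normal(0.0, spec.noise_sigma, size=(h, w, 1)).astype(np.float32)

    n_blobs = int(rng.poisson(spec.densities[class_index]))
    shrink = spec.radius_shrink ** class_index
    r_lo, r_hi = (r * shrink for r in spec.blob_radius)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(r_lo, r_hi)
        amp = rng.uniform(0.7, 1.0)
        half = int(np.ceil(3 * r))
        y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1, dtype=np.float32) - cy
        xx = np.arange(x0, x1, dtype=np.float32) - cx
        g = np.exp(-(yy[:, None] ** 2 + xx[None, :] ** 2) / (2 * r * r))
        g = (amp * g)[:, :, None]
        img[y0:y1, x0:x1] = img[y0:y1, x0:x1] * (1 - g) \
            + g * _NUCLEUS_COLOR.astype(np.float32)
    img = np.clip(img, 0.0, 1.0)
    return np.rint(img * 255).astype(np.uint8), n_blobs


def _breakhis_paths(root: Path, cls: str, patient: str, mag: int,
                    seq: int) -> Path:
    binary = binary_label_for(cls, "breakhis")
    tumor_flag = "B" if binary == "benign" else "M"
    d = root / binary / "SOB" / cls / f"SOB_{tumor_flag}_{cls}_{patient}" \
        / f"{mag}X"
    return d / f"SOB_{tumor_flag}_{cls}-{patient}-{mag}-{seq:03d}.png"


def generate_dataset(spec: SyntheticSpec, out_dir,
                     force: bool = False) -> pd.DataFrame:
    """Write the dataset tree + manifest.csv; returns the manifest."""
    spec.validate()
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"{out_dir} is not empty; pass force=True to overwrite into it")
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    patient_counter = 0
    for ci, cls in enumerate(spec.class_names):
        for _ in range(spec.n_patients_per_class):
            patient_counter += 1
            patient = f"{patient_counter:02d}-{spec.seed % 10000:04d}"
            for seq in range(1, spec.images_per_patient + 1):
                img, n_blobs = render_image(spec, ci, rng)
                if spec.layout == "breakhis":
                    path = _breakhis_paths(out_dir, cls, patient,
                                           spec.magnification, seq)
                    patient_id, mag = patient, spec.magnification
                    dataset = "breakhis"
                else:
                    path = out_dir / cls / f"{cls}_p{patient}_{seq:03d}.png"
                    patient_id, mag = "", 0
                    dataset = "iciar"
                path.parent.mkdir(parents=True, exist_ok=True)
                Image.fromarray(img).save(path)
                rows.append((str(path), dataset, cls,
                             binary_label_for(cls, dataset),
                             patient_id, mag, n_blobs))
    manifest = pd.DataFrame(
        rows, columns=["path", "dataset", "label", "binary_label",
                       "patient_id", "magnification", "n_blobs"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
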