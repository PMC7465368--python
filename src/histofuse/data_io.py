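"""Directory-tree readers for the two supported dataset layouts and
patient-disjoint train/test splitting.

The BreakHis-style layout encodes everything in the canonical filename
grammar ``SOB_<B|M>_<subtype>-<patient>-<magnification>-<seq>.<ext>``
(e.g. ``SOB_B_A-14-22549AB-40-001.png``); tumor-subtype codes map
deterministically onto the benign/malignant binary label. The ICIAR-style
layout is one folder per class (Benign, Normal, InSitu, Invasive) with no
patient metadata; its binary label is non-carcinoma (Benign, Normal) vs
carcinoma (InSitu, Invasive).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from PIL import Image

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")

BREAKHIS_CLASSES = ("A", "F", "TA", "PT", "DC", "LC", "MC", "PC")
BREAKHIS_BENIGN = frozenset({"A", "F", "TA", "PT"})
ICIAR_CLASSES = ("Benign", "Normal", "InSitu", "Invasive")
ICIAR_NONCARCINOMA = frozenset({"Benign", "Normal"})
MAGNIFICATIONS = (40, 100, 200, 400)

# published per-class, per-magnification image counts of the public BreakHis
# release (82 patients); scan_dataset output on a full download can be
# validated against these
BREAKHIS_PUBLISHED_COUNTS = {
    "A": {40: 114, 100: 113, 200: 111, 400: 106},
    "F": {40: 253, 100: 260, 200: 264, 400: 237},
    "TA": {40: 109, 100: 121, 200: 108, 400: 115},
    "PT": {40: 149, 100: 150, 200: 140, 400: 130},
    "DC": {40: 864, 100: 903, 200: 896, 400: 788},
    "LC": {40: 156, 100: 170, 200: 163, 400: 137},
    "MC": {40: 205, 100: 222, 200: 196, 400: 169},
    "PC": {40: 145, 100: 142, 200: 135, 400: 138},
}

_SOB_RE = re.compile(
    r"^SOB_([BM])_([A-Z]{1,2})[-_](?P<patient>.+)-(?P<mag>40|100|200|400)"
    r"-(?P<seq>\d+)$",
    re.IGNORECASE,
)

_ICIAR_FOLDER_ALIASES = {
    "benign": "Benign", "b": "Benign",
    "normal": "Normal", "n": "Normal",
    "insitu": "InSitu", "in_situ": "InSitu", "in situ": "InSitu",
    "is": "InSitu",
    "invasive": "Invasive", "iv": "Invasive",
}


def binary_label_for(label: str, dataset: str) -> str:
    """Deterministic class -> binary mapping per dataset vocabulary."""
    if dataset in ("breakhis", "synthetic"):
        if label not in BREAKHIS_CLASSES:
            raise ValueError(f"unknown BreakHis class {label!r}")
        return "benign" if label in BREAKHIS_BENIGN else "malignant"
    if dataset == "iciar":
        if label not in ICIAR_CLASSES:
            raise ValueError(f"unknown ICIAR class {label!r}")
        return "non-carcinoma" if label in ICIAR_NONCARCINOMA else "carcinoma"
    raise ValueError(f"unknown dataset {dataset!r}")


@dataclass(frozen=True)
class SlideRecord:
    """One source image plus its parsed metadata."""

    path: str
    dataset: str
    label: str
    binary_label: str
    patient_id: str | None
    magnification: int | None
    width: int
    height: int

    @property
    def record_id(self) -> str:
        return self.path


@dataclass
class ScanReport:
    n_parsed: int = 0
    skipped: list[str] = field(default_factory=list)


def _image_size(path: Path) -> tuple[int, int]:
    with Image.open(path) as im:
        return im.size  # (width, height)


def _parse_breakhis(path: Path, dataset: str) -> SlideRecord:
    m = _SOB_RE.match(path.stem)
    if not m:
        raise ValueError(f"filename does not match the SOB grammar: "
                         f"{path.name}")
    subtype = m.group(2).upper()
    if subtype not in BREAKHIS_CLASSES:
        raise ValueError(f"unknown tumor subtype code {subtype!r} in "
                         f"{path.name}")
    w, h = _image_size(path)
    return SlideRecord(
        path=str(path), dataset=dataset, label=subtype,
        binary_label=binary_label_for(subtype, dataset),
        patient_id=m.group("patient"), magnification=int(m.group("mag")),
        width=w, height=h)


def _parse_iciar(path: Path, root: Path) -> SlideRecord:
    try:
        folder = path.relative_to(root).parts[0]
    except (ValueError, IndexError):
        folder = path.parent.name
    label = _ICIAR_FOLDER_ALIASES.get(folder.strip().lower())
    if label is None:
        raise ValueError(f"folder {folder!r} is not an ICIAR class")
    w, h = _image_size(path)
    return SlideRecord(
        path=str(path), dataset="iciar", label=label,
        binary_label=binary_label_for(label, "iciar"),
        patient_id=None, magnification=None, width=w, height=h)


def scan_dataset(root, layout: str,
                 report: ScanReport | None = None) -> list[SlideRecord]:
    """Read a directory tree into slide records (lexicographic by path).

    Unparseable files are skipped with a warning and counted in ``report``;
    an empty tree raises ``ValueError("no images found")``.
    """
    root = Path(root)
    if layout not in ("breakhis", "iciar", "synthetic"):
        raise ValueError(f"unknown layout {layout!r}")
    if not root.is_dir():
        raise ValueError(f"dataset root {root} does not exist")
    files = sorted(p for p in root.rglob("*")
                   if p.suffix.lower() in IMAGE_EXTENSIONS)
    records = []
    for path in files:
        try:
            if layout == "iciar":
                records.append(_parse_iciar(path, root))
            else:
                records.append(_parse_breakhis(path, layout))
        except ValueError as exc:
            if report is not None:
                report.skipped.append(str(path))
            warnings.warn(f"skipping {path}: {exc}", stacklevel=2)
    if report is not None:
        report.n_parsed = len(records)
    if not records:
        raise ValueError("no images found")
    return records


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint train/test record-id sets (patient-disjoint when possible)."""

    train: frozenset[str]
    test: frozenset[str]
    seed: int
    ratio: float
    by_patient: bool

    def apply(self, records):
        train = [r for r in records if r.record_id in self.train]
        test = [r for r in records if r.record_id in self.test]
        return train, test


def patient_split(records, ratio: float = 0.7,
                  seed: int = 0) -> SplitAssignment:
    """Seeded 70:30-style split keeping each patient on one side only.

    Patients are shuffled and moved into the training set until its image
    fraction reaches ``ratio`` (the last added patient may overshoot). When
    any record lacks a patient id the split falls back to image level.
    """
    import numpy as np

    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1): {ratio}")
    records = list(records)
    by_patient = all(r.patient_id is not None for r in records) \
        and len(records) > 0
    if by_patient:
        groups: dict[str, list[str]] = {}
        for r in records:
            groups.setdefault(r.patient_id, []).append(r.record_id)
        keys = sorted(groups)
        kind = "patients"
    else:
        groups = {r.record_id: [r.record_id] for r in records}
        keys = sorted(groups)
        kind = "images"
    if len(keys) < 2:
        raise ValueError(f"need at least 2 {kind} to split, got {len(keys)}")
    rng = np.random.default_rng(seed)
    order = [keys[i] for i in rng.permutation(len(keys))]
    total = len(records)
    train: list[str] = []
    cut = 0
    for cut, key in enumerate(order, start=1):
        train.extend(groups[key])
        if len(train) / total >= ratio:
            break
    if cut == len(order):  # never leave the test side empty
        cut -= 1
        train = [rid for key in order[:cut] for rid in groups[key]]
    test = [rid for key in order[cut:] for rid in groups[key]]
    return SplitAssignment(frozenset(train), frozenset(test), seed=seed,
                           ratio=ratio, by_patient=by_patient)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["path", "dataset", "label", "binary_label",
                    "patient_id", "magnification", "split"]


def records_to_frame(records,
                     split: SplitAssignment | None = None) -> pd.DataFrame:
    def side(r):
        if split is None:
            return ""
        return "train" if r.record_id in split.train else "test"

    return pd.DataFrame(
        [(r.path, r.dataset, r.label, r.binary_label,
          r.patient_id or "", r.magnification or 0, side(r))
         for r in records],
        columns=MANIFEST_COLUMNS)


def write_manifest(records, path, split: SplitAssignment | None = None):
    df = records_to_frame(records, split)
    df.to_csv(path, index=False)
    return df


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)
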