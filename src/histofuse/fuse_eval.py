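"""Patch-to-image probability fusion, metrics, and paired-model comparison.

Three voting rules turn the 16 per-patch probability vectors of an image
into one image-level label:

* ``majority`` — the most frequent per-patch argmax label;
* ``maximum``  — the label of the single highest patch probability;
* ``sum``      — the argmax of the summed probability vectors.

All ties (including per-patch argmax ties and equal top probabilities under
``maximum``) are broken by a malignancy-priority order, most malignant class
first, so an ambiguous image is never resolved toward the benign side.

The paired-model comparison is the standardized McNemar test with Edwards'
continuity correction: chi2 = (|n12 - n21| - 1)^2 / (n12 + n21) referred to
the upper tail of a chi-square distribution with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

VOTING_METHODS = ("majority", "maximum", "sum")

PRIORITY_BREAKHIS = ("DC", "LC", "MC", "PC", "A", "F", "TA", "PT")
PRIORITY_ICIAR = ("Invasive", "InSitu", "Benign", "Normal")
PRIORITY_BINARY = {"breakhis": ("malignant", "benign"),
                   "synthetic": ("malignant", "benign"),
                   "iciar": ("carcinoma", "non-carcinoma")}


@dataclass(frozen=True)
class PriorityOrder:
    """Class names ordered most-malignant first; used for tie-breaking."""

    order: tuple[str, ...]

    def validate(self, classes) -> None:
        missing = set(classes) - set(self.order)
        if missing:
            raise ValueError(f"classes missing from priority order: "
                             f"{sorted(missing)}")

    def rank(self, label: str) -> int:
        return self.order.index(label)

    def first(self, labels) -> str:
        return min(labels, key=self.rank)

    @classmethod
    def for_dataset(cls, dataset: str, classes=None) -> "PriorityOrder":
        base = PRIORITY_ICIAR if dataset == "iciar" else PRIORITY_BREAKHIS
        if classes is not None and set(classes) <= set(
                PRIORITY_BINARY.get(dataset, ())):
            base = PRIORITY_BINARY[dataset]
        order = tuple(c for c in base if classes is None or c in classes)
        if classes is not None:
            extra = tuple(c for c in classes if c not in order)
            order = order + extra
        return cls(order)


@dataclass(frozen=True)
class PredictionRecord:
    """One patch's probability vector with its provenance."""

    image_id: str
    scale: int
    quadrant: int
    probs: tuple[float, ...]


def _check_probs(probs: np.ndarray, tol: float = 1e-5) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] == 0:
        raise ValueError("need a non-empty (patches x classes) matrix")
    if (probs < -tol).any():
        raise ValueError("negative probabilities")
    sums = probs.sum(axis=1)
    if np.abs(sums - 1.0).max() > tol:
        raise ValueError(
            f"probability rows must sum to 1 +- {tol}; worst row sums to "
            f"{sums[np.abs(sums - 1).argmax()]:.6f}")
    return probs


def fuse_votes(probs, classes, method: str,
               priority: PriorityOrder) -> str:
    """Fuse one image's patch probability vectors into a single label."""
    probs = _check_probs(probs)
    classes = list(classes)
    if probs.shape[1] != len(classes):
        raise ValueError("probability columns must match the class list")
    priority.validate(classes)
    if method not in VOTING_METHODS:
        raise ValueError(f"unknown voting method {method!r}")

    def argmax_label(vec) -> str:
        top = vec.max()
        return priority.first([c for c, v in zip(classes, vec) if v == top])

    if method == "majority":
        patch_labels = [argmax_label(row) for row in probs]
        counts: dict[str, int] = {}
        for lab in patch_labels:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        return priority.first([c for c, n in counts.items() if n == best])
    if method == "maximum":
        top = probs.max()
        winners = {classes[j] for i, j in zip(*np.where(probs == top))}
        return priority.first(winners)
    summed = probs.sum(axis=0)
    return argmax_label(summed)


def predict_patches(model, x: np.ndarray, image_ids, provenance,
                    classes) -> pd.DataFrame:
    """Per-patch class probabilities as a tidy frame (one row per patch)."""
    probs = model.predict_proba(x)
    df = pd.DataFrame(probs, columns=[f"p_{c}" for c in classes])
    df.insert(0, "image_id", list(image_ids))
    df.insert(1, "scale", [p[0] for p in provenance])
    df.insert(2, "quadrant", [p[1] for p in provenance])
    return df


def fuse_images(patch_df: pd.DataFrame, classes, method: str,
                priority: PriorityOrder) -> pd.DataFrame:
    """Image-level labels from a per-patch prediction frame."""
    cols = [f"p_{c}" for c in classes]
    rows = []
    for image_id, grp in patch_df.groupby("image_id", sort=True):
        label = fuse_votes(grp[cols].to_numpy(), classes, method, priority)
        rows.append((image_id, label))
    return pd.DataFrame(rows, columns=["image_id", "label"])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsResult:
    confusion: pd.DataFrame  # rows = true classes, columns = predicted
    accuracy: float
    sensitivity: dict[str, float]  # per class, NaN when undefined
    specificity: dict[str, float]

    def to_dict(self) -> dict:
        def clean(d):
            return {k: (None if np.isnan(v) else float(v))
                    for k, v in d.items()}

        return {
            "accuracy": float(self.accuracy),
            "sensitivity": clean(self.sensitivity),
            "specificity": clean(self.specificity),
            "confusion": self.confusion.to_dict(),
        }


def confusion_and_metrics(y_true, y_pred, classes=None) -> MetricsResult:
    """Confusion matrix, accuracy, and one-vs-rest sensitivity/specificity.

    A class absent from both the true and the predicted sequence gets NaN
    (undefined) rather than zero.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    cm = _sk_confusion(y_true, y_pred, labels=list(classes))
    total = cm.sum()
    accuracy = np.trace(cm) / total
    sens, spec = {}, {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = tp / (tp + fn) if (tp + fn) else float("nan")
        spec[c] = tn / (tn + fp) if (tn + fp) else float("nan")
    confusion = pd.DataFrame(cm, index=list(classes), columns=list(classes))
    return MetricsResult(confusion, float(accuracy), sens, spec)


def plot_confusion(metrics: MetricsResult, path) -> None:
    """Optional heat-map rendering of a confusion matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = metrics.confusion
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(cm),) * 2)
    im = ax.imshow(cm.to_numpy(), cmap="Blues")
    ax.set_xticks(range(len(cm)), cm.columns, rotation=45)
    ax.set_yticks(range(len(cm)), cm.index)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(len(cm)):
        for j in range(len(cm)):
            ax.text(j, i, str(cm.iat[i, j]), ha="center", va="center")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# paired-model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedOutcomeTable:
    """2x2 correct/incorrect cross-tabulation of two models on one test set."""

    n11: int  # both correct
    n12: int  # A correct, B wrong
    n21: int  # A wrong, B correct
    n22: int  # both wrong

    def __post_init__(self):
        cells = (self.n11, self.n12, self.n21, self.n22)
        if any(int(c) != c or c < 0 for c in cells):
            raise ValueError(f"cells must be non-negative integers: {cells}")

    @classmethod
    def from_predictions(cls, y_true, pred_a, pred_b) -> "PairedOutcomeTable":
        y, a, b = map(np.asarray, (y_true, pred_a, pred_b))
        if not (len(y) == len(a) == len(b)):
            raise ValueError("prediction arrays must have equal length")
        ca, cb = a == y, b == y
        return cls(int((ca & cb).sum()), int((ca & ~cb).sum()),
                   int((~ca & cb).sum()), int((~ca & ~cb).sum()))


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float


def mcnemar_standardized(table: PairedOutcomeTable) -> McNemarResult:
    """Continuity-corrected McNemar test on the discordant cells.

    statistic = (|n12 - n21| - 1)^2 / (n12 + n21), p from the upper tail of
    chi-square with 1 degree of freedom.
    """
    discordant = table.n12 + table.n21
    if discordant < 1:
        raise ValueError("test undefined: no discordant pairs")
    statistic = (abs(table.n12 - table.n21) - 1) ** 2 / discordant
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(float(statistic), p)
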