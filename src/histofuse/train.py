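"""Patch-wise supervised training, cross-validated hyperparameter selection,
repeated trials, and the ablation harness.

Training minimizes cross-entropy on one-hot patch labels (each patch inherits
its source image's label). Hyperparameters are selected by 5-fold
cross-validation with patient-disjoint folds whenever patient ids exist;
reported metrics are means over independent seeded trials. The ablation
harness re-runs the pipeline restricted to a subset of pyramid scales and/or
GAP taps, mirroring the multi-scale-input and multi-feature-map studies.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .augment import AugmentConfig, augment_patch
from .data_io import SlideRecord, SplitAssignment, patient_split
from .fuse_eval import (
    MetricsResult,
    PriorityOrder,
    confusion_and_metrics,
    fuse_images,
    predict_patches,
)
from .net import ArchitectureSpec, MultiScaleFusionNet, build_model
from .nn import make_optimizer
from .preprocess import DEFAULT_RATIOS, StainStats, build_patchset

# the assessed search space (plus the final selected epoch values 32/64)
HYPERPARAMETER_GRID = {
    "n_layers": (201, 205, 210),
    "epochs": (30, 40, 50, 70, 32, 64),
    "learning_rate": (1e-1, 1e-2, 1e-3, 1e-4, 5e-1, 5e-2),
    "batch_size": (32, 64, 128),
    "optimizer": ("SGD", "RMSprop", "Adadelta", "Adam", "Adamax", "Nadam"),
    "dropout": (0.5, 0.6, 0.7, 0.8),
}

LOSSES = ("categorical_cross_entropy", "binary_cross_entropy")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol; defaults are the best selected values
    (Adam, learning rate 1e-4, dropout 0.5, 64 epochs, batch 32)."""

    epochs: int = 64
    learning_rate: float = 1e-4
    batch_size: int = 32
    optimizer: str = "Adam"
    dropout: float = 0.5
    loss: str = "categorical_cross_entropy"
    folds: int = 5
    trials: int = 5
    seed: int = 0
    class_weights: bool = False
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def validate(self, grid: bool = False) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")
        if self.folds < 2 or self.trials < 1:
            raise ValueError("folds >= 2 and trials >= 1 required")
        self.augment.validate()
        if grid:
            for name in ("epochs", "learning_rate", "batch_size", "dropout"):
                if getattr(self, name) not in HYPERPARAMETER_GRID[name]:
                    raise ValueError(
                        f"{name}={getattr(self, name)} outside the assessed "
                        f"grid {HYPERPARAMETER_GRID[name]}")
            if self.optimizer not in HYPERPARAMETER_GRID["optimizer"]:
                raise ValueError(f"optimizer {self.optimizer!r} outside the "
                                 "assessed grid")


@dataclass
class PatchData:
    """Patches of many images stacked for training."""

    x: np.ndarray                 # (N, 3, S, S) float32 in [0, 1]
    y: np.ndarray                 # (N,) int class indices
    classes: tuple[str, ...]
    image_ids: list[str]
    provenance: list[tuple[int, int]]
    patient_ids: list[str | None]

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, mask) -> "PatchData":
        idx = np.where(mask)[0]
        return PatchData(self.x[idx], self.y[idx], self.classes,
                         [self.image_ids[i] for i in idx],
                         [self.provenance[i] for i in idx],
                         [self.patient_ids[i] for i in idx])


def load_image(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def prepare_patches(records: Sequence[SlideRecord],
                    ratios=DEFAULT_RATIOS,
                    out_size: int = 224,
                    *,
                    normalize: bool = True,
                    reference: StainStats | None = None,
                    scale_subset: Sequence[int] | None = None,
                    binary: bool = False,
                    classes: Sequence[str] | None = None) -> PatchData:
    """Run the preprocessing pipeline over records and stack the patches.

    ``scale_subset`` uses 1-based scale indices (1 = the 1x level); ``binary``
    swaps the class vocabulary for the benign/malignant-style binary labels.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to prepare")
    labels = [r.binary_label if binary else r.label for r in records]
    if classes is None:
        classes = tuple(sorted(set(labels)))
    else:
        classes = tuple(classes)
    keep = None
    if scale_subset is not None:
        if not scale_subset:
            raise ValueError("scale_subset must be non-empty")
        keep = {s - 1 for s in scale_subset}
        if not keep <= set(range(len(ratios))):
            raise ValueError(f"scale_subset {scale_subset} out of range")
    xs, ys, ids, prov, pats = [], [], [], [], []
    cls_index = {c: i for i, c in enumerate(classes)}
    for rec, label in zip(records, labels):
        ps = build_patchset(load_image(rec.path), ratios, out_size,
                            normalize=normalize, reference=reference,
                            label=label, source=rec.record_id)
        arr = ps.to_array()
        for patch, (si, qi) in zip(arr, ps.provenance):
            if keep is not None and si not in keep:
                continue
            xs.append(patch)
            ys.append(cls_index[label])
            ids.append(rec.record_id)
            prov.append((si, qi))
            pats.append(rec.patient_id)
    return PatchData(np.stack(xs), np.asarray(ys), classes, ids, prov, pats)


def _augment_batch(xb: np.ndarray, config: AugmentConfig,
                   rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(xb)
    for i in range(len(xb)):
        hwc = np.ascontiguousarray(xb[i].transpose(1, 2, 0))
        out[i] = augment_patch(hwc, config, rng).transpose(2, 0, 1)
    return out


def train_patchwise(model: MultiScaleFusionNet, data: PatchData,
                    config: TrainConfig, verbose: bool = False):
    """Train in place; returns a per-epoch loss/accuracy history frame."""
    config.validate()
    n_classes = model.spec.n_classes
    if len(data.classes) != n_classes:
        raise ValueError(f"model expects {n_classes} classes, data has "
                         f"{len(data.classes)}")
    present = np.unique(data.y)
    if len(present) < 2:
        raise ValueError("training data contains a single class; "
                         "cross-entropy selection is degenerate")
    model.head.ops[0].rate = config.dropout
    rng = np.random.default_rng(config.seed)
    optimizer = make_optimizer(config.optimizer, model.parameters(),
                               config.learning_rate)
    eye = np.eye(n_classes, dtype=np.float32)
    weights = None
    if config.class_weights:
        counts = np.bincount(data.y, minlength=n_classes).astype(float)
        weights = np.where(counts > 0, counts.sum() / np.maximum(counts, 1),
                           0.0)
        weights *= n_classes / weights.sum()
    history = []
    n = len(data)
    for epoch in range(1, config.epochs + 1):
        t0 = time.time()
        perm = rng.permutation(n)
        losses, correct, seen = [], 0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb = data.x[idx]
            if config.augment.enabled:
                xb = _augment_batch(xb, config.augment, rng)
            yb = data.y[idx]
            onehot = eye[yb]
            if weights is not None:
                onehot = onehot * weights[yb][:, None]
            loss, probs = model.loss_and_grads(xb, onehot)
            optimizer.step()
            optimizer.zero_grad()
            losses.append(loss)
            correct += int((probs.argmax(axis=1) == yb).sum())
            seen += len(idx)
        history.append((epoch, float(np.mean(losses)), correct / seen,
                        time.time() - t0))
        if verbose:
            print(f"epoch {epoch}: loss={history[-1][1]:.4f} "
                  f"acc={history[-1][2]:.3f} ({history[-1][3]:.1f}s)")
    return pd.DataFrame(history,
                        columns=["epoch", "loss", "accuracy", "seconds"])


def patch_accuracy(model: MultiScaleFusionNet, data: PatchData) -> float:
    probs = model.predict_proba(data.x)
    return float((probs.argmax(axis=1) == data.y).mean())


def evaluate_images(model: MultiScaleFusionNet, data: PatchData,
                    method: str, priority: PriorityOrder
                    ) -> tuple[MetricsResult, pd.DataFrame]:
    """Image-level metrics after patch-probability fusion."""
    df = predict_patches(model, data.x, data.image_ids, data.provenance,
                         data.classes)
    fused = fuse_images(df, data.classes, method, priority)
    truth = {img: data.classes[y]
             for img, y in zip(data.image_ids, data.y)}
    y_true = [truth[i] for i in fused["image_id"]]
    metrics = confusion_and_metrics(y_true, list(fused["label"]),
                                    classes=data.classes)
    return metrics, fused


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    table: pd.DataFrame          # config_index, fold, accuracy
    best_index: int
    best_config: TrainConfig

    def mean_accuracy(self) -> pd.Series:
        return self.table.groupby("config_index")["accuracy"].mean()


def _fold_groups(data: PatchData, folds: int, seed: int) -> list[np.ndarray]:
    """Patient-disjoint (or image-disjoint) masks, one per validation fold."""
    if all(p is not None for p in data.patient_ids):
        group_of = np.asarray(data.patient_ids)
    else:
        group_of = np.asarray(data.image_ids)
    groups = np.asarray(sorted(set(group_of)))
    if len(groups) < folds:
        raise ValueError(f"{len(groups)} groups is fewer than {folds} folds")
    rng = np.random.default_rng(seed)
    order = groups[rng.permutation(len(groups))]
    parts = np.array_split(order, folds)
    return [np.isin(group_of, part) for part in parts]


def cross_validate(data: PatchData, configs: Sequence[TrainConfig],
                   arch: ArchitectureSpec, verbose: bool = False) -> CVResult:
    """K-fold selection: highest mean validation patch accuracy wins."""
    if not configs:
        raise ValueError("need at least one candidate configuration")
    folds = configs[0].folds
    masks = _fold_groups(data, folds, configs[0].seed)
    rows = []
    for ci, config in enumerate(configs):
        config.validate()
        for fi, val_mask in enumerate(masks):
            train_data = data.subset(~val_mask)
            val_data = data.subset(val_mask)
            model = build_model(arch, len(data.classes),
                                seed=config.seed + 1000 * fi)
            train_patchwise(model, train_data, config, verbose=verbose)
            acc = patch_accuracy(model, val_data)
            rows.append((ci, fi, acc))
    table = pd.DataFrame(rows, columns=["config_index", "fold", "accuracy"])
    mean_acc = table.groupby("config_index")["accuracy"].mean()
    best = int(mean_acc.idxmax())
    return CVResult(table, best, configs[best])


# ---------------------------------------------------------------------------
# end-to-end runs and the ablation harness
# ---------------------------------------------------------------------------

@dataclass
class RunMetrics:
    scales: tuple[int, ...]
    taps: tuple[int, ...]
    fused_width: int
    patch_train_accuracy: float
    patch_test_accuracy: float
    image_metrics: MetricsResult
    history: pd.DataFrame

    def row(self) -> dict:
        return {
            "scales": "".join(map(str, self.scales)),
            "taps": "".join(map(str, self.taps)),
            "fused_width": self.fused_width,
            "patch_train_accuracy": self.patch_train_accuracy,
            "patch_test_accuracy": self.patch_test_accuracy,
            "image_accuracy": self.image_metrics.accuracy,
        }


def train_and_evaluate(records: Sequence[SlideRecord],
                       config: TrainConfig,
                       arch: ArchitectureSpec,
                       *,
                       scale_subset: Sequence[int] = (1, 2, 3, 4),
                       split: SplitAssignment | None = None,
                       ratios=DEFAULT_RATIOS,
                       out_size: int = 224,
                       binary: bool = False,
                       voting: str = "maximum",
                       normalize: bool = True,
                       verbose: bool = False) -> RunMetrics:
    """One full run: split, preprocess, train, fuse, evaluate."""
    records = list(records)
    if split is None:
        split = patient_split(records, 0.7, config.seed)
    train_recs, test_recs = split.apply(records)
    dataset = records[0].dataset
    data_train = prepare_patches(train_recs, ratios, out_size,
                                 scale_subset=scale_subset, binary=binary,
                                 normalize=normalize)
    data_test = prepare_patches(test_recs, ratios, out_size,
                                scale_subset=scale_subset, binary=binary,
                                normalize=normalize,
                                classes=data_train.classes)
    arch = replace(arch, n_classes=len(data_train.classes),
                   dropout=config.dropout)
    model = build_model(arch, seed=config.seed)
    history = train_patchwise(model, data_train, config, verbose=verbose)
    priority = PriorityOrder.for_dataset(dataset, data_train.classes)
    image_metrics, _ = evaluate_images(model, data_test, voting, priority)
    return RunMetrics(
        scales=tuple(sorted(scale_subset)), taps=tuple(sorted(arch.taps)),
        fused_width=model.fused_width,
        patch_train_accuracy=patch_accuracy(model, data_train),
        patch_test_accuracy=patch_accuracy(model, data_test),
        image_metrics=image_metrics, history=history)


def run_ablation(records: Sequence[SlideRecord],
                 scale_subset: Sequence[int],
                 tap_subset: Sequence[int],
                 config: TrainConfig,
                 arch: ArchitectureSpec,
                 **kwargs) -> RunMetrics:
    """Train/evaluate one (scale subset, tap subset) combination."""
    if not scale_subset or not tap_subset:
        raise ValueError("scale and tap subsets must be non-empty")
    arch = arch.with_taps(tap_subset)
    return train_and_evaluate(records, config, arch,
                              scale_subset=scale_subset, **kwargs)


def ablation_table(records, combos, config, arch, **kwargs) -> pd.DataFrame:
    """Run several (scales, taps) combinations; one metrics row each."""
    rows = []
    for scales, taps in combos:
        rm = run_ablation(records, scales, taps, config, arch, **kwargs)
        rows.append(rm.row())
    return pd.DataFrame(rows)


def repeated_trials(records, config: TrainConfig, arch: ArchitectureSpec,
                    **kwargs) -> pd.DataFrame:
    """Means over ``config.trials`` independently seeded end-to-end runs."""
    rows = []
    for t in range(config.trials):
        cfg = replace(config, seed=config.seed + t)
        rm = train_and_evaluate(records, cfg, arch, **kwargs)
        rows.append(rm.row() | {"trial": t})
    return pd.DataFrame(rows)
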