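"""Training loop, cross-validation selection, and the ablation harness."""

import numpy as np
import pytest

from histofuse.augment import AugmentConfig
from histofuse.net import build_model
from histofuse.train import (
    HYPERPARAMETER_GRID,
    TrainConfig,
    _fold_groups,
    cross_validate,
    patch_accuracy,
    prepare_patches,
    run_ablation,
    train_patchwise,
)


def quick_config(**kw):
    base = dict(epochs=2, learning_rate=1e-3, batch_size=16, seed=0,
                augment=AugmentConfig(enabled=False))
    base.update(kw)
    return TrainConfig(**base)


class TestTrainPatchwise:
    def test_separable_classes_reach_90pct(self, tiny_arch,
                                           separable_patches):
        model = build_model(tiny_arch, seed=0)
        history = train_patchwise(model, separable_patches,
                                  quick_config(epochs=5))
        assert list(history.columns[:3]) == ["epoch", "loss", "accuracy"]
        assert len(history) == 5
        assert history["accuracy"].iloc[-1] >= 0.9

    def test_loss_finite_for_all_grid_learning_rates(self, tiny_arch,
                                                     separable_patches):
        for lr in HYPERPARAMETER_GRID["learning_rate"]:
            model = build_model(tiny_arch, seed=0)
            history = train_patchwise(model, separable_patches,
                                      quick_config(epochs=1,
                                                   learning_rate=lr))
            assert np.isfinite(history["loss"]).all(), lr

    def test_identical_seed_identical_first_epoch_loss(self, tiny_arch,
                                                       separable_patches):
        losses = []
        for _ in range(2):
            model = build_model(tiny_arch, seed=7)
            history = train_patchwise(model, separable_patches,
                                      quick_config(epochs=1, seed=7))
            losses.append(history["loss"].iloc[0])
        assert losses[0] == losses[1]

    def test_single_class_data_rejected(self, tiny_arch, separable_patches):
        mask = separable_patches.y == 0
        model = build_model(tiny_arch, seed=0)
        with pytest.raises(ValueError, match="single class"):
            train_patchwise(model, separable_patches.subset(mask),
                            quick_config())

    def test_augmented_training_runs(self, tiny_arch, separable_patches):
        model = build_model(tiny_arch, seed=0)
        cfg = quick_config(epochs=1, augment=AugmentConfig())
        history = train_patchwise(model, separable_patches, cfg)
        assert np.isfinite(history["loss"]).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            quick_config(learning_rate=-1).validate()
        with pytest.raises(ValueError):
            quick_config(loss="hinge").validate()
        with pytest.raises(ValueError, match="outside the assessed grid"):
            quick_config(learning_rate=3e-4).validate(grid=True)
        # the published best configuration sits inside the grid
        TrainConfig(epochs=64, learning_rate=1e-4, batch_size=32,
                    optimizer="Adam", dropout=0.5).validate(grid=True)


class TestCrossValidation:
    def test_folds_partition_by_patient(self, separable_patches):
        masks = _fold_groups(separable_patches, folds=2, seed=0)
        total = np.zeros(len(separable_patches), dtype=int)
        for m in masks:
            total += m.astype(int)
        assert (total == 1).all()  # disjoint and exhaustive
        pats = np.asarray(separable_patches.patient_ids)
        for m in masks:
            assert not (set(pats[m]) & set(pats[~m]))

    def test_five_folds_over_25_single_image_patients(self):
        from histofuse.train import PatchData

        data = PatchData(
            x=np.zeros((25, 3, 2, 2), np.float32),
            y=np.arange(25) % 2, classes=("a", "b"),
            image_ids=[f"i{k}" for k in range(25)],
            provenance=[(0, 0)] * 25,
            patient_ids=[f"p{k:02d}" for k in range(25)])
        masks = _fold_groups(data, folds=5, seed=3)
        assert [int(m.sum()) for m in masks] == [5] * 5

    def test_fewer_groups_than_folds(self, separable_patches):
        with pytest.raises(ValueError, match="fewer than"):
            _fold_groups(separable_patches, folds=50, seed=0)

    def test_sabotaged_config_loses(self, tiny_arch, separable_patches):
        sane = quick_config(folds=2)
        sabotaged = quick_config(folds=2, learning_rate=0.5)
        cv = cross_validate(separable_patches, [sane, sabotaged], tiny_arch)
        assert cv.best_index == 0
        means = cv.mean_accuracy()
        assert means[0] > means[1]
        # every image lands in exactly one validation fold
        assert len(cv.table) == 2 * 2

    def test_empty_grid(self, tiny_arch, separable_patches):
        with pytest.raises(ValueError):
            cross_validate(separable_patches, [], tiny_arch)


class TestAblation:
    def test_scale_subset_filters_patches(self, small_records):
        data = prepare_patches(small_records, out_size=16, scale_subset=[1],
                               normalize=False)
        assert len(data) == 4 * len(small_records)
        assert {s for s, _ in data.provenance} == {0}

    def test_tap_subset_controls_fused_width(self, tiny_arch):
        full = tiny_arch.channel_plan()
        assert tiny_arch.with_taps([4]).fused_width == full["tap_width"][4]

    def test_empty_subsets_rejected(self, tiny_arch, small_records):
        with pytest.raises(ValueError, match="non-empty"):
            run_ablation(small_records, [], [1], quick_config(), tiny_arch)
        with pytest.raises(ValueError, match="non-empty"):
            run_ablation(small_records, [1], [], quick_config(), tiny_arch)

    def test_single_combination_end_to_end(self, tiny_arch, small_records):
        rm = run_ablation(small_records, [1, 2], [3, 4],
                          quick_config(epochs=1), tiny_arch,
                          out_size=32, normalize=False)
        plan = tiny_arch.channel_plan()
        assert rm.fused_width == plan["tap_width"][3] + plan["tap_width"][4]
        assert rm.scales == (1, 2) and rm.taps == (3, 4)
        assert 0.0 <= rm.image_metrics.accuracy <= 1.0
        row = rm.row()
        assert row["scales"] == "12" and row["taps"] == "34"


def test_class_weights_option(tiny_arch, separable_patches):
    model = build_model(tiny_arch, seed=0)
    cfg = quick_config(epochs=1, class_weights=True)
    history = train_patchwise(model, separable_patches, cfg)
    assert np.isfinite(history["loss"]).all()
    assert 0 <= patch_accuracy(model, separable_patches) <= 1
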