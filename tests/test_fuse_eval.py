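"""Voting fusion, metrics, and the standardized McNemar test."""

import numpy as np
import pandas as pd
import pytest

from histofuse.fuse_eval import (
    PRIORITY_BREAKHIS,
    PRIORITY_ICIAR,
    MetricsResult,
    PairedOutcomeTable,
    PriorityOrder,
    confusion_and_metrics,
    fuse_images,
    fuse_votes,
    mcnemar_standardized,
)

BH = PriorityOrder(PRIORITY_BREAKHIS)


def onehotish(label, classes, p=1.0):
    v = np.full(len(classes), (1 - p) / (len(classes) - 1))
    v[classes.index(label)] = p
    return v


class TestFuseVotes:
    def test_majority_modal_label(self):
        classes = ["A", "DC"]
        probs = [onehotish("A", classes, 0.9), onehotish("A", classes, 0.8),
                 onehotish("DC", classes, 0.95)]
        assert fuse_votes(probs, classes, "majority", BH) == "A"

    def test_majority_tie_goes_to_malignant(self):
        classes = ["A", "DC"]
        probs = [onehotish("DC", classes, 0.6), onehotish("A", classes, 0.9)]
        assert fuse_votes(probs, classes, "majority", BH) == "DC"

    def test_sum_and_maximum_worked_example(self):
        classes = ["c1", "c2"]
        pri = PriorityOrder(("c1", "c2"))
        probs = np.array([[0.6, 0.4], [0.2, 0.8]])
        # sums: 0.8 vs 1.2 -> c2; single largest value 0.8 -> c2
        assert fuse_votes(probs, classes, "sum", pri) == "c2"
        assert fuse_votes(probs, classes, "maximum", pri) == "c2"

    def test_maximum_tie_broken_by_priority(self):
        classes = ["A", "DC"]
        probs = np.array([[0.7, 0.3], [0.3, 0.7]])
        assert fuse_votes(probs, classes, "maximum", BH) == "DC"

    def test_unanimous_patches_agree_for_every_method(self, rng):
        classes = ["A", "F", "DC"]
        for _ in range(20):
            label = classes[rng.integers(3)]
            probs = np.stack([onehotish(label, classes, rng.uniform(0.5, 1))
                              for _ in range(rng.integers(1, 6))])
            for method in ("majority", "maximum", "sum"):
                assert fuse_votes(probs, classes, method,
                                  PriorityOrder(tuple(classes))) == label

    def test_input_validation(self):
        pri = PriorityOrder(("a", "b"))
        with pytest.raises(ValueError, match="non-empty"):
            fuse_votes(np.empty((0, 2)), ["a", "b"], "sum", pri)
        with pytest.raises(ValueError, match="sum to 1"):
            fuse_votes([[0.9, 0.4]], ["a", "b"], "sum", pri)
        with pytest.raises(ValueError, match="unknown voting"):
            fuse_votes([[0.5, 0.5]], ["a", "b"], "plurality", pri)
        with pytest.raises(ValueError, match="missing from priority"):
            fuse_votes([[0.5, 0.5]], ["a", "b"], "sum",
                       PriorityOrder(("a",)))

    def test_priority_defaults(self):
        assert PriorityOrder.for_dataset("iciar").order == PRIORITY_ICIAR
        assert PriorityOrder.for_dataset("breakhis",
                                         ["A", "DC"]).order == ("DC", "A")
        assert PriorityOrder.for_dataset(
            "breakhis", ["benign", "malignant"]).order == \
            ("malignant", "benign")

    def test_fuse_images_frame(self):
        classes = ("A", "DC")
        df = pd.DataFrame({
            "image_id": ["i1"] * 2 + ["i2"] * 2,
            "scale": [0, 0, 0, 0], "quadrant": [0, 1, 0, 1],
            "p_A": [0.9, 0.8, 0.1, 0.2],
            "p_DC": [0.1, 0.2, 0.9, 0.8],
        })
        fused = fuse_images(df, classes, "sum", BH)
        assert dict(zip(fused["image_id"], fused["label"])) == \
            {"i1": "A", "i2": "DC"}


class TestMetrics:
    def test_perfect_predictions(self):
        m = confusion_and_metrics(["a", "b", "a"], ["a", "b", "a"])
        assert m.accuracy == 1.0
        assert np.allclose(np.diag(m.confusion), [2, 1])
        assert all(v == 1.0 for v in m.sensitivity.values())
        assert all(v == 1.0 for v in m.specificity.values())

    def test_binary_hand_arithmetic(self):
        # TP=3, FN=1, FP=0, TN=4 for class "pos"
        y_true = ["pos"] * 4 + ["neg"] * 4
        y_pred = ["pos"] * 3 + ["neg"] * 5
        m = confusion_and_metrics(y_true, y_pred, classes=["pos", "neg"])
        assert m.sensitivity["pos"] == pytest.approx(0.75)
        assert m.specificity["pos"] == pytest.approx(1.0)

    def test_constant_predictor_on_balanced_data(self):
        y_true = ["a"] * 5 + ["b"] * 5
        m = confusion_and_metrics(y_true, ["a"] * 10)
        assert m.accuracy == pytest.approx(0.5)
        assert m.sensitivity["a"] == 1.0 and m.sensitivity["b"] == 0.0

    def test_absent_class_is_nan_not_zero(self):
        m = confusion_and_metrics(["a", "a"], ["a", "a"],
                                  classes=["a", "ghost"])
        assert np.isnan(m.sensitivity["ghost"])
        assert m.to_dict()["sensitivity"]["ghost"] is None

    def test_row_sums_equal_sample_count(self, rng):
        classes = ["a", "b", "c"]
        y_true = [classes[i] for i in rng.integers(0, 3, 50)]
        y_pred = [classes[i] for i in rng.integers(0, 3, 50)]
        m = confusion_and_metrics(y_true, y_pred, classes=classes)
        assert int(m.confusion.to_numpy().sum()) == 50
        # sum over classes of (TP + FN) = row sums = number of samples
        assert int(m.confusion.sum(axis=1).sum()) == 50

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_and_metrics(["a"], ["a", "b"])

    def test_heatmap_written(self, tmp_path):
        from histofuse.fuse_eval import plot_confusion

        m = confusion_and_metrics(["a", "b"], ["a", "b"])
        plot_confusion(m, tmp_path / "cm.png")
        assert (tmp_path / "cm.png").stat().st_size > 0


class TestMcNemar:
    @pytest.mark.parametrize("cells,expected_p", [
        ((254, 14, 20, 76), 0.39),   # pooled two-model comparison, 4 classes
        ((773, 89, 115, 495), 0.08),
    ])
    def test_published_tables(self, cells, expected_p):
        res = mcnemar_standardized(PairedOutcomeTable(*cells))
        assert round(res.p_value, 2) == expected_p

    def test_closed_form_balanced_discordance(self):
        res = mcnemar_standardized(PairedOutcomeTable(0, 10, 10, 0))
        assert res.statistic == pytest.approx((0 - 1) ** 2 / 20)
        assert res.p_value == pytest.approx(0.8231, abs=1e-4)

    def test_symmetry_in_discordant_cells(self):
        a = mcnemar_standardized(PairedOutcomeTable(5, 14, 20, 3))
        b = mcnemar_standardized(PairedOutcomeTable(5, 20, 14, 3))
        assert a.p_value == b.p_value and a.statistic == b.statistic

    def test_zero_discordant_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            mcnemar_standardized(PairedOutcomeTable(10, 0, 0, 5))

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            PairedOutcomeTable(1, -2, 3, 4)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for cells in [(254, 14, 20, 76), (773, 89, 115, 495), (0, 3, 9, 0)]:
            t = PairedOutcomeTable(*cells)
            ours = mcnemar_standardized(t)
            ref = sm_mcnemar([[t.n11, t.n12], [t.n21, t.n22]], exact=False,
                             correction=True)
            assert ours.statistic == pytest.approx(float(ref.statistic))
            assert ours.p_value == pytest.approx(float(ref.pvalue))

    def test_from_predictions(self):
        y = [0, 1, 0, 1, 1]
        a = [0, 1, 1, 1, 0]  # correct: 0,1,3
        b = [0, 0, 0, 1, 1]  # correct: 0,2,3,4
        t = PairedOutcomeTable.from_predictions(y, a, b)
        assert (t.n11, t.n12, t.n21, t.n22) == (2, 1, 2, 0)
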