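"""Dataset scanning, label vocabularies, and patient-disjoint splitting."""

import numpy as np
import pandas as pd
import pytest

from histofuse.data_io import (
    BREAKHIS_CLASSES,
    ICIAR_CLASSES,
    ScanReport,
    SlideRecord,
    binary_label_for,
    patient_split,
    read_manifest,
    records_to_frame,
    scan_dataset,
    write_manifest,
)


def _fake_records(n_patients, images_per_patient=1, label="A"):
    recs = []
    for p in range(n_patients):
        for i in range(images_per_patient):
            recs.append(SlideRecord(
                path=f"/x/p{p:03d}_{i}.png", dataset="breakhis", label=label,
                binary_label=binary_label_for(label, "breakhis"),
                patient_id=f"p{p:03d}", magnification=200,
                width=64, height=64))
    return recs


class TestScan:
    def test_fixture_tree_counts(self, small_records):
        # 2 classes x 3 patients x 4 images
        assert len(small_records) == 24
        assert len({r.patient_id for r in small_records}) == 6
        assert {r.label for r in small_records} == {"A", "DC"}
        assert all(r.magnification == 200 for r in small_records)
        assert all(r.width == 64 and r.height == 64 for r in small_records)

    def test_roundtrip_matches_generator_manifest(self, small_dataset_dir,
                                                  small_records):
        _, _, manifest = small_dataset_dir
        scanned = pd.DataFrame(
            {"path": [r.path for r in small_records],
             "label": [r.label for r in small_records],
             "patient_id": [r.patient_id for r in small_records]})
        expected = manifest[["path", "label", "patient_id"]] \
            .sort_values("path").reset_index(drop=True)
        assert scanned.sort_values("path").reset_index(drop=True) \
            .equals(expected)

    def test_deterministic_lexicographic_order(self, small_dataset_dir):
        root, _, _ = small_dataset_dir
        recs = scan_dataset(root, "breakhis")
        assert [r.path for r in recs] == sorted(r.path for r in recs)

    def test_empty_root_errors(self, tmp_path):
        with pytest.raises(ValueError, match="no images found"):
            scan_dataset(tmp_path, "breakhis")

    def test_unparseable_filename_skipped_with_warning(self, tmp_path):
        from PIL import Image

        Image.new("RGB", (8, 8)).save(tmp_path / "SOB_B_A-01-200-001.png")
        (tmp_path / "holiday_photo.png").write_bytes(b"not an image")
        report = ScanReport()
        with pytest.warns(UserWarning, match="SOB grammar"):
            recs = scan_dataset(tmp_path, "breakhis", report=report)
        assert len(recs) == 1 and report.skipped == \
            [str(tmp_path / "holiday_photo.png")]

    def test_iciar_layout(self, tmp_path):
        from PIL import Image

        for cls in ("Benign", "InSitu"):
            (tmp_path / cls).mkdir()
            Image.new("RGB", (8, 8)).save(tmp_path / cls / "img1.png")
        recs = scan_dataset(tmp_path, "iciar")
        assert [r.label for r in recs] == ["Benign", "InSitu"]
        assert all(r.patient_id is None for r in recs)
        assert [r.binary_label for r in recs] == ["non-carcinoma",
                                                  "carcinoma"]


class TestBinaryLabels:
    @pytest.mark.parametrize("label,expected", [
        ("A", "benign"), ("F", "benign"), ("TA", "benign"), ("PT", "benign"),
        ("DC", "malignant"), ("LC", "malignant"), ("MC", "malignant"),
        ("PC", "malignant"),
    ])
    def test_breakhis_mapping(self, label, expected):
        assert binary_label_for(label, "breakhis") == expected

    @pytest.mark.parametrize("label,expected", [
        ("Benign", "non-carcinoma"), ("Normal", "non-carcinoma"),
        ("InSitu", "carcinoma"), ("Invasive", "carcinoma"),
    ])
    def test_iciar_mapping(self, label, expected):
        assert binary_label_for(label, "iciar") == expected

    def test_vocabularies(self):
        assert len(BREAKHIS_CLASSES) == 8 and len(ICIAR_CLASSES) == 4
        with pytest.raises(ValueError):
            binary_label_for("XX", "breakhis")


class TestPatientSplit:
    def test_patients_never_straddle_sides(self, small_records):
        for seed in range(100):
            split = patient_split(small_records, 0.7, seed)
            assert split.by_patient
            train_p = {r.patient_id for r in small_records
                       if r.record_id in split.train}
            test_p = {r.patient_id for r in small_records
                      if r.record_id in split.test}
            assert not (train_p & test_p)
            assert split.train.isdisjoint(split.test)
            assert len(split.train) + len(split.test) == len(small_records)

    def test_greedy_fill_is_exact_for_single_image_patients(self):
        recs = _fake_records(100)
        for seed in (0, 1, 42):
            split = patient_split(recs, 0.7, seed)
            assert len(split.train) == 70

    def test_same_seed_identical(self, small_records):
        a = patient_split(small_records, 0.7, 9)
        b = patient_split(small_records, 0.7, 9)
        assert a.train == b.train and a.test == b.test

    def test_too_few_patients(self):
        with pytest.raises(ValueError, match="at least 2"):
            patient_split(_fake_records(1, images_per_patient=5), 0.7, 0)

    def test_bad_ratio(self, small_records):
        with pytest.raises(ValueError, match="ratio"):
            patient_split(small_records, 1.5, 0)

    def test_test_side_never_empty(self):
        recs = _fake_records(2, images_per_patient=3)
        split = patient_split(recs, 0.99, 0)
        assert split.test

    def test_image_level_fallback_without_patient_ids(self):
        recs = [SlideRecord(path=f"/x/{i}.png", dataset="iciar",
                            label="Benign", binary_label="non-carcinoma",
                            patient_id=None, magnification=None,
                            width=8, height=8) for i in range(10)]
        split = patient_split(recs, 0.7, 0)
        assert not split.by_patient and len(split.train) == 7


class TestManifest:
    def test_roundtrip(self, small_records, tmp_path):
        split = patient_split(small_records, 0.7, 0)
        path = tmp_path / "manifest.csv"
        write_manifest(small_records, path, split)
        df = read_manifest(path)
        assert list(df.columns) == ["path", "dataset", "label",
                                    "binary_label", "patient_id",
                                    "magnification", "split"]
        assert set(df["split"]) == {"train", "test"}
        assert len(df) == len(small_records)

    def test_frame_without_split(self, small_records):
        df = records_to_frame(small_records)
        assert (df["split"] == "").all()
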