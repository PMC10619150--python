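"""Split arithmetic against the reference per-class table, augmentation
bookkeeping, and the synthetic generator's statistical guarantees."""
import numpy as np
import pandas as pd
import pytest
from PIL import Image

from mobilemfs.datasets import (APPLE_LEAF_CLASSES, APPLE_LEAF_CLASS_TOTALS,
                                DatasetManifest, SyntheticSpec, assign_split,
                                augment_training_set, color_texture_features,
                                generate_synthetic_arrays,
                                generate_synthetic_dataset, load_arrays,
                                load_image_folder,
                                nearest_class_mean_accuracy, stratified_split)

# reference per-class (train, test, augmented-train) figures
REFERENCE_TABLE = {
    "Alternaria leaf spot": (526, 131, 1578),
    "Brown spot": (354, 88, 1062),
    "Frogeye leaf spot": (2544, 635, 7632),
    "Grey spot": (285, 71, 855),
    "Health": (704, 175, 2112),
    "Mosaic": (316, 79, 948),
    "Powdery mildew": (947, 236, 2841),
    "Rust": (2202, 550, 6606),
    "Scab": (4326, 1081, 12978),
}


class TestStratifiedSplit:
    @pytest.mark.parametrize("total,expected", [
        (657, (526, 131)), (5407, (4326, 1081)), (5, (4, 1)), (4, (4, 0)),
    ])
    def test_floor_rule(self, total, expected):
        assert stratified_split([total]) == [expected]

    def test_reference_table_reproduced_exactly(self):
        totals = [APPLE_LEAF_CLASS_TOTALS[c] for c in APPLE_LEAF_CLASSES]
        splits = stratified_split(totals)
        for cls, (tr, te) in zip(APPLE_LEAF_CLASSES, splits):
            assert (tr, te) == REFERENCE_TABLE[cls][:2]
        assert sum(tr for tr, _ in splits) == 12204
        assert sum(te for _, te in splits) == 3046
        assert sum(totals) == 15250

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            stratified_split([0])


def _bookkeeping_manifest(per_class: dict[str, int]) -> DatasetManifest:
    rows = [{"path": f"{c}/{i}.png", "label": c, "split": "",
             "origin": "original"}
            for c, n in per_class.items() for i in range(n)]
    return DatasetManifest(classes=tuple(per_class), entries=pd.DataFrame(rows))


class TestAugmentationBookkeeping:
    def test_reference_augmented_figures(self):
        manifest = _bookkeeping_manifest(APPLE_LEAF_CLASS_TOTALS)
        manifest = assign_split(manifest, seed=0)
        aug = augment_training_set(manifest, factor=3, seed=0,
                                   write_images=False)
        train_counts = aug.class_counts("train")
        for cls, (_tr, _te, augmented) in REFERENCE_TABLE.items():
            assert train_counts[cls] == augmented
        assert sum(train_counts.values()) == 36612

    def test_factor_one_is_identity(self, tiny_image_folder):
        _, manifest = tiny_image_folder
        m = assign_split(manifest, seed=1)
        assert augment_training_set(m, factor=1) is m

    def test_total_row_count(self):
        manifest = _bookkeeping_manifest({"a": 10, "b": 25})
        manifest = assign_split(manifest, seed=3)
        aug = augment_training_set(manifest, factor=3, write_images=False)
        n_train = len(manifest.subset("train"))
        n_test = len(manifest.subset("test"))
        assert len(aug.entries) == 3 * n_train + n_test
        assert (aug.subset("test") == manifest.subset("test")).all().all()

    def test_invalid_factor(self):
        manifest = _bookkeeping_manifest({"a": 5})
        with pytest.raises(ValueError):
            augment_training_set(manifest, factor=0)


class TestAssignSplit:
    def test_deterministic_and_partitioning(self):
        manifest = _bookkeeping_manifest({"x": 442, "y": 37})
        m1 = assign_split(manifest, seed=9)
        m2 = assign_split(manifest, seed=9)
        pd.testing.assert_frame_equal(m1.entries, m2.entries)
        assert m1.class_counts("test")["x"] == 88   # floor(442/5)
        splits = set(m1.entries["split"])
        assert splits == {"train", "test"}
        assert len(m1.subset("train")) + len(m1.subset("test")) == 479

    def test_different_seed_changes_assignment(self):
        manifest = _bookkeeping_manifest({"x": 50})
        a = assign_split(manifest, seed=1).entries["split"]
        b = assign_split(manifest, seed=2).entries["split"]
        assert not a.equals(b)

    def test_empty_class_rejected(self):
        df = pd.DataFrame([{"path": "a/1.png", "label": "a", "split": "",
                            "origin": "original"}])
        manifest = DatasetManifest(classes=("a", "b"), entries=df)
        with pytest.raises(ValueError, match="'b'"):
            assign_split(manifest, seed=0)


class TestSyntheticGenerator:
    def test_image_and_manifest_counts(self, tmp_path):
        spec = SyntheticSpec(image_size=32, n_per_class=20, seed=1)
        manifest = generate_synthetic_dataset(spec, tmp_path)
        assert len(manifest.entries) == 180
        pngs = list(tmp_path.rglob("*.png"))
        assert len(pngs) == 180

    def test_same_seed_byte_identical(self):
        spec = SyntheticSpec(image_size=48, n_per_class=3, seed=42)
        a = generate_synthetic_arrays(spec)
        b = generate_synthetic_arrays(spec)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[2], b[2])

    def test_rust_red_exceeds_grey_spot_inside_lesions(self):
        # parameter-recovery style check on 100 images per class at defaults
        spec = SyntheticSpec(n_per_class=100, seed=5)
        images, labels, masks = generate_synthetic_arrays(spec)

        def lesion_red(cls):
            ci = APPLE_LEAF_CLASSES.index(cls)
            vals = [images[i][masks[i], 0].mean()
                    for i in np.nonzero(labels == ci)[0] if masks[i].any()]
            return float(np.mean(vals))

        assert lesion_red("Rust") - lesion_red("Grey spot") >= 30.0

    def test_classes_learnable_by_pixel_statistics(self, small_synth):
        # a trivial nearest class-mean classifier on 8 color/texture
        # features must already separate the classes well
        _, images, labels, _ = small_synth
        feats = color_texture_features(images)
        train_mask = np.zeros(len(labels), dtype=bool)
        for c in np.unique(labels):
            train_mask[np.nonzero(labels == c)[0][:16]] = True
        acc = nearest_class_mean_accuracy(feats, labels, train_mask)
        assert acc >= 0.80

    def test_health_has_no_lesions(self):
        spec = SyntheticSpec(image_size=48, n_per_class=2, seed=3)
        images, labels, masks = generate_synthetic_arrays(spec)
        hi = APPLE_LEAF_CLASSES.index("Health")
        assert not masks[labels == hi].any()


class TestImageFolderLoading:
    def test_lexicographic_class_order(self, tiny_image_folder):
        root, _ = tiny_image_folder
        manifest = load_image_folder(root)
        assert list(manifest.classes) == sorted(manifest.classes)
        assert len(manifest.classes) == 9

    def test_empty_class_dir_errors_with_name(self, tmp_path):
        (tmp_path / "klassA").mkdir()
        (tmp_path / "klassB").mkdir()
        Image.new("RGB", (8, 8)).save(tmp_path / "klassA" / "x.png")
        with pytest.raises(ValueError, match="klassB"):
            load_image_folder(tmp_path)

    def test_grayscale_replicated_to_three_channels(self, tmp_path):
        d = tmp_path / "gray"
        d.mkdir()
        Image.new("L", (10, 10), color=128).save(d / "g.png")
        manifest = load_image_folder(tmp_path)
        manifest.entries["split"] = "train"
        X, y = load_arrays(manifest, "train", image_size=10, normalize=False)
        assert X.shape == (1, 3, 10, 10)
        np.testing.assert_allclose(X[0, 0], X[0, 1])

    def test_corrupt_file_skipped_with_warning(self, tmp_path, caplog):
        d = tmp_path / "c"
        d.mkdir()
        Image.new("RGB", (8, 8)).save(d / "ok.png")
        (d / "broken.png").write_bytes(b"not a png")
        manifest = load_image_folder(tmp_path)
        manifest.entries["split"] = "train"
        with caplog.at_level("WARNING"):
            X, _ = load_arrays(manifest, "train", image_size=8)
        assert len(X) == 1
        assert any("unreadable" in r.message for r in caplog.records)


def test_manifest_csv_roundtrip(tmp_path):
    manifest = _bookkeeping_manifest({"a": 3, "b": 2})
    manifest = assign_split(manifest, seed=4)
    manifest.to_csv(tmp_path / "m.csv")
    restored = DatasetManifest.from_csv(tmp_path / "m.csv")
    assert restored.classes == manifest.classes
    assert restored.seed == 4
    pd.testing.assert_frame_equal(restored.entries, manifest.entries)
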