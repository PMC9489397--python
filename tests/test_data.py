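"""Dataset I/O, stratified splitting, augmentation and the synthetic generator."""

import numpy as np
import pytest
from PIL import Image

from cervnet.data import (DEFAULT_LABELS, TABLE1_COUNTS, EvalTransform,
                          ImageRecord, LabelScheme, SyntheticConfig,
                          TrainTransform, compute_channel_stats,
                          generate_synthetic_dataset, inventory,
                          load_image_folder, scaled_table1_counts,
                          stratified_split, write_image_folder)
from cervnet.errors import (ConfigurationError, EmptyDatasetError,
                            InvalidShapeError, StratificationError)


class TestInventory:
    def test_clinical_reference_counts_total_6996(self):
        records = [ImageRecord(label=k, pixels=np.zeros((4, 4, 3), np.uint8))
                   for k, n in TABLE1_COUNTS.items() for _ in range(n)]
        inv = inventory(records)
        assert inv.per_class_counts == {0: 2352, 1: 780, 2: 2532, 3: 408, 4: 924}
        assert inv.total == 6996

    def test_empty_list_all_zero(self):
        inv = inventory([])
        assert inv.total == 0 and inv.per_class_counts == {}

    def test_total_invariant_under_permutation(self, rng, tiny_records):
        shuffled = list(tiny_records)
        rng.shuffle(shuffled)
        assert inventory(shuffled).total == inventory(tiny_records).total


class TestLoadImageFolder:
    def test_labels_follow_directory_names(self, tmp_path):
        for label, n in [(0, 2), (3, 1)]:
            d = tmp_path / str(label)
            d.mkdir()
            for i in range(n):
                Image.fromarray(np.zeros((8, 8, 3), np.uint8)).save(d / f"{i}.png")
        records = load_image_folder(tmp_path)
        assert [r.label for r in records] == [0, 0, 3]
        assert inventory(records).total == 3

    def test_ordering_is_deterministic(self, image_folder):
        a = [r.path for r in load_image_folder(image_folder)]
        b = [r.path for r in load_image_folder(image_folder)]
        assert a == b == sorted(a)

    def test_unreadable_file_is_skipped_with_warning(self, tmp_path):
        d = tmp_path / "0"
        d.mkdir()
        Image.fromarray(np.zeros((8, 8, 3), np.uint8)).save(d / "ok.png")
        (d / "broken.png").write_bytes(b"not an image")
        with pytest.warns(UserWarning, match="unreadable"):
            records = load_image_folder(tmp_path)
        assert len(records) == 1

    def test_empty_dataset_raises(self, tmp_path):
        with pytest.raises(EmptyDatasetError):
            load_image_folder(tmp_path)


class TestStratifiedSplit:
    def test_ten_per_class_gives_nine_one(self, tiny_records):
        train, val = stratified_split(tiny_records, 0.9, seed=0)
        assert inventory(train).per_class_counts == {k: 9 for k in range(5)}
        assert inventory(val).per_class_counts == {k: 1 for k in range(5)}

    def test_split_is_a_partition(self, tiny_records):
        train, val = stratified_split(tiny_records, 0.8, seed=1)
        ids = lambda rs: {id(r) for r in rs}
        assert ids(train) | ids(val) == ids(tiny_records)
        assert not ids(train) & ids(val)

    def test_same_seed_reproduces_different_seed_differs(self, tiny_records):
        t1, _ = stratified_split(tiny_records, 0.9, seed=5)
        t2, _ = stratified_split(tiny_records, 0.9, seed=5)
        t3, _ = stratified_split(tiny_records, 0.9, seed=6)
        assert [id(r) for r in t1] == [id(r) for r in t2]
        assert {id(r) for r in t1} != {id(r) for r in t3}
        assert inventory(t1).per_class_counts == inventory(t3).per_class_counts

    def test_imbalanced_classes_hit_global_fraction_within_one(self):
        records = [ImageRecord(label=k, pixels=np.zeros((4, 4, 3), np.uint8))
                   for k, n in {0: 23, 1: 7, 2: 31, 3: 5, 4: 11}.items()
                   for _ in range(n)]
        train, val = stratified_split(records, 0.9, seed=0)
        assert abs(len(train) - round(0.9 * len(records))) <= 1
        for k, n in inventory(records).per_class_counts.items():
            t = inventory(train).per_class_counts[k]
            assert abs(t - 0.9 * n) <= 1  # proportions preserved within rounding
            assert 1 <= t <= n - 1

    def test_group_aware_keeps_patients_together(self, tiny_records):
        train, val = stratified_split(tiny_records, 0.8, seed=0, group_aware=True)
        train_groups = {r.group_id for r in train}
        val_groups = {r.group_id for r in val}
        assert not train_groups & val_groups
        assert val  # both subsets populated

    def test_class_with_single_record_rejected(self):
        records = [ImageRecord(label=0, pixels=np.zeros((4, 4, 3), np.uint8))
                   for _ in range(5)]
        records.append(ImageRecord(label=1, pixels=np.zeros((4, 4, 3), np.uint8)))
        with pytest.raises(StratificationError):
            stratified_split(records)


class TestTransforms:
    def test_train_output_is_3x224x224(self, rng):
        tf = TrainTransform(rng=rng)
        img = (rng.random((300, 400, 3)) * 255).astype(np.uint8)
        assert tf(img).shape == (3, 224, 224)

    def test_eval_is_deterministic(self, rng):
        tf = EvalTransform()
        img = (rng.random((260, 260, 3)) * 255).astype(np.uint8)
        np.testing.assert_array_equal(tf(img), tf(img))

    def test_center_crop_of_256_spans_16_to_239(self):
        img = np.zeros((256, 256, 3), np.uint8)
        img[16:240, 16:240] = 255  # exactly the region a center 224-crop should keep
        tf = EvalTransform(size=224, resize_short=None, mean=(0, 0, 0), std=(1, 1, 1))
        out = tf(img)
        assert (out == 1.0).all()

    def test_train_without_flips_and_tight_crop_is_deterministic(self, rng):
        img = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
        mk = lambda: TrainTransform(size=64, resize_short=None, hflip=False,
                                    vflip=False, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(mk()(img), mk()(img))

    def test_undersized_image_rejected(self, rng):
        tf = EvalTransform(size=224, resize_short=None)
        with pytest.raises(InvalidShapeError):
            tf((rng.random((100, 100, 3)) * 255).astype(np.uint8))

    def test_standardized_train_set_has_zero_mean_unit_sd(self, tiny_records):
        mean, std = compute_channel_stats(tiny_records)
        tf = EvalTransform(size=48, resize_short=None, mean=mean, std=std)
        xs = np.stack([tf(r.load()) for r in tiny_records])
        assert np.abs(xs.mean(axis=(0, 2, 3))).max() < 0.05
        assert np.abs(xs.std(axis=(0, 2, 3)) - 1).max() < 0.05


class TestSyntheticGenerator:
    def test_table1_proportions_divided_by_12(self):
        assert scaled_table1_counts(12) == {0: 196, 1: 65, 2: 211, 3: 34, 4: 77}

    def test_same_seed_pixel_identical(self):
        cfg = dict(per_class_counts={0: 2, 1: 2, 2: 2, 3: 2, 4: 2},
                   image_size=32, noise_sd=0.1)
        a = generate_synthetic_dataset(SyntheticConfig(seed=3, **cfg))
        b = generate_synthetic_dataset(SyntheticConfig(seed=3, **cfg))
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.pixels, rb.pixels)

    def test_noise_free_classes_are_nearest_mean_separable(self):
        cfg = SyntheticConfig(per_class_counts={k: 8 for k in range(5)},
                              image_size=32, noise_sd=0.0, seed=1)
        records = generate_synthetic_dataset(cfg)
        feats = np.stack([r.load().reshape(-1, 3).mean(axis=0) for r in records])
        labels = np.array([r.label for r in records])
        correct = 0
        for i in range(len(records)):  # leave-one-out 1-NN on mean color
            d = np.linalg.norm(feats - feats[i], axis=1)
            d[i] = np.inf
            correct += labels[int(np.argmin(d))] == labels[i]
        assert correct == len(records)

    def test_mean_hue_is_monotone_in_class_signal(self):
        import colorsys
        cfg = SyntheticConfig(per_class_counts={k: 4 for k in range(5)},
                              image_size=32, noise_sd=0.0, seed=2)
        records = generate_synthetic_dataset(cfg)
        hues = []
        for k in range(5):
            rgb = np.mean([r.load().reshape(-1, 3).mean(axis=0)
                           for r in records if r.label == k], axis=0) / 255
            hues.append(colorsys.rgb_to_hsv(*rgb)[0])
        assert all(a < b for a, b in zip(hues, hues[1:]))

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(noise_sd=-0.1)

    def test_roundtrip_through_image_folder(self, tmp_path):
        cfg = SyntheticConfig(per_class_counts={0: 2, 1: 2, 2: 2, 3: 2, 4: 2},
                              image_size=16, noise_sd=0.0, seed=0)
        records = generate_synthetic_dataset(cfg)
        write_image_folder(records, tmp_path)
        loaded = load_image_folder(tmp_path)
        assert inventory(loaded).per_class_counts == cfg.per_class_counts
        np.testing.assert_array_equal(loaded[0].load(), records[0].pixels)


def test_label_scheme_default_and_validation():
    scheme = LabelScheme()
    assert scheme.num_classes == 5
    assert scheme.names == DEFAULT_LABELS
    with pytest.raises(ConfigurationError):
        LabelScheme({1: "a", 2: "b"})
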