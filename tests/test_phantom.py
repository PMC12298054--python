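"""Phantom generator, augmentation registry, balancing and splits."""

import numpy as np
import pandas as pd
import pytest

from quanvit.phantom import (
    AUGMENTATIONS,
    CLASSES,
    ImageDataset,
    MANIFEST_COLUMNS,
    augment,
    balance_and_expand,
    generate_dataset,
    generate_image,
    make_splits,
    nearest_template_accuracy,
    polyp_mask,
    rim_gradient_energy,
    sample_spec,
    validate_manifest,
)


class TestGenerator:
    def test_byte_identical_for_equal_specs(self):
        spec = sample_spec("adenomatous", seed=5, image_size=48)
        assert np.array_equal(generate_image(spec), generate_image(spec))

    def test_normal_frames_have_empty_polyp_mask(self):
        spec = sample_spec("normal", seed=3, image_size=32)
        assert not polyp_mask(spec).any()
        assert spec.polyp is None

    def test_polyp_mask_nonempty_for_lesions(self):
        for label in ("hyperplastic", "adenomatous", "serrated"):
            spec = sample_spec(label, seed=1, image_size=48)
            assert polyp_mask(spec).sum() > 10

    def test_rim_roughness_ordering(self):
        # by construction: saw-tooth serrated margins > lobulated adenomatous
        # > smooth hyperplastic domes, measured as rim gradient energy
        energies = {}
        for label in ("hyperplastic", "adenomatous", "serrated"):
            vals = []
            for s in range(100):
                spec = sample_spec(label, seed=1000 + s, image_size=64)
                vals.append(rim_gradient_energy(generate_image(spec), spec))
            energies[label] = np.mean(vals)
        assert energies["serrated"] > energies["adenomatous"] > energies["hyperplastic"]

    def test_output_is_uint8_rgb(self):
        img = generate_image(sample_spec("serrated", seed=2, image_size=24))
        assert img.dtype == np.uint8 and img.shape == (24, 24, 3)

    def test_binary_polyp_label_mixes_subtypes(self):
        subtypes = {
            sample_spec("polyp", seed=s).polyp.serration_amp > 0.05
            for s in range(30)
        }
        assert subtypes == {True, False}  # both serrated and non-serrated drawn


class TestAugmentation:
    def test_registry_has_exactly_21_ops(self):
        assert len(AUGMENTATIONS) == 21

    def test_unknown_op_lists_registry(self):
        img = np.zeros((8, 8, 3), np.uint8)
        with pytest.raises(ValueError, match="h_flip"):
            augment(img, "warp_speed")

    @pytest.mark.parametrize("op", sorted(AUGMENTATIONS))
    def test_shape_dtype_preserved_and_deterministic(self, op):
        img = generate_image(sample_spec("adenomatous", seed=4, image_size=32))
        out1 = augment(img, op, seed=9)
        out2 = augment(img, op, seed=9)
        assert out1.shape == img.shape and out1.dtype == np.uint8
        assert np.array_equal(out1, out2)

    def test_horizontal_flip_involution(self):
        img = generate_image(sample_spec("normal", seed=6, image_size=16))
        assert np.array_equal(augment(augment(img, "h_flip"), "h_flip"), img)

    def test_rot90_four_times_identity(self):
        img = generate_image(sample_spec("normal", seed=6, image_size=16))
        out = img
        for _ in range(4):
            out = augment(out, "rot90")
        assert np.array_equal(out, img)

    def test_brightness_round_trip_within_one_level(self):
        img = np.full((8, 8, 3), 120, np.uint8)  # clipping-free mid-range
        out = augment(augment(img, "brightness_up"), "brightness_down")
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 1


class TestBalanceAndExpand:
    def test_stage1_equalizes_82_100(self):
        ds = generate_dataset({"polyp": 82, "normal": 100}, image_size=16, seed=0)
        out = balance_and_expand(ds, stage1_target=100, seed=1)
        counts = out.manifest["label"].value_counts()
        assert counts["polyp"] == 100 and counts["normal"] == 100

    def test_stage2_expands_normals_to_1100(self):
        # desk-scale version of the published flow: 10 normal originals
        # expanded to 110 (the printed 100 -> 1100 at one-tenth size)
        ds = generate_dataset({"normal": 10}, image_size=16, seed=0)
        out = balance_and_expand(ds, stage2_target=110, seed=1)
        assert (out.manifest["label"] == "normal").sum() == 110
        aug = out.manifest[out.manifest["provenance"] == "augmented"]
        assert len(aug) == 100

    def test_already_balanced_stage1_noop(self):
        ds = generate_dataset({"normal": 5, "polyp": 5}, image_size=16, seed=0)
        out = balance_and_expand(ds, seed=1)
        assert len(out.manifest) == len(ds.manifest)

    def test_target_below_count_rejected(self):
        ds = generate_dataset({"normal": 5}, image_size=16, seed=0)
        with pytest.raises(ValueError):
            balance_and_expand(ds, stage1_target=3)

    def test_augmented_rows_record_origin(self):
        ds = generate_dataset({"normal": 3}, image_size=16, seed=0)
        out = balance_and_expand(ds, stage2_target=9, seed=1)
        aug = out.manifest[out.manifest["provenance"] == "augmented"]
        assert set(aug["origin_id"]) <= set(ds.manifest["path"])


class TestMakeSplits:
    def _published_flow_pool(self):
        """Desk-scale replica of the published pool: one-tenth sizes.

        110 polyp originals; 10 normal originals, 5 of which (the eventual
        holdout candidates) have no augmented derivatives and the other 5
        are expanded to 105 augmented normals -> 110 + 110 pool.
        """
        ds = generate_dataset({"polyp": 110, "normal": 10}, image_size=16, seed=0)
        mf = ds.manifest.copy()
        # pre-assign the 5 expandable normals by augmenting only them
        normals = mf[mf["label"] == "normal"]["path"].tolist()
        rows = []
        images = dict(ds.images)
        ops = sorted(AUGMENTATIONS)
        for k in range(100):
            src = normals[k % 5]
            img = augment(ds.images[src], ops[k % 21], seed=k)
            path = f"aug_{k:03d}.png"
            images[path] = img
            rows.append((path, "normal", "train", "augmented", src, k))
        manifest = pd.concat(
            [mf, pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))],
            ignore_index=True,
        )
        return ImageDataset(images, manifest)

    def test_published_split_arithmetic(self):
        # (220 - 10) * 0.8 / 0.2 with a 5+5 holdout of originals
        ds = self._published_flow_pool()
        out = make_splits(ds, {"polyp": 5, "normal": 5}, ratio=0.8, seed=3)
        counts = out.manifest["split"].value_counts()
        assert counts["test"] == 10
        assert counts["train"] == 168
        assert counts["val"] == 42

    def test_ratio_one_rejected(self, binary_dataset):
        with pytest.raises(ValueError):
            make_splits(binary_dataset, {"normal": 2, "polyp": 2}, ratio=1.0)

    def test_same_seed_identical_assignment(self, binary_dataset):
        a = make_splits(binary_dataset, {"normal": 3, "polyp": 3}, seed=5)
        b = make_splits(binary_dataset, {"normal": 3, "polyp": 3}, seed=5)
        assert a.manifest["split"].tolist() == b.manifest["split"].tolist()

    def test_stratification_within_one_image(self, binary_dataset):
        out = make_splits(binary_dataset, {"normal": 3, "polyp": 3}, ratio=0.8, seed=1)
        for _, rows in out.manifest[out.manifest["split"] != "test"].groupby("label"):
            n = len(rows)
            n_train = (rows["split"] == "train").sum()
            assert abs(n_train - 0.8 * n) <= 1

    def test_infeasible_holdout_rejected(self, binary_dataset):
        with pytest.raises(ValueError):
            make_splits(binary_dataset, {"normal": 1000})

    def test_leakage_guard_drops_test_derivatives(self):
        ds = generate_dataset({"normal": 4}, image_size=16, seed=0)
        expanded = balance_and_expand(ds, stage2_target=12, seed=1)
        out = make_splits(expanded, {"normal": 2}, ratio=0.8, seed=2)
        validate_manifest(out.manifest)  # raises on any leak
        test_origins = set(
            out.manifest[out.manifest["split"] == "test"]["origin_id"]
        )
        trainval = out.manifest[out.manifest["split"] != "test"]
        assert not (set(trainval["origin_id"]) & test_origins)

    def test_validate_manifest_catches_augmented_test(self):
        mf = pd.DataFrame(
            [("a.png", "normal", "test", "augmented", "b.png", 0)],
            columns=list(MANIFEST_COLUMNS),
        )
        with pytest.raises(ValueError):
            validate_manifest(mf)


class TestSeparability:
    def test_template_classifier_beats_chance_binary(self, binary_dataset):
        X, y = binary_dataset.arrays(classes=("normal", "polyp"))
        assert nearest_template_accuracy(X, y, seed=0) > 0.65  # chance = 0.5

    def test_template_classifier_beats_chance_multiclass(self, multi_dataset):
        X, y = multi_dataset.arrays()
        assert nearest_template_accuracy(X, y, seed=0) > 0.45  # chance = 0.25


class TestDatasetIO:
    def test_save_load_roundtrip(self, tmp_path):
        ds = generate_dataset({"normal": 2, "polyp": 2}, image_size=16, seed=0)
        manifest_path = ds.save(tmp_path / "data")
        loaded = ImageDataset.load(manifest_path)
        assert set(loaded.images) == set(ds.images)
        for p in ds.images:
            assert np.array_equal(loaded.images[p], ds.images[p])

    def test_arrays_class_order(self, binary_dataset):
        X, y = binary_dataset.arrays(classes=("normal", "polyp"))
        assert X.shape[1:] == (32, 32, 3)
        assert X.min() >= 0 and X.max() <= 1
        assert set(y) == {0, 1}

    def test_spec_label_polyp_consistency(self):
        with pytest.raises(ValueError):
            sample_spec("granuloma", seed=0)
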