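"""Annotation readers, transforms and the synthetic fixture generator."""

import hashlib
import json

import numpy as np
import pytest
from PIL import Image

from esanet.data import (AnnotationRecord, SyntheticDatasetSpec, TransformConfig,
                         class_histogram, denormalize, eval_transform,
                         generate_synthetic_dataset, read_annotations,
                         read_image_folder, synthetic_arrays,
                         synthetic_dataset, train_transform)


class TestAnnotations:
    def _write(self, tmp_path, entries):
        f = tmp_path / "ann.json"
        f.write_text(json.dumps(entries))
        return f

    def test_toy_file_preserves_classes(self, tmp_path):
        f = self._write(tmp_path, [
            {"image_id": "a.jpg", "disease_class": 0},
            {"image_id": "b.jpg", "disease_class": 60}])
        recs = read_annotations(f)
        assert [r.disease_class for r in recs] == [0, 60]
        assert recs[0].image_path == "a.jpg"

    def test_empty_array_gives_empty_list(self, tmp_path):
        assert read_annotations(self._write(tmp_path, [])) == []

    def test_histogram_matches_independent_tally(self, tmp_path):
        classes = [0, 0, 1, 2, 2, 2, 5, 5, 1, 0]
        f = self._write(tmp_path, [
            {"image_id": f"{i}.jpg", "disease_class": c}
            for i, c in enumerate(classes)])
        hist = class_histogram(read_annotations(f))
        want = {}
        for c in classes:
            want[c] = want.get(c, 0) + 1
        assert hist == dict(sorted(want.items()))

    def test_missing_field_names_entry_index(self, tmp_path):
        f = self._write(tmp_path, [{"image_id": "a.jpg", "disease_class": 1},
                                   {"image_id": "b.jpg"}])
        with pytest.raises(ValueError, match="entry 1"):
            read_annotations(f)

    def test_out_of_range_class_rejected(self, tmp_path):
        f = self._write(tmp_path, [{"image_id": "a.jpg", "disease_class": 61}])
        with pytest.raises(ValueError, match="outside"):
            read_annotations(f)


class TestTransforms:
    def _gradient_image(self, w=256, h=256):
        arr = np.zeros((h, w, 3), dtype=np.uint8)
        arr[:, :, 0] = np.linspace(0, 255, w, dtype=np.uint8)[None, :]
        arr[:, :, 1] = 128
        return Image.fromarray(arr)

    def test_output_geometry(self):
        out = eval_transform(self._gradient_image())
        assert out.shape == (3, 224, 224)
        # odd aspect ratios still give 3x224x224
        tall = self._gradient_image(300, 600)
        assert eval_transform(tall).shape == (3, 224, 224)

    def test_eval_transform_deterministic(self):
        img = self._gradient_image()
        np.testing.assert_array_equal(eval_transform(img), eval_transform(img))

    def test_constant_gray_image_value(self):
        img = Image.fromarray(np.full((256, 256, 3), 128, np.uint8))
        out = eval_transform(img)
        cfg = TransformConfig()
        for c in range(3):
            want = (128 / 255 - cfg.mean[c]) / cfg.sd[c]
            np.testing.assert_allclose(out[c], want, atol=1e-6)

    def test_flip_matches_column_reversal_oracle(self):
        img = self._gradient_image()
        unflipped = eval_transform(img)
        seed_flip = next(s for s in range(50)
                         if np.random.default_rng(s).random() < 0.5)
        seed_keep = next(s for s in range(50)
                         if np.random.default_rng(s).random() >= 0.5)
        flipped = train_transform(img, np.random.default_rng(seed_flip))
        np.testing.assert_allclose(flipped, unflipped[:, :, ::-1], atol=1e-6)
        kept = train_transform(img, np.random.default_rng(seed_keep))
        np.testing.assert_allclose(kept, unflipped, atol=1e-6)

    def test_same_rng_state_same_output(self):
        img = self._gradient_image()
        a = train_transform(img, np.random.default_rng(42))
        b = train_transform(img, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_denormalize_round_trip(self):
        img = self._gradient_image()
        out = eval_transform(img)
        recovered = denormalize(out)
        cropped = np.asarray(img)[16:240, 16:240]
        assert np.max(np.abs(recovered.astype(int) - cropped.astype(int))) <= 1

    def test_non_rgb_converted_with_warning(self):
        gray = Image.fromarray(np.full((256, 256), 99, np.uint8), mode="L")
        with pytest.warns(UserWarning, match="RGB"):
            out = eval_transform(gray)
        assert out.shape == (3, 224, 224)

    def test_small_image_upscaled_with_warning(self):
        tiny = Image.fromarray(np.zeros((50, 50, 3), np.uint8))
        with pytest.warns(UserWarning, match="upscal"):
            assert eval_transform(tiny).shape == (3, 224, 224)


class TestSyntheticGenerator:
    def test_sample_counts(self, synth_spec):
        imgs, labels = synthetic_arrays(synth_spec)
        assert imgs.shape == (200, 32, 32, 3)
        assert np.array_equal(np.bincount(labels), [40] * 5)

    def test_zero_samples_is_valid_empty_dataset(self, tmp_path):
        spec = SyntheticDatasetSpec(num_classes=3, samples_per_class=0)
        recs = generate_synthetic_dataset(spec, tmp_path / "empty")
        assert recs == []
        assert json.loads((tmp_path / "empty" / "annotations.json").read_text()) == []

    def test_regeneration_is_byte_identical(self, tmp_path):
        spec = SyntheticDatasetSpec(num_classes=3, samples_per_class=4,
                                    image_size=24, seed=7)
        generate_synthetic_dataset(spec, tmp_path / "a")
        generate_synthetic_dataset(spec, tmp_path / "b")
        man_a = json.loads((tmp_path / "a" / "manifest.json").read_text())
        man_b = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert man_a["checksums"] == man_b["checksums"]
        # and the manifest checksums are real
        for rel, digest in man_a["checksums"].items():
            assert hashlib.sha256(
                (tmp_path / "a" / rel).read_bytes()).hexdigest() == digest

    def test_different_seeds_differ(self):
        a, _ = synthetic_arrays(SyntheticDatasetSpec(3, 2, 24, seed=1))
        b, _ = synthetic_arrays(SyntheticDatasetSpec(3, 2, 24, seed=2))
        assert not np.array_equal(a, b)

    def test_both_layouts_round_trip(self, tmp_path):
        spec = SyntheticDatasetSpec(num_classes=3, samples_per_class=2,
                                    image_size=24, seed=3)
        written = generate_synthetic_dataset(spec, tmp_path / "ds")
        from_json = read_annotations(tmp_path / "ds" / "annotations.json",
                                     num_classes=3, check_paths=True)
        assert from_json == written
        from_tree = read_image_folder(tmp_path / "ds" / "images")
        assert sorted((r.disease_class) for r in from_tree) == \
            sorted(r.disease_class for r in written)

    def test_distinct_blob_params_enforced(self):
        from esanet.data import BlobParams
        same = [BlobParams(2, (0.1, 0.2), (200, 40, 40))] * 2
        with pytest.raises(ValueError, match="distinct"):
            SyntheticDatasetSpec(num_classes=2, samples_per_class=1,
                                 blob_params=same)

    def test_nearest_mean_color_classifier_beats_chance(self, synth_spec):
        """Classes are separable by design: a trivial nearest-mean-color
        classifier must beat the 20% chance level comfortably."""
        imgs, labels = synthetic_arrays(synth_spec)
        feats = imgs.reshape(len(imgs), -1, 3).mean(axis=1)
        centroids = np.stack([feats[labels == c].mean(axis=0)
                              for c in range(synth_spec.num_classes)])
        pred = np.argmin(((feats[:, None, :] - centroids[None]) ** 2).sum(-1),
                         axis=1)
        assert (pred == labels).mean() > 0.6

    def test_training_ready_dataset(self, synth_data):
        assert synth_data.images.shape == (200, 3, 32, 32)
        assert synth_data.images.dtype == np.float32
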