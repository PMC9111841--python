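"""Feature extraction, classifier heads, augmentation and cross-validation."""

import numpy as np
import pytest

from mycoquant import (
    ClassLabel,
    SamplingArea,
    augment_dataset,
    classify,
    cross_validate,
    extract_features,
    load_model,
    save_model,
    train_classifier,
)
from mycoquant.classify import _feature_matrix, _HIST_BINS


def _blobs(rng, n_per_class=50, spread=0.3):
    """Four well-separated 2-D Gaussian blobs, one per class."""
    means = np.array([[0, 0], [4, 0], [0, 4], [4, 4]], float)
    X = np.concatenate([rng.normal(0, spread, (n_per_class, 2)) + m for m in means])
    y = np.repeat([0, 1, 2, 3], n_per_class)
    return X, y


class TestExtractFeatures:
    def test_deterministic(self, patch_set):
        a = patch_set[0]
        v1 = extract_features(a).values
        v2 = extract_features(a).values
        assert np.array_equal(v1, v2)

    def test_black_white_distinct(self):
        black = SamplingArea(patch=np.zeros((64, 64, 3), np.uint8))
        white = SamplingArea(patch=np.full((64, 64, 3), 255, np.uint8))
        d = np.linalg.norm(extract_features(black).values - extract_features(white).values)
        assert d > 0.5

    def test_color_histogram_counting_oracle(self):
        patch = np.zeros((64, 64, 3), np.uint8)
        patch[:, :32] = (0, 0, 255)  # blue half
        patch[:, 32:] = (255, 255, 255)  # white half
        v = extract_features(SamplingArea(patch=patch)).values
        nb = _HIST_BINS
        blue_bin = 0 * nb * nb + 0 * nb + (nb - 1)
        white_bin = (nb - 1) * nb * nb + (nb - 1) * nb + (nb - 1)
        assert v[blue_bin] == pytest.approx(0.5)
        assert v[white_bin] == pytest.approx(0.5)
        assert np.sum(v[: nb**3]) == pytest.approx(1.0)

    def test_unknown_extractor_rejected(self, patch_set):
        with pytest.raises(ValueError, match="unknown extractor"):
            extract_features(patch_set[0], extractor="resnet-9000")


class TestTrainClassifier:
    @pytest.mark.parametrize("kind", ["svm", "fc"])
    def test_separable_blobs_memorized(self, kind, rng):
        X, y = _blobs(rng)
        model = train_classifier(X, y, kind=kind, seed=0)
        assert (model.predict_features(X) == y).mean() == 1.0

    def test_same_seed_identical_predictions(self, rng):
        X, y = _blobs(rng)
        Xtest = rng.normal(2, 2, (40, 2))
        p1 = train_classifier(X, y, kind="fc", seed=3).predict_features(Xtest)
        p2 = train_classifier(X, y, kind="fc", seed=3).predict_features(Xtest)
        assert np.array_equal(p1, p2)

    def test_invalid_labels_rejected(self, rng):
        X, _ = _blobs(rng, 5)
        with pytest.raises(ValueError, match="invalid class label"):
            train_classifier(X, [7] * len(X), kind="svm")

    def test_single_class_names_missing(self, rng):
        X = rng.normal(0, 1, (10, 2))
        with pytest.raises(ValueError, match=r"missing classes: \[0, 2, 3\]"):
            train_classifier(X, [1] * 10, kind="svm")

    def test_unknown_kind_rejected(self, rng):
        X, y = _blobs(rng, 5)
        with pytest.raises(ValueError):
            train_classifier(X, y, kind="forest")


class TestClassify:
    def test_empty_input(self, patch_set):
        X = _feature_matrix(patch_set, "handcrafted")
        y = [int(a.label) for a in patch_set]
        model = train_classifier(X, y, kind="svm")
        assert classify(model, []) == []

    def test_no_root_patch_labeled_no_root(self, patch_set):
        X = _feature_matrix(patch_set, "handcrafted")
        y = [int(a.label) for a in patch_set]
        model = train_classifier(X, y, kind="svm")
        background = [a for a in patch_set if a.label == ClassLabel.NO_ROOT][:10]
        assert all(l == ClassLabel.NO_ROOT for l in classify(model, background))

    def test_save_load_prediction_identical(self, patch_set, tmp_path):
        X = _feature_matrix(patch_set, "handcrafted")
        y = [int(a.label) for a in patch_set]
        model = train_classifier(X, y, kind="svm")
        save_model(model, tmp_path / "m.bin")
        loaded = load_model(tmp_path / "m.bin")
        assert np.array_equal(model.predict_features(X), loaded.predict_features(X))
        assert loaded.extractor_id == model.extractor_id


class TestAugment:
    def test_output_count(self, patch_set):
        out = augment_dataset(patch_set[:1], seed=0, n_crops=2, keep_originals=True)
        assert len(out) == 1 + 2 + 2
        assert all(a.label == patch_set[0].label for a in out)
        assert all(a.patch.shape == (224, 224, 3) for a in out)

    def test_horizontal_flip_is_involution(self, patch_set):
        patch = patch_set[0].resized(224)
        assert np.array_equal(patch[:, ::-1][:, ::-1], patch)

    def test_bad_crop_fraction(self, patch_set):
        with pytest.raises(ValueError):
            augment_dataset(patch_set[:1], crop_fraction=1.5)


class TestCrossValidate:
    def test_separable_patch_set_high_accuracy(self, patch_set):
        report = cross_validate(patch_set, k=5, kind="svm", seed=0)
        assert report.accuracy >= 0.9
        counts = np.bincount([int(a.label) for a in patch_set], minlength=4)
        np.testing.assert_array_equal(report.confusion.sum(axis=1), counts)
        assert report.pooled_accuracy == pytest.approx(
            np.trace(report.confusion) / report.confusion.sum()
        )

    def test_permuted_labels_chance_level(self, patch_set, rng):
        shuffled = [
            SamplingArea(patch=a.patch, label=int(l))
            for a, l in zip(patch_set, rng.permutation([int(a.label) for a in patch_set]))
        ]
        report = cross_validate(shuffled, k=5, kind="svm", seed=0)
        assert 0.15 <= report.accuracy <= 0.35

    def test_thin_class_stratification_error(self, patch_set):
        few = patch_set[:3] + [a for a in patch_set if a.label == ClassLabel.ARBUSCULES][:60]
        with pytest.raises(ValueError, match="fewer than k"):
            cross_validate(few, k=5)
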