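"""Centroid training, Euclidean prediction and cross-validation."""

import numpy as np
import pytest

from glcm3d.classification import (
    CentroidModel,
    LabeledFeatureSet,
    cross_validate,
    euclidean_distance,
    kfold_split,
    predict,
    train_centroids,
)
from glcm3d.errors import InvalidInputError
from glcm3d.features import FeatureVector


def fv(values, variant="original", n=16):
    return FeatureVector.from_array(np.asarray(values, float), variant, n)


def make_set(labels, vectors, variant="original", n=16):
    return LabeledFeatureSet(
        ids=tuple(f"im{i}" for i in range(len(labels))),
        labels=tuple(labels),
        vectors=np.asarray(vectors, dtype=np.float64),
        variant=variant,
        n_levels=n,
    )


class TestTrainCentroids:
    def test_single_sample_classes_equal_their_samples(self, rng):
        vecs = rng.normal(size=(3, 6))
        model = train_centroids(make_set(["a", "b", "c"], vecs))
        assert np.allclose(model.centroids, vecs)

    def test_mean_of_two_samples(self):
        model = train_centroids(make_set(["a", "a"], [np.zeros(6), np.full(6, 2.0)]))
        assert np.allclose(model.centroids[0], np.ones(6))

    def test_matches_summation_oracle(self, rng):
        vecs = rng.normal(size=(10, 6))
        labels = ["a"] * 5 + ["b"] * 5
        model = train_centroids(make_set(labels, vecs))
        for ci, sel in enumerate((slice(0, 5), slice(5, 10))):
            expected = sum(vecs[i] for i in range(*sel.indices(10))) / 5
            assert np.allclose(model.centroids[ci], expected)

    def test_empty_class_is_named_in_error(self):
        data = LabeledFeatureSet(
            ids=("x",), labels=("a",), vectors=np.zeros((1, 6)),
            variant="original", n_levels=16, classes=("a", "ghost"),
        )
        with pytest.raises(InvalidInputError, match="ghost"):
            train_centroids(data)

    def test_standardization_uses_training_stats(self, rng):
        vecs = rng.normal(size=(8, 6)) * 100
        model = train_centroids(make_set(["a"] * 4 + ["b"] * 4, vecs), standardize=True)
        assert model.feature_mean == pytest.approx(vecs.mean(axis=0))


class TestEuclideanDistance:
    def test_identical_vectors(self):
        assert euclidean_distance(fv(np.ones(6)), fv(np.ones(6))) == 0.0

    def test_three_four_five(self):
        a = fv([0, 0, 0, 0, 0, 0])
        b = fv([3, 4, 0, 0, 0, 0])
        assert euclidean_distance(a, b) == pytest.approx(5.0)

    def test_matches_termwise_oracle(self, rng):
        a, b = rng.normal(size=(2, 6))
        expected = sum((x - y) ** 2 for x, y in zip(a, b)) ** 0.5
        assert euclidean_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_variant_and_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            euclidean_distance(fv(np.ones(6), "original"), fv(np.ones(6), "invariant"))
        with pytest.raises(InvalidInputError):
            euclidean_distance(np.ones(6), np.ones(5))


class TestPredict:
    def test_centroid_maps_to_its_own_class(self):
        model = train_centroids(make_set(["a", "b"], [np.zeros(6), np.ones(6)]))
        assert predict(model, np.zeros(6)) == "a"
        assert predict(model, np.ones(6)) == "b"

    def test_ties_broken_by_class_order(self):
        model = train_centroids(make_set(["a", "b"], [np.zeros(6), np.full(6, 2.0)]))
        assert predict(model, np.ones(6)) == "a"

    def test_nearest_by_brute_force(self, rng):
        cents = rng.normal(size=(2, 6)) * 10
        model = train_centroids(make_set(["a", "b"], cents))
        for _ in range(20):
            x = rng.normal(size=6)
            d = [np.linalg.norm(x - c) for c in cents]
            assert predict(model, x) == ("a", "b")[int(np.argmin(d))]

    def test_feature_permutation_invariance(self, rng):
        vecs = rng.normal(size=(4, 6))
        model = train_centroids(make_set(["a", "a", "b", "b"], vecs))
        x = rng.normal(size=6)
        perm = rng.permutation(6)
        model_p = train_centroids(make_set(["a", "a", "b", "b"], vecs[:, perm]))
        assert predict(model, x) == predict(model_p, x[perm])

    def test_variant_mismatch_rejected(self):
        model = train_centroids(make_set(["a", "b"], np.zeros((2, 6))))
        with pytest.raises(InvalidInputError):
            predict(model, fv(np.zeros(6), "invariant"))


class TestKfoldSplit:
    def test_stratified_partition(self):
        labels = ["a"] * 25 + ["b"] * 25 + ["c"] * 25 + ["d"] * 25
        folds = kfold_split(labels, k=5, seed=0)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(100))
        for fold in folds:
            assert len(fold) == 20
            _, counts = np.unique(np.asarray(labels)[fold], return_counts=True)
            assert np.all(counts == 5)

    def test_same_seed_identical_folds(self):
        labels = ["a"] * 10 + ["b"] * 10
        f1 = kfold_split(labels, 5, seed=7)
        f2 = kfold_split(labels, 5, seed=7)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_two_folds_partition(self):
        folds = kfold_split(["a"] * 5 + ["b"] * 5, k=2, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [5, 5]
        assert len(set(np.concatenate(folds))) == 10

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(InvalidInputError):
            kfold_split(["a", "b"], k=3)

    def test_small_class_degrades_with_warning(self):
        with pytest.warns(UserWarning):
            kfold_split(["a"] * 9 + ["b"], k=5, seed=0)


class TestCrossValidate:
    def test_separable_clusters_are_perfect(self, rng):
        vecs = np.vstack([rng.normal(0, 0.1, (10, 6)), rng.normal(10, 0.1, (10, 6))])
        data = make_set(["a"] * 10 + ["b"] * 10, vecs)
        res = cross_validate(data, k=5, seed=0)
        assert res.accuracy() == 1.0

    def test_each_record_predicted_once(self, rng):
        vecs = rng.normal(size=(20, 6))
        data = make_set(["a"] * 10 + ["b"] * 10, vecs)
        res = cross_validate(data, k=5, seed=0)
        assert len(res.predicted_labels) == 20
        assert len(res.fold_of_record) == 20
        # folds disjoint & exhaustive: every fold index appears
        assert set(res.fold_of_record) == set(range(5))

    def test_identical_vectors_follow_tie_rule(self):
        # all-equal features: every query lands exactly between centroids of
        # equal value, so the first class in model order always wins
        data = make_set(["a"] * 6 + ["b"] * 6, np.ones((12, 6)))
        res = cross_validate(data, k=3, seed=0)
        assert all(p == "a" for p in res.predicted_labels)
        assert res.accuracy() == pytest.approx(0.5)

    def test_leave_one_out_boundary(self, rng):
        vecs = rng.normal(size=(6, 6))
        data = make_set(["a"] * 3 + ["b"] * 3, vecs)
        with pytest.warns(UserWarning):  # classes smaller than k
            res = cross_validate(data, k=6, seed=0)
        assert len(res.predicted_labels) == 6


class TestModelSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        model = train_centroids(
            make_set(["a", "a", "b"], rng.normal(size=(3, 6))), standardize=True
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = CentroidModel.from_json(path)
        assert back.classes == model.classes
        assert np.allclose(back.centroids, model.centroids)
        assert np.allclose(back.feature_mean, model.feature_mean)
        x = rng.normal(size=6)
        assert predict(back, x) == predict(model, x)
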