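"""Nearest-centroid identification under stratified k-fold cross-validation.

Training averages the six texture statistics per class; a query image is
assigned to the class whose mean feature vector is closest in Euclidean
distance.  Evaluation uses seeded stratified k-fold splits (k=5 gives the
80/20 train/test pattern), pooling held-out predictions over folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from glcm3d.errors import InvalidInputError
from glcm3d.features import FEATURE_NAMES, FeatureVector


@dataclass(frozen=True)
class LabeledFeatureSet:
    """Feature vectors with image ids and class labels.

    All vectors must share the same variant and gray-level count; ``classes``
    is the ordered list of distinct labels (order fixes tie-breaking).
    """

    ids: tuple[str, ...]
    labels: tuple[str, ...]
    vectors: np.ndarray  # (n_records, 6)
    variant: str
    n_levels: int
    classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.labels) or len(self.ids) != len(self.vectors):
            raise InvalidInputError("ids, labels and vectors must align")
        if not self.classes:
            seen: dict[str, None] = {}
            for lab in self.labels:
                seen.setdefault(lab, None)
            object.__setattr__(self, "classes", tuple(seen))
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise InvalidInputError(f"labels not in classes: {sorted(unknown)}")

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str, FeatureVector]]
    ) -> "LabeledFeatureSet":
        if not records:
            raise InvalidInputError("empty record list")
        variants = {fv.variant for _, _, fv in records}
        levels = {fv.n_levels for _, _, fv in records}
        if len(variants) != 1 or len(levels) != 1:
            raise InvalidInputError(
                "all feature vectors must share variant and n_levels"
            )
        return cls(
            ids=tuple(r[0] for r in records),
            labels=tuple(r[1] for r in records),
            vectors=np.stack([r[2].as_array() for r in records]),
            variant=variants.pop(),
            n_levels=levels.pop(),
        )

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, idx: np.ndarray) -> "LabeledFeatureSet":
        return LabeledFeatureSet(
            ids=tuple(self.ids[i] for i in idx),
            labels=tuple(self.labels[i] for i in idx),
            vectors=self.vectors[idx],
            variant=self.variant,
            n_levels=self.n_levels,
            classes=self.classes,
        )


@dataclass(frozen=True)
class CentroidModel:
    """Per-class mean feature vectors, optionally with z-score scaling
    (fitted on training data only) applied before distances."""

    classes: tuple[str, ...]
    centroids: np.ndarray  # (n_classes, 6) in standardized space if scaled
    variant: str
    n_levels: int
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return x
        return (x - self.feature_mean) / self.feature_scale

    def to_json(self, path: str | Path) -> None:
        obj = {
            "classes": list(self.classes),
            "centroids": self.centroids.tolist(),
            "variant": self.variant,
            "n_levels": self.n_levels,
            "feature_names": list(FEATURE_NAMES),
            "feature_mean": None
            if self.feature_mean is None
            else self.feature_mean.tolist(),
            "feature_scale": None
            if self.feature_scale is None
            else self.feature_scale.tolist(),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CentroidModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            classes=tuple(obj["classes"]),
            centroids=np.asarray(obj["centroids"], dtype=np.float64),
            variant=obj["variant"],
            n_levels=obj["n_levels"],
            feature_mean=None
            if obj["feature_mean"] is None
            else np.asarray(obj["feature_mean"]),
            feature_scale=None
            if obj["feature_scale"] is None
            else np.asarray(obj["feature_scale"]),
        )


def train_centroids(
    train: LabeledFeatureSet, standardize: bool = False
) -> CentroidModel:
    """Arithmetic per-class mean of the training feature vectors.

    With ``standardize=True``, features are z-scored using the training
    mean/std before averaging (distances are then computed in the same
    standardized space).  Off by default: the identification rule applies
    Euclidean distance to the raw statistics.

    Raises
    ------
    InvalidInputError
        If any declared class has no training record (the error names it).
    """
    x = train.vectors
    mean = scale = None
    if standardize:
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        x = (x - mean) / scale
    labels = np.asarray(train.labels)
    cents = []
    for cls_label in train.classes:
        mask = labels == cls_label
        if not mask.any():
            raise InvalidInputError(f"class {cls_label!r} has no training records")
        cents.append(x[mask].mean(axis=0))
    return CentroidModel(
        classes=train.classes,
        centroids=np.stack(cents),
        variant=train.variant,
        n_levels=train.n_levels,
        feature_mean=mean,
        feature_scale=scale,
    )


def euclidean_distance(a: FeatureVector | np.ndarray, b: FeatureVector | np.ndarray) -> float:
    """Plain Euclidean distance between two feature vectors.

    Raises
    ------
    InvalidInputError
        On length or variant mismatch.
    """
    if isinstance(a, FeatureVector) and isinstance(b, FeatureVector):
        if a.variant != b.variant:
            raise InvalidInputError("feature vectors have different variants")
        a, b = a.as_array(), b.as_array()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidInputError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def predict(model: CentroidModel, x: FeatureVector | np.ndarray) -> str:
    """Label of the nearest centroid; ties broken by class order."""
    if isinstance(x, FeatureVector):
        if x.variant != model.variant:
            raise InvalidInputError(
                f"variant mismatch: model {model.variant!r}, query {x.variant!r}"
            )
        x = x.as_array()
    x = model.transform(np.asarray(x, dtype=np.float64))
    dists = np.sqrt(np.sum((model.centroids - x) ** 2, axis=1))
    return model.classes[int(np.argmin(dists))]  # argmin takes first on ties


def kfold_split(labels: list[str], k: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded stratified partition into k folds of test indices.

    Falls back (with a warning) to unstratified folds when some class has
    fewer than k members.

    Raises
    ------
    InvalidInputError
        If k < 2 or k exceeds the number of records.
    """
    n = len(labels)
    if k < 2:
        raise InvalidInputError(f"k must be >= 2, got {k}")
    if k > n:
        raise InvalidInputError(f"k={k} exceeds the {n} available records")
    labels_arr = np.asarray(labels)
    _, counts = np.unique(labels_arr, return_counts=True)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        warnings.warn(
            f"some class has fewer than {k} members; folds are not stratified",
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n), labels_arr)]


@dataclass(frozen=True)
class CVResult:
    """Pooled cross-validation predictions, one per record."""

    ids: tuple[str, ...]
    true_labels: tuple[str, ...]
    predicted_labels: tuple[str, ...]
    fold_of_record: tuple[int, ...]
    classes: tuple[str, ...]

    def accuracy(self) -> float:
        correct = sum(
            t == p for t, p in zip(self.true_labels, self.predicted_labels)
        )
        return correct / len(self.true_labels)


def cross_validate(
    data: LabeledFeatureSet,
    k: int = 5,
    seed: int = 0,
    standardize: bool = False,
) -> CVResult:
    """k-fold cross-validation of the centroid classifier.

    Each fold is predicted by a model trained on the other k-1 folds; the
    pooled predictions cover every record exactly once.
    """
    folds = kfold_split(list(data.labels), k=k, seed=seed)
    preds: dict[int, tuple[str, int]] = {}
    for fold_no, test_idx in enumerate(folds):
        mask = np.ones(len(data), dtype=bool)
        mask[test_idx] = False
        train_idx = np.flatnonzero(mask)
        model = train_centroids(data.subset(train_idx), standardize=standardize)
        for i in test_idx:
            preds[int(i)] = (predict(model, data.vectors[i]), fold_no)
    order = sorted(preds)
    return CVResult(
        ids=data.ids,
        true_labels=data.labels,
        predicted_labels=tuple(preds[i][0] for i in order),
        fold_of_record=tuple(preds[i][1] for i in order),
        classes=data.classes,
    )
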