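"""Hierarchical sound-image classification.

The on-device model in the original system is a quantized MobileNet; here a
seedable, CPU-trainable baseline stands in: multinomial logistic regression
on 4x4-block-averaged (48x48), standardized spectrogram pixels, wrapped as a
scikit-learn estimator.  Training uses only Level-3 labels; Level-2 and
Level-1 predictions are the taxonomy parents of the Level-3 argmax, so the
coarse levels are classified implicitly.

Ties are broken everywhere toward the lowest class id.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .prep import IMAGE_SIZE, SpectroImage
from .taxonomy import SoundTaxonomy

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ProbabilityVector:
    """Per-class probabilities over the full taxonomy, in class-id order."""

    class_ids: tuple[int, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        if len(self.class_ids) != len(self.probs):
            raise ValueError("class_ids and probs length mismatch")
        if np.any(self.probs < 0) or abs(float(self.probs.sum()) - 1.0) > 1e-6:
            raise ValueError("probabilities must be >= 0 and sum to 1 within 1e-6")

    def argmax(self) -> int:
        """Most probable class; exact ties resolve to the lowest class id."""
        return self.class_ids[int(np.argmax(self.probs))]

    def topk(self, k: int) -> list[tuple[int, float]]:
        """Top-k (class_id, probability), descending, ties by ascending id."""
        if not 1 <= k <= len(self.class_ids):
            raise ValueError(f"k must be in [1, {len(self.class_ids)}], got {k}")
        order = np.lexsort((self.class_ids, -self.probs))
        return [(self.class_ids[i], float(self.probs[i])) for i in order[:k]]

    def as_dict(self) -> dict[int, float]:
        return {c: float(p) for c, p in zip(self.class_ids, self.probs)}


def _image_array(images) -> np.ndarray:
    """Stack SpectroImages (or raw arrays) into (n, 192, 192) float."""
    arrays = [im.pixels if isinstance(im, SpectroImage) else np.asarray(im) for im in images]
    X = np.stack(arrays).astype(np.float64)
    if X.shape[1:] != (IMAGE_SIZE, IMAGE_SIZE):
        raise ValueError(f"expected images of {IMAGE_SIZE}x{IMAGE_SIZE}, got {X.shape[1:]}")
    return X


class SpectroImageClassifier(BaseEstimator, ClassifierMixin):
    """Baseline spectrogram-tile classifier.

    Parameters
    ----------
    taxonomy : SoundTaxonomy, optional
        When given, ``predict_proba`` returns probabilities over the full
        taxonomy class set (zero for classes absent from training).
    block : int
        Downsampling factor; 4 turns 192x192 pixels into 48x48 block means.
    C, max_iter : logistic-regression hyperparameters.
    random_state : seed for the solver; two fits with the same seed and data
        produce identical predictions.
    """

    def __init__(
        self,
        taxonomy: SoundTaxonomy | None = None,
        block: int = 4,
        C: float = 1.0,
        max_iter: int = 300,
        random_state: int = 0,
    ):
        self.taxonomy = taxonomy
        self.block = block
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def _features(self, images) -> np.ndarray:
        X = _image_array(images) / 255.0
        b = self.block
        n, h, w = X.shape
        X = X.reshape(n, h // b, b, w // b, b).mean(axis=(2, 4))
        return X.reshape(n, -1)

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        if len(y) == 0:
            raise ValueError("empty training set")
        feats = self._features(X)
        self.scaler_ = StandardScaler().fit(feats)
        self.model_ = LogisticRegression(
            C=self.C, max_iter=self.max_iter, random_state=self.random_state
        ).fit(self.scaler_.transform(feats), y)
        if self.taxonomy is not None:
            self.classes_ = np.asarray(self.taxonomy.class_ids, dtype=int)
            unknown = set(y) - set(self.classes_.tolist())
            if unknown:
                raise ValueError(f"labels {sorted(unknown)} not in taxonomy")
        else:
            self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        raw = self.model_.predict_proba(self.scaler_.transform(self._features(X)))
        if np.array_equal(self.model_.classes_, self.classes_):
            return raw
        full = np.zeros((raw.shape[0], len(self.classes_)))
        cols = np.searchsorted(self.classes_, self.model_.classes_)
        full[:, cols] = raw
        return full

    def predict(self, X) -> np.ndarray:
        # argmax with lowest-id tie-break (classes_ ascending, argmax -> first)
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def predict_vector(self, image) -> ProbabilityVector:
        """Classify a single image into a full ProbabilityVector."""
        probs = self.predict_proba([image])[0]
        total = probs.sum()
        if total > 0:  # guard against numerical drift in the zero-fill path
            probs = probs / total
        return ProbabilityVector(tuple(int(c) for c in self.classes_), probs)


# ---------------------------------------------------------------------------
# functional surface


def split_dataset(images, labels, train_fraction: float = 0.7, seed: int = 0):
    """Stratified split by Level-3 class, reproducible per seed.

    Returns ((train_images, train_labels), (test_images, test_labels)).
    Every class needs >= 2 examples and both sides must be nonempty.
    """
    labels = np.asarray(labels, dtype=int)
    if len(images) != len(labels):
        raise ValueError("images and labels length mismatch")
    _, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 examples to stratify")
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    idx_train, idx_test = train_test_split(
        np.arange(len(labels)),
        train_size=train_fraction,
        stratify=labels,
        random_state=seed,
    )
    pick = lambda idx: ([images[i] for i in idx], labels[idx])
    return pick(np.sort(idx_train)), pick(np.sort(idx_test))


def train_baseline(
    images, labels, taxonomy: SoundTaxonomy, seed: int = 0, **hyperparams
) -> SpectroImageClassifier:
    """Fit the baseline classifier on Level-3 labels."""
    clf = SpectroImageClassifier(taxonomy=taxonomy, random_state=seed, **hyperparams)
    return clf.fit(images, labels)


def predict(model: SpectroImageClassifier, image) -> ProbabilityVector:
    return model.predict_vector(image)


def rollup(
    prob: ProbabilityVector, taxonomy: SoundTaxonomy, level: int, summed: bool = False
) -> str:
    """Label at the requested level.

    Default rule: the Level-2 / Level-1 parent of the Level-3 argmax (the
    implicit coarse classification).  ``summed=True`` instead sums child
    probability mass per coarse label and takes its argmax.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"level must be 1, 2 or 3, got {level}")
    if not summed or level == 3:
        return taxonomy.level_label(prob.argmax(), level)
    mass: dict[str, float] = {lbl: 0.0 for lbl in taxonomy.level_labels(level)}
    for cid, p in zip(prob.class_ids, prob.probs):
        mass[taxonomy.level_label(cid, level)] += float(p)
    return max(mass, key=lambda lbl: (mass[lbl], -list(mass).index(lbl)))


def topk(prob: ProbabilityVector, k: int) -> list[tuple[int, float]]:
    return prob.topk(k)


# ---------------------------------------------------------------------------
# model persistence


def taxonomy_hash(taxonomy: SoundTaxonomy) -> str:
    return hashlib.sha256(taxonomy.to_json().encode()).hexdigest()[:16]


def save_model(model: SpectroImageClassifier, path) -> None:
    """Serialize to one file with a metadata header."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "taxonomy_hash": taxonomy_hash(model.taxonomy) if model.taxonomy else None,
        "seed": model.random_state,
        "estimator": model,
    }
    joblib.dump(payload, path)


def load_model(path) -> SpectroImageClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload.get('format_version')}")
    return payload["estimator"]
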