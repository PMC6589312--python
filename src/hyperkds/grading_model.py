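"""Pluggable grade classifiers with the study's preprocessing contract.

Any classifier that implements ``fit(images, labels, class_weights, seed)``
and ``predict_proba(image)`` can stand behind the grading pipeline — a
fine-tuned CNN in production, or the feature-based baseline here for
desk-scale work.  What is fixed is the interface: inputs are resampled to
256x192 8-bit RGB and normalised to [0, 1]; outputs are a probability
simplex over the four grades, with the argmax (lowest grade on ties) as
the response.

The baseline extracts three redness features per image — mean redness
score, vessel-area percentage at the default threshold, and redness
standard deviation — and fits a multinomial logistic regression with
per-grade loss weights (default 1.5/1/1/5: the rare advanced grade is
weighted up so the model does not learn to ignore it).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np
from PIL import Image
from sklearn.linear_model import LogisticRegression

from .panels import ORDINAL_GRADES
from .vessel_area import DEFAULT_THRESHOLD, measure_vessel_area, redness_score

__all__ = [
    "TARGET_WIDTH",
    "TARGET_HEIGHT",
    "DEFAULT_CLASS_WEIGHTS",
    "GradeProbabilities",
    "preprocess",
    "extract_features",
    "BaselineGrader",
]

TARGET_WIDTH = 256
TARGET_HEIGHT = 192

#: Per-grade loss weights (grade 0..3).
DEFAULT_CLASS_WEIGHTS = (1.5, 1.0, 1.0, 5.0)


@dataclass(frozen=True)
class GradeProbabilities:
    """Probability simplex over the four grades."""

    probs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,) or not np.isclose(p.sum(), 1.0, atol=1e-9) or (p < 0).any():
            raise ValueError("probabilities must be a 4-simplex")

    @property
    def grade(self) -> int:
        # np.argmax returns the first maximum -> lowest-grade tie-break
        return int(np.argmax(self.probs))


def preprocess(image: np.ndarray) -> np.ndarray:
    """Resample an 8-bit RGB raster to 256x192 and scale into [0, 1].

    Bilinear resampling; non-matching aspect ratios are stretched, not
    cropped.  Returns a float array of shape (192, 256, 3).
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB raster of shape (H, W, 3)")
    pil = Image.fromarray(arr, mode="RGB")
    resized = pil.resize((TARGET_WIDTH, TARGET_HEIGHT), resample=Image.BILINEAR)
    return np.asarray(resized, dtype=float) / 255.0


def extract_features(image: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Redness feature vector: (mean redness, vessel-area %, redness SD)."""
    score = redness_score(image)
    area = measure_vessel_area(image, threshold=threshold)
    return np.array([float(score.mean()), area.percent, float(score.std())])


class NotFittedError(RuntimeError):
    pass


class BaselineGrader:
    """Feature-based multinomial grade classifier.

    Deterministic under a fixed seed.  ``feature_jitter`` adds seeded
    Gaussian noise to the (standardised) features at both fit and predict
    time and ``subsample`` bootstrap draws the training set — both are off
    by default and exist to decorrelate members of an ensemble trained on
    one corpus, the way separately trained networks disagree on borderline
    images.  Predict-time jitter is a pure function of (seed, feature
    vector), so predictions stay deterministic and order-independent.
    """

    def __init__(
        self,
        class_weights: tuple[float, float, float, float] = DEFAULT_CLASS_WEIGHTS,
        seed: int = 0,
        feature_jitter: float = 0.0,
        subsample: float | None = None,
        C: float = 1.0,
    ) -> None:
        if any(w <= 0 for w in class_weights):
            raise ValueError("class weights must be positive")
        self.class_weights = tuple(float(w) for w in class_weights)
        self.seed = int(seed)
        self.feature_jitter = float(feature_jitter)
        self.subsample = subsample
        self.C = float(C)
        self._clf: LogisticRegression | None = None
        self._mu: np.ndarray | None = None
        self._sigma: np.ndarray | None = None

    # -- fitting -----------------------------------------------------------

    def fit(self, images, labels) -> "BaselineGrader":
        """Fit on rasters (sequence of HxWx3 uint8) and ordinal labels."""
        X = np.vstack([extract_features(img) for img in images])
        y = np.asarray(labels, dtype=int)
        return self.fit_features(X, y)

    def fit_features(self, X: np.ndarray, y: np.ndarray) -> "BaselineGrader":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        present = set(np.unique(y))
        absent = set(ORDINAL_GRADES) - present
        if absent:
            raise ValueError(f"grades absent from training data: {sorted(absent)}")
        rng = np.random.default_rng(self.seed)
        if self.subsample is not None:
            n = int(round(self.subsample * len(y)))
            idx = rng.choice(len(y), size=n, replace=True)
            # guarantee every grade survives the bootstrap
            for g in ORDINAL_GRADES:
                if not np.any(y[idx] == g):
                    idx = np.append(idx, rng.choice(np.flatnonzero(y == g)))
            X, y = X[idx], y[idx]
        self._mu = X.mean(axis=0)
        self._sigma = X.std(axis=0)
        self._sigma[self._sigma == 0] = 1.0
        Xs = (X - self._mu) / self._sigma
        if self.feature_jitter > 0:
            Xs = Xs + rng.normal(0.0, self.feature_jitter, Xs.shape)
        sample_weight = np.array([self.class_weights[g] for g in y])
        self._clf = LogisticRegression(
            max_iter=2000, C=self.C, random_state=self.seed
        )
        self._clf.fit(Xs, y, sample_weight=sample_weight)
        return self

    # -- prediction --------------------------------------------------------

    def _require_fitted(self) -> LogisticRegression:
        if self._clf is None:
            raise NotFittedError("classifier is not fitted")
        return self._clf

    def predict_proba(self, image: np.ndarray) -> GradeProbabilities:
        return self.predict_proba_features(extract_features(image))

    def _predict_jitter(self, x: np.ndarray) -> np.ndarray:
        if self.feature_jitter == 0.0:
            return np.zeros_like(x)
        digest = zlib.crc32(np.ascontiguousarray(x, dtype=float).tobytes())
        rng = np.random.default_rng([self.seed, digest])
        return rng.normal(0.0, self.feature_jitter, x.shape)

    def predict_proba_features(self, features: np.ndarray) -> GradeProbabilities:
        clf = self._require_fitted()
        x = (np.asarray(features, dtype=float) - self._mu) / self._sigma
        x = x + self._predict_jitter(x)
        raw = clf.predict_proba(x.reshape(1, -1))[0]
        full = np.zeros(4)
        for cls, p in zip(clf.classes_, raw):
            full[int(cls)] = p
        full = full / full.sum()
        return GradeProbabilities(tuple(full.tolist()))

    def predict(self, image: np.ndarray) -> int:
        return self.predict_proba(image).grade

    def predict_features(self, features: np.ndarray) -> int:
        return self.predict_proba_features(features).grade

    # -- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        clf = self._require_fitted()
        return json.dumps(
            {
                "class_weights": list(self.class_weights),
                "seed": self.seed,
                "classes": [int(c) for c in clf.classes_],
                "coef": clf.coef_.tolist(),
                "intercept": clf.intercept_.tolist(),
                "feature_mean": self._mu.tolist(),
                "feature_scale": self._sigma.tolist(),
            },
            indent=2,
            sort_keys=True,
        )
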