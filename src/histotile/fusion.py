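"""Whole-image prediction by average fusion of sub-image probabilities.

An image is classified by grid-dividing it into K = n² sub-images, scoring
each sub-image with the frozen backbone + trained head, averaging the
per-tile class-probability vectors,

    p̄[j] = (1/K) Σ_k p_k[j],

and taking the arg-max class. Because averaging preserves positive scaling,
"sum then arg-max" and "mean then arg-max" give identical labels. With
n = 1 the procedure reduces exactly to single-image classification.

:class:`TileEnsembleClassifier` wraps the whole pipeline (tile → extract →
head → fuse) as a scikit-learn estimator over lists of images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .augmentation import expand_training_set, tile_grid
from .backbone import Backbone, FixtureBackbone, extract_features
from .head import (
    HeadNetClassifier,
    TrainConfig,
    predict_proba_batch,
)
from .types import HeadParams, Label, LabeledImage, ProbabilityPair


@dataclass
class ImagePrediction:
    """Fused whole-image prediction with its per-tile evidence."""

    parent_id: str
    fused: ProbabilityPair
    predicted_label: Label
    K: int
    per_tile: List[ProbabilityPair]
    true_label: Optional[Label] = None

    def __post_init__(self) -> None:
        if self.K != len(self.per_tile):
            raise ValueError("K must equal the number of per-tile pairs")


def average_fuse(per_tile: Sequence[ProbabilityPair]) -> ProbabilityPair:
    """Componentwise arithmetic mean of normalized probability pairs.

    The mean of distributions is itself a distribution, so the output is
    normalized; the result is invariant to permuting the input list.
    """
    if not per_tile:
        raise ValueError("cannot fuse an empty list of probabilities")
    arr = np.array([[p.p_benign, p.p_malignant] for p in per_tile])
    mean = arr.mean(axis=0)
    return ProbabilityPair(mean[0], mean[1])


def argmax_class(fused: ProbabilityPair) -> Label:
    """The class with the larger fused probability.

    An exact tie (p_benign = p_malignant = 0.5) resolves to malignant,
    favoring sensitivity in a screening context.
    """
    return Label.BENIGN if fused.p_benign > fused.p_malignant else Label.MALIGNANT


def predict_image(
    head: HeadParams,
    backbone: Backbone,
    image: LabeledImage,
    n: int,
) -> ImagePrediction:
    """Tile → extract → per-tile softmax → average fuse → arg-max.

    With n = 1 this is plain single-image classification: the fused pair
    equals the single tile's probability pair bit-for-bit.
    """
    tiles = tile_grid(image, n).tiles
    feats = extract_features(backbone, tiles)
    probs = predict_proba_batch(head, feats)
    per_tile = [ProbabilityPair(p[0], p[1]) for p in probs]
    fused = average_fuse(per_tile)
    return ImagePrediction(
        parent_id=tiles[0].parent_id,
        fused=fused,
        predicted_label=argmax_class(fused),
        K=len(per_tile),
        per_tile=per_tile,
        true_label=image.label,
    )


def predict_batch(
    head: HeadParams,
    backbone: Backbone,
    images: Sequence[LabeledImage],
    n: int,
) -> List[ImagePrediction]:
    """Order-preserving batch version of :func:`predict_image`."""
    return [predict_image(head, backbone, img, n) for img in images]


class TileEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """End-to-end tile-ensemble image classifier.

    Training grid-divides every image into ``n_grid``² label-inheriting
    tiles, extracts frozen-backbone features per tile, and fits the fully
    connected head on them. Prediction tiles each image the same way,
    scores every tile, and average-fuses the per-tile probabilities into a
    whole-image decision.

    Parameters
    ----------
    backbone : Backbone, optional
        Frozen feature extractor; defaults to a seeded
        :class:`~histotile.backbone.FixtureBackbone`.
    n_grid : {1, 2, 4}, default 4
        Grid division per side (1: no tiling, 2: quarter, 4: sixteenth).
    hidden_sizes, learning_rate, beta1, beta2, batch_size, epochs,
    early_stopping, patience, min_delta
        Head-training hyperparameters; see
        :class:`~histotile.head.HeadNetClassifier`.
    seed : int, default 0
        Seeds head initialization and shuffling (the frozen backbone has
        its own seed and is untouched by fitting).

    Attributes
    ----------
    classes_ : ndarray — ``['benign', 'malignant']``
    head_ : HeadNetClassifier
    head_params_ : HeadParams
    loss_curve_ : list of float
    """

    def __init__(
        self,
        backbone: Optional[Backbone] = None,
        n_grid: int = 4,
        hidden_sizes=(1024, 512),
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        batch_size: int = 32,
        epochs: int = 100,
        early_stopping: bool = True,
        patience: int = 10,
        min_delta: float = 1e-4,
        seed: int = 0,
    ):
        self.backbone = backbone
        self.n_grid = n_grid
        self.hidden_sizes = hidden_sizes
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.epochs = epochs
        self.early_stopping = early_stopping
        self.patience = patience
        self.min_delta = min_delta
        self.seed = seed

    def _backbone(self) -> Backbone:
        return self.backbone if self.backbone is not None else FixtureBackbone(seed=0)

    @staticmethod
    def _as_images(images, y=None) -> List[LabeledImage]:
        out = []
        for i, img in enumerate(images):
            if isinstance(img, LabeledImage):
                out.append(img)
            else:
                label = Label(y[i]) if y is not None else Label.BENIGN
                out.append(LabeledImage(pixels=np.asarray(img), label=label,
                                        source_path=f"array-{i}"))
        return out

    def fit(self, images: Sequence, y=None):
        """Fit the head on tile features of the training images.

        ``images`` is a sequence of :class:`LabeledImage` (in which case
        ``y`` may be omitted) or of H×W×3 uint8 arrays with ``y`` giving
        'benign'/'malignant' labels.
        """
        records = self._as_images(images, y)
        if y is not None:
            for rec, label in zip(records, y):
                rec.label = Label(label) if not isinstance(label, Label) else label
        tiles = expand_training_set(records, self.n_grid)
        feats = extract_features(self._backbone(), tiles)
        X = np.stack([f.values for f in feats])
        y_tiles = np.array([f.label.value for f in feats])
        self.head_ = HeadNetClassifier(
            hidden_sizes=self.hidden_sizes,
            learning_rate=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            batch_size=self.batch_size,
            epochs=self.epochs,
            early_stopping=self.early_stopping,
            patience=self.patience,
            min_delta=self.min_delta,
            seed=self.seed,
        ).fit(X, y_tiles)
        self.head_params_ = self.head_.params_
        self.loss_curve_ = self.head_.loss_curve_
        self.classes_ = self.head_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_images(self, images: Sequence) -> List[ImagePrediction]:
        """Full fused predictions (with per-tile evidence) per image."""
        check_is_fitted(self, "head_params_")
        records = self._as_images(images)
        return predict_batch(self.head_params_, self._backbone(), records,
                             self.n_grid)

    def predict_proba(self, images: Sequence) -> np.ndarray:
        preds = self.predict_images(images)
        return np.array([[p.fused.p_benign, p.fused.p_malignant] for p in preds])

    def predict(self, images: Sequence) -> np.ndarray:
        preds = self.predict_images(images)
        return np.array([p.predicted_label.value for p in preds])
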