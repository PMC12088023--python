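"""histotile — tile-ensemble benign/malignant histopathology classification.

Whole pathology images are grid-divided into n×n label-inheriting tiles;
a frozen pretrained backbone turns each tile into a feature vector; a
trainable three-layer fully connected head scores each tile; and the
whole-image decision is the arg-max of the average of the per-tile class
probabilities. Evaluation is image-level with malignant as the positive
class (accuracy, precision, recall, F1, MCC).
"""

__version__ = "0.1.0"

from .augmentation import (
    AugmentConfig,
    expand_training_set,
    routine_augment,
    tile_grid,
)
from .backbone import (
    Backbone,
    FeatureVector,
    FixtureBackbone,
    InceptionResNetV2Backbone,
    cache_features,
    extract_features,
    load_features,
    make_backbone,
    resize_for_backbone,
)
from .dataset_io import scan_dataset, split_dataset, train_test_counts
from .fusion import (
    ImagePrediction,
    TileEnsembleClassifier,
    argmax_class,
    average_fuse,
    predict_batch,
    predict_image,
)
from .head import (
    HeadNetClassifier,
    TrainConfig,
    cross_entropy,
    init_head,
    predict_proba,
    relu,
    softmax,
    train_head,
)
from .metrics import (
    ConfusionMatrix,
    MetricsReport,
    accuracy,
    confusion,
    evaluate,
    f1,
    mcc,
    precision,
    recall,
    render_report,
    report_from_confusion,
)
from .synthetic import SyntheticSpec, generate_dataset, write_fixture_tree
from .types import (
    DatasetSplit,
    HeadParams,
    Label,
    LabeledImage,
    Magnification,
    ProbabilityPair,
    SplitSpec,
    Tile,
    TileSet,
)

__all__ = [
    "AugmentConfig",
    "Backbone",
    "ConfusionMatrix",
    "DatasetSplit",
    "FeatureVector",
    "FixtureBackbone",
    "HeadNetClassifier",
    "HeadParams",
    "ImagePrediction",
    "InceptionResNetV2Backbone",
    "Label",
    "LabeledImage",
    "Magnification",
    "MetricsReport",
    "ProbabilityPair",
    "SplitSpec",
    "SyntheticSpec",
    "Tile",
    "TileEnsembleClassifier",
    "TileSet",
    "TrainConfig",
    "accuracy",
    "argmax_class",
    "average_fuse",
    "cache_features",
    "confusion",
    "cross_entropy",
    "evaluate",
    "expand_training_set",
    "extract_features",
    "f1",
    "generate_dataset",
    "init_head",
    "load_features",
    "make_backbone",
    "mcc",
    "precision",
    "predict_batch",
    "predict_image",
    "predict_proba",
    "recall",
    "relu",
    "render_report",
    "report_from_confusion",
    "resize_for_backbone",
    "routine_augment",
    "scan_dataset",
    "softmax",
    "split_dataset",
    "tile_grid",
    "train_head",
    "train_test_counts",
    "write_fixture_tree",
]
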