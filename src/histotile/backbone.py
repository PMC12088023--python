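"""Frozen feature-extraction backbones and the feature cache.

The classification pipeline never trains its convolutional feature
extractor: the backbone is constructed once (typically from weights
pretrained on a large generic image corpus) and its weights are immutable
thereafter, so extracting features from the same image twice yields
byte-identical vectors before and after any head training. Only the fully
connected head that consumes the features is trainable.

Backbones are pluggable behind a small contract — ``name``, ``input_size``,
``output_dim``, ``extract(batch)`` — with two implementations:

* :class:`InceptionResNetV2Backbone` — adapter for the ImageNet-pretrained
  Inception-ResNet V2 network (299×299 input, 1536-dim globally pooled
  features after the final fully connected layer is removed). Requires a
  deep-learning runtime with published weights.
* :class:`FixtureBackbone` — a fully deterministic, dependency-free
  backbone: a seeded random linear projection of the 32×32 grayscale
  downsample of the input. Runs in milliseconds per tile, which makes the
  whole pipeline exercisable without downloads; it is the default in tests.

Because re-extracting features for every head-training run would repeat the
most expensive stage of the pipeline, extracted vectors can be cached to a
keyed archive and re-loaded losslessly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

from .types import Label, Tile

FIXTURE_DOWNSAMPLE = 32
FIXTURE_OUTPUT_DIM = 64


class BackboneWeightsUnavailable(RuntimeError):
    """Raised when a backbone's pretrained weights cannot be loaded."""


@dataclass
class FeatureVector:
    """A fixed-length feature vector for one (sub-)image."""

    values: np.ndarray
    parent_id: str
    grid_position: Tuple[int, int]
    label: Label

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("feature values must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


class Backbone:
    """Contract every feature backbone implements.

    Attributes
    ----------
    name : str
    input_size : (height, width)
        Spatial size the input is resized to before extraction.
    output_dim : int
        Length of the produced feature vectors.
    input_range : (low, high)
        Value range the backbone expects after scaling from 8-bit.
    weights_origin : {"imagenet_pretrained", "random", "test_fixture"}
    """

    name: str = "abstract"
    input_size: Tuple[int, int] = (299, 299)
    output_dim: int = 0
    input_range: Tuple[float, float] = (-1.0, 1.0)
    weights_origin: str = "random"

    def extract(self, batch: np.ndarray) -> np.ndarray:
        """Map a (B, H, W, 3) scaled batch to (B, output_dim) features."""
        raise NotImplementedError


def resize_for_backbone(tile: Tile, backbone: Backbone) -> np.ndarray:
    """Resize a tile to the backbone's input size and value range.

    Bilinear interpolation to ``backbone.input_size``; 8-bit values are then
    scaled linearly to ``backbone.input_range``. When the tile already has
    the target size, pixels pass through unchanged apart from the scaling.
    """
    pixels = np.asarray(tile.pixels, dtype=np.float64)
    if pixels.shape[0] < 1 or pixels.shape[1] < 1:
        raise ValueError("tile must have at least one pixel per dimension")
    h, w = backbone.input_size
    if pixels.shape[:2] != (h, w):
        pixels = _sk_resize(
            pixels, (h, w), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    lo, hi = backbone.input_range
    return pixels / 255.0 * (hi - lo) + lo


class FixtureBackbone(Backbone):
    """Deterministic test backbone: seeded random projection of a grayscale
    downsample.

    The input is resized to 32×32, converted to grayscale by channel
    averaging, flattened, and mapped through a fixed random linear layer
    ``P x + b`` with entries drawn once from a seeded generator. The weights
    are immutable after construction (frozen contract); a constant-zero
    input maps exactly to the bias vector ``b``.
    """

    input_size = (FIXTURE_DOWNSAMPLE, FIXTURE_DOWNSAMPLE)
    input_range = (0.0, 1.0)
    weights_origin = "test_fixture"

    def __init__(self, seed: int = 0, output_dim: int = FIXTURE_OUTPUT_DIM):
        self.seed = int(seed)
        self.output_dim = int(output_dim)
        self.name = f"fixture-{self.seed}-{self.output_dim}"
        d_in = FIXTURE_DOWNSAMPLE * FIXTURE_DOWNSAMPLE
        rng = np.random.default_rng(self.seed)
        P = rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(self.output_dim, d_in))
        b = rng.normal(0.0, 0.1, size=self.output_dim)
        P.setflags(write=False)
        b.setflags(write=False)
        self._projection = P
        self._bias = b

    @property
    def bias(self) -> np.ndarray:
        return self._bias

    def extract(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 3:
            batch = batch[np.newaxis]
        gray = batch.mean(axis=3)
        flat = gray.reshape(gray.shape[0], -1)
        return flat @ self._projection.T + self._bias


class InceptionResNetV2Backbone(Backbone):
    """Adapter for the ImageNet-pretrained Inception-ResNet V2 extractor.

    The network is consumed as an opaque pretrained model: its final fully
    connected layer is removed and the last feature map is globally
    average-pooled to a 1536-dim vector. Inputs are 299×299 RGB scaled to
    [−1, 1]. Weights are frozen — the model is run in inference mode only
    and never updated by head training.
    """

    name = "inception_resnet_v2"
    input_size = (299, 299)
    output_dim = 1536
    input_range = (-1.0, 1.0)
    weights_origin = "imagenet_pretrained"

    def __init__(self):
        try:
            from tensorflow.keras.applications import InceptionResNetV2  # type: ignore
        except Exception as exc:  # no DL runtime or no weights
            raise BackboneWeightsUnavailable(
                "Inception-ResNet V2 pretrained weights are unavailable "
                "(no deep-learning runtime with published weights could be "
                "loaded); use the 'fixture' backbone (FixtureBackbone) as "
                f"the fallback. Underlying error: {exc}"
            ) from exc
        self._model = InceptionResNetV2(
            include_top=False, weights="imagenet", pooling="avg"
        )
        self._model.trainable = False

    def extract(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim == 3:
            batch = batch[np.newaxis]
        return np.asarray(self._model(batch, training=False), dtype=np.float64)


def make_backbone(name: str, seed: int = 0) -> Backbone:
    """Construct a backbone by name (``"fixture"`` or
    ``"inception_resnet_v2"``)."""
    if name == "fixture" or name.startswith("fixture-"):
        return FixtureBackbone(seed=seed)
    if name == "inception_resnet_v2":
        return InceptionResNetV2Backbone()
    raise ValueError(f"unknown backbone: {name!r}")


def extract_features(
    backbone: Backbone,
    tiles: Sequence[Tile],
    batch_size: int = 64,
) -> List[FeatureVector]:
    """Extract one feature vector per tile, order-preserving.

    Deterministic: the backbone runs in inference mode with no stochastic
    layers, so repeated calls on the same tiles yield identical vectors.
    """
    if not tiles:
        raise ValueError("no tiles to extract features from")
    out: List[FeatureVector] = []
    for start in range(0, len(tiles), batch_size):
        chunk = tiles[start:start + batch_size]
        batch = np.stack([resize_for_backbone(t, backbone) for t in chunk])
        feats = backbone.extract(batch)
        for tile, vec in zip(chunk, feats):
            out.append(
                FeatureVector(
                    values=vec,
                    parent_id=tile.parent_id,
                    grid_position=tile.grid_position,
                    label=tile.inherited_label,
                )
            )
    return out


def feature_cache_key(backbone_name: str, tiling_n: int, manifest_hash: str) -> str:
    """Cache key tying a feature file to its backbone, tiling and inputs."""
    return f"{backbone_name}|n={tiling_n}|{manifest_hash}"


def manifest_fingerprint(paths: Sequence[str]) -> str:
    """Stable fingerprint of an ordered list of source paths."""
    blob = "\n".join(paths).encode()
    return f"{zlib.crc32(blob):08x}-{len(paths)}"


class FeatureCacheError(RuntimeError):
    """Raised on a corrupted cache file or a cache-key mismatch."""


def cache_features(
    vectors: Sequence[FeatureVector],
    path,
    backbone_name: str = "",
    tiling_n: int = 1,
    manifest_hash: str = "",
) -> None:
    """Persist feature vectors to a keyed columnar archive.

    The header records the backbone name, output dimension, tiling n,
    manifest fingerprint and record count; :func:`load_features` refuses a
    file whose key does not match, preventing stale reuse.
    """
    if not vectors:
        raise ValueError("nothing to cache")
    values = np.stack([v.values for v in vectors])
    header = {
        "backbone": backbone_name,
        "output_dim": int(values.shape[1]),
        "tiling_n": int(tiling_n),
        "manifest_hash": manifest_hash,
        "count": len(vectors),
        "key": feature_cache_key(backbone_name, tiling_n, manifest_hash),
    }
    np.savez(
        path,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        values=values,
        parent_ids=np.array([v.parent_id for v in vectors]),
        rows=np.array([v.grid_position[0] for v in vectors], dtype=np.int64),
        cols=np.array([v.grid_position[1] for v in vectors], dtype=np.int64),
        labels=np.array([v.label.value for v in vectors]),
    )


def load_features(path, expected_key: Optional[str] = None) -> List[FeatureVector]:
    """Load cached feature vectors; lossless round-trip of values, labels,
    parent ids and grid positions.

    Raises :class:`FeatureCacheError` on truncated/corrupted files and on a
    cache-key mismatch — never silently truncates.
    """
    try:
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(bytes(data["header"]).decode())
            values = data["values"]
            parent_ids = data["parent_ids"]
            rows, cols = data["rows"], data["cols"]
            labels = data["labels"]
    except Exception as exc:
        raise FeatureCacheError(f"corrupted feature cache {path}: {exc}") from exc
    if expected_key is not None and header.get("key") != expected_key:
        raise FeatureCacheError(
            f"feature cache key mismatch: file has {header.get('key')!r}, "
            f"expected {expected_key!r}"
        )
    n = header.get("count")
    if not (len(values) == len(parent_ids) == len(rows) == len(cols)
            == len(labels) == n):
        raise FeatureCacheError(f"feature cache {path} is inconsistent")
    return [
        FeatureVector(
            values=values[i],
            parent_id=str(parent_ids[i]),
            grid_position=(int(rows[i]), int(cols[i])),
            label=Label(str(labels[i])),
        )
        for i in range(n)
    ]
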