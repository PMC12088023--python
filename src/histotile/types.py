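"""Core domain types for tile-ensemble histopathology classification.

The pipeline operates on whole 8-bit RGB pathology images carrying a binary
benign/malignant label (malignant is the positive class throughout), cuts
them into n×n grids of tiles that inherit the parent label, and represents
per-(sub-)image classifier outputs as normalized two-class probability
pairs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Label",
    "Magnification",
    "BENIGN_SUBTYPES",
    "MALIGNANT_SUBTYPES",
    "SUBTYPE_CODES",
    "LabeledImage",
    "Tile",
    "TileSet",
    "ProbabilityPair",
    "HeadParams",
    "SplitSpec",
    "DatasetSplit",
]


class Label(enum.Enum):
    """Binary tumor class; malignant is the positive class for all metrics."""

    BENIGN = "benign"
    MALIGNANT = "malignant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Magnification(enum.Enum):
    """Optical magnification at acquisition."""

    X40 = "40x"
    X100 = "100x"
    X200 = "200x"
    X400 = "400x"
    UNKNOWN = "unknown"

    @classmethod
    def from_string(cls, s: str) -> "Magnification":
        s = s.strip().lower().rstrip("x×").strip()
        return {
            "40": cls.X40,
            "100": cls.X100,
            "200": cls.X200,
            "400": cls.X400,
        }.get(s, cls.UNKNOWN)


#: Tumor subtype codes used by the BreaKHis filename convention.
BENIGN_SUBTYPES = {
    "A": "adenosis",
    "F": "fibroadenoma",
    "PT": "phyllodes_tumor",
    "TA": "tubular_adenoma",
}
MALIGNANT_SUBTYPES = {
    "DC": "ductal_carcinoma",
    "LC": "lobular_carcinoma",
    "MC": "mucinous_carcinoma",
    "PC": "papillary_carcinoma",
}
SUBTYPE_CODES = {**BENIGN_SUBTYPES, **MALIGNANT_SUBTYPES}


def subtype_label(subtype: str) -> Label:
    """Map a subtype name (or code) to its tumor class."""
    if subtype in BENIGN_SUBTYPES or subtype in BENIGN_SUBTYPES.values():
        return Label.BENIGN
    if subtype in MALIGNANT_SUBTYPES or subtype in MALIGNANT_SUBTYPES.values():
        return Label.MALIGNANT
    raise ValueError(f"unknown tumor subtype: {subtype!r}")


@dataclass
class LabeledImage:
    """An 8-bit RGB pathology image with its class label and provenance.

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3), uint8
        The image data. H and W must both be at least 4.
    label : Label
        Benign or malignant; always defined.
    magnification : Magnification
        Acquisition magnification, ``UNKNOWN`` for generic datasets.
    subtype : str, optional
        One of the eight BreaKHis tumor subtypes; when present it must be
        consistent with ``label``.
    patient_id : str, optional
        Patient/slide identifier parsed from the filename.
    source_path : str
        Where the image came from (file path or a synthetic identifier).
    """

    pixels: np.ndarray
    label: Label
    magnification: Magnification = Magnification.UNKNOWN
    subtype: Optional[str] = None
    patient_id: Optional[str] = None
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"pixels must be H×W×3, got shape {self.pixels.shape}"
            )
        h, w = self.pixels.shape[:2]
        if h < 4 or w < 4:
            raise ValueError(f"image too small: {h}×{w} (need ≥ 4×4)")
        if self.subtype is not None and subtype_label(self.subtype) != self.label:
            raise ValueError(
                f"subtype {self.subtype!r} inconsistent with label {self.label}"
            )

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class Tile:
    """One cell of a parent image's n×n grid, inheriting the parent label."""

    pixels: np.ndarray
    parent_id: str
    grid_position: Tuple[int, int]
    inherited_label: Label


@dataclass
class TileSet:
    """All n² tiles of one parent image, in row-major order.

    The tiles jointly cover the parent exactly once: concatenating their
    pixels along the grid reconstructs the parent image.
    """

    parent_id: str
    n: int
    tiles: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.tiles) != self.n * self.n:
            raise ValueError(
                f"expected {self.n ** 2} tiles, got {len(self.tiles)}"
            )

    def __iter__(self):
        return iter(self.tiles)

    def __len__(self) -> int:
        return len(self.tiles)

    def reassemble(self) -> np.ndarray:
        """Stitch the tiles back into the parent pixel array."""
        rows = []
        for r in range(self.n):
            row_tiles = [self.tiles[r * self.n + c].pixels for c in range(self.n)]
            rows.append(np.concatenate(row_tiles, axis=1))
        return np.concatenate(rows, axis=0)


class ProbabilityPair:
    """A normalized probability distribution over {benign, malignant}."""

    __slots__ = ("p_benign", "p_malignant")

    _TOL = 1e-9

    def __init__(self, p_benign: float, p_malignant: float):
        if not (0.0 <= p_benign <= 1.0 and 0.0 <= p_malignant <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(p_benign + p_malignant - 1.0) > self._TOL:
            raise ValueError(
                f"probabilities must sum to 1 within {self._TOL}: "
                f"{p_benign} + {p_malignant}"
            )
        self.p_benign = float(p_benign)
        self.p_malignant = float(p_malignant)

    def as_array(self) -> np.ndarray:
        return np.array([self.p_benign, self.p_malignant])

    def __iter__(self):
        yield self.p_benign
        yield self.p_malignant

    def __repr__(self) -> str:
        return f"ProbabilityPair(p_benign={self.p_benign!r}, p_malignant={self.p_malignant!r})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProbabilityPair)
            and self.p_benign == other.p_benign
            and self.p_malignant == other.p_malignant
        )


@dataclass
class HeadParams:
    """Weights and biases of the fully connected classifier head.

    The default architecture is d → 1024 → 512 → 2 with ReLU activations on
    the two hidden layers and a softmax output.
    """

    weights: Sequence[np.ndarray]
    biases: Sequence[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must pair up layer by layer")
        for W, b in zip(self.weights, self.biases):
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError("head parameters must be finite")
            if W.shape[1] != b.shape[0]:
                raise ValueError("bias width must match weight output width")

    @property
    def layer_widths(self) -> Tuple[int, ...]:
        return tuple(int(W.shape[1]) for W in self.weights)

    @property
    def input_dim(self) -> int:
        return int(self.weights[0].shape[0])


@dataclass
class SplitSpec:
    """How to split a dataset into train and test partitions."""

    train_fraction: float = 0.8
    seed: int = 0
    stratify_by_label: bool = True
    group_by_patient: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class DatasetSplit:
    """Disjoint train/test partitions of a record list."""

    train: list
    test: list
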