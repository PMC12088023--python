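"""Grid-division data enhancement and routine photometric/geometric augmentation.

Grid division cuts an image into an n×n grid of near-equal tiles (quarter
division: n=2, sixteenth division: n=4); every tile inherits the parent
image's class label, so the training set grows by a factor of n². At
inference the same grid supplies the sub-image ensemble whose class
probabilities are fused.

Routine augmentation covers the usual photometric/geometric operations
(flips, scaling, rotation, color jitter, additive noise); it preserves the
record's label and metadata and the image shape, and is reproducible for a
fixed seed. Grid division and routine augmentation are distinct training
strategies and are not composed by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from skimage.transform import rescale, rotate

from .types import LabeledImage, Tile, TileSet

VALID_GRID_SIZES = (1, 2, 4)

AUGMENT_OPS = ("hflip", "vflip", "scale", "rotate", "color_jitter", "noise")


def grid_boundaries(extent: int, n: int) -> List[int]:
    """Even-partition boundaries 0 = b_0 ≤ … ≤ b_n = extent.

    ``b_k = floor(k·extent/n + 0.5)`` — near-equal tiles with an exact cover
    even when ``extent`` is not divisible by ``n`` (the canonical 700×460
    frame divides exactly for n ∈ {2, 4}).
    """
    return [int(np.floor(k * extent / n + 0.5)) for k in range(n + 1)]


def tile_grid(image: LabeledImage, n: int) -> TileSet:
    """Divide an image into its n×n grid of label-inheriting tiles.

    Tiles are returned in row-major order; tile (r, c) spans rows
    ``[b_r, b_{r+1})`` and columns ``[b_c, b_{c+1})`` of the even partition.
    ``n=1`` returns the unmodified image as a single tile.
    """
    if n not in VALID_GRID_SIZES:
        raise ValueError(f"grid size must be one of {VALID_GRID_SIZES}, got {n}")
    h, w = image.height, image.width
    if h < n or w < n:
        raise ValueError(f"image {h}×{w} too small for a {n}×{n} grid")
    parent_id = image.source_path or "image"
    row_b = grid_boundaries(h, n)
    col_b = grid_boundaries(w, n)
    tiles = [
        Tile(
            pixels=image.pixels[row_b[r]:row_b[r + 1], col_b[c]:col_b[c + 1]],
            parent_id=parent_id,
            grid_position=(r, c),
            inherited_label=image.label,
        )
        for r in range(n)
        for c in range(n)
    ]
    return TileSet(parent_id=parent_id, n=n, tiles=tiles)


def expand_training_set(records: Sequence[LabeledImage], n: int) -> List[Tile]:
    """Grid-divide every training image, multiplying the set by n².

    Parent identifiers are preserved on every tile so downstream fusion can
    re-associate the tiles of one image.
    """
    if n not in VALID_GRID_SIZES:
        raise ValueError(f"grid size must be one of {VALID_GRID_SIZES}, got {n}")
    tiles: List[Tile] = []
    for rec in records:
        tiles.extend(tile_grid(rec, n).tiles)
    return tiles


@dataclass
class AugmentConfig:
    """Routine-augmentation settings.

    ops
        Subset of ``{"hflip", "vflip", "scale", "rotate", "color_jitter",
        "noise"}``. An empty set makes :func:`routine_augment` the identity.
    factor
        Fixed per-image expansion factor: the output contains the original
        plus ``factor − 1`` randomly augmented copies.
    rotate_range
        Rotation angle drawn uniformly from ±this many degrees.
    scale_range
        Isotropic scale factor range; reflect-padded / center-cropped back
        to the input shape.
    color_jitter_range
        Per-channel multiplicative gain range.
    noise_sigma
        Std of additive Gaussian noise on the 8-bit scale.
    """

    ops: Tuple[str, ...] = ("hflip", "vflip", "scale", "rotate", "color_jitter", "noise")
    factor: int = 4
    rotate_range: float = 30.0
    scale_range: Tuple[float, float] = (0.9, 1.1)
    color_jitter_range: Tuple[float, float] = (0.9, 1.1)
    noise_sigma: float = 5.0

    def __post_init__(self) -> None:
        unknown = set(self.ops) - set(AUGMENT_OPS)
        if unknown:
            raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
        if self.factor < 1:
            raise ValueError("factor must be ≥ 1")


def hflip(pixels: np.ndarray) -> np.ndarray:
    return pixels[:, ::-1]


def vflip(pixels: np.ndarray) -> np.ndarray:
    return pixels[::-1, :]


def _rotate(pixels: np.ndarray, angle: float) -> np.ndarray:
    if angle == 0.0:
        return pixels
    out = rotate(
        pixels.astype(np.float64) / 255.0, angle,
        resize=False, mode="reflect", order=1, preserve_range=True,
    )
    return np.clip(out * 255.0, 0, 255).astype(np.uint8)


def _scale(pixels: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return pixels
    h, w = pixels.shape[:2]
    out = rescale(
        pixels.astype(np.float64) / 255.0, factor,
        channel_axis=2, mode="reflect", order=1, preserve_range=True,
    )
    out = np.clip(out * 255.0, 0, 255).astype(np.uint8)
    oh, ow = out.shape[:2]
    if factor >= 1.0:  # center-crop back to the original frame
        r0, c0 = (oh - h) // 2, (ow - w) // 2
        return out[r0:r0 + h, c0:c0 + w]
    # reflect-pad up to the original frame
    pr, pc = h - oh, w - ow
    return np.pad(
        out,
        ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2), (0, 0)),
        mode="reflect",
    )


def _color_jitter(pixels: np.ndarray, gains: np.ndarray) -> np.ndarray:
    out = pixels.astype(np.float64) * gains[np.newaxis, np.newaxis, :]
    return np.clip(out, 0, 255).astype(np.uint8)


def _noise(pixels: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0.0:
        return pixels
    out = pixels.astype(np.float64) + rng.normal(0.0, sigma, pixels.shape)
    return np.clip(out, 0, 255).astype(np.uint8)


def _augment_once(pixels: np.ndarray, config: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    out = pixels
    if "hflip" in config.ops and rng.random() < 0.5:
        out = hflip(out)
    if "vflip" in config.ops and rng.random() < 0.5:
        out = vflip(out)
    if "scale" in config.ops:
        out = _scale(out, float(rng.uniform(*config.scale_range)))
    if "rotate" in config.ops:
        out = _rotate(out, float(rng.uniform(-config.rotate_range,
                                             config.rotate_range)))
    if "color_jitter" in config.ops:
        gains = rng.uniform(*config.color_jitter_range, size=3)
        out = _color_jitter(out, gains)
    if "noise" in config.ops:
        out = _noise(out, config.noise_sigma, rng)
    return np.ascontiguousarray(out)


def routine_augment(
    image: LabeledImage, config: AugmentConfig, seed: int
) -> List[LabeledImage]:
    """Produce the original image plus seeded random augmented copies.

    Label, magnification and patient metadata are carried over unchanged and
    the output shape equals the input shape. With an empty op set the input
    is returned unchanged (identity).
    """
    if not config.ops:
        return [image]
    rng = np.random.default_rng(seed)
    out = [image]
    for k in range(config.factor - 1):
        pixels = _augment_once(image.pixels, config, rng)
        out.append(
            LabeledImage(
                pixels=pixels,
                label=image.label,
                magnification=image.magnification,
                subtype=image.subtype,
                patient_id=image.patient_id,
                source_path=f"{image.source_path}#aug{k}",
            )
        )
    return out


def augment_training_set(
    records: Sequence[LabeledImage], config: AugmentConfig, seed: int
) -> List[LabeledImage]:
    """Apply :func:`routine_augment` across a training set (training only —
    test images are never photometrically augmented)."""
    out: List[LabeledImage] = []
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, len(records)])
    child_seeds = ss.generate_state(max(len(records), 1))
    for rec, s in zip(records, child_seeds):
        out.extend(routine_augment(rec, config, int(s)))
    return out
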