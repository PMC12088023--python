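"""Synthetic two-class textured RGB image datasets for pipeline testing.

The generator emulates the one structural assumption the tile pipeline
rests on: whether the class-discriminating signal is *stationary* (present
in every n×n tile, so label inheritance is exact) or *focal* (present only
in a sub-region covering ``focal_fraction`` of the image, so inherited tile
labels are noisy for tiles outside the lesion).

Class signal is carved as class-specific texture over a light tissue-like
background with Gaussian pixel noise:

* benign — smooth low-frequency blobs with a slight eosin-pink tint;
* malignant — dense high-frequency dark speckle with a hematoxylin-purple
  tint, emulating hyperchromatic nuclei.

Both texture amplitudes scale with ``class_separation`` (8-bit units), so
``class_separation = 0`` makes the two classes distributionally identical
(the null). The families are chosen so that the fully connected head over
the deterministic fixture backbone can separate them — luminance and
smoothness both carry signal — which keeps training-convergence tests
well-posed. No attempt is made to imitate real H&E morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .types import Label, LabeledImage, Magnification

BACKGROUND_LEVEL = 205.0  # light tissue-like base, 8-bit
BENIGN_TINT = np.array([1.0, 0.5, 0.6])      # eosin-pink
MALIGNANT_TINT = np.array([0.8, 0.4, 1.0])   # hematoxylin-purple
SPECKLE_DENSITY = 0.12
BLOB_SIGMA = 8.0


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-class dataset.

    n_images_per_class
        Images generated for each of benign and malignant.
    image_size
        (H, W); the desk-scale default 128×128 keeps end-to-end tests in
        seconds. Use (460, 700) for BreaKHis-frame geometry tests.
    signal_mode
        ``"stationary"`` (class texture everywhere) or ``"focal"`` (texture
        confined to a random rectangle of area ``focal_fraction``).
    focal_fraction
        Lesion area fraction in focal mode, in (0, 1].
    class_separation
        Texture amplitude in 8-bit units; 0 gives the no-signal null.
    noise_sigma
        Std of the additive Gaussian background noise, 8-bit units.
    seed
        Seeds all randomness; identical specs generate byte-identical data.
    """

    n_images_per_class: int = 100
    image_size: Tuple[int, int] = (128, 128)
    signal_mode: str = "stationary"
    focal_fraction: float = 0.25
    class_separation: float = 30.0
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_mode not in ("stationary", "focal"):
            raise ValueError(f"unknown signal_mode: {self.signal_mode!r}")
        if not (0.0 < self.focal_fraction <= 1.0):
            raise ValueError("focal_fraction must lie in (0, 1]")
        if not (np.isfinite(self.class_separation) and self.class_separation >= 0):
            raise ValueError("class_separation must be finite and ≥ 0")
        if not (np.isfinite(self.noise_sigma) and self.noise_sigma >= 0):
            raise ValueError("noise_sigma must be finite and ≥ 0")


@dataclass
class GenerationInfo:
    """Ground truth about where class signal was placed.

    ``signal_rects[i]`` is the (r0, r1, c0, c1) extent of the signal-bearing
    region of image i (the full frame in stationary mode).
    """

    spec: SyntheticSpec
    signal_rects: List[Tuple[int, int, int, int]] = field(default_factory=list)

    def tile_signal_coverage(self, n: int) -> float:
        """Realized fraction of n×n tiles that overlap a signal region by at
        least half of the tile area — the inherited-label noise quantifier."""
        from .augmentation import grid_boundaries

        h, w = self.spec.image_size
        rb = grid_boundaries(h, n)
        cb = grid_boundaries(w, n)
        covered = total = 0
        for (r0, r1, c0, c1) in self.signal_rects:
            for r in range(n):
                for c in range(n):
                    area = (rb[r + 1] - rb[r]) * (cb[c + 1] - cb[c])
                    orow = max(0, min(r1, rb[r + 1]) - max(r0, rb[r]))
                    ocol = max(0, min(c1, cb[c + 1]) - max(c0, cb[c]))
                    covered += (orow * ocol) >= 0.5 * area
                    total += 1
        return covered / total if total else 0.0


def _benign_texture(shape, sep: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean low-frequency blobs, unit-std before scaling."""
    t = gaussian_filter(rng.normal(size=shape), BLOB_SIGMA, mode="reflect")
    sd = t.std()
    if sd > 0:
        t /= sd
    return sep * t


def _malignant_texture(shape, sep: float, rng: np.random.Generator) -> np.ndarray:
    """Dark high-frequency speckle: sparse nuclei-like dots lowering
    luminance, amplitude 3·sep at density SPECKLE_DENSITY."""
    mask = rng.random(shape) < SPECKLE_DENSITY
    depth = rng.uniform(0.5, 1.0, shape)
    return -3.0 * sep * mask * depth


def _generate_one(
    label: Label, spec: SyntheticSpec, rng: np.random.Generator
) -> Tuple[np.ndarray, Tuple[int, int, int, int]]:
    h, w = spec.image_size
    base = BACKGROUND_LEVEL + rng.normal(0.0, spec.noise_sigma, (h, w, 3))
    if label is Label.BENIGN:
        texture = _benign_texture((h, w), spec.class_separation, rng)
        tint = BENIGN_TINT
    else:
        texture = _malignant_texture((h, w), spec.class_separation, rng)
        tint = MALIGNANT_TINT

    if spec.signal_mode == "focal":
        f = spec.focal_fraction
        fw = float(rng.uniform(f, 1.0))
        fh = min(1.0, f / fw)
        rh, rw = max(1, round(fh * h)), max(1, round(fw * w))
        r0 = int(rng.integers(0, h - rh + 1))
        c0 = int(rng.integers(0, w - rw + 1))
        rect = (r0, r0 + rh, c0, c0 + rw)
        mask = np.zeros((h, w))
        mask[r0:r0 + rh, c0:c0 + rw] = 1.0
        texture = texture * mask
    else:
        rect = (0, h, 0, w)

    pixels = base + texture[:, :, np.newaxis] * tint[np.newaxis, np.newaxis, :]
    return np.clip(pixels, 0, 255).astype(np.uint8), rect


def generate_dataset_with_info(
    spec: SyntheticSpec,
) -> Tuple[List[LabeledImage], GenerationInfo]:
    """Generate the dataset together with signal-placement ground truth."""
    rng = np.random.default_rng(spec.seed)
    info = GenerationInfo(spec=spec)
    images: List[LabeledImage] = []
    for label, subtype in (
        (Label.BENIGN, "fibroadenoma"),
        (Label.MALIGNANT, "ductal_carcinoma"),
    ):
        for i in range(spec.n_images_per_class):
            pixels, rect = _generate_one(label, spec, rng)
            info.signal_rects.append(rect)
            images.append(
                LabeledImage(
                    pixels=pixels,
                    label=label,
                    magnification=Magnification.X40,
                    subtype=subtype,
                    patient_id=f"SYN-{label.value[:1].upper()}-{i:04d}",
                    source_path=f"synthetic://{spec.signal_mode}/{label.value}/{i:04d}",
                )
            )
    return images, info


def generate_dataset(spec: SyntheticSpec) -> List[LabeledImage]:
    """Generate a reproducible two-class synthetic image dataset.

    Returns 2·``n_images_per_class`` images (benign first), byte-identical
    across runs for a fixed seed. Zero images requested → empty list.
    """
    return generate_dataset_with_info(spec)[0]


def write_fixture_tree(
    images: List[LabeledImage],
    root,
    layout: str = "two_class_folders",
):
    """Materialize synthetic images on disk in a layout ``scan_dataset``
    reads, closing the generation → ingestion loop for integration tests.

    Returns the manifest DataFrame written alongside the tree.
    """
    from .dataset_io import write_manifest

    root = Path(root)
    subtype_code = {Label.BENIGN: "F", Label.MALIGNANT: "DC"}
    cls_code = {Label.BENIGN: "B", Label.MALIGNANT: "M"}
    written = []
    for i, img in enumerate(images):
        if layout == "two_class_folders":
            path = root / img.label.value / f"synthetic_{i:05d}.png"
        elif layout == "breakhis":
            mag = img.magnification.value.rstrip("x")
            if mag == "unknown":
                mag = "40"
            name = (
                f"SOB_{cls_code[img.label]}_{subtype_code[img.label]}"
                f"-SYN-{i:05d}-{mag}-001.png"
            )
            path = root / img.label.value / name
        else:
            raise ValueError(f"unknown layout: {layout!r}")
        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img.pixels).save(path)
        img.source_path = str(path)
        written.append(img)
    return write_manifest(written, root / "manifest.csv")
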