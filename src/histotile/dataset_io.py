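"""Reading labeled pathology image collections and reproducible splitting.

Two on-disk layouts are supported:

``breakhis``
    The BreaKHis directory/filename convention, where each file is named
    ``<BIOPSY>_<CLASS>_<SUBTYPE>-<SLIDE>-<MAG>-<SEQ>.png`` (for example
    ``SOB_B_TA-14-4659-40-001.png``): tumor class (B/M), subtype code,
    patient slide code and magnification are all parsed from the name.

``two_class_folders``
    A generic layout with one subdirectory per class, ``benign/`` and
    ``malignant/`` (any nesting below those is allowed).

Splitting is at the whole-image level — every tile later derived from an
image lands in the same partition — and is reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
import math
import re
from fractions import Fraction
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .types import (
    BENIGN_SUBTYPES,
    DatasetSplit,
    Label,
    LabeledImage,
    Magnification,
    SplitSpec,
    SUBTYPE_CODES,
    subtype_label,
)

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}

#: filename stem: BIOPSY _ CLASS _ SUBTYPE - SLIDE... - MAG - SEQ
_BREAKHIS_RE = re.compile(
    r"^(?P<biopsy>[A-Za-z]+)_(?P<cls>[BM])_(?P<tail>[A-Za-z]+(?:-[A-Za-z0-9]+)+)$"
)


class FilenameParseError(ValueError):
    """Raised when a file does not follow the BreaKHis naming convention."""


def parse_breakhis_name(path: Path) -> Tuple[Label, str, str, Magnification]:
    """Parse (label, subtype, patient_id, magnification) from a BreaKHis filename.

    Falls back to directory names for components the filename lacks, per the
    published convention ``<BIOPSY>_<CLASS>_<SUBTYPE>-<SLIDE>-<MAG>-<SEQ>``.
    """
    m = _BREAKHIS_RE.match(path.stem)
    if m is None:
        raise FilenameParseError(
            f"cannot parse BreaKHis filename: {path}"
        )
    tokens = m.group("tail").split("-")
    if len(tokens) < 4:
        raise FilenameParseError(
            f"BreaKHis filename has too few '-' components: {path}"
        )
    subtype_code = tokens[0].upper()
    mag_token, _seq = tokens[-2], tokens[-1]
    slide_code = "-".join(tokens[1:-2])
    label = Label.BENIGN if m.group("cls") == "B" else Label.MALIGNANT
    if subtype_code in SUBTYPE_CODES:
        subtype = SUBTYPE_CODES[subtype_code]
        if subtype_label(subtype) != label:
            raise FilenameParseError(
                f"subtype code {subtype_code} contradicts class "
                f"{m.group('cls')} in {path}"
            )
    else:
        raise FilenameParseError(
            f"unknown subtype code {subtype_code!r} in {path}"
        )
    magnification = Magnification.from_string(mag_token)
    if magnification is Magnification.UNKNOWN:
        # fall back to a directory named like "40X"
        for part in reversed(path.parent.parts):
            magnification = Magnification.from_string(part)
            if magnification is not Magnification.UNKNOWN:
                break
    patient_id = f"{m.group('biopsy')}_{m.group('cls')}_{subtype_code}-{slide_code}"
    return label, subtype, patient_id, magnification


def _load_pixels(path: Path) -> Optional[np.ndarray]:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (OSError, UnidentifiedImageError) as exc:
        logger.warning("skipping unreadable image %s: %s", path, exc)
        return None


def scan_dataset(
    root,
    layout: str = "two_class_folders",
    magnification: Optional[str] = None,
) -> List[LabeledImage]:
    """Scan ``root`` for labeled images and return them in sorted-path order.

    Parameters
    ----------
    root : path-like
        Dataset root directory.
    layout : {"breakhis", "two_class_folders"}
        Naming convention to use for label/metadata extraction.
    magnification : str, optional
        If given (e.g. ``"40x"``), keep only records at that magnification.

    Returns
    -------
    list of LabeledImage
        One record per decodable image file, in deterministic sorted order.
        Unreadable files are skipped with a logged warning; a filename that
        cannot be parsed under the breakhis layout raises
        :class:`FilenameParseError` naming the offending path.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root does not exist: {root}")
    if layout not in ("breakhis", "two_class_folders"):
        raise ValueError(f"unknown layout: {layout!r}")
    mag_filter = Magnification.from_string(magnification) if magnification else None

    paths = sorted(
        p for p in root.rglob("*")
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )
    records: List[LabeledImage] = []
    for path in paths:
        if layout == "breakhis":
            label, subtype, patient_id, mag = parse_breakhis_name(path)
        else:
            label = _two_class_label(path, root)
            subtype, patient_id, mag = None, None, Magnification.UNKNOWN
        if mag_filter is not None and mag != mag_filter:
            continue
        pixels = _load_pixels(path)
        if pixels is None:
            continue
        records.append(
            LabeledImage(
                pixels=pixels,
                label=label,
                magnification=mag,
                subtype=subtype,
                patient_id=patient_id,
                source_path=str(path),
            )
        )
    return records


def _two_class_label(path: Path, root: Path) -> Label:
    rel = path.relative_to(root)
    top = rel.parts[0].lower()
    try:
        return Label(top)
    except ValueError:
        raise ValueError(
            f"two_class_folders layout requires top-level 'benign'/'malignant' "
            f"directories; got {top!r} for {path}"
        ) from None


def train_test_counts(n_label: int, train_fraction: float) -> Tuple[int, int]:
    """Per-label (train, test) counts under stratified splitting.

    The test partition takes ``floor((1 - train_fraction) * n)`` records and
    the train partition the remainder, so the realized train fraction never
    falls below the requested one by more than one record per label. The
    fraction is handled as an exact rational so decimal fractions like 0.8
    behave exactly.
    """
    frac = Fraction(train_fraction).limit_denominator(10**6)
    n_test = math.floor((1 - frac) * n_label)
    return n_label - n_test, n_test


def split_dataset(records: Sequence[LabeledImage], spec: SplitSpec) -> DatasetSplit:
    """Randomly partition records into train/test per ``spec``.

    Stratified by label when ``spec.stratify_by_label`` is set; reproducible
    for a fixed seed. Records are ordered by source path before shuffling so
    the split is stable across filesystems.
    """
    if not records:
        raise ValueError("cannot split an empty record list")
    ordered = sorted(range(len(records)), key=lambda i: records[i].source_path)
    rng = np.random.default_rng(spec.seed)

    if spec.group_by_patient:
        return _split_by_patient(records, ordered, spec, rng)

    if spec.stratify_by_label:
        train_idx: List[int] = []
        test_idx: List[int] = []
        for label in (Label.BENIGN, Label.MALIGNANT):
            group = [i for i in ordered if records[i].label is label]
            if not group:
                continue
            if len(group) < 2:
                raise ValueError(
                    f"label {label.value} has fewer than 2 records; "
                    "cannot stratify"
                )
            perm = rng.permutation(len(group))
            n_train, _ = train_test_counts(len(group), spec.train_fraction)
            train_idx.extend(group[j] for j in perm[:n_train])
            test_idx.extend(group[j] for j in perm[n_train:])
    else:
        perm = rng.permutation(len(ordered))
        n_train, _ = train_test_counts(len(ordered), spec.train_fraction)
        train_idx = [ordered[j] for j in perm[:n_train]]
        test_idx = [ordered[j] for j in perm[n_train:]]

    return DatasetSplit(
        train=[records[i] for i in sorted(train_idx)],
        test=[records[i] for i in sorted(test_idx)],
    )


def _split_by_patient(records, ordered, spec, rng) -> DatasetSplit:
    # optional extension: keep all images of one patient in one partition
    patients: dict = {}
    for i in ordered:
        key = records[i].patient_id or records[i].source_path
        patients.setdefault(key, []).append(i)
    keys = sorted(patients)
    perm = rng.permutation(len(keys))
    n_train, _ = train_test_counts(len(keys), spec.train_fraction)
    train_keys = {keys[j] for j in perm[:n_train]}
    train_idx = [i for k in keys if k in train_keys for i in patients[k]]
    test_idx = [i for k in keys if k not in train_keys for i in patients[k]]
    return DatasetSplit(
        train=[records[i] for i in sorted(train_idx)],
        test=[records[i] for i in sorted(test_idx)],
    )


def write_manifest(
    records: Iterable[LabeledImage],
    path,
    split: Optional[DatasetSplit] = None,
) -> pd.DataFrame:
    """Write a dataset manifest CSV (path, label, subtype, magnification,
    patient_id, split)."""
    split_of = {}
    if split is not None:
        for rec in split.train:
            split_of[rec.source_path] = "train"
        for rec in split.test:
            split_of[rec.source_path] = "test"
    rows = [
        {
            "path": r.source_path,
            "label": r.label.value,
            "subtype": r.subtype or "",
            "magnification": r.magnification.value,
            "patient_id": r.patient_id or "",
            "split": split_of.get(r.source_path, ""),
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=["path", "label", "subtype", "magnification", "patient_id", "split"],
    )
    df.to_csv(path, index=False)
    return df


def read_manifest(path) -> pd.DataFrame:
    """Read a manifest CSV written by :func:`write_manifest`."""
    return pd.read_csv(path, keep_default_na=False)


def load_manifest_images(path) -> List[LabeledImage]:
    """Load every image listed in a manifest CSV back into memory."""
    df = read_manifest(path)
    records = []
    for row in df.itertuples(index=False):
        pixels = _load_pixels(Path(row.path))
        if pixels is None:
            continue
        records.append(
            LabeledImage(
                pixels=pixels,
                label=Label(row.label),
                magnification=Magnification(row.magnification)
                if row.magnification else Magnification.UNKNOWN,
                subtype=row.subtype or None,
                patient_id=row.patient_id or None,
                source_path=str(row.path),
            )
        )
    return records
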