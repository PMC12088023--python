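"""Dataset scanning, BreaKHis filename parsing, and reproducible splitting."""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from histotile.dataset_io import (
    FilenameParseError,
    load_manifest_images,
    parse_breakhis_name,
    read_manifest,
    scan_dataset,
    split_dataset,
    train_test_counts,
    write_manifest,
)
from histotile.types import Label, LabeledImage, Magnification, SplitSpec

from conftest import make_image


def _write_png(path: Path, seed: int = 0, size=(8, 8)) -> None:
    rng = np.random.default_rng(seed)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(
        rng.integers(0, 256, (*size, 3), dtype=np.uint8), "RGB"
    ).save(path)


@pytest.fixture
def two_class_tree(tmp_path):
    for i in range(3):
        _write_png(tmp_path / "benign" / f"b{i}.png", seed=i)
    for i in range(2):
        _write_png(tmp_path / "malignant" / f"m{i}.png", seed=10 + i)
    return tmp_path


class TestScan:
    def test_two_class_folders(self, two_class_tree):
        records = scan_dataset(two_class_tree, layout="two_class_folders")
        assert len(records) == 5
        assert sum(r.label is Label.BENIGN for r in records) == 3
        # deterministic sorted-path order
        assert [r.source_path for r in records] == sorted(
            r.source_path for r in records
        )

    def test_unreadable_file_skipped(self, two_class_tree, caplog):
        bad = two_class_tree / "benign" / "corrupt.png"
        bad.write_bytes(b"not a png at all")
        with caplog.at_level("WARNING"):
            records = scan_dataset(two_class_tree)
        assert len(records) == 5
        assert any("corrupt.png" in m for m in caplog.messages)

    def test_breakhis_layout(self, tmp_path):
        name = "SOB_M_DC-14-10926-400-003.png"
        _write_png(tmp_path / "malignant" / name)
        records = scan_dataset(tmp_path, layout="breakhis")
        (rec,) = records
        assert rec.label is Label.MALIGNANT
        assert rec.subtype == "ductal_carcinoma"
        assert rec.magnification is Magnification.X400
        assert rec.patient_id == "SOB_M_DC-14-10926"

    def test_magnification_filter(self, tmp_path):
        _write_png(tmp_path / "SOB_B_F-14-21998AB-40-001.png")
        _write_png(tmp_path / "SOB_B_F-14-21998AB-100-001.png")
        records = scan_dataset(tmp_path, layout="breakhis", magnification="40x")
        assert len(records) == 1
        assert records[0].magnification is Magnification.X40

    def test_unparseable_breakhis_name_errors(self, tmp_path):
        _write_png(tmp_path / "justsomefile.png")
        with pytest.raises(FilenameParseError, match="justsomefile"):
            scan_dataset(tmp_path, layout="breakhis")

    def test_missing_root(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            scan_dataset(tmp_path / "nope")


class TestBreakhisParser:
    @pytest.mark.parametrize(
        "name, label, subtype, mag",
        [
            ("SOB_M_DC-14-10926-400-003", Label.MALIGNANT,
             "ductal_carcinoma", Magnification.X400),
            ("SOB_B_TA-14-4659-40-001", Label.BENIGN,
             "tubular_adenoma", Magnification.X40),
            ("SOB_B_PT-14-21998AB-200-012", Label.BENIGN,
             "phyllodes_tumor", Magnification.X200),
            ("SOB_M_PC-14-9146-100-002", Label.MALIGNANT,
             "papillary_carcinoma", Magnification.X100),
        ],
    )
    def test_parse(self, name, label, subtype, mag):
        got_label, got_subtype, _pid, got_mag = parse_breakhis_name(
            Path(f"{name}.png")
        )
        assert (got_label, got_subtype, got_mag) == (label, subtype, mag)

    def test_class_subtype_contradiction(self):
        with pytest.raises(FilenameParseError):
            parse_breakhis_name(Path("SOB_B_DC-14-10926-40-001.png"))


def _records(n_benign, n_malignant, mag=Magnification.UNKNOWN):
    recs = []
    rng = np.random.default_rng(0)
    for i in range(n_benign + n_malignant):
        label = Label.BENIGN if i < n_benign else Label.MALIGNANT
        rec = make_image(
            rng.integers(0, 256, (4, 4, 3), dtype=np.uint8),
            label, f"mem://{label.value}/{i:05d}",
        )
        rec.magnification = mag
        recs.append(rec)
    return recs


class TestSplit:
    # the published per-magnification totals and their 80/20 partition
    TABLE_CELLS = [
        (625, 500, 125),
        (1370, 1096, 274),
        (644, 516, 128),
        (1437, 1150, 287),
        (623, 499, 124),
        (1390, 1112, 278),
        (588, 471, 117),
        (1232, 986, 246),
    ]

    @pytest.mark.parametrize("total, n_train, n_test", TABLE_CELLS)
    def test_counts_match_published_distribution(self, total, n_train, n_test):
        assert train_test_counts(total, 0.8) == (n_train, n_test)

    def test_stratified_40x_counts(self):
        recs = _records(625, 1370)
        split = split_dataset(recs, SplitSpec(train_fraction=0.8, seed=7))
        bt = sum(r.label is Label.BENIGN for r in split.train)
        mt = sum(r.label is Label.MALIGNANT for r in split.train)
        assert (bt, mt) == (500, 1096)
        assert (625 - bt, 1370 - mt) == (125, 274)

    def test_partition_property(self):
        recs = _records(13, 17)
        split = split_dataset(recs, SplitSpec(seed=3))
        ids = lambda rs: {r.source_path for r in rs}
        assert ids(split.train) | ids(split.test) == ids(recs)
        assert ids(split.train) & ids(split.test) == set()

    def test_reproducible_and_seed_sensitive(self):
        recs = _records(5, 5)
        a1 = split_dataset(recs, SplitSpec(seed=1))
        a2 = split_dataset(recs, SplitSpec(seed=1))
        b = split_dataset(recs, SplitSpec(seed=2))
        ids = lambda rs: [r.source_path for r in rs]
        assert ids(a1.train) == ids(a2.train)
        assert ids(a1.train) != ids(b.train)

    def test_single_label_rounding(self):
        # 5 records of one class, fraction 0.8 → 4 train / 1 test
        recs = _records(5, 0)
        split = split_dataset(recs, SplitSpec(seed=0, stratify_by_label=True))
        assert (len(split.train), len(split.test)) == (4, 1)

    def test_too_few_per_label_errors(self):
        recs = _records(1, 5)
        with pytest.raises(ValueError, match="fewer than 2"):
            split_dataset(recs, SplitSpec())

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            split_dataset([], SplitSpec())

    @given(
        n_b=st.integers(2, 40),
        n_m=st.integers(2, 40),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_stratified_proportions_property(self, n_b, n_m, seed):
        """Per-label train counts deviate from the target fraction by at
        most one record, for every seed."""
        recs = _records(n_b, n_m)
        split = split_dataset(recs, SplitSpec(seed=seed))
        assert len(split.train) + len(split.test) == n_b + n_m
        for label, n in ((Label.BENIGN, n_b), (Label.MALIGNANT, n_m)):
            got = sum(r.label is label for r in split.train)
            assert abs(got - 0.8 * n) <= 1.0

    def test_group_by_patient_keeps_patients_together(self):
        recs = _records(6, 6)
        for i, r in enumerate(recs):
            r.patient_id = f"P{i // 3}"
        split = split_dataset(
            recs, SplitSpec(seed=0, group_by_patient=True)
        )
        train_p = {r.patient_id for r in split.train}
        test_p = {r.patient_id for r in split.test}
        assert train_p & test_p == set()


def test_manifest_round_trip(tmp_path, two_class_tree=None):
    root = tmp_path / "data"
    for i in range(5):
        _write_png(root / "benign" / f"b{i}.png", seed=i)
        _write_png(root / "malignant" / f"m{i}.png", seed=5 + i)
    records = scan_dataset(root)
    split = split_dataset(records, SplitSpec(seed=0))
    out = tmp_path / "manifest.csv"
    write_manifest(records, out, split=split)
    df = read_manifest(out)
    assert list(df.columns) == [
        "path", "label", "subtype", "magnification", "patient_id", "split"
    ]
    assert set(df["split"]) == {"train", "test"}
    loaded = load_manifest_images(out)
    assert len(loaded) == 10
    assert all(
        np.array_equal(a.pixels, b.pixels) for a, b in zip(records, loaded)
    )
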