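import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import epitopescan as es
from epitopescan.errors import DatasetError, MissingParentError

from util import ALPHABET, random_peptide


def make_record(peptide, label=1, record_id="r0", parent=None, start=1):
    parent = parent if parent is not None else peptide
    return es.EpitopeRecord(
        record_id=record_id,
        parent_id=f"{record_id}_parent",
        start=start,
        end=start + len(peptide) - 1,
        peptide=peptide,
        label=label,
        parent_sequence=parent,
    )


HEADER = "record_id\tparent_id\tstart\tend\tpeptide\tlabel\n"


class TestLoadDataset:
    def test_nonstandard_residue_rows_are_rejected_not_fatal(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text(
            HEADER
            + "a\tp1\t1\t5\tACDEF\t+1\n"
            + "b\tp2\t1\t5\tACXEF\t-1\n"
            + "c\tp3\t1\t5\tGHIKL\t-1\n"
        )
        records = es.load_dataset(path)
        assert [r.record_id for r in records] == ["a", "c"]

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text(HEADER)
        assert es.load_dataset(path) == []

    def test_end_before_start_raises(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text(HEADER + "a\tp1\t5\t1\tACDEF\t+1\n")
        with pytest.raises(DatasetError):
            es.load_dataset(path)

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("record_id\tparent_id\tstart\tend\tpeptide\n" + "a\tp\t1\t5\tACDEF\n")
        with pytest.raises(DatasetError):
            es.load_dataset(path)

    def test_label_outside_plus_minus_one_raises(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text(HEADER + "a\tp1\t1\t5\tACDEF\t2\n")
        with pytest.raises(DatasetError):
            es.load_dataset(path)

    def test_roundtrip_through_writer(self, tmp_path):
        records = [make_record("ACDEFGH", 1, "a"), make_record("KLMNPQR", -1, "b")]
        path = tmp_path / "out.tsv"
        es.write_dataset(records, path)
        loaded = es.load_dataset(path)
        assert [(r.record_id, r.peptide, r.label) for r in loaded] == [
            ("a", "ACDEFGH", 1), ("b", "KLMNPQR", -1),
        ]


class TestExtendToLength:
    def test_interior_epitope_splits_deficit_left_floor(self, rng):
        parent = random_peptide(rng, 200)
        rec = make_record(parent[45:60], start=46, parent=parent)
        ext = es.extend_to_length(rec, 100)
        assert (ext.start, ext.end) == (4, 103)
        assert len(ext.peptide) == 100
        assert ext.peptide == parent[3:103]

    def test_left_terminus_clamp_takes_remainder_from_right(self, rng):
        parent = random_peptide(rng, 200)
        rec = make_record(parent[0:15], start=1, parent=parent)
        ext = es.extend_to_length(rec, 100)
        assert (ext.start, ext.end) == (1, 100)

    def test_short_parent_caps_at_parent_length(self, rng):
        parent = random_peptide(rng, 40)
        rec = make_record(parent[10:25], start=11, parent=parent)
        ext = es.extend_to_length(rec, 100)
        assert len(ext.peptide) == 40
        assert (ext.start, ext.end) == (1, 40)

    def test_already_long_enough_returned_unchanged(self, rng):
        rec = make_record(random_peptide(rng, 30))
        assert es.extend_to_length(rec, 20) is rec

    def test_missing_parent_raises(self, rng):
        peptide = random_peptide(rng, 10)
        rec = es.EpitopeRecord("r", "p", 1, 10, peptide, 1, parent_sequence=None)
        with pytest.raises(MissingParentError):
            es.extend_to_length(rec, 100)

    @given(
        parent_len=st.integers(30, 120),
        epi_len=st.integers(7, 20),
        target=st.integers(21, 100),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_extension_contains_original_at_original_coordinates(
        self, parent_len, epi_len, target, data
    ):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**20)))
        parent = random_peptide(rng, parent_len)
        start = data.draw(st.integers(1, parent_len - epi_len + 1))
        rec = make_record(parent[start - 1 : start - 1 + epi_len], start=start, parent=parent)
        ext = es.extend_to_length(rec, target)
        assert len(ext.peptide) == min(target, parent_len) or target <= epi_len
        # Cropping the extension back to the original span recovers the peptide.
        lo = rec.start - ext.start
        assert ext.peptide[lo : lo + epi_len] == rec.peptide


class TestResizeToLength:
    def test_symmetric_crop_of_longer_peptide(self, rng):
        parent = random_peptide(rng, 50)
        rec = make_record(parent[9:30], start=10, parent=parent)  # 21-mer
        out = es.resize_to_length(rec, 15)
        assert (out.start, out.end) == (13, 27)
        assert out.peptide == parent[12:27]

    def test_equal_length_is_identity(self, rng):
        rec = make_record(random_peptide(rng, 15))
        assert es.resize_to_length(rec, 15) is rec

    def test_growth_splits_deficit_left_floor(self, rng):
        parent = random_peptide(rng, 30)
        rec = make_record(parent[4:13], start=5, parent=parent)  # 9-mer at [5,13]
        out = es.resize_to_length(rec, 15)
        assert (out.start, out.end) == (2, 16)


class TestDeduplicate:
    def test_consistent_duplicates_keep_first(self):
        a = make_record("ACDEF", 1, "a")
        b = make_record("ACDEF", 1, "b")
        assert es.deduplicate([a, b]) == [a]

    def test_label_conflicts_removed_entirely(self):
        a = make_record("ACDEF", 1, "a")
        b = make_record("ACDEF", -1, "b")
        assert es.deduplicate([a, b]) == []

    def test_distinct_peptides_untouched(self, rng):
        records = [
            make_record(random_peptide(rng, 10), 1, f"r{i}") for i in range(10)
        ]
        assert es.deduplicate(records) == records

    @given(st.lists(st.tuples(st.sampled_from(["AAA", "CCC", "GGG", "TTT", "WWW"]),
                              st.sampled_from([1, -1])), max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, pairs):
        records = [
            make_record(p, label, f"r{i}") for i, (p, label) in enumerate(pairs)
        ]
        once = es.deduplicate(records)
        assert es.deduplicate(once) == once


class TestMakeFolds:
    def _records(self, rng, n_pos, n_neg):
        recs = []
        for i in range(n_pos + n_neg):
            recs.append(make_record(random_peptide(rng, 12), 1 if i < n_pos else -1, f"r{i}"))
        return recs

    def test_balanced_classes_give_equal_folds(self, rng):
        records = self._records(rng, 100, 100)
        fa = es.make_folds(records, k=5, seed=3)
        for f in range(5):
            members = [r for r in records if fa.fold_of(r.record_id) == f]
            assert sum(r.label == 1 for r in members) == 20
            assert sum(r.label == -1 for r in members) == 20

    def test_seed_determinism(self, rng):
        records = self._records(rng, 20, 20)
        a = es.make_folds(records, k=5, seed=11)
        b = es.make_folds(records, k=5, seed=11)
        assert dict(a.assignment) == dict(b.assignment)

    def test_uneven_counts_differ_by_at_most_one(self, rng):
        records = self._records(rng, 7, 7)
        fa = es.make_folds(records, k=5, seed=0)
        for label in (1, -1):
            sizes = [
                sum(1 for r in records if r.label == label and fa.fold_of(r.record_id) == f)
                for f in range(5)
            ]
            assert set(sizes) <= {1, 2}
            assert sum(sizes) == 7

    def test_partition_is_disjoint_and_complete(self, rng):
        records = self._records(rng, 13, 9)
        fa = es.make_folds(records, k=4, seed=5)
        assert sorted(fa.assignment) == sorted(r.record_id for r in records)
        assert set(fa.assignment.values()) == set(range(4))

    def test_single_class_raises(self, rng):
        records = self._records(rng, 10, 0)
        with pytest.raises(DatasetError):
            es.make_folds(records, k=5, seed=0)
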