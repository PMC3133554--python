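"""Labeled epitope datasets: ingestion, normalization, extension, deduplication, folds.

An epitope record anchors a labeled peptide (+1 antigenic, -1 not) to a parent
protein via 1-based inclusive coordinates.  Epitope databases report peptides of
very different lengths, so training protocols first bring them to a fixed length
(centered crop/extension within the parent) and remove redundant peptides.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from sklearn.model_selection import StratifiedKFold

from .errors import AlphabetError, DatasetError, MissingParentError, ConsistencyError

logger = logging.getLogger(__name__)

#: The 20 standard residues, alphabetical by one-letter code.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_RESIDUES)

REQUIRED_COLUMNS = ("record_id", "parent_id", "start", "end", "peptide", "label")


@dataclass(frozen=True)
class EpitopeRecord:
    """One labeled peptide anchored to a parent protein.

    Coordinates are 1-based inclusive, matching the numbering used by the
    per-residue annotation file formats.
    """

    record_id: str
    parent_id: str
    start: int
    end: int
    peptide: str
    label: int
    parent_sequence: Optional[str] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise DatasetError(
                f"{self.record_id}: end ({self.end}) < start ({self.start})"
            )
        if self.label not in (1, -1):
            raise DatasetError(f"{self.record_id}: label must be +1 or -1")
        if len(self.peptide) != self.end - self.start + 1:
            raise DatasetError(
                f"{self.record_id}: peptide length {len(self.peptide)} does not "
                f"match coordinates [{self.start},{self.end}]"
            )
        bad = set(self.peptide) - _STANDARD_SET
        if bad:
            raise AlphabetError(
                f"{self.record_id}: non-standard residues {sorted(bad)}"
            )
        if self.parent_sequence is not None:
            segment = self.parent_sequence[self.start - 1 : self.end]
            if segment != self.peptide:
                raise ConsistencyError(
                    f"{self.record_id}: parent_sequence[{self.start}..{self.end}] "
                    f"= {segment!r} != peptide {self.peptide!r}"
                )

    def __len__(self) -> int:
        return len(self.peptide)


@dataclass(frozen=True)
class FoldAssignment:
    """Seed-deterministic stratified fold assignment, record_id -> fold index."""

    assignment: Mapping[str, int]
    k: int
    seed: int

    def fold_of(self, record_id: str) -> int:
        return self.assignment[record_id]


def _parse_label(raw) -> int:
    try:
        value = int(str(raw).strip())
    except (TypeError, ValueError) as exc:
        raise DatasetError(f"unparseable label {raw!r}") from exc
    if value not in (1, -1):
        raise DatasetError(f"label {raw!r} outside {{+1, -1}}")
    return value


def load_parents_fasta(path) -> Dict[str, str]:
    """Read parent protein sequences keyed by FASTA record id (uppercased)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def load_dataset(path, parents: Optional[Mapping[str, str]] = None) -> List[EpitopeRecord]:
    """Load a TSV of labeled peptides; reject rows with non-standard residues.

    The TSV must carry the columns record_id, parent_id, start, end, peptide,
    label.  Sequences are uppercased.  Rows whose peptide contains a residue
    outside the 20-letter alphabet (B, J, O, U, X, Z, ...) are dropped with a
    logged count; structural problems (missing column, bad label, end < start)
    raise instead.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DatasetError(f"{path}: missing required column(s) {missing}")
    records: List[EpitopeRecord] = []
    n_rejected = 0
    for row in table.itertuples(index=False):
        peptide = str(row.peptide).strip().upper()
        if set(peptide) - _STANDARD_SET:
            n_rejected += 1
            continue
        parent_id = str(row.parent_id).strip()
        parent_seq = parents.get(parent_id) if parents else None
        records.append(
            EpitopeRecord(
                record_id=str(row.record_id).strip(),
                parent_id=parent_id,
                start=int(row.start),
                end=int(row.end),
                peptide=peptide,
                label=_parse_label(row.label),
                parent_sequence=parent_seq,
                source=str(getattr(row, "source", "") or ""),
            )
        )
    if n_rejected:
        logger.info(
            "load_dataset(%s): rejected %d row(s) with non-standard residues",
            path, n_rejected,
        )
    return records


def write_dataset(records: Iterable[EpitopeRecord], path) -> None:
    """Write records as the TSV dialect `load_dataset` reads."""
    rows = [
        {
            "record_id": r.record_id,
            "parent_id": r.parent_id,
            "start": r.start,
            "end": r.end,
            "peptide": r.peptide,
            "label": f"{r.label:+d}",
            "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _grow_within_parent(start: int, end: int, parent_len: int, target_len: int):
    """Grow [start, end] to target_len, splitting evenly, clamped at termini.

    The left side receives floor(deficit/2); once one terminus is reached the
    remainder is taken from the other side.  Returns new (start, end).
    """
    deficit = target_len - (end - start + 1)
    left = deficit // 2
    right = deficit - left
    new_start = start - left
    new_end = end + right
    if new_start < 1:
        new_end += 1 - new_start
        new_start = 1
    if new_end > parent_len:
        new_start -= new_end - parent_len
        new_end = parent_len
    new_start = max(1, new_start)
    return new_start, new_end


def extend_to_length(record: EpitopeRecord, target_len: int = 100) -> EpitopeRecord:
    """Extend a peptide equally on both sides within its parent to target_len.

    Returns the record unchanged when it is already at least target_len long.
    The result has length min(target_len, len(parent)).
    """
    if target_len <= len(record):
        return record
    if record.parent_sequence is None:
        raise MissingParentError(
            f"{record.record_id}: extension requires the parent sequence"
        )
    new_start, new_end = _grow_within_parent(
        record.start, record.end, len(record.parent_sequence), target_len
    )
    return replace(
        record,
        start=new_start,
        end=new_end,
        peptide=record.parent_sequence[new_start - 1 : new_end],
    )


def resize_to_length(record: EpitopeRecord, length: int) -> EpitopeRecord:
    """Return a record of exactly `length`, centered on the original midpoint.

    Longer peptides are cropped symmetrically (the left side loses
    floor(excess/2)); shorter ones are extended within the parent with the same
    terminus rules as :func:`extend_to_length`.
    """
    current = len(record)
    if length == current:
        return record
    if length < current:
        left_crop = (current - length) // 2
        new_start = record.start + left_crop
        new_end = new_start + length - 1
        return replace(
            record,
            start=new_start,
            end=new_end,
            peptide=record.peptide[left_crop : left_crop + length],
        )
    return extend_to_length(record, target_len=length)


def deduplicate(records: Sequence[EpitopeRecord]) -> List[EpitopeRecord]:
    """Drop redundant peptides: keep the first record per distinct peptide string.

    A peptide string observed with *both* labels is removed entirely, since
    conflicting labels would poison training.  Removal counts are logged.
    """
    labels_seen: Dict[str, set] = {}
    for r in records:
        labels_seen.setdefault(r.peptide, set()).add(r.label)
    kept: List[EpitopeRecord] = []
    seen: set = set()
    n_dup = n_conflict = 0
    for r in records:
        if len(labels_seen[r.peptide]) > 1:
            n_conflict += 1
            continue
        if r.peptide in seen:
            n_dup += 1
            continue
        seen.add(r.peptide)
        kept.append(r)
    if n_dup or n_conflict:
        logger.info(
            "deduplicate: removed %d duplicate and %d label-conflicting record(s)",
            n_dup, n_conflict,
        )
    return kept


def make_folds(records: Sequence[EpitopeRecord], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified, seed-deterministic k-fold assignment of records.

    Per-class fold sizes differ by at most one.  Raises if only one class is
    present or k < 2.
    """
    if k < 2:
        raise DatasetError("fold count k must be >= 2")
    labels = np.array([r.label for r in records])
    if len(set(labels.tolist())) < 2:
        raise DatasetError("stratified folds require both classes present")
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise DatasetError("record ids must be unique for fold assignment")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: Dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        for i in test_idx:
            assignment[ids[i]] = fold
    return FoldAssignment(assignment=assignment, k=k, seed=seed)
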