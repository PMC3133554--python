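"""Per-residue evolutionary/structural annotations: parsers, writers, synthesis.

Epitope classifiers in this package consume five per-residue signals predicted
by external tools from the protein sequence alone:

* evolutionary conservation — the weighted observed percentage block of a
  PSI-BLAST ASCII position-specific scoring matrix (PSSM);
* 3-state secondary structure probabilities (helix/strand/coil), PSIPRED-style;
* relative solvent accessibility, discretized into 20 classes (0%, 5%, ..., 95%)
  and collapsed here to a scalar in [0, 1];
* per-residue disorder probability;
* a low-complexity mask (seg convention: masked residues lowercase in FASTA).

This module parses those text formats into a unified ``ResidueAnnotations``
object, provides matching writers (used for fixtures and by the simulator), and
a seeded synthetic backend so the pipeline can be exercised end to end without
running any external predictor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datasets import STANDARD_RESIDUES
from .errors import ConsistencyError, ParseError

#: Column order of residues in a PSI-BLAST PSSM (differs from alphabetical).
PSSM_COLUMN_RESIDUES = "ARNDCQEGHILKMFPSTWYV"

#: Secondary-structure states in storage order (helix, strand, coil).
SS_STATES = "HEC"

#: The 20 accessibility classes, as integer percentages.
ACCESSIBILITY_CLASSES = tuple(range(0, 100, 5))


@dataclass(eq=False)
class ResidueAnnotations:
    """All per-residue signals for one protein, length-aligned arrays.

    ``pssm_pct`` holds weighted observed percentages in [0, 100] with columns in
    PSI-BLAST order (:data:`PSSM_COLUMN_RESIDUES`).  ``ss_probs`` columns are
    (helix, strand, coil) and each row sums to 1; ``ss_state`` is the argmax
    with ties broken H > E > C.  ``sequence`` is optional convenience context
    (uppercase) used by writers and the scanner.
    """

    protein_id: str
    length: int
    pssm_pct: np.ndarray
    ss_probs: np.ndarray
    ss_state: np.ndarray
    accessibility: np.ndarray
    disorder: np.ndarray
    low_complexity: np.ndarray
    sequence: Optional[str] = None

    def validate(self) -> "ResidueAnnotations":
        n = self.length
        if self.pssm_pct.shape != (n, 20):
            raise ConsistencyError(f"{self.protein_id}: pssm_pct shape {self.pssm_pct.shape} != ({n}, 20)")
        if self.ss_probs.shape != (n, 3):
            raise ConsistencyError(f"{self.protein_id}: ss_probs shape {self.ss_probs.shape} != ({n}, 3)")
        for name in ("ss_state", "accessibility", "disorder", "low_complexity"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ConsistencyError(f"{self.protein_id}: {name} length {len(arr)} != {n}")
        if self.pssm_pct.size and (self.pssm_pct.min() < 0 or self.pssm_pct.max() > 100):
            raise ConsistencyError(f"{self.protein_id}: pssm_pct outside [0, 100]")
        for name in ("accessibility", "disorder"):
            arr = getattr(self, name)
            if len(arr) and (arr.min() < 0 or arr.max() > 1):
                raise ConsistencyError(f"{self.protein_id}: {name} outside [0, 1]")
        if n and np.abs(self.ss_probs.sum(axis=1) - 1.0).max() > 1e-6:
            raise ConsistencyError(f"{self.protein_id}: ss_probs rows do not sum to 1")
        if n:
            argmax_state = np.array([SS_STATES[i] for i in np.argmax(self.ss_probs, axis=1)])
            if not np.array_equal(np.asarray(self.ss_state), argmax_state):
                raise ConsistencyError(f"{self.protein_id}: ss_state disagrees with argmax of ss_probs")
        if self.sequence is not None and len(self.sequence) != n:
            raise ConsistencyError(f"{self.protein_id}: sequence length != {n}")
        return self

    def __len__(self) -> int:
        return self.length

    def slice(self, start: int, end: int, protein_id: Optional[str] = None) -> "ResidueAnnotations":
        """Sub-annotations for the 1-based inclusive span [start, end]."""
        if start < 1 or end > self.length or end < start:
            raise ConsistencyError(
                f"{self.protein_id}: slice [{start},{end}] outside 1..{self.length}"
            )
        sl = slice(start - 1, end)
        return ResidueAnnotations(
            protein_id=protein_id or f"{self.protein_id}[{start}:{end}]",
            length=end - start + 1,
            pssm_pct=self.pssm_pct[sl],
            ss_probs=self.ss_probs[sl],
            ss_state=np.asarray(self.ss_state)[sl],
            accessibility=self.accessibility[sl],
            disorder=self.disorder[sl],
            low_complexity=self.low_complexity[sl],
            sequence=self.sequence[sl] if self.sequence is not None else None,
        )

    def equals(self, other: "ResidueAnnotations") -> bool:
        return (
            self.protein_id == other.protein_id
            and self.length == other.length
            and np.array_equal(self.pssm_pct, other.pssm_pct)
            and np.array_equal(self.ss_probs, other.ss_probs)
            and np.array_equal(np.asarray(self.ss_state), np.asarray(other.ss_state))
            and np.array_equal(self.accessibility, other.accessibility)
            and np.array_equal(self.disorder, other.disorder)
            and np.array_equal(self.low_complexity, other.low_complexity)
            and self.sequence == other.sequence
        )


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def parse_pssm(text: str, expected_sequence: Optional[str] = None) -> Tuple[np.ndarray, str]:
    """Extract the weighted observed percentage block of an ASCII PSSM.

    Each residue row carries 40 score fields: 20 log-odds followed by 20
    percentages (plus optional trailing per-row statistics).  Only the second
    block — the percentages, i.e. score columns 21-40 — is returned, as an
    (L, 20) float array, together with the residue string for cross-checking.
    """
    rows = []
    residues = []
    expected_pos = 1
    for line in text.splitlines():
        tokens = line.split()
        if len(tokens) < 2:
            continue
        try:
            pos = int(tokens[0])
        except ValueError:
            continue  # header / column-label line
        if pos != expected_pos:
            raise ParseError(f"PSSM row index {pos}, expected {expected_pos}")
        expected_pos += 1
        residue = tokens[1]
        if len(residue) != 1 or not residue.isalpha():
            raise ParseError(f"PSSM row {pos}: bad residue field {residue!r}")
        try:
            numbers = [float(t) for t in tokens[2:]]
        except ValueError as exc:
            raise ParseError(f"PSSM row {pos}: non-numeric score field") from exc
        if len(numbers) not in (40, 41, 42):
            raise ParseError(
                f"PSSM row {pos}: expected 40 score fields, found {len(numbers)}"
            )
        rows.append(numbers[20:40])
        residues.append(residue.upper())
    pct = np.array(rows, dtype=float).reshape(len(rows), 20)
    seq = "".join(residues)
    if pct.size and (pct.min() < 0 or pct.max() > 100):
        raise ParseError("PSSM percentages outside [0, 100]")
    if expected_sequence is not None and seq != expected_sequence.upper():
        raise ConsistencyError("PSSM residue string disagrees with expected sequence")
    return pct, seq


def write_pssm(sequence: str, pssm_pct: np.ndarray, protein_id: str = "query") -> str:
    """Render an ASCII PSSM in the PSI-BLAST layout (log-odds written as 0)."""
    pssm_pct = np.asarray(pssm_pct)
    if pssm_pct.shape != (len(sequence), 20):
        raise ConsistencyError("pssm_pct must be (len(sequence), 20)")
    out = io.StringIO()
    out.write(
        f"\nLast position-specific scoring matrix computed ({protein_id}), "
        "weighted observed percentages rounded down, information per position, "
        "and relative weight of gapped matches\n"
    )
    header = "  ".join(PSSM_COLUMN_RESIDUES)
    out.write(f"           {header}   {header}\n")
    for i, aa in enumerate(sequence):
        logodds = " ".join(f"{0:3d}" for _ in range(20))
        pcts = " ".join(f"{int(round(v)):3d}" for v in pssm_pct[i])
        out.write(f"{i + 1:5d} {aa} {logodds}  {pcts}  0.00 0.00\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# 3-state secondary structure (.ss2 dialect)
# ---------------------------------------------------------------------------

#: File column order of the probability triple in the ss2 dialect.
SS2_FILE_ORDER = "CHE"


def parse_ss2(
    text: str, file_order: str = SS2_FILE_ORDER
) -> Tuple[np.ndarray, np.ndarray, str]:
    """Parse rows of (index, residue, state, three probabilities).

    The probability columns appear in ``file_order`` (coil, helix, strand by
    default — the PSIPRED convention) and are returned re-ordered to the
    storage order (helix, strand, coil).  Rows whose triple is off unity by
    more than 1e-6 are renormalized.  The state letter is preserved as printed.
    Returns (states, probs, residue string).
    """
    if sorted(file_order) != sorted(SS_STATES):
        raise ValueError(f"file_order must be a permutation of {SS_STATES!r}")
    perm = [file_order.index(s) for s in SS_STATES]
    states, rows, residues = [], [], []
    expected_pos = 1
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) != 6:
            raise ParseError(f"ss2 row needs 6 fields, found {len(tokens)}: {line!r}")
        pos = int(tokens[0])
        if pos != expected_pos:
            raise ParseError(f"ss2 row index {pos}, expected {expected_pos}")
        expected_pos += 1
        if tokens[2] not in SS_STATES:
            raise ParseError(f"ss2 state {tokens[2]!r} not one of H/E/C")
        triple = np.array([float(t) for t in tokens[3:6]])[perm]
        total = triple.sum()
        if total <= 0:
            raise ParseError(f"ss2 row {pos}: non-positive probability mass")
        if abs(total - 1.0) > 1e-6:
            triple = triple / total
        states.append(tokens[2])
        rows.append(triple)
        residues.append(tokens[1].upper())
    probs = np.array(rows, dtype=float).reshape(len(rows), 3)
    return np.array(states), probs, "".join(residues)


def write_ss2(
    sequence: str,
    ss_state: Sequence[str],
    ss_probs: np.ndarray,
    file_order: str = SS2_FILE_ORDER,
) -> str:
    perm = [SS_STATES.index(s) for s in file_order]
    out = io.StringIO()
    out.write("# 3-state secondary structure (VFORMAT dialect)\n\n")
    for i, aa in enumerate(sequence):
        p = np.asarray(ss_probs[i])[perm]
        out.write(
            f"{i + 1:4d} {aa} {ss_state[i]}   "
            + "  ".join(f"{v:.4f}" for v in p)
            + "\n"
        )
    return out.getvalue()


# ---------------------------------------------------------------------------
# 20-state solvent accessibility
# ---------------------------------------------------------------------------

def parse_accessibility(text: str) -> Tuple[np.ndarray, str]:
    """Parse per-residue accessibility into fractions in [0, 1].

    Integer values are 20-state class percentages and must be one of
    0, 5, ..., 95 (mapped to class/100); values containing a decimal point are
    taken as fractional accessibilities directly and must lie in [0, 1].
    Returns (values, residue string).
    """
    values, residues = [], []
    expected_pos = 1
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) != 3:
            raise ParseError(f"accessibility row needs 3 fields: {line!r}")
        pos = int(tokens[0])
        if pos != expected_pos:
            raise ParseError(f"accessibility row index {pos}, expected {expected_pos}")
        expected_pos += 1
        raw = tokens[2]
        if "." in raw:
            v = float(raw)
            if not 0.0 <= v <= 1.0:
                raise ParseError(f"fractional accessibility {raw} outside [0, 1]")
        else:
            cls = int(raw)
            if cls not in ACCESSIBILITY_CLASSES:
                raise ParseError(f"accessibility class {cls} not one of 0,5,...,95")
            v = cls / 100.0
        values.append(v)
        residues.append(tokens[1].upper())
    return np.array(values, dtype=float), "".join(residues)


def write_accessibility(sequence: str, accessibility: np.ndarray) -> str:
    out = io.StringIO()
    for i, aa in enumerate(sequence):
        cls = int(round(float(accessibility[i]) * 100))
        if cls not in ACCESSIBILITY_CLASSES:
            raise ConsistencyError(
                f"accessibility {accessibility[i]} is not on the 5% class grid"
            )
        out.write(f"{i + 1:4d} {aa} {cls:3d}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Disorder probabilities
# ---------------------------------------------------------------------------

def parse_disorder(text: str) -> Tuple[np.ndarray, str]:
    """Parse rows of (index, residue, disorder probability), clamped to [0, 1].

    Probabilities outside [-0.01, 1.01] raise; small numeric overshoot from the
    upstream predictor is clamped.
    """
    values, residues = [], []
    expected_pos = 1
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) != 3:
            raise ParseError(f"disorder row needs 3 fields: {line!r}")
        pos = int(tokens[0])
        if pos != expected_pos:
            raise ParseError(f"disorder row index {pos}, expected {expected_pos}")
        expected_pos += 1
        v = float(tokens[2])
        if v < -0.01 or v > 1.01:
            raise ParseError(f"disorder probability {v} outside [-0.01, 1.01]")
        values.append(min(1.0, max(0.0, v)))
        residues.append(tokens[1].upper())
    return np.array(values, dtype=float), "".join(residues)


def write_disorder(sequence: str, disorder: np.ndarray) -> str:
    out = io.StringIO()
    for i, aa in enumerate(sequence):
        out.write(f"{i + 1:4d} {aa} {float(disorder[i]):.4f}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Low-complexity mask (seg -x convention: masked residues lowercase)
# ---------------------------------------------------------------------------

def parse_lowcomplexity(
    text: str, expected_sequence: Optional[str] = None
) -> Tuple[np.ndarray, str]:
    """Parse a seg-masked FASTA: lowercase residues are low-complexity.

    Returns (boolean mask, uppercased sequence).
    """
    handle = io.StringIO(text)
    try:
        record = SeqIO.read(handle, "fasta")
    except ValueError as exc:
        raise ParseError(f"not a single-record FASTA: {exc}") from exc
    raw = str(record.seq)
    mask = np.array([c.islower() for c in raw], dtype=bool)
    seq = raw.upper()
    if expected_sequence is not None and seq != expected_sequence.upper():
        raise ConsistencyError("masked FASTA sequence disagrees with expected sequence")
    return mask, seq


def write_lowcomplexity(sequence: str, mask: np.ndarray, protein_id: str = "query") -> str:
    chars = [
        c.lower() if flag else c.upper() for c, flag in zip(sequence, mask)
    ]
    record = SeqRecord(Seq("".join(chars)), id=protein_id, description="")
    handle = io.StringIO()
    SeqIO.write([record], handle, "fasta")
    return handle.getvalue()


# ---------------------------------------------------------------------------
# Annotation directories (one protein, five files)
# ---------------------------------------------------------------------------

_SUFFIXES = {
    "pssm": ".pssm",
    "ss2": ".ss2",
    "acc": ".acc",
    "disorder": ".dis",
    "lowcomplexity": ".lc.fasta",
}


def write_annotation_dir(ann: ResidueAnnotations, directory) -> None:
    """Write the five annotation files for one protein into a directory."""
    if ann.sequence is None:
        raise ConsistencyError("writing annotations requires the sequence attached")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pid = ann.protein_id
    (directory / f"{pid}{_SUFFIXES['pssm']}").write_text(
        write_pssm(ann.sequence, ann.pssm_pct, pid)
    )
    (directory / f"{pid}{_SUFFIXES['ss2']}").write_text(
        write_ss2(ann.sequence, ann.ss_state, ann.ss_probs)
    )
    (directory / f"{pid}{_SUFFIXES['acc']}").write_text(
        write_accessibility(ann.sequence, ann.accessibility)
    )
    (directory / f"{pid}{_SUFFIXES['disorder']}").write_text(
        write_disorder(ann.sequence, ann.disorder)
    )
    (directory / f"{pid}{_SUFFIXES['lowcomplexity']}").write_text(
        write_lowcomplexity(ann.sequence, ann.low_complexity, pid)
    )


def read_annotation_dir(directory, protein_id: str) -> ResidueAnnotations:
    """Read one protein's five annotation files back into ResidueAnnotations."""
    directory = Path(directory)
    mask, seq = parse_lowcomplexity(
        (directory / f"{protein_id}{_SUFFIXES['lowcomplexity']}").read_text()
    )
    pssm, pssm_seq = parse_pssm(
        (directory / f"{protein_id}{_SUFFIXES['pssm']}").read_text(),
        expected_sequence=seq,
    )
    states, probs, _ = parse_ss2((directory / f"{protein_id}{_SUFFIXES['ss2']}").read_text())
    acc, _ = parse_accessibility((directory / f"{protein_id}{_SUFFIXES['acc']}").read_text())
    dis, _ = parse_disorder((directory / f"{protein_id}{_SUFFIXES['disorder']}").read_text())
    return ResidueAnnotations(
        protein_id=protein_id,
        length=len(seq),
        pssm_pct=pssm,
        ss_probs=probs,
        ss_state=states,
        accessibility=acc,
        disorder=dis,
        low_complexity=mask,
        sequence=seq,
    ).validate()


# ---------------------------------------------------------------------------
# Synthetic backend
# ---------------------------------------------------------------------------

def synthesize_annotations(
    sequence: str,
    label_bias: Union[float, np.ndarray] = 0.0,
    seed: int = 0,
    protein_id: str = "synthetic",
) -> ResidueAnnotations:
    """Seed-deterministic synthetic annotations with a tunable class bias.

    ``label_bias`` (scalar or per-residue array in [0, 1]) shifts the
    annotation distributions the way experimentally antigenic peptides tend to
    differ from background: higher coil probability, higher solvent
    accessibility, higher disorder.  Bias 0 is the class-neutral baseline.
    PSSM rows concentrate on the true residue with seeded Dirichlet noise.

    All values land on the exact grids the file writers print (integer
    percentages, the 5% accessibility classes, 1e-4 probability grids), so a
    write/parse round trip reproduces the object bit for bit.
    """
    L = len(sequence)
    rng = np.random.default_rng(seed)
    bias = np.broadcast_to(np.asarray(label_bias, dtype=float), (L,)).copy()
    if L and (bias.min() < 0 or bias.max() > 1):
        raise ValueError("label_bias must lie in [0, 1]")

    # PSSM: Dirichlet concentrated on the true residue, scaled to percentages.
    col_index = {a: i for i, a in enumerate(PSSM_COLUMN_RESIDUES)}
    onehot = np.zeros((L, 20))
    for i, aa in enumerate(sequence):
        onehot[i, col_index[aa]] = 1.0
    gamma = rng.gamma(1.0 + 30.0 * onehot)
    pssm_pct = np.rint(gamma / gamma.sum(axis=1, keepdims=True) * 100.0)

    # Secondary structure: coil concentration grows with bias.
    alpha = np.column_stack(
        [np.full(L, 2.0), np.full(L, 2.0), 2.0 + 8.0 * bias]
    )
    g = rng.gamma(alpha)
    probs = g / g.sum(axis=1, keepdims=True)
    quantized = np.floor(probs * 10000).astype(np.int64)
    if L:
        quantized[np.arange(L), np.argmax(probs, axis=1)] += 10000 - quantized.sum(axis=1)
    ss_probs = quantized / 10000.0
    ss_state = np.array([SS_STATES[i] for i in np.argmax(ss_probs, axis=1)])

    # Accessibility: Beta with mean 0.5 -> 0.85 as bias grows, on the 5% grid.
    mean_acc = 0.5 + 0.35 * bias
    acc_raw = rng.beta(mean_acc * 10.0, (1.0 - mean_acc) * 10.0)
    accessibility = np.clip(np.floor(acc_raw * 20.0) / 20.0, 0.0, 0.95)

    # Disorder: Beta with mean 0.3 -> 0.8, on the 1e-4 grid.
    mean_dis = 0.3 + 0.5 * bias
    disorder = np.round(np.clip(rng.beta(mean_dis * 8.0, (1.0 - mean_dis) * 8.0), 0.0, 1.0), 4)

    low_complexity = rng.random(L) < (0.05 + 0.15 * bias)

    return ResidueAnnotations(
        protein_id=protein_id,
        length=L,
        pssm_pct=pssm_pct,
        ss_probs=ss_probs,
        ss_state=ss_state,
        accessibility=accessibility,
        disorder=disorder,
        low_complexity=low_complexity,
        sequence=sequence,
    ).validate()
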