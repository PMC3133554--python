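"""Peptide feature encodings: compositional n-grams plus annotation summaries.

A peptide of length L is encoded by six concatenated blocks:

* ``ngram`` — cumulative multiset n-grams: every contiguous window of length
  k (k = 1..5) is canonicalized by sorting its residues, and the multiset
  counts are normalized by the number of windows (L - k + 1).  The index space
  is all residue multisets of size <= 5, giving the cumulative dimension
  ladder 20, 230, 1770, 10625, 53129 (combinations with repetition).  The
  encoding is compositional, not positional.
* ``pssm`` — a 20x20 grid: for each residue identity, the mean of each of the
  20 PSSM weighted-observed-percentage columns (rescaled to [0, 1]) over the
  positions carrying that identity; 400 features.
* ``ss`` — per residue identity the mean (helix, strand, coil) probabilities
  (60 features) plus the peptide's composition in the 3 assigned states
  (3 features); 63 total.
* ``acc`` / ``disorder`` — per residue identity the mean accessibility /
  disorder probability; 20 features each.
* ``seg`` — the fraction of peptide residues flagged low-complexity; 1 feature.

With every block enabled the combined space has 53,633 dimensions.  Vectors
are sparse; features are min-max scaled to [0, 1] on the training set.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations_with_replacement
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp

from .annotations import PSSM_COLUMN_RESIDUES, SS_STATES, ResidueAnnotations
from .datasets import STANDARD_RESIDUES
from .errors import AlphabetError

ALPHABET = STANDARD_RESIDUES
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: Fixed concatenation order of the feature blocks.
BLOCK_ORDER = ("ngram", "pssm", "ss", "acc", "disorder", "seg")

#: The feature combination with the best reported classification performance:
#: composition + evolutionary conservation + secondary structure + accessibility.
BEST_FEATURE_BLOCKS = ("ngram", "pssm", "ss", "acc")

_ANNOTATION_BLOCKS = frozenset({"pssm", "ss", "acc", "disorder", "seg"})


@lru_cache(maxsize=8)
def multiset_vocabulary(k: int) -> Tuple[str, ...]:
    """All sorted residue multisets of size k, in lexicographic order."""
    return tuple("".join(c) for c in combinations_with_replacement(ALPHABET, k))


@lru_cache(maxsize=8)
def _multiset_index(k: int) -> Dict[str, int]:
    return {m: i for i, m in enumerate(multiset_vocabulary(k))}


def ngram_dimension(ngram_max: int) -> int:
    """Cumulative multiset n-gram dimension: sum over k of C(19 + k, k)."""
    return sum(math.comb(19 + k, k) for k in range(1, ngram_max + 1))


_FIXED_BLOCK_DIMS = {"pssm": 400, "ss": 63, "acc": 20, "disorder": 20, "seg": 1}


def block_dimension(block: str, ngram_max: int = 5) -> int:
    if block == "ngram":
        return ngram_dimension(ngram_max)
    try:
        return _FIXED_BLOCK_DIMS[block]
    except KeyError:
        raise ValueError(f"unknown feature block {block!r}") from None


@dataclass(frozen=True)
class FeatureConfig:
    """Which blocks are enabled and how deep the n-gram ladder goes."""

    ngram_max: int = 5
    blocks: Tuple[str, ...] = BLOCK_ORDER

    def __post_init__(self) -> None:
        if not 0 <= self.ngram_max <= 5:
            raise ValueError("ngram_max must be in 0..5")
        unknown = set(self.blocks) - set(BLOCK_ORDER)
        if unknown:
            raise ValueError(f"unknown feature block(s) {sorted(unknown)}")
        # Canonical order and uniqueness regardless of how blocks were given.
        object.__setattr__(
            self, "blocks", tuple(b for b in BLOCK_ORDER if b in set(self.blocks))
        )

    @property
    def block_offsets(self) -> Dict[str, Tuple[int, int]]:
        offsets: Dict[str, Tuple[int, int]] = {}
        pos = 0
        for b in self.blocks:
            dim = block_dimension(b, self.ngram_max)
            offsets[b] = (pos, dim)
            pos += dim
        return offsets

    @property
    def dimension(self) -> int:
        return sum(block_dimension(b, self.ngram_max) for b in self.blocks)

    @property
    def needs_annotations(self) -> bool:
        return bool(set(self.blocks) & _ANNOTATION_BLOCKS)


@dataclass
class FeatureVector:
    """Sparse feature vector with the global block layout recorded."""

    dimension: int
    entries: Dict[int, float]
    block_offsets: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.dimension)
        if self.entries:
            idx = np.fromiter(self.entries.keys(), dtype=int, count=len(self.entries))
            val = np.fromiter(self.entries.values(), dtype=float, count=len(self.entries))
            dense[idx] = val
        return dense


def _check_alphabet(peptide: str) -> None:
    bad = set(peptide) - set(ALPHABET)
    if bad:
        raise AlphabetError(f"non-standard residue(s) {sorted(bad)} in peptide")


def ngram_block(peptide: str, ngram_max: int = 5) -> Dict[int, float]:
    """Sparse cumulative multiset n-gram encoding (block-local indices).

    For each order k, each contiguous window of length k maps to its sorted
    residue string; counts are divided by the window count L - k + 1.  Orders
    with L < k contribute nothing.
    """
    _check_alphabet(peptide)
    if not peptide:
        raise ValueError("peptide must be non-empty")
    L = len(peptide)
    entries: Dict[int, float] = {}
    base = 0
    for k in range(1, ngram_max + 1):
        index = _multiset_index(k)
        n_windows = L - k + 1
        if n_windows > 0:
            counts = Counter(
                "".join(sorted(peptide[i : i + k])) for i in range(n_windows)
            )
            for key, c in counts.items():
                entries[base + index[key]] = c / n_windows
        base += len(index)
    return entries


def _peptide_span(peptide: str, annotations: ResidueAnnotations, offset: int) -> np.ndarray:
    """Validate the span and return per-position alphabet indices."""
    _check_alphabet(peptide)
    L = len(peptide)
    if offset < 0 or offset + L > annotations.length:
        raise ValueError(
            f"peptide span [{offset}, {offset + L}) outside annotations of "
            f"length {annotations.length}"
        )
    return np.fromiter((AA_INDEX[c] for c in peptide), dtype=int, count=L)


def _identity_means(
    aa_idx: np.ndarray, values: np.ndarray, width: int
) -> Dict[int, float]:
    """Mean of each value column per residue identity; absent identities -> 0.

    ``values`` is (L, width); returned indices are a * width + column.
    """
    entries: Dict[int, float] = {}
    for a in np.unique(aa_idx):
        means = values[aa_idx == a].mean(axis=0)
        for c in range(width):
            v = float(means[c]) if width > 1 else float(means[0])
            if v != 0.0:
                entries[int(a) * width + c] = v
    return entries


def pssm_block(peptide: str, annotations: ResidueAnnotations, offset: int) -> Dict[int, float]:
    """20x20 identity-by-conservation-column grid of mean percentages / 100."""
    aa_idx = _peptide_span(peptide, annotations, offset)
    values = annotations.pssm_pct[offset : offset + len(peptide)] / 100.0
    return _identity_means(aa_idx, values, 20)


def ss_block(peptide: str, annotations: ResidueAnnotations, offset: int) -> Dict[int, float]:
    """Identity-averaged 3-state probabilities plus 3-state composition.

    Indices 0..59: identity a x (helix, strand, coil) means; indices 60..62:
    fractions of peptide residues assigned H, E, C (summing to 1).
    """
    aa_idx = _peptide_span(peptide, annotations, offset)
    L = len(peptide)
    values = annotations.ss_probs[offset : offset + L]
    entries = _identity_means(aa_idx, values, 3)
    states = np.asarray(annotations.ss_state)[offset : offset + L]
    for j, s in enumerate(SS_STATES):
        frac = float(np.count_nonzero(states == s)) / L
        if frac != 0.0:
            entries[60 + j] = frac
    return entries


def acc_block(peptide: str, annotations: ResidueAnnotations, offset: int) -> Dict[int, float]:
    """Per residue identity, the mean solvent accessibility."""
    aa_idx = _peptide_span(peptide, annotations, offset)
    values = annotations.accessibility[offset : offset + len(peptide)].reshape(-1, 1)
    return _identity_means(aa_idx, values, 1)


def disorder_block(peptide: str, annotations: ResidueAnnotations, offset: int) -> Dict[int, float]:
    """Per residue identity, the mean disorder probability."""
    aa_idx = _peptide_span(peptide, annotations, offset)
    values = annotations.disorder[offset : offset + len(peptide)].reshape(-1, 1)
    return _identity_means(aa_idx, values, 1)


def seg_block(peptide: str, annotations: ResidueAnnotations, offset: int) -> Dict[int, float]:
    """One feature: the fraction of peptide residues flagged low-complexity."""
    _peptide_span(peptide, annotations, offset)
    frac = float(
        np.asarray(annotations.low_complexity[offset : offset + len(peptide)], dtype=float).mean()
    )
    return {0: frac} if frac != 0.0 else {}


_BLOCK_FUNCS = {
    "pssm": pssm_block,
    "ss": ss_block,
    "acc": acc_block,
    "disorder": disorder_block,
    "seg": seg_block,
}


def assemble(
    peptide: str,
    annotations: Optional[ResidueAnnotations],
    offset: int,
    config: FeatureConfig,
) -> FeatureVector:
    """Concatenate the enabled blocks into one sparse FeatureVector.

    ``offset`` is the 0-based start of the peptide within the annotated
    protein.  Blocks are computed on the peptide span itself (the original,
    non-extended epitope), never on any surrounding context.
    """
    if config.needs_annotations and annotations is None:
        raise ValueError("enabled feature blocks require annotations")
    offsets = config.block_offsets
    entries: Dict[int, float] = {}
    for b in config.blocks:
        start, _ = offsets[b]
        if b == "ngram":
            local = ngram_block(peptide, config.ngram_max)
        else:
            local = _BLOCK_FUNCS[b](peptide, annotations, offset)
        for i, v in local.items():
            entries[start + i] = v
    return FeatureVector(dimension=config.dimension, entries=entries, block_offsets=offsets)


def stack_vectors(vectors: Sequence[FeatureVector]) -> sp.csr_matrix:
    """Stack FeatureVectors (equal dimension) into one CSR matrix."""
    if not vectors:
        raise ValueError("need at least one vector")
    dim = vectors[0].dimension
    if any(v.dimension != dim for v in vectors):
        raise ValueError("vectors have inconsistent dimensions")
    return entries_to_csr([v.entries for v in vectors], dim)


def entries_to_csr(rows: Sequence[Mapping[int, float]], dimension: int) -> sp.csr_matrix:
    data: List[float] = []
    indices: List[int] = []
    indptr = [0]
    for row in rows:
        for j in sorted(row):
            indices.append(j)
            data.append(row[j])
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.array(data), np.array(indices, dtype=np.int32), np.array(indptr, dtype=np.int32)),
        shape=(len(rows), dimension),
    )


class FeatureScaler:
    """Per-feature linear map x -> (x - min) / (max - min) fitted on training data.

    The fitting set maps into [0, 1]; unseen values may fall outside and are
    deliberately not clipped.  Constant features map to 0.  Sparse input stays
    sparse (columns whose training minimum is nonzero receive an explicit
    offset correction).
    """

    def __init__(self) -> None:
        self.data_min: Optional[np.ndarray] = None
        self.data_max: Optional[np.ndarray] = None

    @property
    def n_features(self) -> int:
        if self.data_min is None:
            raise ValueError("scaler is not fitted")
        return len(self.data_min)

    def fit(self, X: Union[np.ndarray, sp.spmatrix]) -> "FeatureScaler":
        if X.shape[0] < 1:
            raise ValueError("scaler must be fitted on at least one vector")
        if sp.issparse(X):
            Xc = X.tocsc()
            self.data_min = np.asarray(Xc.min(axis=0).todense()).ravel().astype(float)
            self.data_max = np.asarray(Xc.max(axis=0).todense()).ravel().astype(float)
        else:
            X = np.asarray(X, dtype=float)
            self.data_min = X.min(axis=0)
            self.data_max = X.max(axis=0)
        return self

    def _scale_vectors(self) -> Tuple[np.ndarray, np.ndarray]:
        rng = self.data_max - self.data_min
        nonconstant = rng > 0
        scale = np.zeros_like(rng)
        scale[nonconstant] = 1.0 / rng[nonconstant]
        return scale, nonconstant

    def transform(self, X: Union[np.ndarray, sp.spmatrix]):
        if self.data_min is None:
            raise ValueError("scaler is not fitted")
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"dimension mismatch: {X.shape[1]} columns, scaler fitted on {self.n_features}"
            )
        scale, nonconstant = self._scale_vectors()
        if sp.issparse(X):
            out = X.tocsr().multiply(scale).tocsr()
            offset_cols = np.where((self.data_min != 0) & nonconstant)[0]
            if offset_cols.size:
                shift = -(self.data_min[offset_cols] * scale[offset_cols])
                shift_row = sp.csr_matrix(
                    (shift, (np.zeros(offset_cols.size, dtype=int), offset_cols)),
                    shape=(1, X.shape[1]),
                )
                ones = sp.csr_matrix(np.ones((X.shape[0], 1)))
                out = (out + ones @ shift_row).tocsr()
            return out
        return (np.asarray(X, dtype=float) - self.data_min) * scale


def fit_scaler(vectors: Union[Sequence[FeatureVector], np.ndarray, sp.spmatrix]) -> FeatureScaler:
    if isinstance(vectors, (list, tuple)):
        vectors = stack_vectors(vectors)
    return FeatureScaler().fit(vectors)


def apply_scaler(scaler: FeatureScaler, vector: FeatureVector) -> FeatureVector:
    """Scale one FeatureVector, preserving its block layout."""
    row = scaler.transform(entries_to_csr([vector.entries], vector.dimension))
    dense = np.asarray(row.todense()).ravel()
    entries = {int(j): float(dense[j]) for j in np.nonzero(dense)[0]}
    return FeatureVector(
        dimension=vector.dimension, entries=entries, block_offsets=dict(vector.block_offsets)
    )


# ---------------------------------------------------------------------------
# Sparse "label idx:value" feature files (SVMlight/libsvm dialect)
# ---------------------------------------------------------------------------

def write_svmlight_file(X: sp.spmatrix, y: Sequence[int], path) -> None:
    """Write features as `label idx:value` lines, 1-based indices, 6 decimals."""
    X = X.tocsr()
    if X.shape[0] != len(y):
        raise ValueError("X and y disagree on the number of examples")
    with open(path, "w") as out:
        for i in range(X.shape[0]):
            row = X.getrow(i).tocoo()
            order = np.argsort(row.col)
            fields = " ".join(
                f"{int(row.col[j]) + 1}:{row.data[j]:.6f}" for j in order if row.data[j] != 0
            )
            out.write(f"{int(y[i]):+d} {fields}".rstrip() + "\n")


def read_svmlight_file(path, dimension: int) -> Tuple[sp.csr_matrix, np.ndarray]:
    """Read the dialect written by :func:`write_svmlight_file`."""
    rows: List[Dict[int, float]] = []
    labels: List[int] = []
    with open(path) as handle:
        for line in handle:
            tokens = line.split()
            if not tokens:
                continue
            labels.append(int(tokens[0]))
            row: Dict[int, float] = {}
            for tok in tokens[1:]:
                idx, val = tok.split(":")
                row[int(idx) - 1] = float(val)
            rows.append(row)
    return entries_to_csr(rows, dimension), np.array(labels, dtype=int)
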