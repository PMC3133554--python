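"""Sliding-window scanning of whole proteins with a trained peptide model.

Every full-length window of a protein (default: 15 residues, step 1) is
featurized exactly like a training peptide — annotations sliced from the
whole-protein annotations — and scored by the SVM decision function.  Windows
with positive scores are candidate linear epitopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .annotations import ResidueAnnotations
from .classify import TrainedModel, predict, verdicts
from .errors import ConsistencyError
from .features import FeatureConfig, assemble, stack_vectors


@dataclass(frozen=True)
class ScanConfig:
    """Window length (>= 7) and step (>= 1) of a scan."""

    window_length: int = 15
    step: int = 1

    def __post_init__(self) -> None:
        if self.window_length < 7:
            raise ValueError("window_length must be >= 7")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass
class ScanResult:
    """Ordered window starts (1-based), decision scores and verdicts."""

    protein_id: str
    config: ScanConfig
    window_starts: np.ndarray
    scores: np.ndarray
    verdicts: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    def windows(self, sequence: str):
        """Yield (start, end, peptide, score, verdict) rows, 1-based inclusive."""
        w = self.config.window_length
        for st, sc, vd in zip(self.window_starts, self.scores, self.verdicts):
            yield int(st), int(st) + w - 1, sequence[st - 1 : st - 1 + w], float(sc), vd


def n_windows(length: int, config: ScanConfig) -> int:
    """floor((L - w) / s) + 1 full windows for a protein of length L >= w."""
    if length < config.window_length:
        return 0
    return (length - config.window_length) // config.step + 1


def scan_protein(
    sequence: str,
    annotations: Optional[ResidueAnnotations],
    model: TrainedModel,
    config: ScanConfig = ScanConfig(),
) -> ScanResult:
    """Score every full window of a protein; no partial windows at the terminus."""
    L = len(sequence)
    w = config.window_length
    if L < w:
        raise ValueError(f"sequence length {L} shorter than window {w}")
    if annotations is not None and annotations.length != L:
        raise ConsistencyError(
            f"annotations length {annotations.length} != sequence length {L}"
        )
    feature_config: FeatureConfig = model.feature_config
    if feature_config is None:
        raise ValueError("model does not record a feature configuration")
    if feature_config.needs_annotations and annotations is None:
        raise ConsistencyError("model features require annotations for the protein")
    starts = np.arange(1, L - w + 2, config.step, dtype=int)
    vectors = [
        assemble(sequence[st - 1 : st - 1 + w], annotations, st - 1, feature_config)
        for st in starts
    ]
    scores = predict(model, stack_vectors(vectors))
    protein_id = annotations.protein_id if annotations is not None else "query"
    return ScanResult(
        protein_id=protein_id,
        config=config,
        window_starts=starts,
        scores=scores,
        verdicts=verdicts(scores),
    )


def score_peptide(
    peptide: str,
    annotations: Optional[ResidueAnnotations],
    model: TrainedModel,
) -> Tuple[float, str]:
    """Score one peptide of length >= the model window.

    A peptide exactly one window long gets that window's score; a longer one is
    summarized by the maximum window score (a peptide is a good epitope if some
    window within it is).
    """
    w = model.peptide_length or (len(peptide))
    config = ScanConfig(window_length=w, step=1)
    result = scan_protein(peptide, annotations, model, config)
    best = int(np.argmax(result.scores))
    return float(result.scores[best]), str(result.verdicts[best])


def call_epitopes(
    scan: ScanResult, min_score: float = 0.0
) -> List[Tuple[int, int, float]]:
    """Candidate windows with score > min_score, best first, ties by position.

    Returns (start, end, score) tuples with 1-based inclusive coordinates.
    """
    w = scan.config.window_length
    candidates = [
        (int(st), int(st) + w - 1, float(sc))
        for st, sc in zip(scan.window_starts, scan.scores)
        if sc > min_score
    ]
    return sorted(candidates, key=lambda t: (-t[2], t[0]))


def top_windows(
    scan: ScanResult, n: int = 5, suppress_overlaps: bool = True
) -> List[Tuple[int, int, float]]:
    """The n highest-scoring windows regardless of sign, ties by position.

    With ``suppress_overlaps`` (the default) the windows are picked greedily
    with non-maximum suppression — each selected window removes every window
    overlapping it from further consideration — so the report names n distinct
    candidate sites instead of n near-identical shifts of the single best one.
    """
    w = scan.config.window_length
    rows = sorted(
        (
            (int(st), int(st) + w - 1, float(sc))
            for st, sc in zip(scan.window_starts, scan.scores)
        ),
        key=lambda t: (-t[2], t[0]),
    )
    if not suppress_overlaps:
        return rows[:n]
    selected: List[Tuple[int, int, float]] = []
    for start, end, score in rows:
        if len(selected) == n:
            break
        if all(end < s or start > e for s, e, _ in selected):
            selected.append((start, end, score))
    return selected


def write_scan_tsv(scan: ScanResult, sequence: str, path) -> None:
    with open(path, "w") as out:
        out.write("protein_id\tstart\tend\tpeptide\tscore\tverdict\n")
        for start, end, pep, score, verdict in scan.windows(sequence):
            out.write(f"{scan.protein_id}\t{start}\t{end}\t{pep}\t{score:.6f}\t{verdict}\n")
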