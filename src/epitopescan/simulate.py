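"""Seeded synthetic data with planted, controllable antigenicity signal.

Real epitope corpora and predictor outputs cannot ship with the package, so
every pipeline stage is exercised on generated data whose ground truth is
known by construction:

* labeled peptides whose positive class is compositionally shifted toward a
  set of enriched residues (defaults approximate classical hydrophilicity /
  turn-propensity residues) and whose synthetic annotations carry the matching
  coil/exposed/disordered enrichment;
* background proteins with positive-class 15-mers spliced in at known,
  non-overlapping coordinates (for scan recovery experiments);
* fixed-length regions that do or do not contain planted epitopes (for the
  region-classifier recovery experiments).

``effect_size`` interpolates between a null (0: class-conditional
distributions identical) and a strong, well-separated signal (1).  All
randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Tuple

import numpy as np

from .annotations import ResidueAnnotations, synthesize_annotations
from .datasets import EpitopeRecord, deduplicate
from .features import ALPHABET
from .regions import RegionExample

#: Residues enriched in the synthetic positive class: polar/charged/turn-prone.
DEFAULT_ENRICHED_RESIDUES = "DEKNQSGP"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults define the package's study conditions."""

    n_pos: int = 400
    n_neg: int = 400
    peptide_length: int = 15
    effect_size: float = 0.8
    seed: int = 0
    enriched_residues: str = DEFAULT_ENRICHED_RESIDUES
    protein_length: int = 200
    epitopes_per_protein: int = 2
    n_proteins: int = 60
    region_length: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        bad = set(self.enriched_residues) - set(ALPHABET)
        if bad:
            raise ValueError(f"enriched_residues outside the alphabet: {sorted(bad)}")


def residue_frequencies(effect_size: float, enriched_residues: str) -> np.ndarray:
    """Residue sampling distribution, shifted toward the enriched set.

    Enriched residues get weight 1 + 4*effect_size; at effect_size 0 the
    distribution is uniform, identical to the background class.
    """
    enriched = set(enriched_residues)
    weights = np.array(
        [1.0 + 4.0 * effect_size if a in enriched else 1.0 for a in ALPHABET]
    )
    return weights / weights.sum()


_AA_ARRAY = np.array(list(ALPHABET))


def _draw_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    return "".join(rng.choice(_AA_ARRAY, size=length, p=probs))


def _annotation_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def generate_labeled_peptides(
    config: SyntheticConfig = SyntheticConfig(),
) -> Tuple[List[EpitopeRecord], Dict[str, ResidueAnnotations]]:
    """Labeled peptides with matched annotations; deduplicated, seed-deterministic.

    Positives are drawn from the enriched residue distribution and annotated at
    label bias = effect_size; negatives come from the neutral background at
    bias 0.  Each peptide is its own parent protein (start = 1).
    """
    rng = np.random.default_rng(config.seed)
    probs_pos = residue_frequencies(config.effect_size, config.enriched_residues)
    probs_neg = residue_frequencies(0.0, config.enriched_residues)
    records: List[EpitopeRecord] = []
    anns: Dict[str, ResidueAnnotations] = {}
    for i in range(config.n_pos + config.n_neg):
        positive = i < config.n_pos
        seq = _draw_sequence(
            rng, config.peptide_length, probs_pos if positive else probs_neg
        )
        rid = f"pep{i:05d}"
        anns[rid] = synthesize_annotations(
            seq,
            label_bias=config.effect_size if positive else 0.0,
            seed=_annotation_seed(rng),
            protein_id=rid,
        )
        records.append(
            EpitopeRecord(
                record_id=rid,
                parent_id=rid,
                start=1,
                end=config.peptide_length,
                peptide=seq,
                label=1 if positive else -1,
                parent_sequence=seq,
                source="synthetic",
            )
        )
    records = deduplicate(records)
    kept = {r.record_id for r in records}
    return records, {k: v for k, v in anns.items() if k in kept}


def _plant_epitopes(
    rng: np.random.Generator,
    length: int,
    n_epitopes: int,
    config: SyntheticConfig,
) -> Tuple[str, np.ndarray, List[Tuple[int, int]]]:
    """Background sequence with non-overlapping positive 15-mers spliced in.

    Returns (sequence, per-residue bias array, list of (start, end) 1-based
    inclusive planted intervals).
    """
    w = config.peptide_length
    if length < w * (n_epitopes + 1):
        raise ValueError(
            f"cannot pack {n_epitopes} epitope(s) of length {w} into {length} residues"
        )
    probs_neg = residue_frequencies(0.0, config.enriched_residues)
    probs_pos = residue_frequencies(config.effect_size, config.enriched_residues)
    chars = list(_draw_sequence(rng, length, probs_neg))
    bias = np.zeros(length)
    intervals: List[Tuple[int, int]] = []
    if n_epitopes:
        # Sorted draws in the "gap" coordinate system guarantee non-overlap.
        slack = length - n_epitopes * w
        anchors = np.sort(rng.integers(0, slack + 1, size=n_epitopes))
        for j, anchor in enumerate(anchors):
            start = int(anchor + j * w) + 1  # 1-based
            epitope = _draw_sequence(rng, w, probs_pos)
            chars[start - 1 : start - 1 + w] = list(epitope)
            bias[start - 1 : start - 1 + w] = config.effect_size
            intervals.append((start, start + w - 1))
    return "".join(chars), bias, intervals


def generate_proteins_with_planted_epitopes(
    config: SyntheticConfig = SyntheticConfig(),
) -> Tuple[Dict[str, str], Dict[str, ResidueAnnotations], List[Tuple[str, int, int]]]:
    """Background proteins with planted positive epitopes at known coordinates.

    Returns (sequences, annotations, truth table of (protein_id, start, end)).
    """
    rng = np.random.default_rng(config.seed)
    sequences: Dict[str, str] = {}
    anns: Dict[str, ResidueAnnotations] = {}
    truth: List[Tuple[str, int, int]] = []
    for i in range(config.n_proteins):
        pid = f"prot{i:04d}"
        seq, bias, intervals = _plant_epitopes(
            rng, config.protein_length, config.epitopes_per_protein, config
        )
        sequences[pid] = seq
        anns[pid] = synthesize_annotations(
            seq, label_bias=bias, seed=_annotation_seed(rng), protein_id=pid
        )
        truth.extend((pid, s, e) for s, e in intervals)
    return sequences, anns, truth


def generate_region_dataset(
    config: SyntheticConfig = SyntheticConfig(),
) -> Tuple[List[RegionExample], Dict[str, ResidueAnnotations]]:
    """Fixed-length regions: positives contain planted epitopes, negatives none.

    n_pos positive and n_neg negative regions of ``region_length`` residues;
    positives carry ``epitopes_per_protein`` planted epitopes each.
    """
    rng = np.random.default_rng(config.seed)
    regions: List[RegionExample] = []
    anns: Dict[str, ResidueAnnotations] = {}
    for i in range(config.n_pos + config.n_neg):
        positive = i < config.n_pos
        rid = f"region{i:05d}"
        n_epi = config.epitopes_per_protein if positive else 0
        seq, bias, _ = _plant_epitopes(rng, config.region_length, n_epi, config)
        anns[rid] = synthesize_annotations(
            seq, label_bias=bias, seed=_annotation_seed(rng), protein_id=rid
        )
        regions.append(RegionExample(region_id=rid, sequence=seq, label=1 if positive else -1))
    return regions, anns
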