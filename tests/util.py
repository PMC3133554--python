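"""Shared helpers: independent brute-force oracles and small generators."""

from typing import Dict, Tuple

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def oracle_ngram(peptide: str, ngram_max: int) -> Dict[Tuple[int, str], float]:
    """Dictionary-counting n-gram oracle, keyed by (order, sorted window)."""
    out: Dict[Tuple[int, str], float] = {}
    for k in range(1, ngram_max + 1):
        windows = [
            "".join(sorted(peptide[i : i + k])) for i in range(len(peptide) - k + 1)
        ]
        for key in set(windows):
            out[(k, key)] = windows.count(key) / len(windows)
    return out


def oracle_ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force ECDF sweep: sup |ECDF_a - ECDF_b| over all sample points."""
    grid = np.concatenate([a, b])
    ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
    ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
    return float(np.max(np.abs(ecdf_a - ecdf_b)))


def intervals_overlap(s1: int, e1: int, s2: int, e2: int) -> bool:
    return not (e1 < s2 or s1 > e2)
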