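"""Region-level specificity prediction from window scan-score summaries.

Arbitrary-length protein regions are scanned with a trained peptide model
(window 15, step 1); the resulting score list is collapsed to a fixed-length
summary — evenly spaced empirical quantiles plus a few order statistics — and a
second SVM (RBF kernel by default) is trained on those summaries to predict
whether immunizing with the whole region yields a specific immune response.
Because the summary has fixed dimension, regions of any length are handled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .annotations import ResidueAnnotations
from .classify import (
    CVResult,
    KernelSpec,
    TrainedModel,
    cross_validate_matrix,
    predict,
    train,
    verdicts,
)
from .errors import DatasetError
from .scan import ScanConfig, scan_protein


@dataclass(frozen=True)
class RegionExample:
    """A labeled protein region (+1 specific response, -1 not)."""

    region_id: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (1, -1):
            raise DatasetError(f"{self.region_id}: label must be +1 or -1")

    def __len__(self) -> int:
        return len(self.sequence)


_SUMMARY_FUNCS = {
    "mean": lambda s: float(np.mean(s)),
    "max": lambda s: float(np.max(s)),
    "min": lambda s: float(np.min(s)),
    "fraction_positive": lambda s: float(np.count_nonzero(s > 0) / len(s)),
    "longest_positive_run_fraction": lambda s: _longest_positive_run(s) / len(s),
}

DEFAULT_SUMMARIES = tuple(_SUMMARY_FUNCS)


def _longest_positive_run(scores: np.ndarray) -> int:
    best = cur = 0
    for s in scores:
        cur = cur + 1 if s > 0 else 0
        best = max(best, cur)
    return best


@dataclass(frozen=True)
class RegionFeatureConfig:
    """How a window-score list is collapsed to a fixed-length vector."""

    q: int = 20
    include: Tuple[str, ...] = DEFAULT_SUMMARIES

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("q must be >= 1")
        unknown = set(self.include) - set(_SUMMARY_FUNCS)
        if unknown:
            raise ValueError(f"unknown summary statistic(s) {sorted(unknown)}")

    @property
    def dimension(self) -> int:
        return self.q + len(self.include)


def region_features(
    scores: Sequence[float], config: RegionFeatureConfig = RegionFeatureConfig()
) -> np.ndarray:
    """q evenly spaced empirical quantiles plus the configured summaries.

    Deterministic for a given score list and independent of its ordering in
    the quantile block; the dimension never depends on the region length.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("region_features requires at least one score")
    if config.q == 1:
        quantiles = np.array([float(np.quantile(scores, 0.5))])
    else:
        quantiles = np.quantile(scores, np.linspace(0.0, 1.0, config.q))
    summaries = np.array([_SUMMARY_FUNCS[name](scores) for name in config.include])
    return np.concatenate([quantiles, summaries])


def _region_design(
    regions: Sequence[RegionExample],
    annotations: Mapping[str, ResidueAnnotations],
    peptide_model: TrainedModel,
    region_config: RegionFeatureConfig,
    scan_step: int = 1,
) -> Tuple[np.ndarray, np.ndarray, List[np.ndarray]]:
    w = peptide_model.peptide_length or 15
    config = ScanConfig(window_length=w, step=scan_step)
    rows, score_lists = [], []
    for region in regions:
        if len(region) < w:
            raise ValueError(
                f"{region.region_id}: region length {len(region)} < scan window {w}"
            )
        scan = scan_protein(
            region.sequence, annotations.get(region.region_id), peptide_model, config
        )
        score_lists.append(scan.scores)
        rows.append(region_features(scan.scores, region_config))
    y = np.array([r.label for r in regions], dtype=int)
    return np.vstack(rows), y, score_lists


def train_region_classifier(
    regions: Sequence[RegionExample],
    annotations: Mapping[str, ResidueAnnotations],
    peptide_model: TrainedModel,
    kernel: KernelSpec = KernelSpec("rbf"),
    k: int = 5,
    seed: int = 0,
    region_config: RegionFeatureConfig = RegionFeatureConfig(),
    scan_step: int = 1,
) -> Tuple[TrainedModel, CVResult]:
    """Scan each region, summarize, cross-validate, and fit the final model.

    Returns the region model (fitted on all regions) and the stratified CV
    result; the CV refits scaler and SVM inside each training split.
    """
    X, y, _ = _region_design(regions, annotations, peptide_model, region_config, scan_step)
    cv = cross_validate_matrix(X, y, kernel, k=k, seed=seed)
    model = train(X, y, kernel, seed=seed, feature_config=region_config)
    return model, cv


def predict_region(
    sequence: str,
    annotations: Optional[ResidueAnnotations],
    peptide_model: TrainedModel,
    region_model: TrainedModel,
    scan_step: int = 1,
) -> Tuple[float, str]:
    """Scan a region, summarize its scores, and apply the region classifier."""
    w = peptide_model.peptide_length or 15
    scan = scan_protein(
        sequence, annotations, peptide_model, ScanConfig(window_length=w, step=scan_step)
    )
    features = region_features(scan.scores, region_model.feature_config).reshape(1, -1)
    score = float(predict(region_model, features)[0])
    return score, str(verdicts(np.array([score]))[0])


def compare_score_distributions(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of window-score distributions.

    Returns (D, p) where D = sup |ECDF_pos - ECDF_neg| and p is the asymptotic
    two-sided p-value.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both samples must be non-empty")
    result = stats.ks_2samp(pos, neg, alternative="two-sided", method="asymp")
    return float(result.statistic), float(result.pvalue)
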