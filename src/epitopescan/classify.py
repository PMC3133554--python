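"""Kernel-SVM training, prediction, metrics and cross-validated evaluation.

The decision rule throughout the package is the sign of the real-valued SVM
decision score: score > 0 predicts an antigenic (+1) example, score < 0 a
non-antigenic (-1) one, and an exact 0 is reported as a third, indeterminate
verdict (counted as non-positive in confusion tables).  Evaluation pools
out-of-fold decision scores across a stratified k-fold split, with the feature
scaler refitted inside every training split so no test information leaks into
the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

from .datasets import EpitopeRecord, FoldAssignment, make_folds
from .errors import ConsistencyError, DatasetError, ModelFormatError
from .features import FeatureConfig, FeatureScaler, assemble, stack_vectors

KERNEL_NAMES = ("linear", "poly", "rbf", "sigmoid")

MODEL_FORMAT_VERSION = 1

VERDICT_POSITIVE = "positive"
VERDICT_NEGATIVE = "negative"
VERDICT_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class KernelSpec:
    """SVM kernel family and hyperparameters.

    ``gamma`` follows the 1/dimension convention when left as "auto";
    ``coef0`` defaults to 1, the classical additive constant of the
    inhomogeneous polynomial kernel (gamma*<x,y> + coef0)^degree (it is
    ignored by the linear and RBF kernels).  ``degree`` is required for and
    only for the polynomial kernel.
    """

    name: str = "rbf"
    degree: Optional[int] = None
    gamma: Union[float, str] = "auto"
    C: float = 1.0
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise ValueError(f"kernel name must be one of {KERNEL_NAMES}")
        if self.name == "poly":
            if self.degree is None:
                raise ValueError("polynomial kernel requires a degree")
            if self.degree < 2:
                raise ValueError("polynomial degree must be >= 2")
        elif self.degree is not None:
            raise ValueError(f"degree is only meaningful for the poly kernel, not {self.name}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, str):
            if self.gamma != "auto":
                raise ValueError('gamma must be a positive real or "auto"')
        elif self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _make_svc(kernel: KernelSpec, seed: int) -> SVC:
    return SVC(
        C=kernel.C,
        kernel=kernel.name,
        degree=kernel.degree if kernel.degree is not None else 3,
        gamma=kernel.gamma,  # sklearn "auto" == 1 / n_features
        coef0=kernel.coef0,
        cache_size=256,
        random_state=seed,
    )


@dataclass
class TrainedModel:
    """A fitted kernel SVM together with its scaler and feature configuration."""

    kernel: KernelSpec
    svc: SVC
    scaler: FeatureScaler
    feature_config: Any = None
    peptide_length: Optional[int] = None
    metadata: Dict[str, Any] = field(default_factory=dict)

    def decision_scores(self, X: Union[np.ndarray, sp.spmatrix]) -> np.ndarray:
        if X.shape[0] == 0:
            return np.empty(0)
        return np.asarray(self.svc.decision_function(self.scaler.transform(X)))


@dataclass
class MetricsReport:
    """Confusion counts, headline rates and the ROC of one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_indeterminate: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc: List[Tuple[float, float]]

    def to_dict(self) -> Dict[str, Any]:
        d = {
            k: getattr(self, k)
            for k in ("tp", "fp", "tn", "fn", "n_indeterminate",
                      "accuracy", "precision", "recall", "f1", "auc")
        }
        return d


def verdicts(scores: np.ndarray) -> np.ndarray:
    """Map decision scores to positive/negative/indeterminate verdicts."""
    scores = np.asarray(scores, dtype=float)
    out = np.where(scores > 0, VERDICT_POSITIVE, VERDICT_NEGATIVE).astype(object)
    out[scores == 0] = VERDICT_INDETERMINATE
    return out


def train(
    X: Union[np.ndarray, sp.spmatrix],
    y: Sequence[int],
    kernel: KernelSpec,
    seed: int = 0,
    feature_config: Any = None,
    peptide_length: Optional[int] = None,
) -> TrainedModel:
    """Fit the scaler on X, then a soft-margin SVM on the scaled features.

    Labels must contain both classes; the positive class is +1 by convention
    (decision scores are positive on the +1 side).
    """
    y = np.asarray(y, dtype=int)
    classes = set(np.unique(y).tolist())
    if classes != {-1, 1}:
        raise DatasetError(f"training requires both labels +1 and -1, found {sorted(classes)}")
    scaler = FeatureScaler().fit(X)
    svc = _make_svc(kernel, seed)
    svc.fit(scaler.transform(X), y)
    n_pos = int(np.count_nonzero(y == 1))
    return TrainedModel(
        kernel=kernel,
        svc=svc,
        scaler=scaler,
        feature_config=feature_config,
        peptide_length=peptide_length,
        metadata={"seed": seed, "n_pos": n_pos, "n_neg": int(len(y) - n_pos)},
    )


def predict(model: TrainedModel, X: Union[np.ndarray, sp.spmatrix]) -> np.ndarray:
    """Real decision score per row of X (raw, unscaled features)."""
    return model.decision_scores(X)


def compute_metrics(scores: Sequence[float], labels: Sequence[int]) -> MetricsReport:
    """Confusion counts via the sign rule plus rank-based (trapezoidal) AUC.

    Zero scores are a separate indeterminate verdict but count as non-positive
    predictions.  AUC handles score ties by rank averaging.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be non-empty and equal-length")
    if not set(np.unique(labels).tolist()) <= {-1, 1}:
        raise ValueError("labels must be +1/-1")
    pred_pos = scores > 0
    tp = int(np.count_nonzero(pred_pos & (labels == 1)))
    fp = int(np.count_nonzero(pred_pos & (labels == -1)))
    tn = int(np.count_nonzero(~pred_pos & (labels == -1)))
    fn = int(np.count_nonzero(~pred_pos & (labels == 1)))
    total = tp + fp + tn + fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    if len(set(labels.tolist())) == 2:
        auc = float(roc_auc_score(labels, scores))
        fpr, tpr, _ = roc_curve(labels, scores)
        roc = list(zip(fpr.tolist(), tpr.tolist()))
    else:
        auc = float("nan")
        roc = []
    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_indeterminate=int(np.count_nonzero(scores == 0)),
        accuracy=(tp + tn) / total,
        precision=precision,
        recall=recall,
        f1=f1,
        auc=auc,
        roc=roc,
    )


@dataclass
class CVResult:
    """Pooled out-of-fold evaluation plus per-fold details."""

    report: MetricsReport
    fold_reports: List[MetricsReport]
    folds: np.ndarray
    fold_scalers: List[FeatureScaler]
    oof_scores: np.ndarray


def cross_validate_matrix(
    X: Union[np.ndarray, sp.spmatrix],
    y: Sequence[int],
    kernel: KernelSpec,
    k: int = 5,
    seed: int = 0,
    folds: Optional[np.ndarray] = None,
) -> CVResult:
    """Stratified k-fold CV on a precomputed design matrix.

    The scaler is fitted on each training split only; pooled out-of-fold
    scores give the headline report ("sum of the folds" = pooled confusion
    counts), with per-fold reports retained.
    """
    y = np.asarray(y, dtype=int)
    if folds is None:
        from sklearn.model_selection import StratifiedKFold

        if k < 2:
            raise DatasetError("fold count k must be >= 2")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = np.empty(len(y), dtype=int)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            folds[test_idx] = f
    else:
        folds = np.asarray(folds, dtype=int)
        k = int(folds.max()) + 1
    X = X.tocsr() if sp.issparse(X) else np.asarray(X)
    oof = np.empty(len(y), dtype=float)
    fold_reports: List[MetricsReport] = []
    fold_scalers: List[FeatureScaler] = []
    for f in range(k):
        test_mask = folds == f
        train_mask = ~test_mask
        model = train(X[train_mask], y[train_mask], kernel, seed=seed)
        oof[test_mask] = model.decision_scores(X[test_mask])
        fold_reports.append(compute_metrics(oof[test_mask], y[test_mask]))
        fold_scalers.append(model.scaler)
    return CVResult(
        report=compute_metrics(oof, y),
        fold_reports=fold_reports,
        folds=folds,
        fold_scalers=fold_scalers,
        oof_scores=oof,
    )


def featurize_records(
    records: Sequence[EpitopeRecord],
    annotations: Optional[Mapping[str, "Any"]],
    config: FeatureConfig,
) -> Tuple[sp.csr_matrix, np.ndarray, List[str]]:
    """Feature matrix, labels and ids for a list of records.

    ``annotations`` maps parent_id to that protein's ResidueAnnotations; the
    peptide span is located via the record's 1-based coordinates.
    """
    vectors = []
    for r in records:
        ann = None
        if config.needs_annotations:
            if annotations is None or r.parent_id not in annotations:
                raise ConsistencyError(f"{r.record_id}: no annotations for parent {r.parent_id}")
            ann = annotations[r.parent_id]
        vectors.append(assemble(r.peptide, ann, r.start - 1, config))
    X = stack_vectors(vectors)
    y = np.array([r.label for r in records], dtype=int)
    return X, y, [r.record_id for r in records]


def cross_validate(
    records: Sequence[EpitopeRecord],
    annotations: Optional[Mapping[str, "Any"]],
    config: FeatureConfig,
    kernel: KernelSpec,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Featurize records, assign stratified folds, and run matrix-level CV."""
    X, y, ids = featurize_records(records, annotations, config)
    assignment = make_folds(records, k=k, seed=seed)
    folds = np.array([assignment.fold_of(i) for i in ids], dtype=int)
    return cross_validate_matrix(X, y, kernel, k=k, seed=seed, folds=folds)


def serialize_model(model: TrainedModel, path) -> None:
    """Write a versioned model artifact (joblib container)."""
    joblib.dump({"format": "epitopescan-model", "version": MODEL_FORMAT_VERSION,
                 "payload": model}, path)


def load_model(path) -> TrainedModel:
    """Load a model artifact; corrupt or mismatched files raise ModelFormatError."""
    try:
        blob = joblib.load(path)
    except Exception as exc:  # joblib/pickle raise a zoo of exceptions
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if (
        not isinstance(blob, dict)
        or blob.get("format") != "epitopescan-model"
        or blob.get("version") != MODEL_FORMAT_VERSION
    ):
        raise ModelFormatError(f"{path} is not a supported model artifact")
    return blob["payload"]
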