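"""RBF-SVM training, cross-validation and evaluation.

Two classifiers share this machinery: a per-residue lipid-exposure
predictor and a per-pair residue-contact predictor. Training follows
the protocol of undersampling the (roughly 1:50 imbalanced) negative
class to parity, compensating any residual imbalance with the SVM
cost factor, leave-one-protein-out cross-validation with homology
exclusion (E-value < 1e-4), and an MCC-driven grid search over the
RBF hyperparameters. Raw decision scores (sign = label at threshold
0) are the predictor output and feed directly into downstream feature
vectors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from helixpack.feature_builder import (
    FeatureConfig,
    NormalizationStats,
    fit_zscore,
)
from helixpack.io_formats import ValidationError

#: Published optima, used whenever grid search is skipped.
LIPID_SVM_DEFAULTS = {"gamma": 0.6, "C": 1.5}
CONTACT_SVM_DEFAULTS = {"gamma": 24.0, "C": 1.0}

#: Default grid spanning both published optima (log-ish spacing).
DEFAULT_GAMMA_GRID = (0.01, 0.03, 0.1, 0.3, 0.6, 1.0, 3.0, 10.0, 24.0, 50.0)
DEFAULT_C_GRID = (0.1, 0.3, 1.0, 1.5, 3.0, 10.0)

HOMOLOGY_EVALUE_CUTOFF = 1e-4


@dataclass(frozen=True)
class SVMParams:
    """RBF kernel hyperparameters plus the positive-class cost factor."""

    gamma: float
    C: float
    cost_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.C <= 0 or self.cost_factor <= 0:
            raise ValueError("gamma, C and cost_factor must be positive")


@dataclass
class TrainedModel:
    """A fitted SVM with its normalization statistics and feature config."""

    svm: SVC
    stats: NormalizationStats
    config: FeatureConfig
    params: SVMParams


@dataclass(frozen=True)
class MetricReport:
    TP: int
    TN: int
    FP: int
    FN: int
    precision: float
    recall: float
    FPR: float
    FNR: float
    MCC: float
    accuracy: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "precision": self.precision, "recall": self.recall,
            "FPR": self.FPR, "FNR": self.FNR,
            "MCC": self.MCC, "accuracy": self.accuracy,
        }


@dataclass(frozen=True)
class HomologyTable:
    """Pairwise E-values between dataset sequences.

    Absent pairs are treated as non-homologous (E = infinity); the
    self E-value is 0 by definition. An aligner is never run here —
    the table is a precomputed input.
    """

    evalues: Mapping[frozenset, float] = field(default_factory=dict)

    def evalue(self, id_a: str, id_b: str) -> float:
        if id_a == id_b:
            return 0.0
        return self.evalues.get(frozenset((id_a, id_b)), math.inf)

    def excluded_with(
        self, target: str, ids: Iterable[str], cutoff: float = HOMOLOGY_EVALUE_CUTOFF
    ) -> set[str]:
        """Ids to drop from the training fold of ``target``: the target
        itself plus everything with E-value below ``cutoff`` to it."""
        return {i for i in ids if self.evalue(target, i) < cutoff}


def balance_training(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Random-undersample negatives to the positive count.

    All positives are kept; negatives are drawn without replacement.
    Returns (features, labels, cost_factor) where the cost factor
    j = kept negatives / positives compensates any residual imbalance
    (1.0 once parity is reached).
    """
    labels = np.asarray(labels, dtype=bool)
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    if len(pos_idx) == 0:
        raise ValidationError("no positive examples to balance against")
    rng = np.random.default_rng(seed)
    if len(neg_idx) > len(pos_idx):
        neg_idx = rng.choice(neg_idx, size=len(pos_idx), replace=False)
    keep = np.sort(np.concatenate([pos_idx, neg_idx]))
    cost_factor = len(neg_idx) / len(pos_idx)
    return features[keep], labels[keep], cost_factor


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    params: SVMParams,
    stats: NormalizationStats | None = None,
    config: FeatureConfig | None = None,
) -> TrainedModel:
    """Fit an RBF SVM on (already normalized) features.

    The cost factor weights positive-class errors: class_weight
    {True: cost_factor}. Deterministic for fixed inputs.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValidationError("training labels are single-class")
    svm = SVC(
        kernel="rbf",
        gamma=params.gamma,
        C=params.C,
        class_weight={True: params.cost_factor, False: 1.0},
    )
    svm.fit(np.asarray(features, dtype=float), labels)
    if stats is None:
        stats = NormalizationStats(
            mean=np.zeros(features.shape[1]), sd=np.ones(features.shape[1])
        )
    return TrainedModel(
        svm=svm, stats=stats, config=config or FeatureConfig(), params=params
    )


def predict_scores(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Raw SVM decision values; label = score > 0. Features must be on
    the same (normalized) scale the model was trained on."""
    features = np.asarray(features, dtype=float)
    expected = model.svm.n_features_in_
    if features.ndim != 2 or features.shape[1] != expected:
        raise ValidationError(
            f"feature width {features.shape[-1] if features.ndim else 0} "
            f"does not match model width {expected}"
        )
    return model.svm.decision_function(features)


def compute_metrics(TP: int, TN: int, FP: int, FN: int) -> MetricReport:
    """Standard confusion-matrix metrics.

    accuracy = (TP+TN)/(TP+TN+FP+FN); MCC by its product formula with
    0 substituted when a denominator factor vanishes; rate metrics with
    empty denominators are reported as 0 and the report flagged
    degenerate.
    """
    if min(TP, TN, FP, FN) < 0:
        raise ValidationError("confusion counts must be non-negative")
    total = TP + TN + FP + FN
    if total == 0:
        raise ValidationError("empty confusion matrix")
    degenerate = False

    def rate(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = rate(TP, TP + FP)
    recall = rate(TP, TP + FN)
    fpr = rate(FP, FP + TN)
    fnr = rate(FN, FN + TP)
    denom = math.sqrt(
        float(TP + FP) * float(TP + FN) * float(TN + FP) * float(TN + FN)
    )
    if denom == 0:
        degenerate = True
        mcc = 0.0
    else:
        mcc = (TP * TN - FP * FN) / denom
    return MetricReport(
        TP=TP, TN=TN, FP=FP, FN=FN,
        precision=precision, recall=recall, FPR=fpr, FNR=fnr,
        MCC=mcc, accuracy=(TP + TN) / total, degenerate=degenerate,
    )


def metrics_from_predictions(
    labels: Sequence[bool], predicted: Sequence[bool]
) -> MetricReport:
    labels = np.asarray(labels, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    return compute_metrics(
        TP=int(np.sum(labels & predicted)),
        TN=int(np.sum(~labels & ~predicted)),
        FP=int(np.sum(~labels & predicted)),
        FN=int(np.sum(labels & ~predicted)),
    )


@dataclass(frozen=True)
class ProteinExamples:
    """One protein's examples for cross-validation."""

    id: str
    features: np.ndarray
    labels: np.ndarray


def leave_one_protein_out(
    dataset: Sequence[ProteinExamples],
    params: SVMParams,
    homology: HomologyTable | None = None,
    seed: int = 0,
    balance: bool = False,
) -> tuple[MetricReport, list[tuple[str, np.ndarray]]]:
    """Leave-one-protein-out cross-validation.

    For each fold the target protein and every sequence with E-value
    < 1e-4 to it are excluded from training; Z-score statistics are
    fitted on the fold's training matrix only. Returns the pooled
    metric report and per-protein raw score arrays.
    """
    if len(dataset) < 2:
        raise ValidationError("cross-validation needs at least 2 proteins")
    homology = homology or HomologyTable()
    ids = [p.id for p in dataset]
    all_true: list[np.ndarray] = []
    all_pred: list[np.ndarray] = []
    fold_scores: list[tuple[str, np.ndarray]] = []
    for fold, target in enumerate(dataset):
        excluded = homology.excluded_with(target.id, ids)
        train = [p for p in dataset if p.id not in excluded]
        if not train:
            raise ValidationError(
                f"fold {target.id}: homology exclusion removed all training data"
            )
        X = np.vstack([p.features for p in train])
        y = np.concatenate([p.labels for p in train]).astype(bool)
        cost = 1.0
        if balance:
            X, y, cost = balance_training(X, y, seed=seed + fold)
        stats = fit_zscore(X)
        model = train_svm(
            X if stats is None else stats.transform(X),
            y,
            SVMParams(gamma=params.gamma, C=params.C, cost_factor=cost),
            stats=stats,
        )
        scores = predict_scores(model, stats.transform(target.features))
        fold_scores.append((target.id, scores))
        all_true.append(np.asarray(target.labels, dtype=bool))
        all_pred.append(scores > 0)
    report = metrics_from_predictions(
        np.concatenate(all_true), np.concatenate(all_pred)
    )
    return report, fold_scores


def grid_search_cv(
    dataset: Sequence[ProteinExamples],
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    homology: HomologyTable | None = None,
    seed: int = 0,
    balance: bool = False,
) -> tuple[SVMParams, float]:
    """MCC-driven grid search under leave-one-protein-out CV.

    Returns the (gamma, C) maximizing pooled MCC; ties broken by
    smaller C, then smaller gamma.
    """
    if not gamma_grid or not C_grid:
        raise ValidationError("empty parameter grid")
    best: tuple[float, float, float] | None = None  # (mcc, -C, -gamma)
    best_params: SVMParams | None = None
    for gamma, C in itertools.product(sorted(gamma_grid), sorted(C_grid)):
        report, _ = leave_one_protein_out(
            dataset,
            SVMParams(gamma=gamma, C=C),
            homology=homology,
            seed=seed,
            balance=balance,
        )
        key = (report.MCC, -C, -gamma)
        if best is None or key > best:
            best = key
            best_params = SVMParams(gamma=gamma, C=C)
    assert best_params is not None
    return best_params, best[0]
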