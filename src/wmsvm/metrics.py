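"""Classifier evaluation: confusion metrics, ROC/AUC, permutation inference,
and the decision-value vs clinical-score correlation.

The patient group is the positive class: sensitivity is the fraction of
patients labelled patient, specificity the fraction of controls labelled
control. The ROC treats the control group as the higher-decision-value
class, matching the sign rule of the classifier.

Significance of the observed LOOCV accuracy comes from a permutation test:
group labels are shuffled over all subjects, the full leakage-free LOOCV at
the fixed feature count is re-run under the permuted labels (Fisher ranking
and scaling recomputed inside every fold), and the p-value is the fraction
of permutations whose accuracy is at least the observed one. That count/N
estimator can return p = 0; the standard (count+1)/(N+1) estimator is
reported alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import CohortDataset, HC, PATIENT
from .errors import CohortError, DimensionError, ParameterError
from .features import BinaryMask, volumes_to_matrix
from .loocv import FoldResult, loocv_accuracy


@dataclass(frozen=True)
class ConfusionMetrics:
    """Counts and proportions with the patient group as positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def confusion_metrics(truths: Sequence[int], predictions: Sequence[int]) -> ConfusionMetrics:
    """Tally a confusion matrix from true and predicted group codes (+1/-1)."""
    truths = np.asarray(truths)
    predictions = np.asarray(predictions)
    if truths.size == 0 or truths.shape != predictions.shape:
        raise DimensionError("need equal, non-empty truth and prediction vectors")
    if not ((truths == PATIENT).any() and (truths == HC).any()):
        raise CohortError("both classes must be present in the truths")
    return ConfusionMetrics(
        tp=int(((truths == PATIENT) & (predictions == PATIENT)).sum()),
        fn=int(((truths == PATIENT) & (predictions == HC)).sum()),
        tn=int(((truths == HC) & (predictions == HC)).sum()),
        fp=int(((truths == HC) & (predictions == PATIENT)).sum()),
    )


def confusion_from_folds(folds: Sequence[FoldResult]) -> ConfusionMetrics:
    return confusion_metrics(
        [f.true_label for f in folds], [f.predicted_label for f in folds]
    )


@dataclass(frozen=True)
class ROCResult:
    """ROC curve points (threshold sweep over decision values) and its AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_analysis(decision_values: Sequence[float], truths: Sequence[int]) -> ROCResult:
    """ROC over decision values with the control group as the high-value class.

    The AUC (trapezoidal) equals the probability that a random control's
    decision value exceeds a random patient's, ties counted half.
    """
    values = np.asarray(decision_values, dtype=np.float64)
    truths = np.asarray(truths)
    if not ((truths == PATIENT).any() and (truths == HC).any()):
        raise CohortError("both classes are needed for a ROC curve")
    fpr, tpr, thresholds = _sk_roc_curve(truths, values, pos_label=HC)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


@dataclass(frozen=True)
class PermutationResult:
    """Observed accuracy against its label-permutation null distribution."""

    n_permutations: int
    observed_accuracy: float
    null_accuracies: np.ndarray
    count_ge: int
    p_value: float
    p_value_plus_one: float


def permutation_test(
    dataset: CohortDataset,
    mask: BinaryMask,
    k: int,
    n_perm: int = 10_000,
    seed: int = 0,
    C: float = 1.0,
) -> PermutationResult:
    """Permutation significance of the LOOCV accuracy at a fixed k.

    Each permutation shuffles the label vector once over all subjects and
    re-runs the complete nested LOOCV. Deterministic for a fixed seed; the
    permutation RNG stream is independent of any cohort-generation RNG.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    fm = volumes_to_matrix(dataset, mask)
    if k > fm.mask.n_voxels:
        raise ParameterError(f"k={k} exceeds the {fm.mask.n_voxels} in-mask features")
    labels = dataset.labels
    observed = loocv_accuracy(fm.X, labels, k, C=C)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = loocv_accuracy(fm.X, rng.permutation(labels), k, C=C)
    count_ge = int((null >= observed).sum())
    return PermutationResult(
        n_permutations=n_perm,
        observed_accuracy=observed,
        null_accuracies=null,
        count_ge=count_ge,
        p_value=count_ge / n_perm,
        p_value_plus_one=(count_ge + 1) / (n_perm + 1),
    )


def spearman_correlation(
    patient_decision_values: Sequence[float], clinical_scores: Sequence[float]
) -> tuple[float, float]:
    """Spearman rho between patients' decision values and clinical scores.

    rho is the Pearson correlation of mid-ranks; the p-value uses the
    large-sample t approximation. Controls carry no clinical score, so the
    correlation is computed over patients only.
    """
    values = np.asarray(patient_decision_values, dtype=np.float64)
    scores = np.asarray(clinical_scores, dtype=np.float64)
    if values.shape != scores.shape or values.ndim != 1:
        raise DimensionError("need paired 1D value/score vectors")
    if len(values) < 3:
        raise ParameterError("Spearman correlation needs at least 3 pairs")
    if np.unique(values).size < 2 or np.unique(scores).size < 2:
        raise ParameterError("correlation undefined: zero variance in a ranking")
    result = stats.spearmanr(values, scores)
    return float(result.statistic), float(result.pvalue)
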