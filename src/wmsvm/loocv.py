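"""Nested leave-one-out cross-validation and the discriminative weight map.

With n subjects, LOOCV runs n folds. In each fold one subject is held out
and every training-derived quantity — Fisher scores, the descending feature
ranking, the top-k selection, the per-feature scaler and the SVM itself —
is recomputed from the remaining n-1 subjects only, so no information about
the held-out subject leaks into the model that scores it.

The feature-count sweep repeats the full LOOCV for k = step, 2*step, ...,
k_max (at the study scale: step 100 up to 20,000, i.e. 200 cycles) and
records accuracy, sensitivity and specificity per k. The optimal k is the
midpoint of the longest contiguous accuracy-maximal run of the grid
(earliest run on ties, midpoint snapped down to the grid), which formalises
picking "the middle of the plateau".

Because the winning feature set varies slightly from fold to fold, the
discriminative map averages each fold's weight vector after scattering it
to the full in-mask feature space (zeros at unselected voxels) and
back-projects the average into a volume. Weights live in the standardised
feature space in which they were learned; a positive map value means the
patient group's FA at that voxel is lower than the controls'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import CohortDataset, HC, PATIENT
from .errors import CohortError, DimensionError, ParameterError
from .features import BinaryMask, FeatureMatrix, matrix_to_volume, volumes_to_matrix
from .fisher import fisher_scores, select_top_k
from .svm import (
    SVMModel,
    Scaler,
    apply_scaler,
    decision_value,
    fit_scaler,
    predict_label,
    train_linear_svm,
)
from .volumes import ScalarVolume


@dataclass(frozen=True)
class FoldResult:
    """Outcome of one LOOCV fold at a fixed k."""

    left_out_subject: str
    true_label: int
    decision_value: float
    predicted_label: int
    selected_features: np.ndarray
    w: np.ndarray
    b: float
    scaler: Scaler

    @property
    def k(self) -> int:
        return len(self.selected_features)


@dataclass(frozen=True)
class SweepResult:
    """Per-k metrics (and optionally fold results) across the feature-count grid."""

    k_grid: np.ndarray
    accuracies: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    fold_results: tuple[tuple[FoldResult, ...], ...] | None = None

    def __post_init__(self) -> None:
        k_grid = np.asarray(self.k_grid, dtype=np.int64)
        if len(k_grid) == 0:
            raise ParameterError("sweep grid is empty")
        if not (np.diff(k_grid) > 0).all():
            raise ParameterError("k grid must be strictly increasing")
        object.__setattr__(self, "k_grid", k_grid)
        object.__setattr__(self, "accuracies", np.asarray(self.accuracies, dtype=np.float64))
        if len(self.accuracies) != len(k_grid):
            raise DimensionError("one accuracy per grid point required")


def _check_loocv_cohort(labels: np.ndarray) -> None:
    n = len(labels)
    if n < 4:
        raise CohortError(f"LOOCV needs at least 4 subjects, got {n}")
    # leaving out one subject must keep >= 2 members per group
    for group in (HC, PATIENT):
        if (labels == group).sum() < 3:
            raise CohortError(
                "each group needs >= 3 subjects so every training split keeps >= 2"
            )


def _run_fold(
    X: np.ndarray, labels: np.ndarray, k: int, leave_out: int, C: float = 1.0
) -> tuple[np.ndarray, Scaler, SVMModel, float]:
    """Train on all rows but ``leave_out`` and score the held-out row."""
    train = np.arange(len(labels)) != leave_out
    X_train = X[train]
    y_train = labels[train]
    fs = fisher_scores(X_train, y_train)
    selected = select_top_k(fs.ranking, k)
    scaler = fit_scaler(X_train[:, selected])
    model = train_linear_svm(apply_scaler(scaler, X_train[:, selected]), y_train, C=C)
    x_test = apply_scaler(scaler, X[leave_out, selected][None, :])[0]
    return selected, scaler, model, decision_value(model, x_test)


def loocv_run(
    dataset: CohortDataset,
    mask: BinaryMask,
    k: int,
    C: float = 1.0,
    features: FeatureMatrix | None = None,
) -> list[FoldResult]:
    """Run all n LOOCV folds at a fixed feature count k.

    ``features`` may carry a precomputed feature matrix for the same dataset
    and mask to avoid re-extracting it per call.
    """
    _check_loocv_cohort(dataset.labels)
    fm = features if features is not None else volumes_to_matrix(dataset, mask)
    if k > fm.mask.n_voxels:
        raise ParameterError(f"k={k} exceeds the {fm.mask.n_voxels} in-mask features")
    results = []
    for i in range(dataset.n_subjects):
        selected, scaler, model, value = _run_fold(fm.X, dataset.labels, k, i, C=C)
        results.append(
            FoldResult(
                left_out_subject=dataset.subject_ids[i],
                true_label=int(dataset.labels[i]),
                decision_value=value,
                predicted_label=predict_label(value),
                selected_features=selected,
                w=model.w,
                b=model.b,
                scaler=scaler,
            )
        )
    return results


def loocv_accuracy(X: np.ndarray, labels: np.ndarray, k: int, C: float = 1.0) -> float:
    """Lean LOOCV accuracy on a raw feature matrix (used by the permutation test)."""
    n = len(labels)
    correct = 0
    for i in range(n):
        _, _, _, value = _run_fold(X, labels, k, i, C=C)
        if predict_label(value) == labels[i]:
            correct += 1
    return correct / n


def _fold_metrics(folds: Sequence[FoldResult]) -> tuple[float, float, float]:
    truths = np.array([f.true_label for f in folds])
    preds = np.array([f.predicted_label for f in folds])
    tp = int(((truths == PATIENT) & (preds == PATIENT)).sum())
    fn = int(((truths == PATIENT) & (preds == HC)).sum())
    tn = int(((truths == HC) & (preds == HC)).sum())
    fp = int(((truths == HC) & (preds == PATIENT)).sum())
    acc = (tp + tn) / len(folds)
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return acc, sens, spec


def feature_count_grid(k_max: int, step: int = 100) -> np.ndarray:
    """The feature-count grid {step, 2*step, ..., k_max} (study scale: 200 points)."""
    if step < 1:
        raise ParameterError("step must be >= 1")
    grid = np.arange(step, k_max + 1, step, dtype=np.int64)
    if len(grid) == 0:
        raise ParameterError(f"no grid points: step={step} exceeds k_max={k_max}")
    return grid


def k_sweep(
    dataset: CohortDataset,
    mask: BinaryMask,
    k_max: int = 20_000,
    step: int = 100,
    C: float = 1.0,
    truncate_at_m: bool = True,
    keep_folds: bool = True,
) -> SweepResult:
    """Run LOOCV over the k grid {step, 2*step, ..., k_max}.

    When the mask holds fewer than ``k_max`` voxels, ``truncate_at_m``
    shortens the grid at m (small synthetic grids); otherwise the excess is
    a parameter error.
    """
    if step < 1:
        raise ParameterError("step must be >= 1")
    fm = volumes_to_matrix(dataset, mask)
    m = fm.mask.n_voxels
    if k_max > m:
        if not truncate_at_m:
            raise ParameterError(f"k_max={k_max} exceeds the {m} in-mask features")
        k_max = m
    k_grid = feature_count_grid(k_max, step)
    all_folds = []
    metrics = []
    for k in k_grid:
        folds = loocv_run(dataset, mask, int(k), C=C, features=fm)
        all_folds.append(tuple(folds))
        metrics.append(_fold_metrics(folds))
    acc, sens, spec = zip(*metrics)
    return SweepResult(
        k_grid=k_grid,
        accuracies=np.array(acc),
        sensitivities=np.array(sens),
        specificities=np.array(spec),
        fold_results=tuple(all_folds) if keep_folds else None,
    )


def select_optimal_k(sweep: SweepResult) -> int:
    """Midpoint of the longest accuracy-maximal contiguous run of the grid.

    Ties between equally long runs go to the earliest; the midpoint in
    k-space is snapped down to the nearest grid point. A plateau spanning
    1,400-3,400 on a step-100 grid therefore yields 2,400.
    """
    acc = sweep.accuracies
    k_grid = sweep.k_grid
    best = acc.max()
    is_max = acc == best
    best_start = best_end = None
    best_len = 0
    i = 0
    while i < len(acc):
        if is_max[i]:
            j = i
            while j + 1 < len(acc) and is_max[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_len = j - i + 1
                best_start, best_end = i, j
            i = j + 1
        else:
            i += 1
    midpoint = (k_grid[best_start] + k_grid[best_end]) / 2
    # snap down to the grid
    idx = int(np.searchsorted(k_grid, midpoint, side="right")) - 1
    return int(k_grid[idx])


def average_weight_map(
    folds: Sequence[FoldResult],
    mask: BinaryMask,
    fill: float = 0.0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    affine: np.ndarray | None = None,
) -> ScalarVolume:
    """Average the per-fold weight vectors into one discriminative volume.

    Each fold's w is scattered to its own selected voxels (zeros elsewhere
    over the full m in-mask features), the full-length vectors are averaged
    over folds, and the average is back-projected through the mask.
    """
    if len(folds) == 0:
        raise DimensionError("no folds to average")
    k = folds[0].k
    if any(f.k != k for f in folds):
        raise DimensionError("all folds must share the same k")
    total = np.zeros(mask.n_voxels)
    for fold in folds:
        total[fold.selected_features] += fold.w
    return matrix_to_volume(total / len(folds), mask, fill=fill, voxel_size=voxel_size, affine=affine)
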