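"""Soft-margin linear SVM with feature standardisation.

The classifier is the soft-margin linear SVM in its dual form: maximise
sum_j alpha_j - 1/2 sum_ij alpha_i alpha_j y_i y_j <x_i, x_j> subject to
0 <= alpha_j <= C and sum_j alpha_j y_j = 0, with the misclassification
penalty C fixed to 1 throughout the pipeline. The weight vector is
w = sum_j alpha_j y_j x_j and the decision value for a test input x is
f(x) = <w, x> + b; f(x) > 0 assigns the control group, otherwise the
patient group.

Before training, the selected features are mean-centred and scaled to unit
sample standard deviation, with statistics fitted on training rows only and
applied unchanged to the held-out row — the nested cross-validation
contract forbids any test leakage.

The quadratic programme is solved by libsvm via scikit-learn; the model
object exposes the full Lagrange-multiplier vector, the training inputs and
labels, and w and b, so the dual identity and the Karush-Kuhn-Tucker
conditions can be checked directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from sklearn.svm import _libsvm

_libsvm.set_verbosity_wrap(0)

from .cohort import HC, PATIENT
from .errors import DimensionError, LabelError, ParameterError

#: floor applied to per-feature standard deviations; constant features map to 0
SD_FLOOR = 1e-8

#: libsvm stopping tolerances, tried in order: the tight value gives 1e-6-level
#: agreement with a QP oracle; the solver can cycle at that tolerance on some
#: degenerate instances, which then fall back to the looser value
SOLVER_TOLS = (1e-8, 1e-6)

#: iteration cap for the libsvm solver (per tolerance attempt)
MAX_ITER = 100_000


@dataclass(frozen=True)
class Scaler:
    """Per-column mean/sd standardisation fitted on training rows only."""

    means: np.ndarray
    sds: np.ndarray


def fit_scaler(X_train: np.ndarray) -> Scaler:
    """Column means and unbiased sample sds, floored at ``SD_FLOOR``.

    A constant column gets the floor sd, so its standardised values are 0
    rather than NaN.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    if X_train.ndim != 2 or X_train.size == 0:
        raise DimensionError("scaler needs a non-empty 2D training matrix")
    if X_train.shape[0] < 2:
        raise DimensionError("scaler needs at least 2 training rows")
    means = X_train.mean(axis=0)
    sds = np.maximum(X_train.std(axis=0, ddof=1), SD_FLOOR)
    return Scaler(means=means, sds=sds)


def apply_scaler(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    """Standardise rows with the fitted training statistics."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != len(scaler.means):
        raise DimensionError(
            f"matrix has {X.shape[1]} columns, scaler was fitted on {len(scaler.means)}"
        )
    return (X - scaler.means) / scaler.sds


@dataclass(frozen=True)
class SVMModel:
    """Trained soft-margin linear SVM.

    ``alphas`` are the Lagrange multipliers of all training points (0 for
    non-support vectors), satisfying 0 <= alpha_j <= C and
    sum_j alpha_j y_j = 0; ``w = sum_j alpha_j y_j x_j`` and ``b`` define
    the decision function <w, x> + b.
    """

    alphas: np.ndarray
    train_labels: np.ndarray
    train_inputs: np.ndarray
    w: np.ndarray
    b: float
    C: float

    def dual_objective(self) -> float:
        """Value of the dual objective at the stored multipliers."""
        a, y, X = self.alphas, self.train_labels, self.train_inputs
        q = (a * y) @ X
        return float(a.sum() - 0.5 * q @ q)

    def to_dict(self) -> dict[str, Any]:
        return {
            "alphas": self.alphas.tolist(),
            "train_labels": self.train_labels.tolist(),
            "w": self.w.tolist(),
            "b": self.b,
            "C": self.C,
        }


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SVMModel:
    """Solve the soft-margin linear-SVM dual on scaled training rows.

    ``y`` must contain both classes, encoded +1 / -1. Identical input gives
    an identical model (the solver is deterministic).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if C <= 0:
        raise ParameterError(f"C must be positive, got {C}")
    if X.ndim != 2 or X.shape[0] != len(y):
        raise DimensionError("X must be 2D with one row per label")
    present = set(np.unique(y))
    if present != {-1.0, 1.0}:
        raise LabelError(f"labels must contain both classes +1/-1, got {sorted(present)}")
    X = np.ascontiguousarray(X)
    y = np.ascontiguousarray(y)
    for tol in SOLVER_TOLS:
        support, sv, _, sv_coef, intercept, _, _, fit_status, _ = _libsvm.fit(
            X, y, svm_type=0, kernel="linear", C=C, tol=tol, max_iter=MAX_ITER
        )
        if fit_status == 0:
            break
    else:  # pragma: no cover - iteration cap exceeded at every tolerance
        raise ParameterError("SVM solver did not converge within the iteration cap")
    # libsvm's sv_coef holds alpha_j * y_j in its own internal class orientation,
    # which depends on the order labels first appear; orient so that f(x) > 0
    # means class +1, by matching the sign of one support coefficient to its label.
    flip = 1.0 if sv_coef[0, 0] * y[support[0]] > 0 else -1.0
    alphas = np.zeros(len(y))
    alphas[support] = flip * sv_coef[0] * y[support]
    w = flip * (sv_coef[0] @ sv)
    b = flip * float(intercept[0])
    return SVMModel(alphas=alphas, train_labels=y.copy(), train_inputs=X.copy(), w=w, b=b, C=float(C))


def decision_value(model: SVMModel, x: np.ndarray) -> float:
    """Decision function <w, x> + b for one test input."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.shape != model.w.shape:
        raise DimensionError(f"input length {x.shape} does not match weight length {model.w.shape}")
    return float(model.w @ x + model.b)


def predict_label(value: float) -> int:
    """Sign rule: value > 0 -> control (+1); value <= 0 -> patient (-1)."""
    if not np.isfinite(value):
        raise ParameterError(f"decision value must be finite, got {value}")
    return HC if value > 0 else PATIENT
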