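"""Fisher-score feature ranking.

For feature q with group means x1_q, x2_q, grand mean x_q and unbiased
within-group sample variances s1_q^2, s2_q^2, the Fisher score is

    F(q) = [(x1_q - x_q)^2 + (x2_q - x_q)^2] / (s1_q^2 + s2_q^2).

The numerator measures interclass separation, the denominator intraclass
spread; larger F means a more discriminative feature. Scores are computed on
training subjects only (the caller enforces the cross-validation contract)
and on raw, unscaled features — centering/normalisation happens after
selection, on the selected columns.

Degenerate features (zero within-group variance in both groups) score 0
when the group means also coincide, and +inf when they differ: a feature
that is constant within each group but differs between groups separates the
classes perfectly and ranks first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import HC, PATIENT
from .errors import CohortError, ParameterError


@dataclass(frozen=True)
class FisherScores:
    """Per-feature scores and the descending-score ranking.

    ``ranking`` is a permutation of 0..m-1 sorting scores non-increasingly;
    ties are broken by ascending feature (voxel) index so the order is
    reproducible across platforms.
    """

    scores: np.ndarray
    ranking: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.scores)


def fisher_scores(X_train: np.ndarray, labels: np.ndarray) -> FisherScores:
    """Score every feature on training rows; labels are +1 (HC) / -1 (patient).

    Both groups need at least two members (the within-group variances use
    n-1 denominators).
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    labels = np.asarray(labels)
    g1 = labels == HC
    g2 = labels == PATIENT
    if g1.sum() < 2 or g2.sum() < 2:
        raise CohortError("each group needs >= 2 training subjects for Fisher scoring")
    scores = _raw_scores(X_train[g1], X_train[g2])
    return FisherScores(scores=scores, ranking=rank_features(scores))


def _raw_scores(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    m1 = X1.mean(axis=0)
    m2 = X2.mean(axis=0)
    grand = np.concatenate([X1, X2]).mean(axis=0)
    numerator = (m1 - grand) ** 2 + (m2 - grand) ** 2
    denominator = X1.var(axis=0, ddof=1) + X2.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = numerator / denominator
    zero_den = denominator == 0
    scores[zero_den & (numerator > 0)] = np.inf
    scores[zero_den & (numerator == 0)] = 0.0
    return scores


def rank_features(scores: np.ndarray) -> np.ndarray:
    """Stable descending sort of scores; ties broken by ascending index."""
    scores = np.asarray(scores)
    return np.argsort(-scores, kind="stable")


def select_top_k(ranking: np.ndarray, k: int) -> np.ndarray:
    """First k entries of the ranking, order preserved."""
    m = len(ranking)
    if not 1 <= k <= m:
        raise ParameterError(f"k must lie in [1, {m}], got {k}")
    return np.asarray(ranking)[:k]
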