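"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different route from the implementation it
verifies: the SVM dual is solved by a general-purpose constrained optimiser,
the AUC by brute-force pair counting, Fisher scores by explicit loops, and
connected components by breadth-first flood fill.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy.optimize import minimize


def solve_svm_dual_qp(X: np.ndarray, y: np.ndarray, C: float = 1.0):
    """Solve the soft-margin SVM dual with SLSQP.

    maximise  sum(a) - 0.5 * a^T Q a,   Q_ij = y_i y_j <x_i, x_j>
    s.t.      0 <= a <= C,  sum(a * y) = 0

    Returns (alphas, w, dual_objective).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    G = (y[:, None] * X) @ (y[:, None] * X).T

    def fun(a):
        return 0.5 * a @ G @ a - a.sum()

    def jac(a):
        return G @ a - 1.0

    res = minimize(
        fun,
        np.zeros(n),
        jac=jac,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    if not res.success:  # SLSQP's line search can stall; retry with trust-constr
        from scipy.optimize import LinearConstraint

        res = minimize(
            fun,
            np.full(n, C / 2),
            jac=jac,
            bounds=[(0.0, C)] * n,
            constraints=[LinearConstraint(y[None, :], 0.0, 0.0)],
            method="trust-constr",
            options={"maxiter": 5000, "gtol": 1e-12, "xtol": 1e-14},
        )
        assert res.success, res.message
    a = res.x
    w = (a * y) @ X
    return a, w, a.sum() - 0.5 * a @ G @ a


def svm_primal_objective(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, C: float) -> float:
    margins = y * (X @ w + b)
    return 0.5 * w @ w + C * np.maximum(0.0, 1.0 - margins).sum()


def kkt_violation(model, tol_alpha: float = 1e-8) -> float:
    """Largest violation of the KKT conditions at the stored solution."""
    a, y, X, C = model.alphas, model.train_labels, model.train_inputs, model.C
    margins = y * (X @ model.w + model.b)
    worst = 0.0
    for ai, mi in zip(a, margins):
        if ai <= tol_alpha:  # alpha = 0 -> margin >= 1
            worst = max(worst, 1.0 - mi)
        elif ai >= C - tol_alpha:  # alpha = C -> margin <= 1
            worst = max(worst, mi - 1.0)
        else:  # interior -> margin = 1
            worst = max(worst, abs(mi - 1.0))
    worst = max(worst, abs(float(a @ y)))
    worst = max(worst, float(np.max(-a, initial=0.0)), float(np.max(a - C, initial=0.0)))
    return worst


def pairwise_auc(values, truths) -> float:
    """P(control value > patient value), ties counted half, by enumeration."""
    values = np.asarray(values, dtype=float)
    truths = np.asarray(truths)
    hc = values[truths == 1]
    pat = values[truths == -1]
    wins = 0.0
    for vh, vp in itertools.product(hc, pat):
        if vh > vp:
            wins += 1.0
        elif vh == vp:
            wins += 0.5
    return wins / (len(hc) * len(pat))


def fisher_scores_direct(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Loop-based evaluation of the Fisher score definition."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    out = np.empty(X.shape[1])
    for q in range(X.shape[1]):
        col = X[:, q]
        g1 = col[labels == 1]
        g2 = col[labels == -1]
        grand = col.mean()
        num = (g1.mean() - grand) ** 2 + (g2.mean() - grand) ** 2
        den = sum((v - g1.mean()) ** 2 for v in g1) / (len(g1) - 1) + sum(
            (v - g2.mean()) ** 2 for v in g2
        ) / (len(g2) - 1)
        if den == 0:
            out[q] = np.inf if num > 0 else 0.0
        else:
            out[q] = num / den
    return out


_OFFSETS = {
    6: [d for d in itertools.product((-1, 0, 1), repeat=3) if sum(abs(v) for v in d) == 1],
    26: [d for d in itertools.product((-1, 0, 1), repeat=3) if any(d)],
}


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components of a 3D boolean mask by breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    components = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            vox = queue.popleft()
            comp.add(vox)
            for off in _OFFSETS[connectivity]:
                nb = tuple(v + o for v, o in zip(vox, off))
                if all(0 <= c < s for c, s in zip(nb, mask.shape)) and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        components.append(comp)
    return components
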