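"""Linear soft-margin SVM trained in the dual by pairwise (SMO-style) ascent.

Labels enter as {0, 1} and are recoded internally to {-1, +1}.  The working
pair is chosen deterministically: the first index is the sample with the
largest KKT violation (ties to the lowest index), the second maximizes the
prediction-error gap.  ``C=inf`` gives the hard-margin problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SVMModel", "svm_fit", "svm_predict", "svm_decision", "svm_margin"]

_ALPHA_EPS = 1e-8


@dataclass
class SVMModel:
    """Fitted separating hyperplane w . x + b = 0 with dual coefficients."""

    w: np.ndarray
    b: float
    alpha: np.ndarray
    support_idx: np.ndarray
    C: float

    def save(self, path: str | Path) -> None:
        np.savez(
            path, w=self.w, b=self.b, alpha=self.alpha,
            support_idx=self.support_idx, C=self.C,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SVMModel":
        with np.load(path) as z:
            return cls(
                w=z["w"], b=float(z["b"]), alpha=z["alpha"],
                support_idx=z["support_idx"], C=float(z["C"]),
            )


def dual_objective(alpha: np.ndarray, y_pm: np.ndarray, K: np.ndarray) -> float:
    """0.5 * sum_ij a_i a_j y_i y_j K_ij - sum_i a_i (the minimized form)."""
    ay = alpha * y_pm
    return 0.5 * float(ay @ K @ ay) - float(alpha.sum())


def svm_fit(
    X2_train: np.ndarray,
    y_train: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-3,
    max_iter: int = 20000,
    seed: int | None = None,
) -> SVMModel:
    """Fit the linear SVM on {0,1}-labeled features.

    The solver is fully deterministic (``seed`` is accepted for interface
    uniformity but unused — pair selection has no random component).

    Raises
    ------
    ValueError
        For single-class input, fewer than two samples, or non-finite
        features.
    """
    X = np.atleast_2d(np.asarray(X2_train, dtype=float))
    y01 = np.asarray(y_train)
    if X.shape[0] < 2:
        raise ValueError("need at least two training samples")
    if not np.isin(y01, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if len(set(y01.tolist())) < 2:
        raise ValueError("training set contains a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    y = 2.0 * y01.astype(float) - 1.0
    n = X.shape[0]
    K = X @ X.T
    alpha = np.zeros(n)
    f = np.zeros(n)  # sum_j a_j y_j K_ij, intercept-free decision value

    # maximal-violating-pair working-set selection: the dual gradient is
    # G_i = y_i f_i - 1; optimality holds when max_{up}(-y G) - min_{down}(-y G)
    # drops below tol (the shared threshold is the intercept multiplier).
    for _ in range(max_iter):
        G = y * f - 1.0
        can_grow = alpha < C - _ALPHA_EPS if np.isfinite(C) else np.ones(n, bool)
        can_shrink = alpha > _ALPHA_EPS
        up = np.where(y > 0, can_grow, can_shrink)
        down = np.where(y > 0, can_shrink, can_grow)
        score = -y * G
        up_score = np.where(up, score, -np.inf)
        down_score = np.where(down, score, np.inf)
        i = int(np.argmax(up_score))
        j = int(np.argmin(down_score))
        if up_score[i] - down_score[j] <= tol:
            break
        if not _pair_step(i, j, X, y, K, alpha, f, C):
            # fall back to the best progressing partner for i
            gaps = np.where(down, up_score[i] - score, -np.inf)
            gaps[i] = -np.inf
            progressed = False
            for j2 in np.argsort(-gaps, kind="stable"):
                if gaps[int(j2)] <= 0:
                    break
                if _pair_step(i, int(j2), X, y, K, alpha, f, C):
                    progressed = True
                    break
            if not progressed:
                break
    b = _intercept(alpha, y, f, C)
    w = (alpha * y) @ X
    support = np.flatnonzero(alpha > _ALPHA_EPS)
    return SVMModel(w=w, b=b, alpha=alpha, support_idx=support, C=C)


def _pair_step(
    i: int,
    j: int,
    X: np.ndarray,
    y: np.ndarray,
    K: np.ndarray,
    alpha: np.ndarray,
    f: np.ndarray,
    C: float,
) -> bool:
    """Optimize the (i, j) pair analytically; update alpha and f in place."""
    if y[i] != y[j]:
        L = max(0.0, alpha[j] - alpha[i])
        H = min(C, C + alpha[j] - alpha[i]) if np.isfinite(C) else np.inf
    else:
        L = max(0.0, alpha[i] + alpha[j] - C) if np.isfinite(C) else 0.0
        H = min(C, alpha[i] + alpha[j])
    if H - L < 1e-14:
        return False
    eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
    if eta <= 1e-14:
        return False
    E_i = f[i] - y[i]
    E_j = f[j] - y[j]
    aj_new = np.clip(alpha[j] + y[j] * (E_i - E_j) / eta, L, H)
    delta_j = aj_new - alpha[j]
    if abs(delta_j) < 1e-14:
        return False
    ai_new = alpha[i] - y[i] * y[j] * delta_j
    delta_i = ai_new - alpha[i]
    alpha[i], alpha[j] = ai_new, aj_new
    f += y[i] * delta_i * K[i] + y[j] * delta_j * K[j]
    return True


def _intercept(alpha: np.ndarray, y: np.ndarray, f: np.ndarray, C: float) -> float:
    """Mean of y_i - w.x_i over free support vectors (all SVs as fallback)."""
    free = (alpha > _ALPHA_EPS) & (alpha < C - _ALPHA_EPS if np.isfinite(C) else True)
    if not free.any():
        free = alpha > _ALPHA_EPS
    if not free.any():
        return 0.0
    return float(np.mean(y[free] - f[free]))


def svm_decision(model: SVMModel, X2: np.ndarray) -> np.ndarray:
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X2.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"feature width {X2.shape[1]} != model width {model.w.shape[0]}"
        )
    return X2 @ model.w + model.b


def svm_predict(model: SVMModel, X2: np.ndarray) -> np.ndarray:
    """Predict {0,1} labels; a point exactly on the hyperplane maps to the
    positive (cancer) class."""
    return (svm_decision(model, X2) >= 0.0).astype(int)


def svm_margin(model: SVMModel) -> float:
    """Band width 2 / ||w|| between the two support hyperplanes."""
    norm = float(np.linalg.norm(model.w))
    if norm == 0.0:
        raise ValueError("zero weight vector has no margin")
    return 2.0 / norm
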