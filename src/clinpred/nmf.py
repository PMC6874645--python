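"""Nonnegative matrix factorization with multiplicative updates.

Factorizes the preprocessed nonnegative sample matrix X (n x m) as W @ H
with W (n x k) >= 0 and H (k x m) >= 0 by minimizing the squared Frobenius
reconstruction error.  Rows of W are the reduced k-dimensional samples fed
downstream; rows of H are per-latent-feature attribute weights.

Also hosts the latent-dimension sweep (select k by downstream classification
quality) and the attribute-weight report derived from H.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "NMFModel",
    "nmf_factorize",
    "project_rows",
    "k_sweep",
    "feature_weight_report",
]

_EPS = 1e-12


@dataclass
class NMFModel:
    """Fitted factorization X ~ W @ H at latent dimension k."""

    W: np.ndarray
    H: np.ndarray
    k: int
    objective_trace: np.ndarray
    seed: int | None = None

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            W=self.W,
            H=self.H,
            k=self.k,
            objective_trace=self.objective_trace,
            seed=-1 if self.seed is None else self.seed,
        )

    @classmethod
    def load(cls, path: str | Path) -> "NMFModel":
        with np.load(path) as z:
            seed = int(z["seed"])
            return cls(
                W=z["W"],
                H=z["H"],
                k=int(z["k"]),
                objective_trace=z["objective_trace"],
                seed=None if seed < 0 else seed,
            )


def _frobenius_objective(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    R = X - W @ H
    return float(np.sum(R * R))


def _init_factors(
    X: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    # uniform(0,1) scaled so that E[(WH)_ij] ~ mean(X)
    n, m = X.shape
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    W = rng.uniform(0.0, 1.0, size=(n, k)) * 2.0 * scale
    H = rng.uniform(0.0, 1.0, size=(k, m)) * 2.0 * scale
    return W, H


def _multiplicative_run(
    X: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    max_iter: int,
    tol: float,
    debug_checks: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    trace = [_frobenius_objective(X, W, H)]
    for _ in range(max_iter):
        # H <- H * (W^T X) / (W^T W H)
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        # W <- W * (X H^T) / (W H H^T)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        if debug_checks:
            assert (W >= 0).all() and (H >= 0).all(), "negative factor entry"
        obj = _frobenius_objective(X, W, H)
        prev = trace[-1]
        trace.append(obj)
        if prev > 0 and (prev - obj) / prev < tol:
            break
    return W, H, np.asarray(trace)


def nmf_factorize(
    Xp: np.ndarray,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    restarts: int = 5,
    seed: int | None = 0,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    debug_checks: bool = False,
) -> NMFModel:
    """Best-of-``restarts`` multiplicative-update factorization.

    Parameters
    ----------
    Xp:
        Nonnegative matrix of shape (n, m).
    k:
        Latent dimension, ``1 <= k <= min(n, m)``.
    init:
        Optional explicit ``(W0, H0)`` initialization; overrides restarts.
    debug_checks:
        Assert factor nonnegativity after every iteration.

    Raises
    ------
    ValueError
        If ``k`` is out of range or ``Xp`` has a negative entry (the first
        offending cell is named).
    """
    X = np.asarray(Xp, dtype=float)
    if X.ndim != 2:
        raise ValueError("Xp must be 2-D")
    n, m = X.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"k={k} out of range [1, {min(n, m)}]")
    neg = np.argwhere(X < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(f"negative entry Xp[{i}, {j}] = {X[i, j]}")

    if init is not None:
        W0 = np.array(init[0], dtype=float)
        H0 = np.array(init[1], dtype=float)
        W, H, trace = _multiplicative_run(X, W0, H0, max_iter, tol, debug_checks)
        return NMFModel(W=W, H=H, k=k, objective_trace=trace, seed=seed)

    ss = np.random.SeedSequence(seed)
    best: NMFModel | None = None
    for child in ss.spawn(max(restarts, 1)):
        rng = np.random.default_rng(child)
        W0, H0 = _init_factors(X, k, rng)
        W, H, trace = _multiplicative_run(X, W0, H0, max_iter, tol, debug_checks)
        model = NMFModel(W=W, H=H, k=k, objective_trace=trace, seed=seed)
        if best is None or model.objective < best.objective:
            best = model
    assert best is not None
    return best


def project_rows(H: np.ndarray, X_new: np.ndarray) -> np.ndarray:
    """Project new rows onto a fitted basis: per row solve
    ``min_w ||x - w H||^2  s.t.  w >= 0`` by nonnegative least squares.

    Used by the leakage-free mode, where H is fitted on training rows only.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    k = H.shape[0]
    W_new = np.empty((X_new.shape[0], k))
    A = H.T  # (m, k)
    for i, x in enumerate(X_new):
        W_new[i], _ = nnls(A, x)
    return W_new


def feature_weight_report(
    model: NMFModel,
    feature_names: Sequence[str],
    top_fraction: float = 0.2,
) -> pd.DataFrame:
    """Tidy table of attribute weights per extracted latent feature.

    Returns all ``k x m`` weights as rows ``(feature_index, attribute_name,
    weight, rank, selected)`` sorted by latent feature then descending
    weight.  ``selected`` marks attributes whose weight reaches the
    ``(1 - top_fraction)`` quantile of that latent feature's row of H —
    the "most important attributes" for that feature.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if len(feature_names) != model.H.shape[1]:
        raise ValueError("feature_names length does not match H columns")
    frames = []
    for f in range(model.k):
        row = model.H[f]
        threshold = np.quantile(row, 1.0 - top_fraction)
        order = np.argsort(-row, kind="stable")
        frames.append(
            pd.DataFrame(
                {
                    "feature_index": f,
                    "attribute_name": [feature_names[j] for j in order],
                    "weight": row[order],
                    "rank": np.arange(1, len(order) + 1),
                    "selected": row[order] >= threshold,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def k_sweep(
    Xp: np.ndarray,
    y: np.ndarray,
    k_values: Iterable[int],
    evaluate: Callable[[np.ndarray, np.ndarray, int], dict],
    select_rule: str = "one_se",
) -> tuple[pd.DataFrame, int]:
    """Sweep the latent dimension and score each k with the downstream model.

    Parameters
    ----------
    evaluate:
        Callback ``(Xp, y, k) -> {"precision": .., "recall": .., "f1": ..,
        "f1_std": .., "n_runs": ..}`` running the repeated-split protocol at
        dimension ``k`` (see :func:`clinpred.pipeline.make_sweep_evaluator`).
    select_rule:
        ``"argmax"`` picks the k with the highest mean F1 (ties to the
        smallest k); ``"one_se"`` (default) picks the smallest k whose mean
        F1 is within one standard error of the best, which is robust to the
        flat-plateau noise of repeated random splits.

    Returns
    -------
    (table, selected_k) where ``table`` has one row per k with mean
    precision, recall and F1.
    """
    ks = sorted(set(int(k) for k in k_values))
    n, m = np.asarray(Xp).shape
    for k in ks:
        if not 1 <= k <= min(n, m):
            raise ValueError(f"k={k} out of range [1, {min(n, m)}]")
    records = []
    for k in ks:
        scores = evaluate(Xp, y, k)
        records.append(
            {
                "k": k,
                "precision": scores["precision"],
                "recall": scores["recall"],
                "f1": scores["f1"],
                "f1_std": scores.get("f1_std", 0.0),
                "n_runs": scores.get("n_runs", 1),
            }
        )
    table = pd.DataFrame.from_records(records)
    f1 = table["f1"].to_numpy()
    best = int(np.argmax(f1))
    if select_rule == "argmax":
        selected = table["k"].iloc[best]
    elif select_rule == "one_se":
        se = table["f1_std"].to_numpy() / np.sqrt(np.maximum(table["n_runs"].to_numpy(), 1))
        cutoff = f1[best] - se[best]
        eligible = np.flatnonzero(f1 >= cutoff)
        selected = table["k"].iloc[int(eligible[0])]
    else:
        raise ValueError(f"unknown select_rule {select_rule!r}")
    return table, int(selected)
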