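"""Column-wise z-score standardization followed by nonnegativity restoration.

Standardization maps each column to zero mean and unit standard deviation
(population form, dividing by n).  Because the factorization stage requires
a nonnegative input and the feature-extraction stage expects values that can
be read as probabilities, a per-column min-max rescale to [0, 1] is applied
afterwards.  Both transforms are affine per column, so within-column rank
order is preserved throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data_model import SampleTable

__all__ = ["ColumnStats", "zscore_fit_transform", "rescale_nonnegative", "preprocess"]


@dataclass
class ColumnStats:
    """Fitted per-column transform parameters.

    ``mu``/``sigma`` parameterize the z-score; ``shift_min``/``shift_range``
    parameterize the subsequent min-max rescale of the standardized values.
    Constant columns (``sigma == 0``) map to all-zeros and are flagged in
    ``constant_columns``.
    """

    mu: np.ndarray
    sigma: np.ndarray
    shift_min: np.ndarray
    shift_range: np.ndarray
    constant_columns: list[int]
    binary_passthrough_columns: list[int]

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("mu", "sigma", "shift_min", "shift_range"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnStats":
        return cls(
            mu=np.asarray(d["mu"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            shift_min=np.asarray(d["shift_min"], dtype=float),
            shift_range=np.asarray(d["shift_range"], dtype=float),
            constant_columns=list(d["constant_columns"]),
            binary_passthrough_columns=list(d["binary_passthrough_columns"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ColumnStats":
        return cls.from_dict(json.loads(Path(path).read_text()))


def zscore_fit_transform(
    table: SampleTable | np.ndarray,
    binary_passthrough: bool = False,
) -> tuple[np.ndarray, ColumnStats]:
    """Standardize each column to mean 0, standard deviation 1.

    Population standard deviation (divide by n) is used so the unit-variance
    postcondition is exact.  Constant columns are mapped to all-zeros rather
    than raising.  With ``binary_passthrough`` columns whose values all lie
    in {0, 1} are copied unchanged (they are already probability-valued).
    """
    X = table.X if isinstance(table, SampleTable) else np.asarray(table, dtype=float)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)  # population form
    constant = np.flatnonzero(sigma == 0.0)
    binary_cols: list[int] = []
    if binary_passthrough:
        binary_cols = [
            j for j in range(X.shape[1]) if np.isin(X[:, j], (0.0, 1.0)).all()
        ]

    safe_sigma = np.where(sigma == 0.0, 1.0, sigma)
    Z = (X - mu) / safe_sigma
    Z[:, constant] = 0.0
    for j in binary_cols:
        Z[:, j] = X[:, j]
        mu[j] = 0.0
        sigma[j] = 1.0

    stats = ColumnStats(
        mu=mu,
        sigma=np.where(np.isin(np.arange(X.shape[1]), constant), 0.0, safe_sigma),
        shift_min=np.zeros(X.shape[1]),
        shift_range=np.ones(X.shape[1]),
        constant_columns=constant.tolist(),
        binary_passthrough_columns=binary_cols,
    )
    return Z, stats


def rescale_nonnegative(Z: np.ndarray, stats: ColumnStats) -> np.ndarray:
    """Affinely map each column of ``Z`` into [0, 1] (min -> 0, max -> 1).

    Zero-range columns map to all-zeros.  The fitted shift parameters are
    recorded on ``stats`` so the identical transform can be applied to new
    samples.  Binary pass-through columns are left untouched.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("standardized matrix contains non-finite values")
    lo = Z.min(axis=0)
    rng = Z.max(axis=0) - lo
    safe = np.where(rng == 0.0, 1.0, rng)
    out = (Z - lo) / safe
    out[:, rng == 0.0] = 0.0
    for j in stats.binary_passthrough_columns:
        out[:, j] = Z[:, j]
        lo[j] = 0.0
        safe[j] = 1.0
    stats.shift_min = lo
    stats.shift_range = safe
    return out


def preprocess(
    table: SampleTable, binary_passthrough: bool = False
) -> tuple[np.ndarray, ColumnStats]:
    """Standardize then rescale: the composed transform feeding factorization."""
    Z, stats = zscore_fit_transform(table, binary_passthrough=binary_passthrough)
    Xp = rescale_nonnegative(Z, stats)
    return Xp, stats


def apply_transform(stats: ColumnStats, X: np.ndarray) -> np.ndarray:
    """Apply a fitted transform to new rows (no refitting, may leave [0,1])."""
    X = np.asarray(X, dtype=float)
    sigma = np.where(stats.sigma == 0.0, 1.0, stats.sigma)
    Z = (X - stats.mu) / sigma
    Z[:, stats.constant_columns] = 0.0
    out = (Z - stats.shift_min) / stats.shift_range
    out[:, stats.constant_columns] = 0.0
    for j in stats.binary_passthrough_columns:
        out[:, j] = X[:, j]
    return out
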