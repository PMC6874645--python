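"""Core tabular types and CSV I/O for patient case-report matrices.

The on-disk convention is a plain UTF-8 CSV with one header row, a first
column named ``sample_id``, one column per numeric clinical feature and an
optional trailing ``label`` column holding binary outcomes (1 = positive /
early-cancer case).  Missing values are rejected: the downstream pipeline
assumes a complete matrix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["SampleTable", "SplitIndices", "read_sample_csv", "write_sample_csv"]


class DataModelError(ValueError):
    """Raised for malformed tables or CSV files."""


@dataclass
class SampleTable:
    """An n-samples by m-features clinical matrix with IDs and optional labels.

    Attributes
    ----------
    sample_ids:
        Opaque string identifiers, one per row.
    feature_names:
        Column names, one per feature.
    X:
        Float matrix of shape ``(n, m)`` in clinical units.
    y:
        Optional binary label vector (0/1 ints) of length ``n``; ``None``
        for unlabeled prediction input.
    """

    sample_ids: list[str]
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DataModelError(f"X must be 2-D, got ndim={self.X.ndim}")
        n, m = self.X.shape
        if n < 1 or m < 1:
            raise DataModelError(f"table must have n >= 1 and m >= 1, got shape {self.X.shape}")
        if len(self.sample_ids) != n:
            raise DataModelError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.feature_names) != m:
            raise DataModelError(
                f"{len(self.feature_names)} feature names for {m} columns"
            )
        if len(set(self.sample_ids)) != n:
            raise DataModelError("duplicate sample ids")
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise DataModelError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape != (n,):
                raise DataModelError(f"label vector length {self.y.shape} != n={n}")
            if not np.isin(self.y, (0, 1)).all():
                bad = int(np.flatnonzero(~np.isin(self.y, (0, 1)))[0])
                raise DataModelError(
                    f"label of sample {self.sample_ids[bad]!r} is "
                    f"{self.y[bad]!r}, expected 0 or 1"
                )
            self.y = self.y.astype(int)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def equals(self, other: "SampleTable", atol: float = 1e-12) -> bool:
        """Value equality within ``atol`` per cell."""
        if self.sample_ids != other.sample_ids:
            return False
        if self.feature_names != other.feature_names:
            return False
        if self.X.shape != other.X.shape:
            return False
        if not np.allclose(self.X, other.X, rtol=0.0, atol=atol):
            return False
        if (self.y is None) != (other.y is None):
            return False
        if self.y is not None and not np.array_equal(self.y, other.y):
            return False
        return True


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint, exhaustive train/test row-index partition of ``range(n)``."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    n: int = field(default=0)

    def __post_init__(self) -> None:
        train = np.asarray(self.train_idx, dtype=int)
        test = np.asarray(self.test_idx, dtype=int)
        object.__setattr__(self, "train_idx", train)
        object.__setattr__(self, "test_idx", test)
        n = self.n or (train.size + test.size)
        object.__setattr__(self, "n", n)
        tr, te = set(train.tolist()), set(test.tolist())
        if tr & te:
            raise DataModelError("train and test indices overlap")
        if tr | te != set(range(n)):
            raise DataModelError("train/test indices do not partition range(n)")


def read_sample_csv(path: str | Path, label_column: str | None = "label") -> SampleTable:
    """Read a sample table from CSV.

    Parameters
    ----------
    path:
        CSV file with a header row; first column is the sample ID.
    label_column:
        Name of the label column, removed from the features and stored as
        ``y``.  Pass ``None`` for unlabeled input.  A named label column
        that is absent from the header is not an error (the table is then
        unlabeled).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataModelError(f"{path}: empty file") from None
        rows = list(reader)

    if len(header) < 2:
        raise DataModelError(f"{path}: need at least an id column and one feature")
    id_name, colnames = header[0], header[1:]

    has_label = label_column is not None and label_column in colnames
    if has_label:
        label_pos = colnames.index(label_column)
        feature_names = colnames[:label_pos] + colnames[label_pos + 1 :]
    else:
        label_pos = -1
        feature_names = list(colnames)
    if not feature_names:
        raise DataModelError(f"{path}: no feature columns")

    sample_ids: list[str] = []
    data: list[list[float]] = []
    labels: list[int] = []
    for r, row in enumerate(rows, start=2):  # header is line 1
        if len(row) != len(header):
            raise DataModelError(
                f"{path}:{r}: expected {len(header)} cells, got {len(row)}"
            )
        sample_ids.append(row[0])
        feats: list[float] = []
        for c, cell in enumerate(row[1:]):
            name = colnames[c]
            if has_label and c == label_pos:
                if cell not in ("0", "1"):
                    raise DataModelError(
                        f"{path}:{r}: label {cell!r} of sample {row[0]!r} "
                        "not in {0, 1}"
                    )
                labels.append(int(cell))
                continue
            try:
                value = float(cell)
            except ValueError:
                raise DataModelError(
                    f"{path}:{r}: non-numeric value {cell!r} in column {name!r}"
                ) from None
            if not np.isfinite(value):
                raise DataModelError(
                    f"{path}:{r}: non-finite value {cell!r} in column {name!r}"
                )
            feats.append(value)
        data.append(feats)

    if not data:
        raise DataModelError(f"{path}: no data rows")
    return SampleTable(
        sample_ids=sample_ids,
        feature_names=feature_names,
        X=np.asarray(data, dtype=float),
        y=np.asarray(labels, dtype=int) if has_label else None,
    )


def write_sample_csv(table: SampleTable, path: str | Path) -> None:
    """Write ``table`` so that :func:`read_sample_csv` recovers it exactly.

    Floats are written with ``repr`` (shortest round-tripping form), so the
    write/read cycle is bit-exact.
    """
    path = Path(path)
    header = ["sample_id", *table.feature_names]
    if table.y is not None:
        header.append("label")
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i, sid in enumerate(table.sample_ids):
            row: list[str] = [sid]
            row.extend(repr(float(v)) for v in table.X[i])
            if table.y is not None:
                row.append(str(int(table.y[i])))
            writer.writerow(row)


def subset_rows(table: SampleTable, idx: Sequence[int] | np.ndarray) -> SampleTable:
    """Row-subset helper preserving IDs, features and labels."""
    idx = np.asarray(idx, dtype=int)
    return SampleTable(
        sample_ids=[table.sample_ids[i] for i in idx],
        feature_names=list(table.feature_names),
        X=table.X[idx],
        y=None if table.y is None else table.y[idx],
    )
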