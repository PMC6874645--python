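"""End-to-end orchestration: preprocess -> NMF -> stratified split -> DBN ->
SVM -> metrics, with repeated-run averaging.

The default protocol factorizes the FULL matrix before splitting (as the
source protocol prescribes), which leaks unlabeled test-row structure into
the factorization; labels are never leaked.  ``strict_no_leakage=True``
instead refits the factorization on training rows only and projects test
rows onto the fitted basis by nonnegative least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import SampleTable, SplitIndices
from .dbn import dbn_finetune, dbn_pretrain, dbn_transform
from .metrics import METRIC_NAMES, MetricsReport, compute_metrics, confusion
from .nmf import k_sweep, nmf_factorize, project_rows
from .preprocessing import preprocess
from .svm import svm_fit, svm_predict

__all__ = [
    "PipelineConfig",
    "RunResult",
    "stratified_split",
    "run_once",
    "run_repeated",
    "sweep_dimensions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Hyperparameters of the full pipeline.

    ``hidden_sizes`` are the DBN hidden-layer widths stacked on top of the
    k-dimensional factorized input (last entry = exported feature width).
    """

    k: int = 14
    hidden_sizes: tuple[int, ...] = (10, 4)
    pretrain_epochs: int = 50
    finetune_epochs: int = 1000
    dbn_learning_rate: float = 0.1
    finetune_learning_rate: float = 2.0
    batch_size: int = 10
    cd_steps: int = 1
    svm_C: float = 1.0
    svm_tol: float = 1e-3
    test_fraction: float = 0.10
    n_runs: int = 100
    seed: int = 0
    strict_no_leakage: bool = False
    binary_passthrough: bool = False
    nmf_max_iter: int = 300
    nmf_tol: float = 1e-6
    nmf_restarts: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(f"test_fraction={self.test_fraction} not in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.hidden_sizes:
            raise ValueError("need at least one hidden layer")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "hidden_sizes" in d:
            d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunResult:
    """Per-run reports plus aggregate mean/std for the five measures."""

    reports: list[MetricsReport]
    mean: dict[str, float]
    std: dict[str, float]
    config: PipelineConfig
    run_seeds: list[int]

    def per_run_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.reports]
        frame = pd.DataFrame(rows)
        frame.insert(0, "run", np.arange(len(rows)))
        frame["run_seed"] = self.run_seeds
        return frame

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": list(METRIC_NAMES),
                "mean": [self.mean[m] for m in METRIC_NAMES],
                "std": [self.std[m] for m in METRIC_NAMES],
            }
        )


def stratified_split(
    y: np.ndarray, test_fraction: float, seed: int | None
) -> SplitIndices:
    """Per-class random partition: round((1 - test_fraction) * class_count)
    rows of each class go to train, the rest to test."""
    y = np.asarray(y)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction={test_fraction} not in (0, 1)")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        n_train = int(np.floor((1.0 - test_fraction) * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size)
        perm = rng.permutation(idx.size)
        train_parts.append(idx[perm[:n_train]])
        test_parts.append(idx[perm[n_train:]])
    return SplitIndices(
        train_idx=np.sort(np.concatenate(train_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
        n=y.size,
    )


def _unit_scale_fit(X: np.ndarray) -> np.ndarray:
    """Per-column max used to map nonnegative factor scores into [0, 1]."""
    top = X.max(axis=0)
    return np.where(top == 0.0, 1.0, top)


def _split_seeds(master_seed: int, run_index: int) -> list[int]:
    """Counter-based per-run seed derivation: independent yet reproducible."""
    ss = np.random.SeedSequence((master_seed, run_index))
    return [int(s.generate_state(1)[0]) for s in ss.spawn(4)]


def _evaluate_split(
    X1: np.ndarray,
    Xp: np.ndarray | None,
    y: np.ndarray,
    config: PipelineConfig,
    run_index: int,
) -> MetricsReport:
    """Split -> (optionally refit NMF) -> DBN -> SVM -> metrics for one run.

    ``X1`` is the full-matrix factorization's row-factor matrix (ignored in
    strict mode); ``Xp`` is the preprocessed matrix, needed only for the
    strict per-split refit.
    """
    split_seed, nmf_seed, pretrain_seed, finetune_seed = _split_seeds(
        config.seed, run_index
    )
    split = stratified_split(y, config.test_fraction, split_seed)
    tr, te = split.train_idx, split.test_idx

    if config.strict_no_leakage:
        assert Xp is not None
        model = nmf_factorize(
            Xp[tr],
            config.k,
            max_iter=config.nmf_max_iter,
            tol=config.nmf_tol,
            restarts=config.nmf_restarts,
            seed=nmf_seed,
        )
        X1_train = model.W
        X1_test = project_rows(model.H, Xp[te])
    else:
        X1_train, X1_test = X1[tr], X1[te]

    scale = _unit_scale_fit(X1_train)
    V_train = np.clip(X1_train / scale, 0.0, 1.0)
    V_test = np.clip(X1_test / scale, 0.0, 1.0)

    layer_sizes = [config.k, *config.hidden_sizes]
    dbn = dbn_pretrain(
        V_train,
        layer_sizes,
        epochs=config.pretrain_epochs,
        learning_rate=config.dbn_learning_rate,
        batch_size=config.batch_size,
        cd_steps=config.cd_steps,
        seed=pretrain_seed,
    )
    dbn = dbn_finetune(
        dbn,
        V_train,
        y[tr],
        epochs=config.finetune_epochs,
        learning_rate=config.finetune_learning_rate,
        seed=finetune_seed,
    )
    X2_train = dbn_transform(dbn, V_train)
    X2_test = dbn_transform(dbn, V_test)

    svm = svm_fit(X2_train, y[tr], C=config.svm_C, tol=config.svm_tol)
    y_pred = svm_predict(svm, X2_test)
    return compute_metrics(confusion(y[te], y_pred))


def _factorize_full(
    Xp: np.ndarray, config: PipelineConfig
) -> np.ndarray:
    # fixed sub-stream tag keeps the full-matrix factorization independent
    # of the per-run streams
    nmf_seed = int(
        np.random.SeedSequence((config.seed, 0x6E6D66)).generate_state(1)[0]
    )
    model = nmf_factorize(
        Xp,
        config.k,
        max_iter=config.nmf_max_iter,
        tol=config.nmf_tol,
        restarts=config.nmf_restarts,
        seed=nmf_seed,
    )
    return model.W


def run_once(
    table: SampleTable, config: PipelineConfig, run_index: int = 0
) -> MetricsReport:
    """Execute all stages once and return test-set metrics.

    Fully reproducible given ``config.seed`` and ``run_index``.
    """
    if table.y is None:
        raise ValueError("labeled table required")
    Xp, _ = preprocess(table, binary_passthrough=config.binary_passthrough)
    X1 = None if config.strict_no_leakage else _factorize_full(Xp, config)
    return _evaluate_split(X1, Xp, table.y, config, run_index)


def run_repeated(table: SampleTable, config: PipelineConfig) -> RunResult:
    """``config.n_runs`` independent splits with deterministic per-run seeds.

    In the default (leaky) mode the preprocessing and factorization happen
    once on the full matrix; everything downstream of the split is retrained
    per run.
    """
    if table.y is None:
        raise ValueError("labeled table required")
    Xp, _ = preprocess(table, binary_passthrough=config.binary_passthrough)
    X1 = None if config.strict_no_leakage else _factorize_full(Xp, config)
    logger.info(
        "pipeline: n=%d m=%d k=%d runs=%d strict=%s",
        table.n, table.m, config.k, config.n_runs, config.strict_no_leakage,
    )
    reports = [
        _evaluate_split(X1, Xp, table.y, config, i) for i in range(config.n_runs)
    ]
    values = {m: np.array([getattr(r, m) for r in reports]) for m in METRIC_NAMES}
    return RunResult(
        reports=reports,
        mean={m: float(v.mean()) for m, v in values.items()},
        std={m: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for m, v in values.items()},
        config=config,
        run_seeds=[_split_seeds(config.seed, i)[0] for i in range(config.n_runs)],
    )


def _repeated_on_matrix(
    Xp: np.ndarray, y: np.ndarray, config: PipelineConfig
) -> dict[str, float]:
    X1 = None if config.strict_no_leakage else _factorize_full(Xp, config)
    reports = [
        _evaluate_split(X1, Xp, y, config, i) for i in range(config.n_runs)
    ]
    f1 = np.array([r.f1 for r in reports])
    return {
        "precision": float(np.mean([r.precision for r in reports])),
        "recall": float(np.mean([r.recall for r in reports])),
        "f1": float(f1.mean()),
        "f1_std": float(f1.std(ddof=1)) if f1.size > 1 else 0.0,
        "n_runs": config.n_runs,
    }


def sweep_dimensions(
    table: SampleTable,
    k_values: Iterable[int],
    config: PipelineConfig,
    select_rule: str = "one_se",
) -> tuple[pd.DataFrame, int]:
    """Run the latent-dimension sweep on a labeled table.

    For each k the repeated-split protocol is evaluated at that dimension;
    returns the per-k precision/recall/F1 table and the selected k.
    """
    if table.y is None:
        raise ValueError("labeled table required")
    Xp, _ = preprocess(table, binary_passthrough=config.binary_passthrough)

    def evaluate(Xp_: np.ndarray, y_: np.ndarray, k: int) -> dict:
        cfg = PipelineConfig.from_dict({**config.to_dict(), "k": k})
        return _repeated_on_matrix(Xp_, y_, cfg)

    return k_sweep(Xp, table.y, k_values, evaluate, select_rule=select_rule)
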