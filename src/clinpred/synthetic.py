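"""Seeded generator of synthetic clinical tables with planted structure.

Real early-cancer case-report cohorts are private, so the pipeline is
exercised on tables that emulate their statistical shape: ~50 nonnegative
features in three blocks (binary demographic/behavioral, continuous
endoscopic, continuous blood-test), a planted low-rank latent factor
linking a subset of features to the label, a handful of pure-noise
(redundant) columns, and a strongly imbalanced binary label.

The label depends on the data only through the latent sample factors U:
logits are a linear function of the rows of U, and the logistic intercept
is calibrated so the realized prevalence matches the configured rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .data_model import SampleTable

__all__ = ["SyntheticConfig", "generate", "make_reference_fixture", "REFERENCE_SEED"]

REFERENCE_SEED = 20191122

_BLOCK_PREFIXES = ("demo", "endo", "blood")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    feature_blocks:
        Sizes of the (binary demographic, continuous endoscopic, continuous
        blood) blocks; must sum to ``m``.  Only the first block is
        binarized.
    label_signal:
        Scale of the logits (standardized latent score times this factor);
        larger values make the label more deterministic given U.
    class_gap:
        Optional additive shift of the first latent factor for positive
        samples, creating a separable-by-construction table (used by
        separability tests; 0 disables it).
    deterministic_labels:
        If True, exactly ``round(n * positive_rate)`` samples with the
        highest logits are labeled positive (no Bernoulli draw).
    """

    n: int = 270
    m: int = 50
    k_true: int = 5
    positive_rate: float = 0.10
    noise_sd: float = 0.10
    n_noise_features: int = 10
    feature_blocks: tuple[int, int, int] = (15, 20, 15)
    label_signal: float = 4.0
    class_gap: float = 0.0
    deterministic_labels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.feature_blocks) != self.m:
            raise ValueError(
                f"feature_blocks {self.feature_blocks} do not sum to m={self.m}"
            )
        if not 1 <= self.k_true <= min(self.n, self.m):
            raise ValueError(f"k_true={self.k_true} out of range")
        if not 0.0 < self.positive_rate < 1.0:
            raise ValueError(f"positive_rate={self.positive_rate} not in (0, 1)")
        target = round(self.n * self.positive_rate)
        if target < 1 or target >= self.n:
            raise ValueError(
                f"positive_rate={self.positive_rate} unreachable at n={self.n}"
            )
        if self.n_noise_features < 0 or self.n_noise_features >= self.m:
            raise ValueError("n_noise_features must be in [0, m)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_blocks"] = list(self.feature_blocks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "feature_blocks" in d:
            d["feature_blocks"] = tuple(d["feature_blocks"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _feature_names(config: SyntheticConfig) -> list[str]:
    names = []
    for prefix, size in zip(_BLOCK_PREFIXES, config.feature_blocks):
        names.extend(f"{prefix}_{i + 1:02d}" for i in range(size))
    return names


def _draw_labels(
    logits: np.ndarray, target: int, rng: np.random.Generator, deterministic: bool
) -> np.ndarray:
    """Labels with exactly ``target`` positives.

    Logistic mode draws y_i = 1[u_i < sigmoid(logits_i + c)] with a shared
    intercept c; since the positive count is monotone in c, c is chosen so
    the count equals the target exactly (equivalent to thresholding
    logit(u_i) - logits_i).  Deterministic mode thresholds the logits
    directly.
    """
    n = logits.shape[0]
    if deterministic:
        scores = -logits
    else:
        u = rng.uniform(size=n)
        scores = np.log(u / (1.0 - u)) - logits
    order = np.argsort(scores, kind="stable")
    y = np.zeros(n, dtype=int)
    y[order[:target]] = 1
    return y


def generate(config: SyntheticConfig) -> SampleTable:
    """Generate a synthetic clinical table; deterministic given the seed.

    X = clip(U @ V + noise, 0) with entrywise-nonnegative gamma factors U
    (n x k_true) and V (k_true x m); the binary block is thresholded at the
    column median; ``n_noise_features`` randomly chosen columns are
    regenerated as label-irrelevant pure noise.
    """
    rng = np.random.default_rng(config.seed)
    n, m, k = config.n, config.m, config.k_true

    U = rng.gamma(shape=2.0, scale=0.5, size=(n, k))
    V = rng.gamma(shape=2.0, scale=0.5, size=(k, m))
    # mixed-sign label weights: the label is a contrast between latent
    # factors, so it cannot be recovered from a lower-rank factorization
    beta = rng.normal(size=k)

    score = U @ beta
    sd = score.std()
    logits = config.label_signal * (score - score.mean()) / (sd if sd > 0 else 1.0)
    target = round(n * config.positive_rate)
    y = _draw_labels(logits, target, rng, config.deterministic_labels)

    if config.class_gap != 0.0:
        # shift positives along the positive part of the label direction:
        # increases their latent score while keeping U entrywise nonnegative
        direction = np.clip(beta, 0.0, None)
        norm = np.linalg.norm(direction)
        if norm == 0.0:
            direction = np.ones(k)
            norm = np.sqrt(k)
        U = U.copy()
        U[y == 1] += config.class_gap * direction / norm

    latent = U @ V
    if config.noise_sd > 0:
        latent = latent + rng.normal(0.0, config.noise_sd, size=(n, m))
    X = np.clip(latent, 0.0, None)

    n_binary = config.feature_blocks[0]
    noise_cols = (
        rng.choice(m, size=config.n_noise_features, replace=False)
        if config.n_noise_features
        else np.empty(0, dtype=int)
    )
    signal_mean = X.mean() if X.size else 1.0
    for j in noise_cols:
        if j < n_binary:
            X[:, j] = rng.integers(0, 2, size=n).astype(float)
        else:
            X[:, j] = rng.gamma(shape=2.0, scale=max(signal_mean, 1e-6) / 2.0, size=n)

    # binarize the demographic block at each column's median
    for j in range(n_binary):
        if j in noise_cols:
            continue
        X[:, j] = (X[:, j] > np.median(X[:, j])).astype(float)

    return SampleTable(
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
        feature_names=_feature_names(config),
        X=X,
        y=y,
    )


def make_reference_fixture(noiseless: bool = False) -> SampleTable:
    """The canonical seeded fixture used across the test suite and docs.

    ``noiseless=True`` returns the continuous-only, zero-noise variant whose
    matrix has numerical rank exactly ``k_true``.
    """
    if noiseless:
        config = SyntheticConfig(
            feature_blocks=(0, 25, 25),
            noise_sd=0.0,
            n_noise_features=0,
            seed=REFERENCE_SEED,
        )
    else:
        config = SyntheticConfig(seed=REFERENCE_SEED)
    return generate(config)
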