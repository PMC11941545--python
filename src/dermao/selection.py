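"""Binary wrapper feature selection driven by the Aquila Optimizer.

A candidate feature subset is encoded as a binary mask over the D
columns (1 = selected).  The optimizer searches the continuous box
[0, 1]^D; positions are binarized at a fixed threshold and scored with
the convex wrapper objective

    F(mask) = mu * E(mask) + (1 - mu) * |mask| / D,

where E is the stratified cross-validated classification error of a
cheap classifier (k-nearest-neighbour by default) restricted to the
selected columns, and |mask| the number of selected features.  Lower is
better: the first term rewards discrimination, the second parsimony.
With the default mu = 0.99 the error term dominates and the size
penalty acts as a tie-break toward smaller subsets.

Cross-validation folds are frozen once per run (from the seed), so the
objective is a deterministic function of the mask and can be memoized;
caching changes runtime only, never results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from . import ao
from .metrics import as_percent, kfold_indices

__all__ = [
    "SelectionMask",
    "FitnessWeights",
    "FSConfig",
    "SelectionResult",
    "FitnessEvaluator",
    "binarize_position",
    "fitness",
    "select_features",
    "reduction_percentage",
]


@dataclass(frozen=True)
class SelectionMask:
    """Binary feature-inclusion vector; at least one bit must be set."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.ndim != 1:
            raise ValueError("mask bits must be a 1-D vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("mask bits must be 0/1")
        if bits.sum() == 0:
            raise ValueError("mask must select at least one feature")
        bits.setflags(write=False)
        object.__setattr__(self, "bits", bits)

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def __len__(self) -> int:
        return self.bits.shape[0]

    def as_string(self) -> str:
        return "".join(map(str, self.bits.tolist()))


@dataclass(frozen=True)
class FitnessWeights:
    """mu weights CV error against subset size; (1-mu) weights size."""

    mu: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")


@dataclass(frozen=True)
class FSConfig:
    ao: ao.AOConfig = field(default_factory=ao.AOConfig)
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    classifier: str = "knn"
    knn_k: int = 5
    cv_folds: int = 5
    binarize_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ValueError("binarize_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class SelectionResult:
    mask: SelectionMask
    fitness: float
    cv_error: float
    features_before: int
    features_after: int
    reduction_pct: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "mask": self.mask.as_string(),
                "fitness": self.fitness,
                "cv_error": self.cv_error,
                "features_before": self.features_before,
                "features_after": self.features_after,
                "reduction_pct": self.reduction_pct,
            },
            indent=2,
        )


def binarize_position(position: np.ndarray, threshold: float = 0.5) -> SelectionMask:
    """Threshold a continuous position in [0, 1]^D into a mask.

    Bit j is set iff position_j >= threshold.  An all-zero result is
    rescued by forcing the single largest component on (lowest index on
    ties), since the wrapper objective is undefined for empty subsets.
    """
    position = np.asarray(position, dtype=float)
    bits = (position >= threshold).astype(np.int8)
    if bits.sum() == 0:
        bits[int(np.argmax(position))] = 1
    return SelectionMask(bits)


def _make_classifier(config: FSConfig):
    if config.classifier == "knn":
        return KNeighborsClassifier(n_neighbors=config.knn_k)
    raise ValueError(f"unknown classifier {config.classifier!r}")


class FitnessEvaluator:
    """Memoized wrapper objective with folds frozen at construction.

    Freezing the folds makes the objective a pure function of the mask,
    which (a) lets the exhaustive small-D oracle and the optimizer score
    masks identically and (b) makes memoization semantically invisible.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        config: FSConfig | None = None,
        cache: bool = True,
    ) -> None:
        config = config or FSConfig()
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1 (1 = malignant)")
        self.config = config
        self.mu = config.weights.mu
        self.n_features = self.features.shape[1]
        self.folds = kfold_indices(
            len(self.labels), config.cv_folds, self.labels, seed=config.seed
        )
        self._cache: dict[bytes, float] | None = {} if cache else None
        self.evaluations = 0

    def cv_error(self, mask: SelectionMask) -> float:
        """Stratified k-fold misclassification rate on the selected columns."""
        cols = mask.indices
        X = self.features[:, cols]
        errors = 0
        total = 0
        for train_idx, test_idx in self.folds:
            clf = _make_classifier(self.config)
            clf.fit(X[train_idx], self.labels[train_idx])
            pred = clf.predict(X[test_idx])
            errors += int(np.sum(pred != self.labels[test_idx]))
            total += len(test_idx)
        return errors / total

    def __call__(self, mask: SelectionMask) -> float:
        key = mask.bits.tobytes()
        if self._cache is not None and key in self._cache:
            return self._cache[key]
        err = self.cv_error(mask)
        value = self.mu * err + (1.0 - self.mu) * mask.selected_count / self.n_features
        self.evaluations += 1
        if self._cache is not None:
            self._cache[key] = value
        return value


def fitness(
    mask: SelectionMask,
    features: np.ndarray,
    labels: np.ndarray,
    weights: FitnessWeights | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> float:
    """One-shot wrapper fitness F = mu*E + (1-mu)*|mask|/D."""
    config = FSConfig(
        weights=weights or FitnessWeights(), cv_folds=cv_folds, seed=seed
    )
    return FitnessEvaluator(features, labels, config, cache=False)(mask)


def select_features(
    features: np.ndarray,
    labels: np.ndarray,
    config: FSConfig | None = None,
    evaluator: FitnessEvaluator | None = None,
) -> SelectionResult:
    """Search for the best feature subset with the Aquila Optimizer.

    Optimizes the wrapper objective over [0, 1]^D (positions binarized
    at ``config.binarize_threshold``) and reports the best mask, its CV
    error, and the before/after reduction accounting.
    """
    config = config or FSConfig()
    features = np.asarray(features, dtype=float)
    d = features.shape[1]
    if d < 2:
        raise ValueError("need at least 2 features to select from")
    if len(labels) < 2 * config.cv_folds:
        raise ValueError("need at least 2*cv_folds samples")
    if evaluator is None:
        evaluator = FitnessEvaluator(features, labels, config)

    def objective(position: np.ndarray) -> float:
        return evaluator(binarize_position(position, config.binarize_threshold))

    rng = np.random.default_rng(config.seed)
    bounds = ao.Bounds.cube(d, 0.0, 1.0)
    result = ao.optimize(objective, bounds, config.ao, rng=rng)

    best_mask = binarize_position(result.best_position, config.binarize_threshold)
    return SelectionResult(
        mask=best_mask,
        fitness=float(result.best_fitness),
        cv_error=evaluator.cv_error(best_mask),
        features_before=d,
        features_after=best_mask.selected_count,
        reduction_pct=reduction_percentage(d, best_mask.selected_count),
    )


def reduction_percentage(features_before: int, features_after: int) -> float:
    """100 * (before - after) / before, half-up to two decimals."""
    if not (0 < features_after <= features_before):
        raise ValueError("need 0 < features_after <= features_before")
    return as_percent((features_before - features_after) / features_before)
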