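"""End-to-end orchestration: simulate -> (train/extract) -> select ->
classify -> evaluate, plus the with/without-selection ablation harness.

Two modes are supported.  ``features`` mode starts from a feature table
(generated or loaded from CSV) and exercises selection + classification
only; ``images`` mode starts from lesion images, trains the compact
convnet, extracts penultimate-layer features, and then proceeds
identically.  The final classifier is k-nearest-neighbour on the
selected columns; malignant is the positive class throughout.

Every run is a pure function of its config and seed: reports emitted
twice from the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.neighbors import KNeighborsClassifier

from . import ao
from .features import (
    CNNSpec,
    PreprocessConfig,
    TrainConfig,
    extract_features,
    preprocess,
    train_cnn,
)
from .metrics import (
    MetricsReport,
    confusion_from_predictions,
    metrics_report,
    roc_curve_points,
)
from .selection import FSConfig, SelectionResult, select_features
from .synthetic import (
    SyntheticFeatureSpec,
    SyntheticImageSpec,
    gen_feature_dataset,
    gen_image_arrays,
    read_feature_csv,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "AblationReport",
    "run_pipeline",
    "run_ablation",
    "write_report",
    "load_config",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "features"  # "features" | "images"
    seed: int = 0
    seeds: tuple[int, ...] = (0,)
    test_fraction: float = 0.25
    feature_spec: SyntheticFeatureSpec = field(default_factory=SyntheticFeatureSpec)
    image_spec: SyntheticImageSpec = field(default_factory=SyntheticImageSpec)
    n_per_class: int = 100
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cnn: CNNSpec = field(default_factory=CNNSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    fs: FSConfig = field(default_factory=FSConfig)
    feature_csv: str | None = None  # load instead of generating (features mode)
    knn_k: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("features", "images"):
            raise ValueError("mode must be 'features' or 'images'")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        if not self.seeds:
            raise ValueError("seeds must be nonempty")

    def reseeded(self, seed: int) -> "PipelineConfig":
        """Rebuild the config with every stage seed derived from ``seed``."""
        return dataclasses.replace(
            self,
            seed=seed,
            feature_spec=dataclasses.replace(self.feature_spec, seed=seed),
            image_spec=dataclasses.replace(self.image_spec, seed=seed),
            train=dataclasses.replace(self.train, seed=seed),
            fs=dataclasses.replace(
                self.fs, seed=seed, ao=dataclasses.replace(self.fs.ao, seed=seed)
            ),
        )

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    metrics: MetricsReport
    selection: SelectionResult
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    config_snapshot: dict
    timings: dict[str, float]
    cnn_history: dict[str, list[float]] | None = None


@dataclass
class AblationReport:
    """Paired evaluation on identical splits: all features vs selected."""

    without_selection: MetricsReport
    with_selection: MetricsReport
    deltas: dict[str, float]
    features_without: int
    features_with: int
    selection: SelectionResult
    split_hash: str


def _split(labels: np.ndarray, test_fraction: float, seed: int):
    """Stratified train/test split; deterministic in the seed."""
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(rng.permutation(idx)[:n_test].tolist())
    mask = np.zeros(len(labels), dtype=bool)
    mask[test_idx] = True
    return np.flatnonzero(~mask), np.flatnonzero(mask)


def _split_hash(train_idx: np.ndarray, test_idx: np.ndarray) -> str:
    payload = train_idx.tobytes() + b"|" + test_idx.tobytes()
    return hashlib.sha256(payload).hexdigest()


def _knn_eval(X_train, y_train, X_test, y_test, k: int):
    clf = KNeighborsClassifier(n_neighbors=k)
    clf.fit(X_train, y_train)
    y_pred = clf.predict(X_test)
    scores = clf.predict_proba(X_test)[:, list(clf.classes_).index(1)]
    return y_pred, scores, metrics_report(y_test, y_pred, scores)


def _feature_table(config: PipelineConfig):
    """Stage 1: obtain the feature matrix (features mode)."""
    if config.feature_csv is not None:
        return read_feature_csv(config.feature_csv)
    X, y, _ = gen_feature_dataset(config.feature_spec)
    return X, y


def _image_features(config: PipelineConfig, train_idx, labels, images):
    """Train the convnet on the training split and extract features for
    every image; the test split never influences the weights."""
    model, history = train_cnn(
        images[train_idx], labels[train_idx], config.cnn, config.train
    )
    return extract_features(model, images), history


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full method for one seed and return metrics + selection."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    history = None

    if config.mode == "features":
        X, y = _feature_table(config)
        timings["data"] = time.perf_counter() - t0
        train_idx, test_idx = _split(y, config.test_fraction, config.seed)
    else:
        raw, y, _ = gen_image_arrays(config.n_per_class, config.image_spec)
        images = np.stack([preprocess(im, config.preprocess) for im in raw])
        timings["data"] = time.perf_counter() - t0
        train_idx, test_idx = _split(y, config.test_fraction, config.seed)
        t1 = time.perf_counter()
        X, history = _image_features(config, train_idx, y, images)
        timings["cnn"] = time.perf_counter() - t1
    logger.info("pipeline seed=%d mode=%s n=%d D=%d", config.seed, config.mode, *X.shape)

    t1 = time.perf_counter()
    selection = select_features(X[train_idx], y[train_idx], config.fs)
    timings["selection"] = time.perf_counter() - t1

    t1 = time.perf_counter()
    cols = selection.mask.indices
    y_pred, scores, report = _knn_eval(
        X[train_idx][:, cols], y[train_idx], X[test_idx][:, cols], y[test_idx],
        config.knn_k,
    )
    timings["classify"] = time.perf_counter() - t1

    return PipelineResult(
        metrics=report,
        selection=selection,
        y_true=y[test_idx],
        y_pred=y_pred,
        scores=scores,
        config_snapshot=config.snapshot(),
        timings=timings,
        cnn_history=history,
    )


def run_ablation(config: PipelineConfig) -> AblationReport:
    """Evaluate the identical split with all features vs AO-selected ones.

    Both arms share the same train/test indices and the same classifier;
    they differ only in the column subset, so any metric delta is
    attributable to the selection stage.
    """
    if config.mode == "features":
        X, y = _feature_table(config)
        train_idx, test_idx = _split(y, config.test_fraction, config.seed)
    else:
        raw, y, _ = gen_image_arrays(config.n_per_class, config.image_spec)
        images = np.stack([preprocess(im, config.preprocess) for im in raw])
        train_idx, test_idx = _split(y, config.test_fraction, config.seed)
        X, _hist = _image_features(config, train_idx, y, images)

    _, _, without = _knn_eval(
        X[train_idx], y[train_idx], X[test_idx], y[test_idx], config.knn_k
    )
    selection = select_features(X[train_idx], y[train_idx], config.fs)
    cols = selection.mask.indices
    _, _, with_sel = _knn_eval(
        X[train_idx][:, cols], y[train_idx], X[test_idx][:, cols], y[test_idx],
        config.knn_k,
    )
    deltas = {
        name: getattr(with_sel, name) - getattr(without, name)
        for name in ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")
    }
    return AblationReport(
        without_selection=without,
        with_selection=with_sel,
        deltas=deltas,
        features_without=X.shape[1],
        features_with=selection.features_after,
        selection=selection,
        split_hash=_split_hash(train_idx, test_idx),
    )


def replicate(config: PipelineConfig) -> pd.DataFrame:
    """Run the pipeline once per seed in ``config.seeds``; returns a
    per-seed metric table (mean and sd summarize run-to-run variability)."""
    rows = []
    for seed in config.seeds:
        result = run_pipeline(config.reseeded(seed))
        rows.append({"seed": seed, **dataclasses.asdict(result.metrics)})
    return pd.DataFrame(rows)


def write_report(result: PipelineResult, out_dir) -> dict[str, Path]:
    """Emit metrics JSON, ROC CSV, confusion JSON, selection JSON, a
    config snapshot (with content hash) and a plain-text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["metrics"] = out / "metrics.json"
    paths["metrics"].write_text(result.metrics.to_json())

    cm = confusion_from_predictions(result.y_true, result.y_pred)
    paths["confusion"] = out / "confusion.json"
    paths["confusion"].write_text(cm.to_json())
    paths["confusion_txt"] = out / "confusion.txt"
    paths["confusion_txt"].write_text(cm.render() + "\n")

    roc = roc_curve_points(result.scores, result.y_true)
    paths["roc"] = out / "roc.csv"
    pd.DataFrame(roc, columns=["fpr", "tpr", "threshold"]).to_csv(
        paths["roc"], index=False
    )

    paths["selection"] = out / "selection.json"
    paths["selection"].write_text(result.selection.to_json())

    snapshot = yaml.safe_dump(result.config_snapshot, sort_keys=True)
    digest = hashlib.sha256(snapshot.encode()).hexdigest()
    paths["config"] = out / "config_snapshot.yaml"
    paths["config"].write_text(f"# sha256: {digest}\n" + snapshot)
    logger.info("config snapshot sha256=%s", digest)

    pct = result.metrics.as_percent_dict()
    summary = [
        "melanoma recognition pipeline report",
        f"config sha256: {digest}",
        f"features: {result.selection.features_before} -> "
        f"{result.selection.features_after} "
        f"({result.selection.reduction_pct:.2f}% reduction)",
    ]
    summary += [f"{name}: {value:.2f}%" for name, value in pct.items()]
    summary += [f"[timing] {k}: {v:.2f}s" for k, v in result.timings.items()]
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text("\n".join(summary) + "\n")
    return paths


# ---------------------------------------------------------------------------
# YAML config loading (CLI entry)

def _build(cls, data: dict | None):
    if not data:
        return cls()
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file of nested sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    nested = {
        "feature_spec": SyntheticFeatureSpec,
        "image_spec": SyntheticImageSpec,
        "preprocess": PreprocessConfig,
        "cnn": CNNSpec,
        "train": TrainConfig,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = _build(nested[key], value)
        elif key == "fs":
            fs_raw = dict(value or {})
            ao_cfg = _build(ao.AOConfig, fs_raw.pop("ao", None))
            from .selection import FitnessWeights

            weights = _build(FitnessWeights, fs_raw.pop("weights", None))
            kwargs["fs"] = FSConfig(ao=ao_cfg, weights=weights, **fs_raw)
        elif key == "seeds":
            kwargs["seeds"] = tuple(value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)
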