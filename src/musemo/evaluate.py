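"""Training, 10-fold cross-validated evaluation, and the experiment suites.

Folds are segment-level and stratified by default; a subject/trial-grouped
splitter is available for leakage-aware splits (segment-level folds share
trials between train and test, so their accuracies measure within-trial
generalization only — see docs/methods.md).

Metrics: accuracy, precision and F1 on the positive class (label 1), and
rank-based AUC from the positive-class probability.  Per-fold models are
re-initialized from (seed, fold) so folds are independent but the whole
run reproduces bit-for-bit.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    roc_auc_score,
)
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold

from .features import DEMatrix, select_bands
from .model import CSBNModel, ModelSpec, build_model, model_spec_for_input
from .nn import Adam, cross_entropy_logits, Tensor

__all__ = [
    "TrainConfig", "Metrics", "FoldResult", "kfold_indices", "train_model",
    "evaluate", "metrics_from_predictions", "cross_validate",
    "run_ablation_suite", "run_band_suite", "BAND_SUITE_SUBSETS",
]

logger = logging.getLogger(__name__)

#: The 4 singleton + 6 pair + 4 triple band subsets of the band experiments.
BAND_SUITE_SUBSETS: list[tuple[str, ...]] = (
    [(b,) for b in ("theta", "alpha", "beta", "gamma")]
    + list(itertools.combinations(("theta", "alpha", "beta", "gamma"), 2))
    + list(itertools.combinations(("theta", "alpha", "beta", "gamma"), 3))
)


@dataclass
class TrainConfig:
    """Optimization settings: Adam + categorical cross-entropy."""

    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    task: str = "valence"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.task not in ("valence", "arousal"):
            raise ValueError("task must be 'valence' or 'arousal'")


@dataclass
class Metrics:
    accuracy: float
    precision: float
    f1: float
    auc: float | None

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class FoldResult:
    fold_index: int
    metrics: Metrics
    history: dict = field(default_factory=dict)


def _fold_seed(seed: int, fold: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(fold,))
    return int(ss.generate_state(1)[0] % (2**31))


def kfold_indices(n: int, k: int, labels=None, stratify: bool = True,
                  seed: int = 0, groups=None):
    """Disjoint covering test folds as ``[(train_idx, test_idx), ...]``.

    With ``stratify`` (and labels), per-fold class proportions stay within
    one sample of the global proportions.  Passing ``groups`` switches to
    group-aware folds (no group straddles train and test).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    X_dummy = np.zeros((n, 1))
    if groups is not None:
        splitter = GroupKFold(n_splits=k)
        return [(tr, te) for tr, te in splitter.split(X_dummy, labels, groups)]
    if stratify and labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(X_dummy, labels)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(X_dummy)]


def train_model(spec: ModelSpec, features: np.ndarray, labels: np.ndarray,
                cfg: TrainConfig) -> tuple[CSBNModel, dict]:
    """Fit one network with Adam on cross-entropy; deterministic per seed.

    Returns ``(model, history)`` with per-epoch mean loss and training
    accuracy.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.intp)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels are misaligned")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    model = build_model(spec, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(7,)))
    n = X.shape[0]
    history = {"loss": [], "accuracy": []}
    model.train()
    for _ in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs > 1 sample
            xb = Tensor(X[idx])
            logits = model(xb)
            loss = cross_entropy_logits(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)
    return model, history


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                             y_score: np.ndarray | None = None) -> Metrics:
    """Accuracy/precision/F1 from hard predictions; AUC from scores."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    auc = None
    if y_score is not None:
        if len(np.unique(y_true)) < 2:
            warnings.warn("single-class test fold: AUC undefined, reported as None")
        else:
            auc = float(roc_auc_score(y_true, y_score))
    return Metrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(precision_score(y_true, y_pred, pos_label=1,
                                        zero_division=0)),
        f1=float(f1_score(y_true, y_pred, pos_label=1, zero_division=0)),
        auc=auc,
    )


def evaluate(model: CSBNModel, features: np.ndarray,
             labels: np.ndarray) -> Metrics:
    """Score a trained model: argmax predictions, positive-class AUC."""
    proba = model.predict_proba(features)
    return metrics_from_predictions(labels, proba.argmax(axis=1), proba[:, 1])


def _aggregate(folds: list[FoldResult]) -> dict[str, Metrics]:
    def agg(fn):
        vals = {}
        for name in ("accuracy", "precision", "f1", "auc"):
            xs = [getattr(f.metrics, name) for f in folds
                  if getattr(f.metrics, name) is not None]
            vals[name] = float(fn(xs)) if xs else None
        return Metrics(**vals)

    return {"mean": agg(np.mean), "max": agg(np.max)}


def cross_validate(spec: ModelSpec, features: np.ndarray, labels: np.ndarray,
                   cfg: TrainConfig, k: int = 10,
                   groups=None) -> tuple[list[FoldResult], dict[str, Metrics]]:
    """k-fold train/evaluate with mean and max aggregates over folds."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.intp)
    folds = kfold_indices(len(y), k, labels=y, stratify=groups is None,
                          seed=cfg.seed, groups=groups)
    results = []
    for i, (tr, te) in enumerate(folds):
        fold_cfg = TrainConfig(lr=cfg.lr, betas=cfg.betas, epochs=cfg.epochs,
                               batch_size=cfg.batch_size,
                               seed=_fold_seed(cfg.seed, i), task=cfg.task)
        model, history = train_model(spec, X[tr], y[tr], fold_cfg)
        m = evaluate(model, X[te], y[te])
        results.append(FoldResult(fold_index=i, metrics=m, history=history))
        logger.info("fold %d (%s): acc=%.4f", i, cfg.task, m.accuracy)
    return results, _aggregate(results)


def _labels_for_task(matrix: DEMatrix, task: str) -> np.ndarray:
    return matrix.row_meta[task].to_numpy(dtype=np.intp)


def run_ablation_suite(matrix: DEMatrix, cfg: TrainConfig, k: int = 10,
                       variants=("CNN", "BiLSTM", "CNN-BiLSTM", "CSBN"),
                       tasks=("valence", "arousal")) -> pd.DataFrame:
    """Cross-validate every ablation variant on every task.

    Returns one row per (variant, task) with mean/max metrics, shaped like
    the standard ablation table.
    """
    input_len = matrix.values.shape[1]
    rows = []
    for variant in variants:
        spec = model_spec_for_input(input_len, variant=variant)
        for task in tasks:
            task_cfg = TrainConfig(lr=cfg.lr, betas=cfg.betas, epochs=cfg.epochs,
                                   batch_size=cfg.batch_size, seed=cfg.seed,
                                   task=task)
            _, agg = cross_validate(spec, matrix.values,
                                    _labels_for_task(matrix, task), task_cfg, k=k)
            rows.append({
                "variant": variant, "task": task,
                **{f"mean_{n}": getattr(agg["mean"], n)
                   for n in ("accuracy", "precision", "f1", "auc")},
                "max_accuracy": agg["max"].accuracy,
            })
    return pd.DataFrame(rows)


def run_band_suite(matrix: DEMatrix, cfg: TrainConfig, k: int = 10,
                   subsets=None, tasks=("valence", "arousal"),
                   variant: str = "CSBN") -> pd.DataFrame:
    """Cross-validate one variant on band-restricted feature matrices.

    ``subsets`` defaults to the 14 singleton/pair/triple subsets.  The
    model spec is re-derived from each subset's column count; a subset too
    narrow for the conv stack raises an ArchitectureError naming it.
    """
    from .model import ArchitectureError

    subsets = subsets if subsets is not None else BAND_SUITE_SUBSETS
    rows = []
    for subset in subsets:
        sub = select_bands(matrix, list(subset))
        input_len = sub.values.shape[1]
        try:
            spec = model_spec_for_input(input_len, variant=variant)
        except ArchitectureError as exc:
            raise ArchitectureError(
                f"band subset {subset}: {exc}"
            ) from exc
        for task in tasks:
            task_cfg = TrainConfig(lr=cfg.lr, betas=cfg.betas, epochs=cfg.epochs,
                                   batch_size=cfg.batch_size, seed=cfg.seed,
                                   task=task)
            _, agg = cross_validate(spec, sub.values,
                                    _labels_for_task(sub, task), task_cfg, k=k)
            rows.append({
                "bands": "+".join(subset), "n_bands": len(subset), "task": task,
                **{f"mean_{n}": getattr(agg["mean"], n)
                   for n in ("accuracy", "precision", "f1", "auc")},
                "max_accuracy": agg["max"].accuracy,
            })
    return pd.DataFrame(rows)


def results_to_json(df: pd.DataFrame, path, config: dict | None = None) -> None:
    """Serialize a suite result table (+ config provenance) to JSON."""
    payload = {"config": config or {}, "rows": df.to_dict(orient="records")}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
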