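"""The study protocol: temporal splits, tuning, and the model comparison.

Windows are split per (subject, task) block, preserving temporal order:
the first two-thirds of each block train, the last third tests, and
within the training block either a trailing-third holdout or 3 contiguous
cross-validation folds tune hyperparameters.  The comparison harness then
trains five model kinds — server, personalized server, federated,
personalized federated, individual — with a fresh seed per repetition and
summarizes held-out accuracy (median / mean / SD) next to the
majority-class baseline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .federated_sim import FedConfig, run_federated
from .model_core import TrainConfig
from .signal_features import FeatureTable
from .trainers import evaluate, train_individual, train_server

logger = logging.getLogger("fedaffect")

MODEL_KINDS = (
    "server",
    "personalized_server",
    "federated",
    "personalized_federated",
    "individual",
)


@dataclass
class SplitSpec:
    """Per-(subject, task) temporal split fractions.

    ``n_test = floor(n / 3)`` per block so the test set is never larger
    than a third; blocks with fewer than 3 windows go wholly to training.
    """

    test_denominator: int = 3
    validation_denominator: int = 3
    n_folds: int = 3


def _blocks(table: FeatureTable):
    """Yield per-(subject, label) row positions in temporal order."""
    df = table.df.reset_index(drop=True)
    for (sid, label), idx in df.groupby(
        [df["subject_id"].astype(str), "label"], sort=True
    ).groups.items():
        block = df.loc[idx].sort_values("window_index")
        yield (sid, label), block.index.to_numpy()


def _subset(table: FeatureTable, positions: np.ndarray) -> FeatureTable:
    df = table.df.reset_index(drop=True)
    return FeatureTable(
        df.loc[np.sort(positions)].reset_index(drop=True), list(table.feature_cols)
    )


def split_train_test(
    table: FeatureTable, spec: SplitSpec | None = None
) -> tuple[FeatureTable, FeatureTable]:
    """First two-thirds of each (subject, task) block train, rest test."""
    spec = spec or SplitSpec()
    train_pos, test_pos = [], []
    for (sid, label), pos in _blocks(table):
        n = len(pos)
        n_test = n // spec.test_denominator
        if n < spec.test_denominator:
            logger.warning(
                "block (%s, class %s) has only %d window(s); all assigned to train",
                sid, label, n,
            )
        train_pos.append(pos[: n - n_test])
        test_pos.append(pos[n - n_test:])
    return (
        _subset(table, np.concatenate(train_pos)),
        _subset(table, np.concatenate(test_pos) if any(len(p) for p in test_pos)
                else np.array([], dtype=int)),
    )


def split_validation(
    train: FeatureTable, spec: SplitSpec | None = None
) -> tuple[FeatureTable, FeatureTable]:
    """Holdout mode: last third of each training block is validation."""
    spec = spec or SplitSpec()
    fit_pos, val_pos = [], []
    for _, pos in _blocks(train):
        n_val = len(pos) // spec.validation_denominator
        fit_pos.append(pos[: len(pos) - n_val])
        val_pos.append(pos[len(pos) - n_val:])
    return (
        _subset(train, np.concatenate(fit_pos)),
        _subset(train, np.concatenate(val_pos)),
    )


def cv_folds(
    train: FeatureTable, spec: SplitSpec | None = None
) -> list[tuple[FeatureTable, FeatureTable]]:
    """Contiguous-in-time per-block 3-fold partition of the training set.

    Blocks smaller than the fold count go wholly to fold 1 (with a
    warning), keeping the folds a partition of the training rows.
    """
    spec = spec or SplitSpec()
    k = spec.n_folds
    fold_pos: list[list[np.ndarray]] = [[] for _ in range(k)]
    for (sid, label), pos in _blocks(train):
        if len(pos) < k:
            logger.warning(
                "block (%s, class %s) smaller than %d folds; assigned to fold 1",
                sid, label, k,
            )
            fold_pos[0].append(pos)
            continue
        for fi, part in enumerate(np.array_split(pos, k)):
            fold_pos[fi].append(part)
    folds = []
    for fi in range(k):
        val = np.concatenate(fold_pos[fi]) if fold_pos[fi] else np.array([], int)
        fit = np.concatenate(
            [p for fj in range(k) if fj != fi for p in fold_pos[fj]]
        )
        folds.append((_subset(train, fit), _subset(train, val)))
    return folds


# ----------------------------------------------------------------------
# fitting any model kind from a hyperparameter mapping
# ----------------------------------------------------------------------

def fit_model(kind: str, train: FeatureTable, hyper: dict, seed: int):
    """Train one model of the given kind; returns what evaluate() accepts."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind '{kind}'")
    if kind in ("server", "personalized_server", "individual"):
        cfg = TrainConfig(
            epochs=int(hyper.get("epochs", 100)),
            learning_rate=float(hyper.get("learning_rate", 0.01)),
            batch_size=int(hyper.get("batch_size", 32)),
            init_seed=seed,
        )
        if kind == "individual":
            return train_individual(train.per_user(), cfg)
        return train_server(
            train, cfg,
            personalized=(kind == "personalized_server"),
            embedding_dim=int(hyper.get("embedding_dim", 2)),
        )
    fed = FedConfig(
        rounds=int(hyper.get("rounds", 100)),
        clients_per_round=int(hyper.get("clients_per_round", 5)),
        local_updates=int(hyper.get("local_updates", 10)),
        local_learning_rate=float(hyper.get("local_learning_rate", 0.01)),
        server_step_size=float(hyper.get("server_step_size", 1.0)),
        local_optimizer=str(hyper.get("local_optimizer", "adam")),
        aggregation=str(hyper.get("aggregation", "uniform")),
        personalized=(kind == "personalized_federated"),
        embedding_dim=int(hyper.get("embedding_dim", 2)),
        seed=seed,
    )
    return run_federated(train.per_user(), fed)


def _tie_key(hyper: dict, order: int) -> tuple:
    epochs = hyper.get("epochs", hyper.get("rounds", 0))
    lr = hyper.get("learning_rate", hyper.get("local_learning_rate", 0.0))
    return (epochs, lr, order)


def grid_search(
    kind: str,
    grid: list[dict],
    train: FeatureTable,
    seed: int = 0,
    spec: SplitSpec | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Score each combination by mean 3-fold validation accuracy.

    Ties break toward fewer epochs, then smaller learning rate, then
    first listed.  A combination whose training raises is scored 0.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    folds = cv_folds(train, spec)
    records = []
    for order, hyper in enumerate(grid):
        scores = []
        for fit_part, val_part in folds:
            if len(val_part) == 0:
                continue
            try:
                model = fit_model(kind, fit_part, hyper, seed)
                scores.append(evaluate(model, val_part).overall)
            except Exception:  # noqa: BLE001 — any failure scores 0
                logger.exception("grid combination %r failed", hyper)
                scores.append(0.0)
        records.append({
            "hyper": hyper,
            "mean_val_accuracy": float(np.mean(scores)) if scores else 0.0,
            "order": order,
        })
    best = max(
        records,
        key=lambda r: (r["mean_val_accuracy"],) + tuple(
            -x for x in _tie_key(r["hyper"], r["order"])[:2]
        ) + (-r["order"],),
    )
    return best["hyper"], pd.DataFrame(records)


def majority_baseline(labels) -> float:
    """Accuracy of always predicting the most frequent class."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    _, counts = np.unique(labels, return_counts=True)
    return float(counts.max() / labels.size)


# ----------------------------------------------------------------------
# the five-model comparison
# ----------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Per-kind accuracies over repeated seeded runs, plus summaries."""

    accuracies: dict[str, list[float]]
    baseline: float
    hyperparameters: dict[str, dict]
    failed: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for kind, accs in self.accuracies.items():
            a = np.asarray(accs)
            rows.append({
                "model": kind,
                "median": float(np.median(a)),
                "mean": float(np.mean(a)),
                "sd": float(np.std(a, ddof=1)) if len(a) > 1 else 0.0,
                "n_runs": len(a),
            })
        rows.append({"model": "majority_baseline", "median": self.baseline,
                     "mean": self.baseline, "sd": 0.0, "n_runs": 0})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "per_seed_accuracies": self.accuracies,
            "summary": self.summary().to_dict(orient="records"),
            "majority_baseline": self.baseline,
            "hyperparameters": self.hyperparameters,
            "failed": self.failed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


DEFAULT_HYPERS: dict[str, dict] = {
    "server": {"epochs": 100, "learning_rate": 0.01},
    "personalized_server": {"epochs": 100, "learning_rate": 0.01,
                            "embedding_dim": 2},
    "federated": {"rounds": 100, "clients_per_round": 5, "local_updates": 10,
                  "local_learning_rate": 0.01, "server_step_size": 1.0},
    "personalized_federated": {"rounds": 100, "clients_per_round": 5,
                               "local_updates": 10,
                               "local_learning_rate": 0.01,
                               "server_step_size": 1.0, "embedding_dim": 2},
    "individual": {"epochs": 100, "learning_rate": 0.01},
}


def run_comparison(
    table: FeatureTable,
    grids: dict[str, list[dict]] | None = None,
    n_seeds: int = 15,
    hypers: dict[str, dict] | None = None,
    kinds: tuple[str, ...] = MODEL_KINDS,
    split: SplitSpec | None = None,
) -> ComparisonReport:
    """Train and test every model kind ``n_seeds`` times (seeds 1..n).

    Hyperparameters come either from ``hypers`` directly or from one
    grid search per kind (``grids``); defaults otherwise.  The split is
    deterministic, so repetitions differ only in initialization, batch
    shuffling and cohort sampling.  A kind that fails on every seed is
    marked failed without affecting the others.
    """
    train, test = split_train_test(table, split)
    chosen: dict[str, dict] = {}
    for kind in kinds:
        if hypers and kind in hypers:
            chosen[kind] = hypers[kind]
        elif grids and kind in grids:
            chosen[kind], _ = grid_search(kind, grids[kind], train)
        else:
            chosen[kind] = DEFAULT_HYPERS[kind]
    accuracies: dict[str, list[float]] = {}
    failed: list[str] = []
    for kind in kinds:
        accs = []
        for seed in range(1, n_seeds + 1):
            try:
                model = fit_model(kind, train, chosen[kind], seed)
                accs.append(evaluate(model, test).overall)
            except Exception:  # noqa: BLE001
                logger.exception("%s failed on seed %d", kind, seed)
        if accs:
            accuracies[kind] = accs
        else:
            failed.append(kind)
    baseline = majority_baseline(table.labels())
    return ComparisonReport(accuracies, baseline, chosen, failed)
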