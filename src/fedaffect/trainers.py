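"""Centralized ("server") and per-user ("individual") training loops.

The server model pools every subject's windows and fits one network; the
individual regime fits one network per subject on that subject's data
alone, sharing nothing (not even the standardizer).  The server model
optionally carries per-subject user embeddings trained jointly with the
network weights.  Both loops are deterministic given their seeds.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    AdamState,
    EmbeddingTable,
    MLPParams,
    ModelSpec,
    Standardizer,
    TrainConfig,
    accuracy,
    adam_step,
    augment_rows,
    fit_standardizer,
    forward,
    gradient,
    init_params,
    loss,
    predict,
)
from .signal_features import FeatureTable

logger = logging.getLogger("fedaffect")


class MissingModelError(KeyError):
    """A test subject has no corresponding individual model."""


@dataclass
class FittedModel:
    """A trained network plus everything needed to score new windows."""

    spec: ModelSpec
    params: MLPParams
    standardizer: Standardizer
    embeddings: EmbeddingTable | None = None
    log: list[dict] = field(default_factory=list)
    embeddings_client_side: bool = False
    allow_unseen_subjects: bool = False

    def predict_rows(self, X: np.ndarray, subject_ids: np.ndarray) -> np.ndarray:
        Xs = self.standardizer.apply(X)
        if self.embeddings is not None and self.embeddings.dim > 0:
            if self.allow_unseen_subjects:
                emb = EmbeddingTable(self.embeddings.dim, dict(self.embeddings.vectors))
                for sid in np.unique(subject_ids):
                    emb.vectors.setdefault(str(sid), np.zeros(emb.dim))
                Xs = augment_rows(Xs, subject_ids, emb)
            else:
                Xs = augment_rows(Xs, subject_ids, self.embeddings)
        return predict(self.params, Xs)


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    if batch_size <= 0 or batch_size >= n:
        yield order
        return
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_server(
    table: FeatureTable,
    cfg: TrainConfig,
    personalized: bool = False,
    embedding_dim: int = 2,
) -> FittedModel:
    """Fit one network on all subjects' pooled windows.

    In personalized mode every subject gets a ``embedding_dim``-vector
    appended to their rows, trained jointly with the network weights via
    the same Adam optimizer.  ``embedding_dim = 0`` reduces exactly to
    the non-personalized path.
    """
    u = embedding_dim if personalized else 0
    X_raw = table.features()
    y = table.labels()
    sids = table.subject_ids()
    subjects = table.subjects
    std = fit_standardizer(X_raw)
    X = std.apply(X_raw)
    n, d = X.shape

    spec = ModelSpec(input_dim=d + u)
    params = init_params(spec, cfg.init_seed)
    opt = AdamState(cfg.beta1, cfg.beta2, cfg.eps)

    emb: EmbeddingTable | None = None
    sub_index = None
    emb_opt = None
    if u > 0:
        emb = EmbeddingTable.init(subjects, u, seed=cfg.init_seed + 1)
        sub_index = {s: i for i, s in enumerate(subjects)}
        emb_opt = AdamState(cfg.beta1, cfg.beta2, cfg.eps)

    rng = np.random.default_rng(cfg.init_seed + 2)
    log: list[dict] = []
    for epoch in range(cfg.epochs):
        for batch in _epoch_batches(n, cfg.batch_size, rng):
            Xb, yb = X[batch], y[batch]
            if u > 0:
                Xb = augment_rows(Xb, sids[batch], emb)
            grads, eg = gradient(params, Xb, yb, embedding_dim=u)
            params = adam_step(opt, params, grads, cfg.learning_rate)
            if u > 0:
                E = np.stack([emb.vectors[s] for s in subjects])
                gE = np.zeros_like(E)
                rows = np.array([sub_index[s] for s in sids[batch]])
                np.add.at(gE, rows, eg)
                E = emb_opt.step({"emb": E}, {"emb": gE}, cfg.learning_rate)["emb"]
                for i, s in enumerate(subjects):
                    emb.vectors[s] = E[i]
        Xf = augment_rows(X, sids, emb) if u > 0 else X
        probs = forward(params, Xf)
        log.append({
            "epoch": epoch,
            "loss": loss(probs, y),
            "accuracy": accuracy(np.argmax(probs, axis=1), y),
        })
    return FittedModel(spec, params, std, embeddings=emb, log=log)


def _user_seed(base_seed: int, subject_id: str) -> int:
    # stable per-subject derivation: independent of which other users exist
    return (base_seed * 2654435761 + zlib.crc32(subject_id.encode())) % (2**31)


def train_individual(
    tables: dict[str, FeatureTable],
    cfg: TrainConfig,
) -> dict[str, FittedModel]:
    """One fully independent model (and standardizer) per subject."""
    models: dict[str, FittedModel] = {}
    for sid, table in tables.items():
        if len(np.unique(table.labels())) < 2:
            logger.warning("subject %s has a single class in training", sid)
        user_cfg = TrainConfig(
            epochs=cfg.epochs, learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size, beta1=cfg.beta1, beta2=cfg.beta2,
            eps=cfg.eps, init_seed=_user_seed(cfg.init_seed, sid),
        )
        models[sid] = train_server(table, user_cfg, personalized=False)
    return models


@dataclass
class EvalResult:
    overall: float
    per_user: dict[str, float]
    n_per_user: dict[str, int]


def evaluate(
    model: FittedModel | dict[str, FittedModel],
    test: FeatureTable,
) -> EvalResult:
    """Pooled and per-subject accuracy on held-out windows.

    Accepts a single fitted model (server/federated) or the per-subject
    mapping from :func:`train_individual`.
    """
    per_user: dict[str, float] = {}
    n_per_user: dict[str, int] = {}
    correct = 0
    for sid, part in test.per_user().items():
        X, y = part.features(), part.labels()
        if isinstance(model, dict):
            if sid not in model:
                raise MissingModelError(f"no individual model for subject '{sid}'")
            pred = model[sid].predict_rows(X, part.subject_ids())
        else:
            pred = model.predict_rows(X, part.subject_ids())
        per_user[sid] = accuracy(pred, y)
        n_per_user[sid] = len(y)
        correct += int((pred == y).sum())
    total = sum(n_per_user.values())
    if total == 0:
        raise ValueError("empty test table")
    return EvalResult(correct / total, per_user, n_per_user)
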