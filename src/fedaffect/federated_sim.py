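"""Federated-averaging simulation with an on-device embedding variant.

One server round has three parts: a random cohort of clients is sampled
and the current network parameters broadcast to them; each client runs a
few local optimizer steps on its own windows; the clients return their
updated *shared* parameters, which the server averages and (optionally
damped by a step size) adopts.  Clients are in-memory partitions of the
feature table — the simulation is sequential and single-process — but the
payload boundary is enforced: in personalized mode each client's user
embedding is updated in place on the client and never enters a payload,
and an audit log records the payload key names seen each round so the
privacy property is checkable after the fact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    AdamState,
    EmbeddingTable,
    MLPParams,
    ModelSpec,
    augment_rows,
    fit_standardizer,
    gradient,
    init_params,
)
from .signal_features import FeatureTable
from .trainers import FittedModel

logger = logging.getLogger("fedaffect")

EMBEDDING_KEY = "emb"  # client-local parameter name; must never be transmitted


class FedConfigError(ValueError):
    """Inconsistent federated-training configuration."""


class AggregationError(ValueError):
    """Client payloads disagree in structure."""


@dataclass
class FedConfig:
    """Tunables of the federated simulation.

    ``rounds`` is the number of server rounds; each round samples
    ``clients_per_round`` clients without replacement, runs
    ``local_updates`` full-batch optimizer steps per client at
    ``local_learning_rate``, then moves the server parameters toward the
    payload average by ``server_step_size`` (1 = replace outright).
    """

    rounds: int = 100
    clients_per_round: int = 5
    local_updates: int = 10
    local_learning_rate: float = 0.01
    server_step_size: float = 1.0
    local_optimizer: str = "adam"      # or "plain"
    aggregation: str = "uniform"       # or "sample_weighted"
    personalized: bool = False
    embedding_dim: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 0 or self.local_updates < 1:
            raise FedConfigError("rounds must be >= 0 and local_updates >= 1")
        if self.local_learning_rate <= 0:
            # lr = 0 is allowed only for the no-op diagnostic path
            if self.local_learning_rate < 0:
                raise FedConfigError("local_learning_rate must be >= 0")
        if not (0 < self.server_step_size <= 1):
            raise FedConfigError("server_step_size must lie in (0, 1]")
        if self.local_optimizer not in ("adam", "plain"):
            raise FedConfigError("local_optimizer must be 'adam' or 'plain'")
        if self.aggregation not in ("uniform", "sample_weighted"):
            raise FedConfigError("aggregation must be 'uniform' or 'sample_weighted'")
        if self.clients_per_round < 1:
            raise FedConfigError("clients_per_round must be >= 1")


@dataclass
class ClientState:
    """One user device: private rows, private embedding, transient state."""

    user_id: str
    X: np.ndarray               # standardized private features
    y: np.ndarray
    embedding: np.ndarray | None = None   # stays on the device

    @property
    def n_rows(self) -> int:
        return len(self.y)


def sample_cohort(
    user_ids: list[str], m: int, rng: np.random.Generator
) -> list[str]:
    """Uniform sample of ``m`` distinct clients for one round."""
    if m > len(user_ids):
        raise FedConfigError(
            f"clients_per_round={m} exceeds the {len(user_ids)} available users"
        )
    picked = rng.choice(len(user_ids), size=m, replace=False)
    return [user_ids[i] for i in picked]


def local_update(
    broadcast: MLPParams, client: ClientState, cfg: FedConfig
) -> dict[str, np.ndarray]:
    """Run the client's local steps; return the shared-parameter payload.

    ``cfg.local_updates`` full-batch optimizer steps on the client's rows.
    In personalized mode the embedding gradient is applied to the client's
    own vector in place and is excluded from the returned payload.
    Optimizer state is transient: it is created fresh for each broadcast.
    """
    if client.n_rows == 0:
        raise ValueError(f"client {client.user_id} has no training rows")
    u = cfg.embedding_dim if cfg.personalized else 0
    arrays = {k: v.copy() for k, v in broadcast.arrays.items()}
    params = MLPParams(broadcast.spec, arrays)
    opt = AdamState() if cfg.local_optimizer == "adam" else None
    for _ in range(cfg.local_updates):
        Xb = client.X
        if u > 0:
            Xb = np.hstack([Xb, np.tile(client.embedding, (client.n_rows, 1))])
        grads, eg = gradient(params, Xb, client.y, embedding_dim=u)
        if u > 0:
            grads = dict(grads)
            grads[EMBEDDING_KEY] = eg.sum(axis=0)
        if opt is not None:
            joint = dict(params.arrays)
            if u > 0:
                joint[EMBEDDING_KEY] = client.embedding
            new = opt.step(joint, grads, cfg.local_learning_rate)
        else:
            joint = dict(params.arrays)
            if u > 0:
                joint[EMBEDDING_KEY] = client.embedding
            new = {k: joint[k] - cfg.local_learning_rate * g
                   for k, g in grads.items()}
        if u > 0:
            client.embedding = new.pop(EMBEDDING_KEY)
        params = MLPParams(broadcast.spec, new)
    return params.payload()


def aggregate(
    payloads: list[dict[str, np.ndarray]],
    weights: list[float] | None = None,
    mode: str = "uniform",
) -> dict[str, np.ndarray]:
    """Average client payloads elementwise.

    ``uniform`` mode is the plain arithmetic mean; ``sample_weighted``
    weights each client by its training-row count (canonical federated
    averaging).
    """
    if not payloads:
        raise AggregationError("no payloads to aggregate")
    keys = payloads[0].keys()
    for ci, p in enumerate(payloads):
        if p.keys() != keys:
            raise AggregationError(f"payload from client #{ci} has different keys")
        for k in keys:
            if p[k].shape != payloads[0][k].shape:
                raise AggregationError(
                    f"payload from client #{ci} has wrong shape for '{k}'"
                )
    if mode == "uniform" or weights is None:
        w = np.ones(len(payloads))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return {
        k: sum(wi * p[k] for wi, p in zip(w, payloads)) for k in keys
    }


def run_federated(
    tables: dict[str, FeatureTable],
    cfg: FedConfig,
) -> FittedModel:
    """Simulate ``cfg.rounds`` server rounds over per-user partitions.

    Standardization is fitted on the pooled training rows (the privacy
    cost of sharing 2x32 aggregate moments is outside this simulation's
    scope) and applied on each client.  Returns the final server model;
    in personalized mode the per-user embeddings ride along flagged as
    client-resident, and ``model.log`` holds one audit record per round
    with the payload key names (cohort ids are not recorded).
    """
    if len(tables) < 2:
        raise FedConfigError("federated training needs at least 2 users")
    u = cfg.embedding_dim if cfg.personalized else 0
    user_ids = list(tables)
    pooled = np.vstack([t.features() for t in tables.values()])
    std = fit_standardizer(pooled)

    clients: dict[str, ClientState] = {}
    for i, (sid, t) in enumerate(tables.items()):
        emb = None
        if u > 0:
            rng_i = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1, i)))
            emb = rng_i.normal(0.0, 0.1, size=u)
        clients[sid] = ClientState(sid, std.apply(t.features()), t.labels(), emb)

    active = [sid for sid in user_ids if clients[sid].n_rows > 0]
    for sid in user_ids:
        if clients[sid].n_rows == 0:
            logger.warning("client %s has no rows and is skipped", sid)
    if not active:
        raise ValueError("all clients are empty")
    if cfg.rounds > 0 and cfg.clients_per_round > len(active):
        raise FedConfigError(
            f"clients_per_round={cfg.clients_per_round} exceeds the "
            f"{len(active)} non-empty users"
        )

    n_features = pooled.shape[1]
    spec = ModelSpec(input_dim=n_features + u)
    params = init_params(spec, cfg.seed)

    audit: list[dict] = []
    for r in range(cfg.rounds):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2, r)))
        cohort = sample_cohort(active, cfg.clients_per_round, rng)
        payloads = [local_update(params, clients[sid], cfg) for sid in cohort]
        weights = [clients[sid].n_rows for sid in cohort]
        mean = aggregate(payloads, weights, cfg.aggregation)
        eta = cfg.server_step_size
        params = MLPParams(spec, {
            k: (1 - eta) * params.arrays[k] + eta * mean[k] for k in mean
        })
        audit.append({
            "round": r,
            "payload_keys": sorted({k for p in payloads for k in p}),
        })

    emb_table = None
    if u > 0:
        emb_table = EmbeddingTable(
            u, {sid: clients[sid].embedding.copy() for sid in active}
        )
    return FittedModel(
        spec, params, std,
        embeddings=emb_table, log=audit, embeddings_client_side=True,
    )
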