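"""The classifier: a small dense network with optional user embeddings.

Architecture: three leaky-ReLU hidden layers of 12, 10 and 8 units on top
of the (optionally embedding-augmented) feature vector, then a 3-way
softmax trained with categorical cross-entropy under Adam.  Everything is
plain numpy with hand-written backpropagation: parameters live in a flat
name -> array mapping (``W0``/``b0`` ... ``W3``/``b3``) so that federated
aggregation and payload auditing are dictionary operations.

Personalization appends a low-dimensional per-subject *user embedding* to
every input row from that subject — the neural-network analogue of a
per-user fixed effect.  Embedding gradients are returned separately from
network gradients so federated clients can apply them locally and never
transmit them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("fedaffect")

LOSS_FLOOR = 1e-12  # cross-entropy clip to avoid -log 0


class ShapeError(ValueError):
    """Input dimensions inconsistent with the model specification."""


class NumericError(FloatingPointError):
    """Non-finite value produced during forward/backward computation."""


@dataclass(frozen=True)
class ModelSpec:
    input_dim: int
    hidden_dims: tuple[int, ...] = (12, 10, 8)
    leaky_slope: float = 0.01
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ShapeError("input_dim must be positive")

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.hidden_dims, self.n_classes]
        return list(zip(dims[:-1], dims[1:]))


@dataclass
class MLPParams:
    """Network weights/biases as a flat name -> array mapping."""

    spec: ModelSpec
    arrays: dict[str, np.ndarray]

    def copy(self) -> "MLPParams":
        return MLPParams(self.spec, {k: v.copy() for k, v in self.arrays.items()})

    def payload(self) -> dict[str, np.ndarray]:
        """The transmissible form: shared network parameters only."""
        return {k: v.copy() for k, v in self.arrays.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MLPParams):
            return NotImplemented
        return self.arrays.keys() == other.arrays.keys() and all(
            np.array_equal(self.arrays[k], other.arrays[k]) for k in self.arrays
        )


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 0.01
    batch_size: int = 32          # <=0 means full batch
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    init_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("Adam betas must lie in (0, 1)")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs and learning_rate must be positive")


def init_params(spec: ModelSpec, seed: int) -> MLPParams:
    """Fan-in-scaled uniform weights, zero biases; deterministic in seed."""
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}
    for li, (fan_in, fan_out) in enumerate(spec.layer_dims):
        limit = np.sqrt(6.0 / fan_in)
        arrays[f"W{li}"] = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        arrays[f"b{li}"] = np.zeros(fan_out)
    return MLPParams(spec, arrays)


def _leaky(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z >= 0, z, slope * z)


def _forward_cached(params: MLPParams, X: np.ndarray):
    """Probabilities plus the per-layer caches backprop needs."""
    spec = params.spec
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.input_dim:
        raise ShapeError(
            f"input has {X.shape[1]} features, model expects {spec.input_dim}"
        )
    n_layers = len(spec.layer_dims)
    acts = [X]          # post-activation per layer (acts[0] = input)
    pre: list[np.ndarray] = []
    h = X
    for li in range(n_layers):
        z = h @ params.arrays[f"W{li}"] + params.arrays[f"b{li}"]
        if not np.all(np.isfinite(z)):
            raise NumericError(f"non-finite activation in layer {li}")
        pre.append(z)
        h = _leaky(z, spec.leaky_slope) if li < n_layers - 1 else z
        acts.append(h)
    logits = acts[-1]
    shifted = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    probs = expz / expz.sum(axis=1, keepdims=True)
    return probs, acts, pre


def forward(params: MLPParams, x: np.ndarray) -> np.ndarray:
    """Class probabilities; accepts a single row or an (n, d) batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    probs, _, _ = _forward_cached(params, x)
    return probs[0] if single else probs


def predict(params: MLPParams, X: np.ndarray) -> np.ndarray:
    """Most probable class index per row."""
    return np.argmax(forward(params, np.atleast_2d(X)), axis=1)


def loss(probs: np.ndarray, y) -> float:
    """Mean categorical cross-entropy, -log p[y], clipped at 1e-12."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=int))
    p_true = probs[np.arange(len(y)), y]
    if np.any(p_true < LOSS_FLOOR):
        logger.warning("cross-entropy clipped %d probabilities at %.0e",
                       int(np.sum(p_true < LOSS_FLOOR)), LOSS_FLOOR)
        p_true = np.clip(p_true, LOSS_FLOOR, None)
    return float(-np.log(p_true).mean())


def gradient(
    params: MLPParams,
    X: np.ndarray,
    y: np.ndarray,
    embedding_dim: int = 0,
) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
    """Gradients of the mean cross-entropy over a batch.

    ``X`` is the (already embedding-augmented) input; when
    ``embedding_dim = u > 0`` the per-row gradient with respect to the
    last ``u`` input entries is returned as the second element — the
    caller sums these per subject to update the shared embedding, and a
    federated client keeps them local.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=int))
    if len(X) == 0:
        raise ValueError("empty batch")
    spec = params.spec
    probs, acts, pre = _forward_cached(params, X)
    n = len(y)
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), y] = 1.0
    delta = (probs - onehot) / n  # dL/dlogits for mean CE + softmax
    grads: dict[str, np.ndarray] = {}
    n_layers = len(spec.layer_dims)
    for li in range(n_layers - 1, -1, -1):
        grads[f"W{li}"] = acts[li].T @ delta
        grads[f"b{li}"] = delta.sum(axis=0)
        if li > 0:
            delta = delta @ params.arrays[f"W{li}"].T
            delta = delta * np.where(pre[li - 1] >= 0, 1.0, spec.leaky_slope)
    emb_grads = None
    if embedding_dim > 0:
        dX = delta @ params.arrays["W0"].T  # dL/dinput per row
        emb_grads = dX[:, -embedding_dim:]
    return grads, emb_grads


# ----------------------------------------------------------------------
# optimizer
# ----------------------------------------------------------------------

class AdamState:
    """First/second moment accumulators and step counter for named arrays."""

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, arrays: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> dict[str, np.ndarray]:
        """One bias-corrected Adam update; returns the new arrays."""
        self.t += 1
        out = {}
        for k, g in grads.items():
            m = self.m.get(k, np.zeros_like(g))
            v = self.v.get(k, np.zeros_like(g))
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g * g
            self.m[k], self.v[k] = m, v
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            out[k] = arrays[k] - lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def adam_step(
    state: AdamState,
    params: MLPParams,
    grads: dict[str, np.ndarray],
    learning_rate: float,
) -> MLPParams:
    """Apply one Adam update to network parameters (state mutated)."""
    return MLPParams(params.spec, state.step(params.arrays, grads, learning_rate))


# ----------------------------------------------------------------------
# standardization, embeddings, accuracy
# ----------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-feature location/scale fitted on training rows only."""

    location: np.ndarray
    scale: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.location) / self.scale


def fit_standardizer(train_X: np.ndarray, ddof: int = 0) -> Standardizer:
    """Column means/SDs; a constant column gets scale 1 with a warning."""
    X = np.atleast_2d(np.asarray(train_X, dtype=float))
    if X.size == 0:
        raise ValueError("cannot standardize an empty table")
    loc = X.mean(axis=0)
    scale = X.std(axis=0, ddof=ddof) if len(X) > ddof else np.zeros(X.shape[1])
    degenerate = scale <= 0
    if degenerate.any():
        logger.warning("standardizer: %d constant column(s); scale set to 1",
                       int(degenerate.sum()))
        scale = np.where(degenerate, 1.0, scale)
    return Standardizer(loc, scale)


def apply_standardizer(s: Standardizer, X: np.ndarray) -> np.ndarray:
    return s.apply(X)


@dataclass
class EmbeddingTable:
    """Per-subject embedding vectors of a common dimension u >= 0."""

    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dim < 0:
            raise ValueError("embedding dimension must be >= 0")
        for sid, v in self.vectors.items():
            if len(v) != self.dim:
                raise ShapeError(f"embedding for {sid} has wrong dimension")

    @classmethod
    def init(cls, subjects, dim: int, seed: int, scale: float = 0.1
             ) -> "EmbeddingTable":
        rng = np.random.default_rng(seed)
        return cls(dim, {
            sid: rng.normal(0.0, scale, size=dim) for sid in subjects
        })

    def get(self, subject_id: str) -> np.ndarray:
        if subject_id not in self.vectors:
            raise KeyError(
                f"no embedding for subject '{subject_id}'; personalized models "
                "cannot predict for unseen subjects"
            )
        return self.vectors[subject_id]


def augment_with_embedding(x: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Concatenate [x, e]; with an empty embedding x is returned unchanged."""
    e = np.asarray(e, dtype=float)
    if e.size == 0:
        return np.asarray(x, dtype=float)
    return np.concatenate([np.asarray(x, dtype=float), e])


def augment_rows(
    X: np.ndarray, subject_ids: np.ndarray, table: EmbeddingTable
) -> np.ndarray:
    """Row-wise augmentation: append each row's subject embedding."""
    if table.dim == 0:
        return np.asarray(X, dtype=float)
    E = np.stack([table.get(str(s)) for s in subject_ids])
    return np.hstack([np.asarray(X, dtype=float), E])


def accuracy(predicted, true) -> float:
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ShapeError("predicted/true length mismatch")
    if predicted.size == 0:
        raise ValueError("empty label sequences")
    return float(np.mean(predicted == true))
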