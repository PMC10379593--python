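"""Tucker-decomposition link prediction (the knowledge tensor).

A triple (h, r, t) is scored by the trilinear form

    phi(h, r, t) = W ×₁ e_h ×₂ w_r ×₃ e_t = Σ_ijk W[i,j,k] e_h[i] w_r[j] e_t[k]

where e_h, e_t are rows of the entity embedding matrix (d_e), w_r a row of
the relation embedding matrix (d_r) and W the d_e × d_r × d_e core tensor.
Training uses 1-N scoring: each (head, relation) pair is scored against
every entity simultaneously, scores are squashed through a logistic to
(0, 1), and the Bernoulli negative log-likelihood is minimised with Adam.
Benign and malignant tail probabilities are independent Bernoullis (1-N
semantics) and are not forced to sum to one; the diagnosis decision
compares the two tail scores, with ties broken toward benign.

Gradients are derived analytically; the whole model is plain numpy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .graph import KnowledgeGraph, Triple
from .records import BENIGN, MALIGNANT, PATHOLOGY_RELATION

__all__ = [
    "TuckerModel",
    "TrainConfig",
    "TrainResult",
    "TrainingError",
    "LossInputs",
    "score_triple",
    "score_all_tails",
    "bernoulli_nll",
    "train",
    "predict_malignancy",
    "predict_label",
]

_CLAMP = 1e-7


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss) or was misconfigured."""


@dataclass
class TuckerModel:
    """Entity embeddings, relation embeddings and the core tensor W.

    Row index spaces match a :class:`KnowledgeGraph`'s first-seen
    entity/relation indices; the vocabularies are carried along so a
    model can be queried (and checkpointed) stand-alone.
    """

    entity_embeddings: np.ndarray  # |E| x d_e
    relation_embeddings: np.ndarray  # |R| x d_r
    core: np.ndarray  # d_e x d_r x d_e
    entities: list[str]
    relations: list[str]

    def __post_init__(self) -> None:
        de = self.entity_embeddings.shape[1]
        dr = self.relation_embeddings.shape[1]
        if self.core.shape != (de, dr, de):
            raise ValueError(
                f"core shape {self.core.shape} does not match (d_e, d_r, d_e)=({de},{dr},{de})"
            )
        if len(self.entities) != self.entity_embeddings.shape[0]:
            raise ValueError("entity vocabulary does not match embedding rows")
        if len(self.relations) != self.relation_embeddings.shape[0]:
            raise ValueError("relation vocabulary does not match embedding rows")

    @property
    def d_e(self) -> int:
        return self.entity_embeddings.shape[1]

    @property
    def d_r(self) -> int:
        return self.relation_embeddings.shape[1]

    @property
    def entity_index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.entities)}

    @property
    def relation_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.relations)}


def score_triple(model: TuckerModel, h_idx: int, r_idx: int, t_idx: int) -> float:
    """Trilinear score of a single triple (raw, before the logistic)."""
    h = model.entity_embeddings[h_idx]
    r = model.relation_embeddings[r_idx]
    t = model.entity_embeddings[t_idx]
    return float(np.einsum("ijk,i,j,k->", model.core, h, r, t))


def score_all_tails(model: TuckerModel, h_idx: int, r_idx: int) -> np.ndarray:
    """Raw scores of (h, r, t) for every entity t (1-N evaluation)."""
    h = model.entity_embeddings[h_idx]
    r = model.relation_embeddings[r_idx]
    m = np.einsum("ijk,i,j->k", model.core, h, r)
    return model.entity_embeddings @ m


@dataclass
class LossInputs:
    """Predicted probabilities and binary targets for the Bernoulli NLL."""

    predictions: np.ndarray
    targets: np.ndarray

    @property
    def n_e(self) -> int:
        return self.predictions.size


def bernoulli_nll(predictions: Sequence[float], targets: Sequence[float]) -> float:
    """Mean Bernoulli negative log-likelihood.

    L = -(1/n) Σ [y log p + (1-y) log(1-p)], with p clamped away from
    {0, 1} so the logs stay finite. Zero iff p equals y elementwise.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(targets, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if p.size == 0:
        raise ValueError("empty inputs")
    p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class TrainConfig:
    """Optimisation settings.

    Defaults follow the standard TuckER regime (1-N scoring, logistic
    outputs, label smoothing, Adam); dimensions are small because the
    graphs here have tens of entities per relation, not thousands —
    larger cores mostly add overfitting capacity.
    ``grid`` maps parameter names (``learning_rate``, ``n_epochs``) to
    candidate lists for a validation-loss grid search.
    """

    d_e: int = 30
    d_r: int = 30
    learning_rate: float = 5e-3
    n_epochs: int = 200
    batch_size: int = 128
    label_smoothing: float = 0.1
    input_dropout: float = 0.0
    hidden_dropout: float = 0.0
    seed: int = 0
    grid: dict[str, list] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.d_e < 1 or self.d_r < 1:
            raise ValueError("embedding dimensions must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be positive")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must be in [0, 1)")
        for p in (self.input_dropout, self.hidden_dropout):
            if not 0.0 <= p < 1.0:
                raise ValueError("dropout rates must be in [0, 1)")
        if self.grid is not None and not self.grid:
            raise ValueError("grid must be non-empty when supplied")


@dataclass
class TrainResult:
    model: TuckerModel
    loss_trace: list[float]
    config: TrainConfig


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _pairs_and_targets(
    triples: Iterable[Triple], graph: KnowledgeGraph
) -> tuple[np.ndarray, list[list[int]]]:
    """Unique (head, relation) index pairs and their true-tail index lists."""
    targets: dict[tuple[int, int], list[int]] = {}
    ei, ri = graph.entity_index, graph.relation_index
    for h, r, t in triples:
        key = (ei[h], ri[r])
        targets.setdefault(key, []).append(ei[t])
    pairs = np.array(list(targets), dtype=np.int64)
    return pairs, [targets[tuple(p)] for p in pairs]


def _fit(
    triples: list[Triple],
    graph: KnowledgeGraph,
    config: TrainConfig,
    init_model: TuckerModel | None,
) -> TrainResult:
    rng = np.random.default_rng(config.seed)
    n_ent, n_rel = len(graph.entities), len(graph.relations)
    if init_model is not None:
        if init_model.entities != graph.entities or init_model.relations != graph.relations:
            raise ValueError("init_model vocabulary does not match the graph")
        E = init_model.entity_embeddings.copy()
        R = init_model.relation_embeddings.copy()
        W = init_model.core.copy()
    else:
        E = rng.normal(0.0, 0.1, (n_ent, config.d_e))
        R = rng.normal(0.0, 0.1, (n_rel, config.d_r))
        W = rng.normal(0.0, 0.1, (config.d_e, config.d_r, config.d_e))

    pairs, tails = _pairs_and_targets(triples, graph)
    n_pairs = len(pairs)
    Y = np.zeros((n_pairs, n_ent))
    for row, ts in enumerate(tails):
        Y[row, ts] = 1.0
    ls = config.label_smoothing
    if ls > 0.0:
        Y = Y * (1.0 - ls) + ls / n_ent

    opt = _Adam([E.shape, R.shape, W.shape], config.learning_rate)
    trace: list[float] = []
    for epoch in range(config.n_epochs):
        order = rng.permutation(n_pairs)
        epoch_loss = 0.0
        for start in range(0, n_pairs, config.batch_size):
            idx = order[start : start + config.batch_size]
            hb, rb = pairs[idx, 0], pairs[idx, 1]
            H, Rb, Yb = E[hb], R[rb], Y[idx]
            if config.input_dropout > 0.0:
                keep = 1.0 - config.input_dropout
                hmask = rng.binomial(1, keep, H.shape) / keep
                H = H * hmask
            # phi = W x1 h x2 r x3 t, batched over (h, r) pairs and all
            # tails at once; contractions are reshaped matmuls (BLAS)
            # rather than einsum, which is slow at these small sizes.
            b = len(idx)
            A = (H @ W.reshape(config.d_e, -1)).reshape(b, R.shape[1], config.d_e)
            M = (A * Rb[:, :, None]).sum(axis=1)
            if config.hidden_dropout > 0.0:
                keep = 1.0 - config.hidden_dropout
                mmask = rng.binomial(1, keep, M.shape) / keep
                M = M * mmask
            S = M @ E.T
            P = np.clip(expit(S), _CLAMP, 1.0 - _CLAMP)
            loss = -np.mean(Yb * np.log(P) + (1.0 - Yb) * np.log(1.0 - P))
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch start {start}: "
                    f"lr={config.learning_rate}, |params| max "
                    f"{max(np.abs(E).max(), np.abs(R).max(), np.abs(W).max()):.3g}"
                )
            epoch_loss += loss * len(idx)

            G = (P - Yb) / P.size  # dL/dS
            dE = G.T @ M  # via tail role
            dM = G @ E
            if config.hidden_dropout > 0.0:
                dM = dM * mmask
            P = (Rb[:, :, None] * dM[:, None, :]).reshape(b, -1)
            dW = (H.T @ P).reshape(W.shape)
            dH = P @ W.reshape(config.d_e, -1).T
            if config.input_dropout > 0.0:
                dH = dH * hmask
            dRb = (A * dM[:, None, :]).sum(axis=2)
            np.add.at(dE, hb, dH)
            dR = np.zeros_like(R)
            np.add.at(dR, rb, dRb)
            opt.step([E, R, W], [dE, dR, dW])
        trace.append(epoch_loss / n_pairs)

    model = TuckerModel(E, R, W, list(graph.entities), list(graph.relations))
    return TrainResult(model=model, loss_trace=trace, config=config)


def train(
    train_triples: Iterable[Triple],
    graph: KnowledgeGraph,
    config: TrainConfig | None = None,
    init_model: TuckerModel | None = None,
) -> TrainResult:
    """Fit a Tucker model on training triples over a graph's vocabulary.

    The graph supplies the entity/relation index spaces (it may contain
    more triples than are trained on — e.g. held-out pathology edges are
    excluded from ``train_triples`` while their heads stay indexed).
    ``init_model`` warm-starts all parameters (used to keep two cores in
    comparable spaces for fusion). With ``config.grid`` set, a grid
    search selects learning rate / epoch count by the Bernoulli NLL on a
    held-out tenth of the (head, relation) pairs, then refits on all.
    Deterministic under ``config.seed``.
    """
    triples = list(train_triples)
    if not triples:
        raise ValueError("no training triples")
    config = config or TrainConfig()
    if config.grid:
        return _grid_search(triples, graph, config, init_model)
    return _fit(triples, graph, config, init_model)


def _grid_search(triples, graph, config, init_model) -> TrainResult:
    rng = np.random.default_rng(config.seed)
    keys = {(t.head, t.relation) for t in triples}
    keys = sorted(keys)
    rng.shuffle(keys)
    n_val = max(1, len(keys) // 10)
    val_keys = set(keys[:n_val])
    tr = [t for t in triples if (t.head, t.relation) not in val_keys]
    va = [t for t in triples if (t.head, t.relation) in val_keys]
    grid = config.grid or {}
    names = sorted(grid)
    best, best_loss = None, np.inf
    for combo in itertools.product(*(grid[k] for k in names)):
        cand = replace(config, grid=None, **dict(zip(names, combo)))
        result = _fit(tr, graph, cand, init_model)
        val_loss = _validation_nll(result.model, va, graph)
        if val_loss < best_loss:
            best, best_loss = cand, val_loss
    assert best is not None
    return _fit(triples, graph, best, init_model)


def _validation_nll(model: TuckerModel, val_triples, graph: KnowledgeGraph) -> float:
    if not val_triples:
        return np.inf
    pairs, tails = _pairs_and_targets(val_triples, graph)
    preds, targs = [], []
    for (h, r), ts in zip(pairs, tails):
        p = expit(score_all_tails(model, h, r))
        y = np.zeros(len(graph.entities))
        y[ts] = 1.0
        preds.append(p)
        targs.append(y)
    return bernoulli_nll(np.concatenate(preds), np.concatenate(targs))


def predict_malignancy(model: TuckerModel, patient_entity: str) -> float:
    """Logistic-squashed score of (patient, pathology, malignant); in (0, 1)."""
    ei = model.entity_index
    if patient_entity not in ei:
        raise KeyError(f"unknown entity {patient_entity!r}")
    ri = model.relation_index
    s = score_triple(model, ei[patient_entity], ri[PATHOLOGY_RELATION], ei[MALIGNANT])
    return float(np.clip(expit(s), _CLAMP, 1.0 - _CLAMP))


def predict_label(model: TuckerModel, patient_entity: str) -> str:
    """Diagnosis by tail-score comparison; an exact tie goes to benign."""
    ei, ri = model.entity_index, model.relation_index
    if patient_entity not in ei:
        raise KeyError(f"unknown entity {patient_entity!r}")
    r = ri[PATHOLOGY_RELATION]
    s_mal = score_triple(model, ei[patient_entity], r, ei[MALIGNANT])
    s_ben = score_triple(model, ei[patient_entity], r, ei[BENIGN])
    return MALIGNANT if s_mal > s_ben else BENIGN
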