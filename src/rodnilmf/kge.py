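"""Relational-rotation knowledge-graph embedding (RotatE) with
self-adversarial negative sampling.

Each entity is a k-dimensional complex vector; each relation is stored as a
k-vector of phases theta so that its materialized elements e^{i theta} have
unit modulus by construction.  A relation acts on a head entity by
elementwise complex rotation, and a triple (h, r, t) is scored by how close
the rotated head lands to the tail:

    d(h, r, t)   = || Theta(h) o Theta(r) - Theta(t) ||        (Euclidean)
    f(h, r, t)   = -d(h, r, t)^2                               (score, <= 0)

Phase storage lets the three relation-algebra patterns be expressed exactly:
symmetric/antisymmetric relations have phases in {0, pi} (elements +-1),
inverse pairs have negated phases, and a composed relation is the
elementwise sum of its parts' phases.

Training minimizes a margin ranking loss over corrupted triples, with each
negative weighted by a softmax (temperature beta) of its current model
score — hard negatives count more.  The temperature decays over training as
beta = beta0 / (1 + sigmoid(progress)).  The squashing function g inside the
loss is either the logistic sigmoid or a tanh variant rescaled into (0, 1)
so the logarithm stays defined; tanh's steeper slope doubles the effective
sharpness of the margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.special import expit, log_expit

from .data_io import Triple

__all__ = [
    "KGETrainConfig",
    "KGEmbedding",
    "PatternHint",
    "init_embeddings",
    "rotate_distance",
    "score_triple",
    "self_adversarial_weights",
    "temperature",
    "negative_sampling_loss",
    "sample_negatives",
    "train_rotate",
    "filtered_ranks",
]

IndexedTriple = tuple[int, int, int]


@dataclass(frozen=True)
class KGETrainConfig:
    """Hyperparameters of the embedding trainer.

    dim
        embedding dimension k (complex coordinates per entity).
    batch_size
        positives per SGD mini-batch.
    margin
        ranking margin gamma separating true from corrupted triples.
    n_negatives
        corrupted triples drawn per positive.
    beta0
        initial self-adversarial temperature.
    optimization_function
        squashing function g in the loss: ``sigmoid`` or ``tanh`` (the tanh
        variant, rescaled into (0, 1)).
    temperature_mode
        ``normalized`` feeds the completed-training fraction i/n to the
        sigmoid of the temperature schedule; ``raw`` feeds the step index.
    squared_score
        if True the score is -d^2; if False, -d.
    """

    dim: int = 64
    batch_size: int = 128
    margin: float = 6.0
    n_negatives: int = 16
    beta0: float = 1.0
    optimization_function: Literal["sigmoid", "tanh"] = "tanh"
    learning_rate: float = 1.0
    epochs: int = 100
    seed: int = 0
    temperature_mode: Literal["normalized", "raw"] = "normalized"
    squared_score: bool = True

    def __post_init__(self) -> None:
        if self.dim < 1 or self.batch_size < 1 or self.n_negatives < 1 or self.epochs < 1:
            raise ValueError("dim, batch_size, n_negatives and epochs must be >= 1")
        if self.margin <= 0 or self.beta0 <= 0 or self.learning_rate <= 0:
            raise ValueError("margin, beta0 and learning_rate must be positive")
        if self.optimization_function not in ("sigmoid", "tanh"):
            raise ValueError(f"unknown optimization function {self.optimization_function!r}")


@dataclass
class KGEmbedding:
    """Complex entity vectors plus relation phase vectors (radians)."""

    entity_ids: tuple[str, ...]
    relation_ids: tuple[str, ...]
    entity: np.ndarray        # (n_entities, k) complex128
    relation_phase: np.ndarray  # (n_relations, k) float64
    dim: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.entity.view(float))):
            raise ValueError("entity vectors must be finite")
        if not np.all(np.isfinite(self.relation_phase)):
            raise ValueError("relation phases must be finite")

    def entity_index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.entity_ids)}

    def relation_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.relation_ids)}

    def relation_element(self, r: int) -> np.ndarray:
        """Materialize relation r as unit-modulus complex multipliers."""
        return np.exp(1j * self.relation_phase[r])

    def copy(self) -> "KGEmbedding":
        return KGEmbedding(
            self.entity_ids, self.relation_ids, self.entity.copy(), self.relation_phase.copy(), self.dim
        )


PatternHint = Mapping[str, object]


def _resolve_pattern_phases(
    relations: Sequence[str],
    hints: Mapping[str, object],
    phases: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Overwrite hinted relations' phases in dependency order (in place)."""
    rel_index = {r: i for i, r in enumerate(relations)}
    for rid, hint in hints.items():
        if rid not in rel_index:
            raise ValueError(f"pattern hint references unknown relation {rid!r}")
    pending = dict(hints)
    resolved: set[str] = set(r for r in relations if r not in pending)
    # simple relations first, then dependents until a fixed point
    while pending:
        progressed = False
        for rid in list(pending):
            hint = pending[rid]
            if hint in ("symmetric", "antisymmetric"):
                phases[rel_index[rid]] = rng.choice([0.0, np.pi], size=phases.shape[1])
            elif isinstance(hint, str) and hint.startswith("inverse_of:"):
                other = hint.split(":", 1)[1]
                if other not in rel_index:
                    raise ValueError(f"inverse hint for {rid!r} references unknown relation {other!r}")
                if other not in resolved:
                    continue
                phases[rel_index[rid]] = -phases[rel_index[other]]
            elif isinstance(hint, str) and hint.startswith("compose_of:"):
                parts = hint.split(":", 1)[1].split(",")
                if len(parts) != 2:
                    raise ValueError(f"compose hint for {rid!r} must name two relations")
                if any(p not in rel_index for p in parts):
                    raise ValueError(f"compose hint for {rid!r} references unknown relations {parts}")
                if any(p not in resolved for p in parts):
                    continue
                phases[rel_index[rid]] = phases[rel_index[parts[0]]] + phases[rel_index[parts[1]]]
            else:
                raise ValueError(f"unrecognized pattern hint {hint!r} for relation {rid!r}")
            resolved.add(rid)
            del pending[rid]
            progressed = True
        if not progressed:
            raise ValueError(f"circular pattern hints among relations: {sorted(pending)}")


def init_embeddings(
    entities: Sequence[str],
    relations: Sequence[str],
    config: KGETrainConfig,
    pattern_hints: Mapping[str, object] | None = None,
) -> KGEmbedding:
    """Seeded random initialization, honoring relation-pattern hints.

    Entity coordinates are uniform in [-gamma/k, gamma/k] (margin-scaled
    noise); relation phases are uniform in [-pi, pi).  A relation hinted
    ``symmetric``/``antisymmetric`` gets phases drawn from {0, pi} so its
    elements are exactly +-1; ``inverse_of:<r>`` negates r's phases;
    ``compose_of:<r1>,<r2>`` sums their phases elementwise.
    """
    if len(set(entities)) != len(entities) or len(set(relations)) != len(relations):
        raise ValueError("entity and relation ids must be distinct")
    rng = np.random.default_rng(config.seed)
    k = config.dim
    bound = config.margin / k
    ent = rng.uniform(-bound, bound, size=(len(entities), k)) + 1j * rng.uniform(
        -bound, bound, size=(len(entities), k)
    )
    phases = rng.uniform(-np.pi, np.pi, size=(len(relations), k))
    if pattern_hints:
        _resolve_pattern_phases(relations, pattern_hints, phases, rng)
    return KGEmbedding(tuple(entities), tuple(relations), ent, phases, k)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _distances(emb: KGEmbedding, h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    rotated = emb.entity[h] * np.exp(1j * emb.relation_phase[r])
    diff = rotated - emb.entity[t]
    return np.sqrt(np.sum(diff.real**2 + diff.imag**2, axis=-1))


def rotate_distance(emb: KGEmbedding, triple: IndexedTriple) -> float:
    """Euclidean distance between the rotated head and the tail."""
    h, r, t = triple
    return float(_distances(emb, np.array([h]), np.array([r]), np.array([t]))[0])


def score_triple(emb: KGEmbedding, triple: IndexedTriple, squared: bool = True) -> float:
    """Triple plausibility: negated (squared) rotation distance, <= 0."""
    d = rotate_distance(emb, triple)
    return -(d * d) if squared else -d


def score_tails(emb: KGEmbedding, h: int, r: int, squared: bool = True) -> np.ndarray:
    """Scores of (h, r, e) for every candidate tail entity e."""
    rotated = emb.entity[h] * np.exp(1j * emb.relation_phase[r])
    diff = rotated[None, :] - emb.entity
    d2 = np.sum(diff.real**2 + diff.imag**2, axis=-1)
    return -d2 if squared else -np.sqrt(d2)


def score_heads(emb: KGEmbedding, r: int, t: int, squared: bool = True) -> np.ndarray:
    """Scores of (e, r, t) for every candidate head entity e."""
    rotated = emb.entity * np.exp(1j * emb.relation_phase[r])[None, :]
    diff = rotated - emb.entity[t][None, :]
    d2 = np.sum(diff.real**2 + diff.imag**2, axis=-1)
    return -d2 if squared else -np.sqrt(d2)


# ---------------------------------------------------------------------------
# self-adversarial machinery
# ---------------------------------------------------------------------------

def self_adversarial_weights(scores: np.ndarray, beta: float) -> np.ndarray:
    """Softmax of beta * score over the negatives, computed stably.

    The weights are treated as constants by the loss gradient.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one negative score")
    if beta <= 0:
        raise ValueError("temperature beta must be positive")
    z = beta * scores
    z = z - z.max(axis=-1, keepdims=True)
    w = np.exp(z)
    return w / w.sum(axis=-1, keepdims=True)


def temperature(step: int, total_steps: int, beta0: float, mode: str = "normalized") -> float:
    """Decaying self-adversarial temperature beta = beta0 / (1 + sigmoid(progress)).

    In ``normalized`` mode progress is the completed fraction step/total_steps,
    keeping the schedule active over the whole run; ``raw`` feeds the bare
    step index (which saturates the sigmoid within a few steps).
    """
    if not (1 <= step <= total_steps):
        raise ValueError("step must lie in [1, total_steps]")
    if beta0 <= 0:
        raise ValueError("beta0 must be positive")
    progress = step / total_steps if mode == "normalized" else float(step)
    return float(beta0 / (1.0 + expit(progress)))


# ---------------------------------------------------------------------------
# loss and gradients
# ---------------------------------------------------------------------------

@dataclass
class LossGradients:
    """Dense gradients w.r.t. entity vectors (complex: re + i*im) and phases."""

    entity: np.ndarray
    relation_phase: np.ndarray


def _batch_loss_and_grads(
    emb: KGEmbedding,
    pos: np.ndarray,      # (B, 3) int
    negs: np.ndarray,     # (B, n, 3) int
    gamma: float,
    beta: float,
    optimization_function: str,
    squared_score: bool = True,
    fixed_weights: np.ndarray | None = None,
) -> tuple[float, LossGradients]:
    s = 2.0 if optimization_function == "tanh" else 1.0  # (tanh(x)+1)/2 == sigmoid(2x)
    ent, phase = emb.entity, emb.relation_phase
    tiny = 1e-12

    def pieces(h, r, t):
        rot = ent[h] * np.exp(1j * phase[r])
        m = rot - ent[t]
        d2 = np.sum(m.real**2 + m.imag**2, axis=-1)
        return rot, m, d2, np.sqrt(np.maximum(d2, tiny))

    B, n = negs.shape[0], negs.shape[1]
    rot_p, m_p, d2_p, d_p = pieces(pos[:, 0], pos[:, 1], pos[:, 2])
    nh, nr, nt = negs[..., 0], negs[..., 1], negs[..., 2]
    rot_n, m_n, d2_n, d_n = pieces(nh, nr, nt)

    if fixed_weights is None:
        neg_scores = -d2_n if squared_score else -d_n
        w = self_adversarial_weights(neg_scores, beta)  # (B, n), constants for the gradient
    else:
        w = np.asarray(fixed_weights, dtype=float).reshape(B, n)

    loss_terms = -log_expit(s * (gamma - d_p)) - np.sum(w * log_expit(s * (d_n - gamma)), axis=1)
    loss = float(np.mean(loss_terms))
    if not np.isfinite(loss):
        bad = int(np.argmax(~np.isfinite(loss_terms)))
        raise FloatingPointError(f"non-finite loss at positive triple {tuple(pos[bad])}")

    # dL/dd, including the 1/B of the batch mean
    coef_p = s * expit(-s * (gamma - d_p)) / B                    # (B,)
    coef_n = -w * s * expit(-s * (d_n - gamma)) / B               # (B, n)

    grad_ent = np.zeros_like(ent)
    grad_phase = np.zeros_like(phase)

    def accumulate(h, r, t, rot, m, d, coef):
        a = coef / (2.0 * d)                       # d(d)/d(d2) chain factor x dL/dd
        rel = np.exp(1j * phase[r])
        gU = (2.0 * a)[..., None] * m * np.conj(rel)
        gV = (-2.0 * a)[..., None] * m
        gTheta = (-2.0 * a)[..., None] * np.imag(np.conj(m) * rot)
        np.add.at(grad_ent, h.ravel(), gU.reshape(-1, emb.dim))
        np.add.at(grad_ent, t.ravel(), gV.reshape(-1, emb.dim))
        np.add.at(grad_phase, r.ravel(), gTheta.reshape(-1, emb.dim))

    accumulate(pos[:, 0], pos[:, 1], pos[:, 2], rot_p, m_p, d_p, coef_p)
    accumulate(nh, nr, nt, rot_n, m_n, d_n, coef_n)
    return loss, LossGradients(grad_ent, grad_phase)


def negative_sampling_loss(
    emb: KGEmbedding,
    positive: IndexedTriple,
    negatives: Sequence[IndexedTriple],
    gamma: float,
    beta: float,
    optimization_function: str = "sigmoid",
    squared_score: bool = True,
    fixed_weights: np.ndarray | None = None,
) -> tuple[float, LossGradients]:
    """Self-adversarially weighted margin ranking loss for one positive.

    L = -log g(gamma - d(pos)) - sum_i p_i log g(d(neg_i) - gamma), where the
    p_i are the softmax weights of the negatives' scores (constants for the
    gradient) and g is the logistic sigmoid or the rescaled tanh
    (tanh(x)+1)/2.  Returns the loss and exact dense gradients.

    ``fixed_weights`` substitutes given constants for the softmax weights;
    because the gradient deliberately does not flow through the weights,
    derivative checks against finite differences should freeze them.
    """
    if len(negatives) == 0:
        raise ValueError("need at least one negative")
    if gamma <= 0:
        raise ValueError("margin gamma must be positive")
    pos = np.asarray([positive], dtype=int)
    negs = np.asarray([negatives], dtype=int)
    return _batch_loss_and_grads(
        emb, pos, negs, gamma, beta, optimization_function, squared_score, fixed_weights
    )


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------

def sample_negatives(
    positive: IndexedTriple,
    n: int,
    n_entities: int,
    known: set[IndexedTriple],
    rng: np.random.Generator | int,
) -> list[IndexedTriple]:
    """Draw n filtered corruptions of a positive triple.

    Each corruption replaces the head or the tail (fair coin) with a
    uniformly sampled entity; corruptions present in ``known`` are rejected
    and resampled.  Deterministic given the generator state / seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    h, r, t = positive
    out: list[IndexedTriple] = []
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not find {n} corruptions of {positive} not present in the known set"
            )
        e = int(rng.integers(n_entities))
        cand = (e, r, t) if rng.random() < 0.5 else (h, r, e)
        if cand in known:
            continue
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def index_triples(
    triples: Sequence[Triple],
    entity_vocab: Sequence[str] = (),
    relation_vocab: Sequence[str] = (),
) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Map string triples to index triples; ids in first-seen order.

    A preset vocabulary may be supplied so entities without triples (e.g.
    drugs with no knowledge-graph facts yet) still receive embeddings.
    """
    entities: dict[str, int] = {e: i for i, e in enumerate(entity_vocab)}
    relations: dict[str, int] = {r: i for i, r in enumerate(relation_vocab)}
    rows = []
    for t in triples:
        for e in (t.head, t.tail):
            if e not in entities:
                entities[e] = len(entities)
        if t.relation not in relations:
            relations[t.relation] = len(relations)
        rows.append((entities[t.head], relations[t.relation], entities[t.tail]))
    return np.asarray(rows, dtype=int), tuple(entities), tuple(relations)


def train_rotate(
    triples: Sequence[Triple] | np.ndarray,
    config: KGETrainConfig,
    pattern_hints: Mapping[str, object] | None = None,
    entity_ids: Sequence[str] | None = None,
    relation_ids: Sequence[str] | None = None,
) -> tuple[KGEmbedding, list[float]]:
    """Mini-batch SGD over shuffled triples with filtered self-adversarial
    negative sampling; returns the embedding and the per-epoch mean loss.

    ``triples`` is either a sequence of string triples (ids derived in
    first-seen order) or an already-indexed (n, 3) integer array with
    ``entity_ids``/``relation_ids`` supplied.
    """
    if isinstance(triples, np.ndarray):
        if entity_ids is None or relation_ids is None:
            raise ValueError("indexed triples need entity_ids and relation_ids")
        idx = np.asarray(triples, dtype=int)
        ents, rels = tuple(entity_ids), tuple(relation_ids)
    else:
        if len(triples) == 0:
            raise ValueError("cannot train on an empty triple set")
        idx, ents, rels = index_triples(triples)

    emb = init_embeddings(ents, rels, config, pattern_hints)
    rng = np.random.default_rng(config.seed + 1)
    known = set(map(tuple, idx.tolist()))
    n_tr = idx.shape[0]
    b = min(config.batch_size, n_tr)
    n_batches = (n_tr + b - 1) // b
    total_steps = config.epochs * n_batches
    n_ent = len(ents)

    trace: list[float] = []
    step = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n_tr)
        epoch_losses = []
        for bi in range(n_batches):
            step += 1
            batch = idx[order[bi * b : (bi + 1) * b]]
            negs = _sample_negative_batch(batch, config.n_negatives, n_ent, known, rng)
            beta = temperature(step, total_steps, config.beta0, config.temperature_mode)
            loss, grads = _batch_loss_and_grads(
                emb, batch, negs, config.margin, beta,
                config.optimization_function, config.squared_score,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training diverged (non-finite loss); try a smaller learning rate"
                )
            emb.entity -= config.learning_rate * grads.entity
            emb.relation_phase -= config.learning_rate * grads.relation_phase
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)))
    return emb, trace


def _sample_negative_batch(
    batch: np.ndarray, n_neg: int, n_entities: int, known: set, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized filtered corruption: resample any corruption found in known."""
    B = batch.shape[0]
    negs = np.repeat(batch[:, None, :], n_neg, axis=1).copy()
    flip = rng.random((B, n_neg)) < 0.5
    repl = rng.integers(n_entities, size=(B, n_neg))
    negs[..., 0] = np.where(flip, repl, negs[..., 0])
    negs[..., 2] = np.where(~flip, repl, negs[..., 2])
    for _ in range(100):
        flat = negs.reshape(-1, 3)
        bad = np.fromiter((tuple(row) in known for row in flat.tolist()), bool, count=flat.shape[0])
        if not bad.any():
            break
        bad = bad.reshape(B, n_neg)
        ii, jj = np.nonzero(bad)
        repl = rng.integers(n_entities, size=ii.size)
        flip_bad = rng.random(ii.size) < 0.5
        negs[ii, jj, 0] = np.where(flip_bad, repl, batch[ii, 0])
        negs[ii, jj, 2] = np.where(~flip_bad, repl, batch[ii, 2])
    else:
        raise RuntimeError("could not draw filtered negatives; known set too dense")
    return negs


# ---------------------------------------------------------------------------
# filtered ranking (link-recovery evaluation)
# ---------------------------------------------------------------------------

def filtered_ranks(
    emb: KGEmbedding,
    test: Iterable[IndexedTriple],
    known: set[IndexedTriple],
    squared: bool = True,
) -> list[int]:
    """Pessimistic filtered ranks of held-out triples (head and tail sides).

    For each test triple, the true tail (head) is ranked against every
    candidate entity, excluding candidates that would form another triple in
    ``known`` (the filtered setting).  Equal-scored competitors rank ahead of
    the true item.
    """
    ranks: list[int] = []
    for h, r, t in test:
        for side, scores, true_e in (
            ("tail", score_tails(emb, h, r, squared), t),
            ("head", score_heads(emb, r, t, squared), h),
        ):
            mask = np.ones(scores.shape[0], dtype=bool)
            for e in range(scores.shape[0]):
                trip = (h, r, e) if side == "tail" else (e, r, t)
                if trip != (h, r, t) and trip in known:
                    mask[e] = False
            true_score = scores[true_e]
            competitors = scores[mask]
            rank = int(np.sum(competitors >= true_score))  # true item included once
            # pessimistic: ties that are not the item itself push it down;
            # >= counts the item itself, so rank is already 1-based pessimistic
            ranks.append(rank)
    return ranks


def hit_at(ranks: Sequence[int], n: int) -> float:
    """Fraction of ranks within the top n."""
    ranks = np.asarray(ranks)
    if ranks.size == 0:
        raise ValueError("empty rank list")
    return float(np.mean(ranks <= n))
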