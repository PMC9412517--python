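"""Synthetic drug-target networks, consistent similarity matrices, and
knowledge graphs with planted structure.

The generator realizes the statistical assumption the whole model family
rests on: interactions arise from a low-rank latent space, and the drug and
target similarity matrices reflect proximity in that same space, so that
neighbor-based inference is informative.  Interaction probabilities are a
logistic function of scaled latent inner products; similarities are
rescaled cosines of latent rows plus symmetric noise; knowledge-graph
triples mirror the interactions (minus dropout, plus spurious edges) and
add auxiliary relations realizing the symmetric / inverse / composed
relation-algebra patterns over latent-nearest entity pairs.

All randomness flows from the spec's single seed through named
``SeedSequence`` substreams, so each artifact is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .data_io import InteractionMatrix, SimilarityMatrix, Triple
from .evaluation import DatasetBundle
from .kge import KGEmbedding

__all__ = [
    "SyntheticSpec",
    "generate_dti_network",
    "generate_kg",
    "generate_planted_rotation_kg",
    "generate_bundle",
]

#: logistic sharpness of the planted interaction probabilities; high enough
#: that the low-rank structure, not Bernoulli label noise, decides who
#: interacts (the true probabilities score held-out positives near-perfectly)
_LOGIT_GAIN = 6.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and noise parameters of one synthetic study.

    Defaults describe a mid-sized benchmark slice: 100 drugs x 80 targets
    with 5% of pairs interacting through a rank-5 latent space, mild
    similarity noise, and a knowledge graph that reproduces 100% of the
    interactions (kg_noise = 0 adds no spurious edges).
    """

    n_drugs: int = 100
    n_targets: int = 80
    latent_rank: int = 5
    interaction_density: float = 0.05
    similarity_noise: float = 0.05
    kg_noise: float = 0.0
    planted_relation_patterns: Mapping[str, int] = field(
        default_factory=lambda: {"symmetric": 1, "inverse": 1, "composed": 1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank > min(self.n_drugs, self.n_targets):
            raise ValueError("latent_rank must not exceed min(n_drugs, n_targets)")
        if not (0.0 < self.interaction_density < 1.0):
            raise ValueError("interaction_density must lie in (0, 1)")
        if self.similarity_noise < 0 or not (0.0 <= self.kg_noise < 1.0):
            raise ValueError("similarity_noise >= 0 and kg_noise in [0, 1) required")


def _substream(spec_seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, label]))


def _latent_factors(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    rng = _substream(spec.seed, 0)
    U = rng.normal(size=(spec.n_drugs, spec.latent_rank))
    V = rng.normal(size=(spec.n_targets, spec.latent_rank))
    return U, V


def _cosine_similarity_01(X: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    norms = np.maximum(np.linalg.norm(X, axis=1), 1e-12)
    C = (X @ X.T) / np.outer(norms, norms)
    S = (1.0 + C) / 2.0
    if noise > 0:
        E = rng.normal(0.0, noise, size=S.shape)
        S = S + (E + E.T) / 2.0
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate_dti_network(
    spec: SyntheticSpec,
) -> tuple[InteractionMatrix, SimilarityMatrix, SimilarityMatrix, np.ndarray]:
    """Draw the planted network: interactions, similarities, and the ground-
    truth probability matrix.

    Interactions are Bernoulli draws from a logistic low-rank model, then
    thinned or raised toward the requested density whenever the realized
    count strays more than 10% from it.
    """
    M, N = spec.n_drugs, spec.n_targets
    target_count = int(round(spec.interaction_density * M * N))
    if target_count < 1:
        raise ValueError("interaction_density too low: expected positive count is zero")
    U, V = _latent_factors(spec)
    raw = (U @ V.T) / np.sqrt(spec.latent_rank)

    # offset chosen by bisection so the expected density matches the spec
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if float(expit(_LOGIT_GAIN * raw + mid).mean()) < spec.interaction_density:
            lo = mid
        else:
            hi = mid
    truth = expit(_LOGIT_GAIN * raw + (lo + hi) / 2.0)

    rng = _substream(spec.seed, 1)
    Y = (rng.random((M, N)) < truth).astype(np.int8)
    realized = int(Y.sum())
    if abs(realized - target_count) > 0.1 * target_count:
        if realized > target_count:  # thin the least probable positives
            pos = np.argwhere(Y == 1)
            order = np.argsort(truth[pos[:, 0], pos[:, 1]], kind="stable")
            drop = pos[order[: realized - target_count]]
            Y[drop[:, 0], drop[:, 1]] = 0
        else:  # raise the most probable non-positives
            neg = np.argwhere(Y == 0)
            order = np.argsort(-truth[neg[:, 0], neg[:, 1]], kind="stable")
            add = neg[order[: target_count - realized]]
            Y[add[:, 0], add[:, 1]] = 1

    drug_ids = tuple(f"D{i:04d}" for i in range(M))
    target_ids = tuple(f"T{j:04d}" for j in range(N))
    rng_sim = _substream(spec.seed, 2)
    Sd = SimilarityMatrix(_cosine_similarity_01(U, spec.similarity_noise, rng_sim), drug_ids)
    St = SimilarityMatrix(_cosine_similarity_01(V, spec.similarity_noise, rng_sim), target_ids)
    return InteractionMatrix(Y, drug_ids, target_ids), Sd, St, truth


# ---------------------------------------------------------------------------
# knowledge-graph generation
# ---------------------------------------------------------------------------

def _proximity_pairs(X: np.ndarray, n_pairs: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Distinct ordered pairs ranked by latent cosine proximity."""
    norms = np.maximum(np.linalg.norm(X, axis=1), 1e-12)
    C = (X @ X.T) / np.outer(norms, norms)
    np.fill_diagonal(C, -np.inf)
    iu = np.triu_indices(C.shape[0], k=1)
    order = np.argsort(-C[iu], kind="stable")
    pairs = [(int(iu[0][o]), int(iu[1][o])) for o in order[:n_pairs]]
    return pairs


def generate_kg(spec: SyntheticSpec, interactions: InteractionMatrix) -> list[Triple]:
    """Emit the knowledge graph implied by an interaction matrix.

    One ``interacts`` triple per interaction, each dropped with probability
    kg_noise; spurious ``interacts`` triples over non-interacting pairs at
    the same rate; plus auxiliary drug-drug relations realizing the
    requested symmetric / inverse / composed patterns over latent-nearest
    pairs.  Deterministic given the spec seed.
    """
    rng = _substream(spec.seed, 3)
    triples: list[Triple] = []
    pos = np.argwhere(interactions.values == 1)
    keep = rng.random(pos.shape[0]) >= spec.kg_noise if spec.kg_noise > 0 else np.ones(pos.shape[0], bool)
    for (i, j), k in zip(pos, keep):
        if k:
            triples.append(Triple(interactions.drug_ids[i], "interacts", interactions.target_ids[j]))
    if spec.kg_noise > 0:
        n_spurious = int(round(spec.kg_noise * pos.shape[0]))
        neg = np.argwhere(interactions.values == 0)
        if n_spurious > 0 and neg.shape[0] > 0:
            take = rng.choice(neg.shape[0], size=min(n_spurious, neg.shape[0]), replace=False)
            for i, j in neg[take]:
                triples.append(
                    Triple(interactions.drug_ids[i], "interacts", interactions.target_ids[j])
                )

    # auxiliary relations over latent-nearest drug pairs; the latent factors
    # are re-derived from the spec seed, so they match the planted network
    U, _ = _latent_factors(replace(spec, n_drugs=len(interactions.drug_ids),
                                   n_targets=len(interactions.target_ids)))
    patterns = dict(spec.planted_relation_patterns or {})
    n_pairs = max(len(interactions.drug_ids), 10)
    pool = _proximity_pairs(U, 3 * n_pairs, rng)
    D = interactions.drug_ids

    for s in range(patterns.get("symmetric", 0)):
        rel = f"similar_to_{s}"
        for a, b in pool[:n_pairs]:
            triples.append(Triple(D[a], rel, D[b]))
            triples.append(Triple(D[b], rel, D[a]))
    for s in range(patterns.get("inverse", 0)):
        fwd, inv = f"parent_of_{s}", f"child_of_{s}"
        for a, b in pool[:n_pairs]:
            triples.append(Triple(D[a], fwd, D[b]))
            triples.append(Triple(D[b], inv, D[a]))
    for s in range(patterns.get("composed", 0)):
        r1, r2, r3 = f"step1_{s}", f"step2_{s}", f"both_steps_{s}"
        half = max(n_pairs // 2, 1)
        e1 = pool[:half]
        e2 = pool[half : 2 * half]
        triples.extend(Triple(D[a], r1, D[b]) for a, b in e1)
        triples.extend(Triple(D[a], r2, D[b]) for a, b in e2)
        # close the composition exhaustively so r1(a,b) & r2(b,c) => r3(a,c)
        heads2 = {}
        for b, c in e2:
            heads2.setdefault(b, []).append(c)
        for a, b in e1:
            for c in heads2.get(b, []):
                triples.append(Triple(D[a], r3, D[c]))

    # deduplicate preserving order, matching the loader contract
    seen: set[Triple] = set()
    out = []
    for t in triples:
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# planted-rotation KG (link-recovery oracle)
# ---------------------------------------------------------------------------

def generate_planted_rotation_kg(
    n_entities: int,
    n_relations: int,
    dim: int,
    n_triples: int,
    seed: int,
    n_clusters: int = 8,
    jitter: float = 0.25,
) -> tuple[list[Triple], KGEmbedding]:
    """A knowledge graph whose true triples are exactly the top-scoring
    pairs under a hidden rotation embedding.

    Entities live on the per-coordinate unit circle: their phase vectors
    are drawn around a handful of cluster centers (jitter in radians), and
    each relation's phases rotate one cluster center onto another.  The
    emitted triples are the (h, r, t) candidates whose rotated head lands
    closest to the tail; the cluster structure makes them mutually
    redundant, so a model trained on part of them can recover the rest.
    Returns the triples and the hidden embedding so training recovery can
    be measured against planted truth.
    """
    n_candidates = n_entities * (n_entities - 1) * n_relations
    if n_triples > n_candidates:
        raise ValueError(f"n_triples exceeds the {n_candidates} feasible candidates")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-np.pi, np.pi, size=(n_clusters, dim))
    assign = rng.integers(n_clusters, size=n_entities)
    ent_phase = centers[assign] + rng.normal(0.0, jitter, size=(n_entities, dim))
    rel_phase = np.empty((n_relations, dim))
    for r in range(n_relations):
        a, b = rng.choice(n_clusters, size=2, replace=False)
        rel_phase[r] = centers[b] - centers[a]
    entity = np.exp(1j * ent_phase)
    entity_ids = tuple(f"E{i:03d}" for i in range(n_entities))
    relation_ids = tuple(f"R{j}" for j in range(n_relations))
    emb = KGEmbedding(entity_ids, relation_ids, entity, rel_phase, dim)

    cands = []
    scores = []
    for r in range(n_relations):
        rotated = entity * np.exp(1j * rel_phase[r])[None, :]
        for h in range(n_entities):
            diff = rotated[h][None, :] - entity
            d2 = np.sum(diff.real**2 + diff.imag**2, axis=-1)
            for t in range(n_entities):
                if t == h:
                    continue
                cands.append((h, r, t))
                scores.append(-d2[t])
    scores_arr = np.asarray(scores)
    order = np.lexsort((np.arange(scores_arr.size), -scores_arr))
    triples = [
        Triple(entity_ids[cands[o][0]], relation_ids[cands[o][1]], entity_ids[cands[o][2]])
        for o in order[:n_triples]
    ]
    return triples, emb


# ---------------------------------------------------------------------------
# evaluation bundles
# ---------------------------------------------------------------------------

def generate_bundle(spec: SyntheticSpec, test_fraction: float = 0.25) -> DatasetBundle:
    """Package a planted network for evaluation: hold out a fixed fraction
    of positives as the test set (with every non-interacting pair as a test
    negative), keep the rest as the training-positive pool, and build the
    knowledge graph from the pool only, so the prior knowledge never
    contains test positives."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    Y, Sd, St, _ = generate_dti_network(spec)
    pos = np.argwhere(Y.values == 1)
    rng = _substream(spec.seed, 4)
    n_test = max(int(round(test_fraction * pos.shape[0])), 1)
    take = rng.choice(pos.shape[0], size=n_test, replace=False)
    is_test = np.zeros(pos.shape[0], dtype=bool)
    is_test[take] = True

    Y_pool = Y.values.copy()
    Y_pool[pos[is_test, 0], pos[is_test, 1]] = 0
    pool_matrix = InteractionMatrix(Y_pool, Y.drug_ids, Y.target_ids)

    neg = np.argwhere(Y.values == 0)
    test_cells = np.vstack([pos[is_test], neg])
    test_labels = np.concatenate([np.ones(is_test.sum(), dtype=int), np.zeros(neg.shape[0], dtype=int)])

    triples = generate_kg(spec, pool_matrix)
    return DatasetBundle(
        interactions=pool_matrix,
        drug_sim=Sd,
        target_sim=St,
        triples=triples,
        dti_relation="interacts",
        test_cells=test_cells,
        test_labels=test_labels,
    )
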