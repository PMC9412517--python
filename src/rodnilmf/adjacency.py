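"""Enriched interaction adjacency construction.

A trained embedding scores every (drug, DTI-relation, target) candidate;
pairs scoring above the minimum passing score xi are admitted into the
enriched binary adjacency Y', which then replaces the raw interaction
matrix as the input to the matrix-factorization stage.  Because the score
scale depends on the embedding dimension and the training run, the default
selection mode is a quantile of the candidate scores rather than an
absolute xi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import InteractionMatrix
from .kge import KGEmbedding, score_tails

__all__ = ["AdjacencyConfig", "score_all_pairs", "build_interaction_matrix", "default_quantile"]


@dataclass(frozen=True)
class AdjacencyConfig:
    """How embedding scores become adjacency entries.

    threshold_mode
        ``absolute`` admits pairs with score > xi; ``quantile`` admits the
        top fraction q of all candidate scores.
    keep_known
        OR the known interactions back in, so prior positives survive even
        when their score falls below the cut.
    """

    threshold_mode: str = "quantile"
    xi: float | None = None
    q: float | None = None
    dti_relation: str = "interacts"
    keep_known: bool = True

    def __post_init__(self) -> None:
        if self.threshold_mode == "absolute":
            if self.xi is None or self.q is not None:
                raise ValueError("absolute mode requires xi and no q")
        elif self.threshold_mode == "quantile":
            if self.q is None or self.xi is not None:
                raise ValueError("quantile mode requires q and no xi")
            if not (0.0 < self.q < 1.0):
                raise ValueError("quantile q must lie in (0, 1)")
        else:
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


def score_all_pairs(
    emb: KGEmbedding,
    drug_ids: Sequence[str],
    target_ids: Sequence[str],
    relation: str,
) -> np.ndarray:
    """Score matrix S[d, t] = f(drug d, relation, target t); entries <= 0."""
    eidx = emb.entity_index()
    ridx = emb.relation_index()
    missing = [x for x in list(drug_ids) + list(target_ids) if x not in eidx]
    if missing:
        raise KeyError(f"ids absent from the embedding: {missing[:10]}")
    if relation not in ridx:
        raise KeyError(f"relation {relation!r} absent from the embedding")
    r = ridx[relation]
    tcols = np.asarray([eidx[t] for t in target_ids])
    rows = []
    for d in drug_ids:
        rows.append(score_tails(emb, eidx[d], r)[tcols])
    return np.asarray(rows)


def default_quantile(known: InteractionMatrix) -> float:
    """Quantile that admits about as many pairs as are already known,
    capping the enriched density at roughly twice the known density."""
    dens = known.density()
    if dens <= 0.0:
        raise ValueError("known matrix has no positives; choose q explicitly")
    return min(dens, 0.5)


def build_interaction_matrix(
    scores: np.ndarray,
    known: InteractionMatrix,
    config: AdjacencyConfig,
) -> InteractionMatrix:
    """Threshold pair scores into the enriched binary adjacency Y'.

    Absolute mode: Y'[d, t] = 1 iff score > xi.  Quantile mode: exactly
    round(q * M * N) top-scoring cells are admitted, ties broken by score
    then by flat index.  With ``keep_known``, Y' <- Y' OR known.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != known.shape:
        raise ValueError(f"score shape {scores.shape} != known shape {known.shape}")
    if config.threshold_mode == "absolute":
        out = (scores > config.xi).astype(np.int8)
    else:
        flat = scores.ravel()
        if np.ptp(flat) == 0.0:
            raise ValueError("all candidate scores are equal; use absolute mode with an explicit xi")
        n_sel = int(round(config.q * flat.size))
        out = np.zeros(flat.size, dtype=np.int8)
        if n_sel > 0:
            # stable sort by (-score, index): equal scores admit lower flat index first
            order = np.lexsort((np.arange(flat.size), -flat))
            out[order[:n_sel]] = 1
        out = out.reshape(scores.shape)
    if config.keep_known:
        out = np.maximum(out, known.values)
    return InteractionMatrix(out, known.drug_ids, known.target_ids)
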