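"""Ranking metrics, cold-start cross-validation, and the sample-size
robustness experiment.

Four cross-validation scenarios reflect how a pair can be unseen: ``pair``
masks individual cells; ``new_drug`` masks whole drug rows (the held-out
drugs have no training interactions, the cold-start case); ``new_target``
masks whole target columns; ``new_both`` masks rows and columns jointly and
scores only the held-row x held-column block.  Unknown pairs in the test
scope are treated as negatives, the field's standard convention for these
benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .adjacency import AdjacencyConfig, build_interaction_matrix, default_quantile, score_all_pairs
from .data_io import InteractionMatrix, SimilarityMatrix, Triple
from .dnilmf import DnilmfConfig, fit_dnilmf, infer_new_latents, predict_interactions
from .kge import KGETrainConfig, train_rotate

__all__ = [
    "CvScenario",
    "split_cv",
    "curve_metrics",
    "rank_metrics",
    "dti_rank_queries",
    "DatasetBundle",
    "evaluate_cv",
    "sample_size_curve",
]


@dataclass(frozen=True)
class CvScenario:
    name: Literal["pair", "new_drug", "new_target", "new_both"]
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ("pair", "new_drug", "new_target", "new_both"):
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def _partition(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, folds)]


def split_cv(
    Y: InteractionMatrix | np.ndarray, scenario: CvScenario
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fold masks for the four cold-start scenarios.

    Returns (train_mask, test_mask) boolean matrices per fold: train_mask
    marks cells visible during training, test_mask the cells to score.  The
    masks are disjoint, test masks partition their scope across folds, and
    the split is deterministic given the scenario seed.
    """
    Yv = Y.values if isinstance(Y, InteractionMatrix) else np.asarray(Y)
    M, N = Yv.shape
    rng = np.random.default_rng(scenario.seed)
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if scenario.name == "pair":
        cells = _partition(M * N, scenario.folds, rng)
        for chunk in cells:
            test = np.zeros(M * N, dtype=bool)
            test[chunk] = True
            test = test.reshape(M, N)
            folds.append((~test, test))
    elif scenario.name == "new_drug":
        for rows in _partition(M, scenario.folds, rng):
            test = np.zeros((M, N), dtype=bool)
            test[rows, :] = True
            folds.append((~test, test))
    elif scenario.name == "new_target":
        for cols in _partition(N, scenario.folds, rng):
            test = np.zeros((M, N), dtype=bool)
            test[:, cols] = True
            folds.append((~test, test))
    else:  # new_both
        row_parts = _partition(M, scenario.folds, rng)
        col_parts = _partition(N, scenario.folds, rng)
        for rows, cols in zip(row_parts, col_parts):
            held_r = np.zeros(M, dtype=bool)
            held_r[rows] = True
            held_c = np.zeros(N, dtype=bool)
            held_c[cols] = True
            train = np.outer(~held_r, ~held_c)
            test = np.outer(held_r, held_c)
            folds.append((train, test))
    for i, (_, test) in enumerate(folds):
        if int(Yv[test].sum()) == 0:
            raise ValueError(
                f"fold {i} has zero test positives; use fewer folds or a denser matrix"
            )
    return folds


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def curve_metrics(scores: Sequence[float], labels: Sequence[int]) -> dict[str, float]:
    """AUC (Mann-Whitney, ties count 1/2) and AUPR (step-wise PR integration)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.size == 0 or labels.min() == labels.max():
        raise ValueError("both classes must be present to compute curve metrics")
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
    }


def rank_metrics(
    queries: Sequence[tuple[Sequence[float], int]],
    N_values: Sequence[int] = (1, 3, 10),
) -> dict[str, object]:
    """MRR and Hit@N over per-query candidate lists with one true item each.

    Ranks are 1-based and pessimistic: equal-scored competitors are placed
    ahead of the true item.
    """
    if len(queries) == 0:
        raise ValueError("empty query set")
    ranks = []
    for scores, true_idx in queries:
        s = np.asarray(scores, dtype=float)
        true_score = s[true_idx]
        rank = int(np.sum(s >= true_score))  # counts the true item itself once
        ranks.append(rank)
    ranks_arr = np.asarray(ranks)
    return {
        "mrr": float(np.mean(1.0 / ranks_arr)),
        "hits": {int(n): float(np.mean(ranks_arr <= n)) for n in N_values},
    }


def dti_rank_queries(
    pred: np.ndarray, truth: np.ndarray, test_mask: np.ndarray
) -> list[tuple[np.ndarray, int]]:
    """One ranking query per test positive: that positive against the test
    negatives of the same drug (other positives are filtered out)."""
    queries: list[tuple[np.ndarray, int]] = []
    for d in range(pred.shape[0]):
        cols = np.flatnonzero(test_mask[d])
        if cols.size == 0:
            continue
        labels = truth[d, cols]
        pos = cols[labels == 1]
        neg = cols[labels == 0]
        if pos.size == 0 or neg.size == 0:
            continue
        neg_scores = pred[d, neg]
        for p in pos:
            scores = np.concatenate(([pred[d, p]], neg_scores))
            queries.append((scores, 0))
    return queries


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

def evaluate_cv(
    Y: InteractionMatrix,
    drug_sim: SimilarityMatrix,
    target_sim: SimilarityMatrix,
    scenario: CvScenario,
    config: DnilmfConfig,
    rank_hits: Sequence[int] = (1, 3, 10),
) -> dict:
    """Cross-validate the DNILMF predictor under one of the four scenarios.

    Cold-start entities (no interaction in the fold's training matrix) get
    their latent rows inferred from similar known entities before
    prediction.  Returns per-fold and mean AUC/AUPR/MRR/Hit@N.
    """
    Yv = Y.values.astype(float)
    fold_reports = []
    for train_mask, test_mask in split_cv(Y, scenario):
        Y_train = Yv * train_mask
        model = fit_dnilmf(Y_train, drug_sim, target_sim, config)
        factors = model.factors
        drug_known = Y_train.sum(axis=1) > 0
        target_known = Y_train.sum(axis=0) > 0
        if not drug_known.all():
            factors = infer_new_latents(factors, drug_sim, drug_known, config.neighbors)
        if not target_known.all():
            factors = infer_new_latents(factors, target_sim, target_known, config.neighbors)
        pred = predict_interactions(
            factors, model.Sd, model.St, config.alpha, config.rho, config.tau
        )
        cm = curve_metrics(pred[test_mask], Yv[test_mask].astype(int))
        rm = rank_metrics(dti_rank_queries(pred, Yv, test_mask), rank_hits)
        fold_reports.append({**cm, **rm})
    mean = {
        "auc": float(np.mean([f["auc"] for f in fold_reports])),
        "aupr": float(np.mean([f["aupr"] for f in fold_reports])),
        "mrr": float(np.mean([f["mrr"] for f in fold_reports])),
        "hits": {
            int(n): float(np.mean([f["hits"][int(n)] for f in fold_reports])) for n in rank_hits
        },
    }
    return {"scenario": scenario.name, "folds": fold_reports, "mean": mean}


# ---------------------------------------------------------------------------
# sample-size robustness
# ---------------------------------------------------------------------------

@dataclass
class DatasetBundle:
    """Everything one evaluation run needs: the training-positive pool, the
    similarity matrices, the knowledge graph, and a fixed held-out test set."""

    interactions: InteractionMatrix            # pool of available training positives
    drug_sim: SimilarityMatrix
    target_sim: SimilarityMatrix
    triples: list[Triple]
    dti_relation: str
    test_cells: np.ndarray                     # (n, 2) int (drug, target)
    test_labels: np.ndarray                    # (n,) binary

    def pool_positives(self) -> np.ndarray:
        return np.argwhere(self.interactions.values == 1)


def _fit_predict_for_curve(
    Y_train: InteractionMatrix,
    bundle: DatasetBundle,
    model: str,
    dnilmf_config: DnilmfConfig,
    kge_scores: np.ndarray | None,
    quantile: float | None,
) -> np.ndarray:
    if model == "ro_dnilmf":
        assert kge_scores is not None
        q = quantile if quantile is not None else default_quantile(Y_train)
        cfg = AdjacencyConfig(threshold_mode="quantile", q=q, keep_known=True)
        Y_enriched = build_interaction_matrix(kge_scores, Y_train, cfg)
        fitted = fit_dnilmf(Y_enriched, bundle.drug_sim, bundle.target_sim, dnilmf_config)
    else:
        fitted = fit_dnilmf(Y_train, bundle.drug_sim, bundle.target_sim, dnilmf_config)
    return fitted.predict()


def sample_size_curve(
    bundle: DatasetBundle,
    sizes: Sequence[int],
    model: Literal["ro_dnilmf", "dnilmf_only"],
    seed: int,
    kge_config: KGETrainConfig | None = None,
    dnilmf_config: DnilmfConfig | None = None,
    quantile: float | None = None,
) -> list[dict[str, float]]:
    """AUC/AUPR on the bundle's fixed test set as the number of training
    interactions grows.

    For each size, that many positives are subsampled (seeded) from the
    bundle's pool, the chosen pipeline is run, and the fixed held-out cells
    are scored.  In the ``ro_dnilmf`` variant the embedding is trained once
    on the bundle's knowledge graph (which does not depend on the
    subsample) and its score matrix enriches each subsampled matrix; unless
    a quantile is given, the enrichment admits as many pairs as the KG
    asserts DTI facts.
    """
    if model not in ("ro_dnilmf", "dnilmf_only"):
        raise ValueError(f"unknown model {model!r}")
    dnilmf_config = dnilmf_config or DnilmfConfig()
    pool = bundle.pool_positives()
    if any(s <= 0 or s > pool.shape[0] for s in sizes):
        raise ValueError(f"sizes must lie in [1, {pool.shape[0]}]")

    kge_scores = None
    if model == "ro_dnilmf":
        from .kge import index_triples  # avoid polluting the module surface

        kge_config = kge_config or KGETrainConfig(
            dim=16, epochs=200, learning_rate=3.0, seed=seed
        )
        vocab = list(bundle.interactions.drug_ids) + list(bundle.interactions.target_ids)
        idx, ents, rels = index_triples(bundle.triples, entity_vocab=vocab)
        emb, _ = train_rotate(idx, kge_config, entity_ids=ents, relation_ids=rels)
        if quantile is None:
            # admit as many pairs as the knowledge graph asserts DTI facts:
            # the KG, not the (possibly tiny) subsample, carries the prior
            n_dti = len(
                {(t.head, t.tail) for t in bundle.triples if t.relation == bundle.dti_relation}
            )
            M, N = bundle.interactions.shape
            quantile = min(max(n_dti / (M * N), 1.0 / (M * N)), 0.5)
        kge_scores = score_all_pairs(
            emb, bundle.interactions.drug_ids, bundle.interactions.target_ids, bundle.dti_relation
        )

    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        chosen = pool[rng.choice(pool.shape[0], size=size, replace=False)]
        Yv = np.zeros(bundle.interactions.shape, dtype=np.int8)
        Yv[chosen[:, 0], chosen[:, 1]] = 1
        Y_train = InteractionMatrix(
            Yv, bundle.interactions.drug_ids, bundle.interactions.target_ids
        )
        cfg = replace(dnilmf_config, seed=dnilmf_config.seed + int(size))
        pred = _fit_predict_for_curve(Y_train, bundle, model, cfg, kge_scores, quantile)
        scores = pred[bundle.test_cells[:, 0], bundle.test_cells[:, 1]]
        cm = curve_metrics(scores, bundle.test_labels)
        rows.append({"size": int(size), **cm})
    return rows
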