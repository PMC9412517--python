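# rodnilmf

Drug–target interaction (DTI) prediction that combines **relational-rotation
knowledge-graph embedding** with **dual-network integrated logistic matrix
factorization** (Ro-DNILMF).

## Who this is for

Computational drug-repositioning work needs to rank candidate drug–target
pairs from three inputs: a binary interaction matrix `Ycn` (M drugs × N
targets), a drug–drug chemical-similarity matrix `Scd`, and a target–target
sequence-similarity matrix `Sct`. Pure matrix-factorization models ignore
prior knowledge (knowledge-graph facts about drugs and targets), while pure
knowledge-graph models cannot score *new* drugs or targets that have no
recorded interactions. This package runs both stages in sequence so each
covers the other's blind spot.

## The model

**Stage 1 — rotation embedding.** Every entity is a complex vector
Θ(h) ∈ ℂᵏ and every relation a unit-modulus rotation Θ(r) = e^{iθ}. A triple
(h, r, t) is scored by how closely the rotated head lands on the tail:

    d_r(h, t) = ‖Θ(h) ∘ Θ(r) − Θ(t)‖          f(h, r, t) = −d_r(h, t)²

Phase storage makes symmetry (θ ∈ {0, π}), inversion (θ₂ = −θ₁) and
composition (θ₃ = θ₁ + θ₂) exact algebraic properties. Training minimizes a
self-adversarial margin loss

    L = −log g(γ − d(pos)) − Σᵢ pᵢ · log g(d(negᵢ) − γ)

where the pᵢ are a softmax (temperature β, decaying as β₀ / (1 + σ(i/n)))
of the negatives' current scores and g is either the logistic sigmoid or a
tanh variant rescaled into (0, 1). Pairs scoring above a minimum passing
score ξ (or, by default, the top quantile of candidate scores) are added to
the interaction matrix, giving the *enriched* adjacency `Y′cn`.

**Stage 2 — dual-network logistic matrix factorization.** For each side, a
Gaussian interaction-profile kernel and a PSD-projected similarity kernel
are fused by similarity-network-style nonlinear diffusion
(P₁ ← L₁P₂L₁ᵀ + I, P₂ ← L₂P₁L₂ᵀ + I over K-nearest-neighbor local matrices)
into diffused kernels S_d, S_t. Latent factors D (M×r) and T (N×r) are then
fit by maximizing a positive-weighted Bernoulli likelihood, with L2 and
graph-Laplacian neighborhood penalties, under the smoothed logistic link

    P′ = σ( α·DTᵀ + ρ·S_d DTᵀ + τ·DTᵀ S_t ),   α + ρ + τ = 1.

Cold-start drugs/targets get interaction profiles and latent rows inferred
from their K most similar "known" neighbors, so the model can score
entities with no training interactions at all.

## Worked example

```
rodnilmf simulate --drugs 30 --targets 25 --rank 3 --density 0.1 --seed 1 --outdir demo
rodnilmf train-kge --triples demo/triples.tsv --known demo/interactions.tsv \
    --dim 8 --epochs 200 --lr 3.0 --out demo/kge.npz
rodnilmf build-adjacency --ckpt demo/kge.npz --known demo/interactions.tsv \
    --quantile 0.15 --out demo/adj.tsv
rodnilmf evaluate --interactions demo/adj.tsv --drug-sim demo/drug_sim.tsv \
    --target-sim demo/target_sim.tsv --scenario pair --folds 3 --rank 20 \
    --seed 1 --out demo/report.json
```

prints, in order,

```
wrote 228 triples and a (30, 25) interaction matrix to demo
final epoch mean loss: 0.261383
enriched density 0.1493 (known 0.0987)
mean AUC 0.7487  AUPR 0.3983
```

The simulator plants a rank-3 latent structure and emits a knowledge graph
consistent with it; the embedding's final training loss has converged;
enrichment admits the embedding's top 15% of pair scores, growing the
positive density from 0.099 to 0.149; and 3-fold cross-validated AUC/AUPR
measure how well the fitted model ranks held-out cells of the enriched
matrix. The same pipeline runs end-to-end from one YAML config via
`rodnilmf run --config cfg.yaml --outdir out`, which also writes a
deterministic `report.json` and a manifest with the config hash.

The library mirrors every CLI step (`rodnilmf.train_rotate`,
`build_interaction_matrix`, `fit_dnilmf`, `evaluate_cv`,
`sample_size_curve`, …) for programmatic use.

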