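# Methods

This note documents the models implemented in `rodnilmf`, the parameters
that matter, the numerical choices made where the design was genuinely
open, what the synthetic generator does and does not emulate, and the known
limitations.

## 1. Rotation embedding (stage 1)

Entities are complex k-vectors stored as free real/imaginary pairs;
relations are stored as phase vectors θ ∈ ℝᵏ and materialized as e^{iθ}, so
every relation element has unit modulus *by construction* — no projection
step is ever needed. The distance of a triple is
d = ‖Θ(h) ∘ e^{iθ} − Θ(t)‖ (Euclidean over ℂᵏ) and the score is −d².
An option (`squared_score=False`) scores by −d instead; the squared form is
the default because the adjacency construction thresholds scores, and the
square only reparameterizes the threshold.

Relation-algebra patterns are exact identities of phase storage:

- symmetric/antisymmetric: θ ∈ {0, π}ᵏ, elements ±1, hence r = r⁻¹;
- inversion: θ₂ = −θ₁, hence d(h, r₁, t) = d(t, r₂, h);
- composition: θ₃ = θ₁ + θ₂ elementwise.

`init_embeddings` accepts per-relation hints that initialize these patterns
exactly; hints are resolved in dependency order and circular composition
chains are rejected.

### Loss and training

The loss per positive is
L = −log g(γ − d_pos) − Σᵢ pᵢ log g(d_negᵢ − γ) with filtered corruptions
(head or tail replaced with a fair coin, resampling anything in the known
set). The self-adversarial weights pᵢ = softmax(β · scoreᵢ) are computed
with max-subtraction and treated as constants by the gradient — the
standard stop-gradient; derivative tests therefore freeze them
(`fixed_weights`).

*The tanh squashing function.* Taking a logarithm of tanh(x) is undefined
for x ≤ 0, so the tanh variant is realized as g(x) = (tanh(x) + 1)/2 —
identically sigmoid(2x). This keeps the log defined while preserving the
motivation for tanh: a steeper slope around the margin, i.e. effectively a
doubled sharpness. It is the default (`optimization_function="tanh"`).

*Temperature schedule.* β = β₀ / (1 + σ(progress)). Fed the raw step index,
σ saturates after a handful of steps and the schedule degenerates to the
constant β₀/2; the default therefore uses progress = i/n (completed
fraction of training), which decays β smoothly from β₀/1.5 toward β₀/1.73
over the run. `temperature_mode="raw"` restores the raw-index reading.

*Optimizer.* Plain mini-batch SGD with a fixed learning rate. Because
entities move on a unit-modulus-scale geometry (the planted generators and
converged embeddings have coordinates of order 1), the default learning
rate is 1.0; the link-recovery experiments use 3.0. Adam was prototyped and
gave no advantage at these problem sizes. Entity initialization is uniform
in [−γ/k, γ/k] per real coordinate (margin-scaled noise); relation phases
uniform in [−π, π).

Exact analytic gradients (w.r.t. entity real/imag parts and relation
phases) are validated against central finite differences at relative error
< 1e-5; training is bitwise reproducible given the config seed.

## 2. Adjacency enrichment

All (drug, DTI-relation, target) candidates are scored by the trained
embedding and thresholded. Because score scales depend on k and on the
training run, an absolute threshold ξ is meaningless across runs; the
default mode selects the top quantile q of candidate scores (exact count
round(q·M·N), ties broken by score then flat index). `default_quantile`
sets q to the known density, capping the enriched density at about twice
the known one. Known interactions are OR-ed back in (`keep_known=True`):
the factorization stage would otherwise lose training signal whenever a
true pair scores below the cut.

Inside the sample-size experiment the quota is different: there the
knowledge graph is the prior and the training matrix is a deliberately tiny
subsample, so capping enrichment at twice the subsample density would
discard most of what the KG knows. The enrichment there defaults to
admitting as many pairs as the KG asserts DTI facts.

## 3. Dual-network logistic matrix factorization (stage 2)

### Kernels and diffusion

Each side (drugs, targets) contributes two similarity views:

1. the chemical/sequence similarity matrix, projected to the nearest PSD
   matrix (eigenvalue clipping) and rescaled to unit diagonal;
2. a Gaussian kernel exp(−‖Yᵢ − Yⱼ‖²/φ) over interaction profiles, with
   profiles of entities that have no interactions inferred as the
   similarity-weighted mean of their K nearest "known" neighbors
   (known = at least one interaction; ties broken by lower index).

The bandwidth φ defaults to the mean squared profile norm of the side
(self-scaling); it can be fixed explicitly.

Both views are row-normalized into status matrices
P[i,j] = K[i,j] / (2 Σ_{k≠i} K[i,k]), P[i,i] = ½ (rows sum to 1), and
fused by alternating diffusion: local matrices L₁, L₂ keep each row's K
largest off-diagonal entries renormalized (computed **once** from the
initial status matrices, the similarity-network-fusion convention), and t
iterations apply, simultaneously from the previous pair,

    P₁ ← L₁ P₂ L₁ᵀ + I        P₂ ← L₂ P₁ L₂ᵀ + I.

The identity term is added to both matrices each iteration (the two printed
update rules are treated as one rule applied to each view) and keeps the
iteration well conditioned. The fused kernel is the arithmetic mean of the
final pair, symmetrized by averaging with its transpose. Diffusion
preserves symmetry, finiteness and non-negativity for all tested t ≤ 50.

### Objective

With P′ = σ(α·DTᵀ + ρ·S_d DTᵀ + τ·DTᵀ S_t), α+ρ+τ = 1 (enforced; values
outside α ∈ [0.5, 1], ρ,τ ∈ [0, 0.25] warn), the fit maximizes

    Σ [ c·Y·log P′ + (1−Y)·log(1−P′) ]
      − (λ_d/2)‖D‖² − (λ_t/2)‖T‖²
      − (η/2) [ tr(Dᵀ L_d D) + tr(Tᵀ L_t T) ]

where L_d, L_t are the unnormalized graph Laplacians of the diffused
kernels and η is `neighborhood_weight`. The Laplacian term is the one
genuinely open design choice of the package: with plain L2 only, the
latent product DTᵀ memorizes the observed cells and generalizes *worse*
than simply smoothing Y with the diffused kernels (held-out AUC ~0.88 vs
~0.93 on the planted benchmark); pulling latent rows of similar entities
together closes that gap and pushes the fit past the smoothing baseline
(~0.92–0.96). η = 0 recovers the plain objective. Defaults: c = 5,
λ_d = λ_t = 0.625, η = 2, α/ρ/τ = 0.5/0.25/0.25, r = 100 (capped at
min(M, N); the recovery experiments use r = 20).

Ascent uses AdaGrad per-parameter steps with a backtracking safeguard:
a proposed step is accepted only if the objective does not decrease
(within 1e-12), otherwise the step size is halved and retried; on
acceptance it relaxes back up (×1.1, capped). The objective trajectory is
therefore monotone by construction and the fit is deterministic given the
seed. The smoothed-logit gradient is
∂obj/∂(DTᵀ) = α G + ρ S_d G + τ G S_t with G = cY(1−P′) − (1−Y)P′, using
the symmetry of S_d, S_t.

### Cold start

A "new" entity (no interactions in the training matrix) is handled twice
with the same weighted-neighbor formula: its interaction profile is
inferred before the Gaussian kernel is built, and after fitting its latent
row is replaced by the similarity-weighted mean of its K nearest known
entities' latent rows. The neighbor weights are the raw similarities; the
side is dispatched from the similarity matrix size.

## 4. Evaluation

- **AUC** is the Mann–Whitney statistic (ties ½) and **AUPR** the
  step-wise precision–recall integral; both are delegated to scikit-learn
  and cross-checked in the test suite against independent brute-force
  implementations (exhaustive pair counting; grouped step integration).
- **MRR / Hit@N** use 1-based pessimistic ranks: equal-scored competitors
  rank ahead of the true item.
- **Cross-validation scenarios**: `pair` partitions cells; `new_drug` /
  `new_target` partition whole rows/columns (held-out entities have no
  training interactions — the cold-start definition); `new_both` partitions
  rows and columns jointly and scores only held-row × held-column cells.
  All unknown pairs in the test scope count as negatives, the field's
  standard convention. Folds with no test positives are rejected.
- **Sample-size curve**: a fixed held-out set is scored while the number of
  training positives grows; the embedding is trained once per bundle
  because the knowledge graph does not depend on the subsample.

## 5. The synthetic generator

The generator makes explicit the statistical assumption the whole model
family rests on: interactions arise from a low-rank latent space and the
similarity matrices reflect proximity in that same space (otherwise
neighbor-based inference carries no information).

- Latent factors U (M×r), V (N×r) are standard normal. True interaction
  probabilities are σ(g·UVᵀ/√r + b) with gain g = 6 and offset b bisected
  so the expected density matches the spec. The gain is set high enough
  that the planted structure, not Bernoulli sampling noise, determines who
  interacts: at g = 6 the true probabilities themselves separate held-out
  positives from negatives at AUC ≈ 0.99, so recovery scores measure the
  model rather than irreducible label noise (at g = 3 that oracle ceiling
  is only ~0.95).
- Interactions are Bernoulli draws, thinned (lowest-probability positives
  removed) or raised (highest-probability negatives added) whenever the
  realized count strays more than 10% from the target.
- Similarities are latent-row cosines rescaled to [0, 1] with unit
  diagonal, plus symmetric Gaussian noise (default sd 0.05), clipped.
- The knowledge graph emits one `interacts` triple per interaction (each
  dropped with probability `kg_noise`), spurious triples at the same rate,
  and auxiliary drug–drug relations realizing the symmetric / inverse /
  composed patterns over latent-nearest pairs, with compositions closed
  exhaustively.
- `generate_planted_rotation_kg` hides a ground-truth rotation embedding
  whose entity phases cluster around a few centers and whose relation
  phases rotate one center onto another; the emitted triples are exactly
  the top-scoring candidates. The clustering is what makes the graph
  redundant enough that 80% of the triples determine the remaining 20%
  (i.i.d. phases produce a near-memorization-only graph).
- All randomness flows from one seed through named `SeedSequence`
  substreams.

What the generator does **not** emulate: real chemical/sequence similarity
distributions (SIMCOMP and Smith–Waterman scores are bimodal and sparse),
hub-dominated degree distributions of curated interaction databases,
relation vocabularies beyond the planted patterns, and any biological
block structure not expressible as a low-rank logistic model. Passing the
recovery tests therefore shows the pipeline is correct and powerful *under
the model's own assumptions*, not that it attains any particular accuracy
on real benchmark data.

## 6. Problem sizes and reproducibility

The recovery experiments run at desk scale, chosen so the full suite and
the acceptance script complete in minutes: 50-entity / 400-triple planted
KGs (dim 8), 100×80 rank-5 networks at 5% density, 60×50 cold-start
networks, 10 seeds per stochastic claim. The full pipeline is
deterministic end to end: identical config and seed give byte-identical
evaluation reports (JSON with sorted keys, no timestamps).

## 7. Known limitations

- The fitting procedure for D, T is a package design (the lineage's
  weighted logistic objective with Laplacian smoothing); other fits of the
  same link are possible and may behave differently on real data.
- Whether the smoothed link should consume latent factors or inferred
  profile matrices is ambiguous in the model family's notation; the
  latent-factor reading is implemented (dimensions only close for it).
- Dense numpy linear algebra throughout: fine to a few thousand entities,
  not engineered for the 10⁴–10⁵ scale of full public databases.
- `train_rotate` keeps the known-triple filter as a Python set; extremely
  dense graphs would slow negative sampling.
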