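"""Dual-network integrated logistic matrix factorization (DNILMF).

The predictor models the probability that drug d interacts with target t as
a logistic function of a smoothed latent-factor product:

    Z  = alpha * D T' + rho * Sd D T' + tau * D T' St,   alpha+rho+tau = 1
    P  = exp(Z) / (1 + exp(Z))

where D (M x r) and T (N x r) are latent factors and Sd, St are *diffused*
drug and target kernels.  Each side's kernel fuses two views — a kernel
derived from the chemical/sequence similarity matrix and a Gaussian kernel
over interaction profiles — by an alternating nonlinear diffusion in the
similarity-network-fusion style: each view is row-normalized into a status
matrix, sparsified to its K nearest neighbors, and the two views repeatedly
exchange mass through L1 @ P2 @ L1' and L2 @ P1 @ L2' updates.

Cold-start entities (no known interactions) enter the model twice: their
interaction profiles are inferred from similar known entities before the
Gaussian kernels are built, and after fitting their latent rows are
inferred the same way from known entities' latent rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit, log_expit

from .data_io import InteractionMatrix, SimilarityMatrix

__all__ = [
    "DnilmfConfig",
    "LatentFactors",
    "DiffusedKernel",
    "infer_profile",
    "gaussian_kernel_matrix",
    "similarity_to_kernel",
    "status_matrix",
    "local_similarity",
    "diffuse",
    "fit_latent_factors",
    "infer_new_latents",
    "predict_interactions",
    "build_diffused_kernels",
    "DnilmfModel",
    "fit_dnilmf",
]


@dataclass(frozen=True)
class DnilmfConfig:
    """Hyperparameters of the DNILMF stage.

    alpha, rho, tau
        smoothing coefficients of the plain, drug-kernel-smoothed and
        target-kernel-smoothed latent products; must sum to 1.
    neighbors
        K, the nearest-neighbor count used for profile inference and for
        the local sparsification inside diffusion.
    bandwidth
        Gaussian kernel bandwidth phi; ``None`` self-scales to the mean
        squared profile norm of the side being kernelized.
    diffusion_steps
        t, the number of alternating diffusion iterations.
    rank
        latent dimension r of D and T.
    positive_weight
        c, the importance weight on observed interactions in the likelihood.
    neighborhood_weight
        strength of the graph-Laplacian penalty pulling latent rows of
        similar entities together (0 disables it, leaving plain L2 only).
    """

    alpha: float = 0.5
    rho: float = 0.25
    tau: float = 0.25
    neighbors: int = 5
    bandwidth: float | None = None
    diffusion_steps: int = 2
    rank: int = 100
    positive_weight: float = 5.0
    lambda_d: float = 0.625
    lambda_t: float = 0.625
    neighborhood_weight: float = 2.0
    learning_rate: float = 0.5
    iterations: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.alpha + self.rho + self.tau - 1.0) > 1e-8:
            raise ValueError("smoothing coefficients alpha + rho + tau must sum to 1")
        if not (0.5 <= self.alpha <= 1.0 and 0.0 <= self.rho <= 0.25 and 0.0 <= self.tau <= 0.25):
            warnings.warn(
                "smoothing coefficients outside the usual ranges "
                "(alpha in [0.5,1], rho/tau in [0,0.25])",
                stacklevel=2,
            )
        if self.neighbors < 1 or self.diffusion_steps < 1 or self.rank < 1:
            raise ValueError("neighbors, diffusion_steps and rank must be >= 1")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth phi must be positive")


@dataclass
class LatentFactors:
    """Drug (M x r) and target (N x r) latent factor matrices."""

    drug_factors: np.ndarray
    target_factors: np.ndarray

    def __post_init__(self) -> None:
        if self.drug_factors.shape[1] != self.target_factors.shape[1]:
            raise ValueError("drug and target factors must share the latent rank")
        if not (np.all(np.isfinite(self.drug_factors)) and np.all(np.isfinite(self.target_factors))):
            raise ValueError("latent factors must be finite")

    @property
    def rank(self) -> int:
        return self.drug_factors.shape[1]


@dataclass(frozen=True)
class DiffusedKernel:
    """Fused kernel after diffusion: square, symmetric, non-negative."""

    values: np.ndarray
    side: Literal["drug", "target"]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("diffused kernel must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("diffused kernel must be finite")
        if np.abs(v - v.T).max(initial=0.0) > 1e-8:
            raise ValueError("diffused kernel must be symmetric within 1e-8")
        if v.size and v.min() < -1e-12:
            raise ValueError("diffused kernel must be non-negative")
        object.__setattr__(self, "values", np.maximum((v + v.T) / 2.0, 0.0))


# ---------------------------------------------------------------------------
# interaction-profile inference for cold-start entities
# ---------------------------------------------------------------------------

def _neighbor_weights(
    sims: np.ndarray, known: np.ndarray, index: int, K: int
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and similarity weights of the K most similar known entities."""
    candidates = np.flatnonzero(known)
    candidates = candidates[candidates != index]
    if candidates.size == 0:
        raise ValueError("no known entities to infer from")
    # K most similar, ties broken by lower index (stable lexsort)
    order = np.lexsort((candidates, -sims[candidates]))
    chosen = candidates[order[:K]]
    w = sims[chosen]
    if w.sum() <= 0.0:
        raise ValueError(f"all candidate neighbors of entity {index} have zero similarity")
    return chosen, w


def infer_profile(
    Y: InteractionMatrix | np.ndarray,
    S: SimilarityMatrix | np.ndarray,
    index: int,
    K: int,
    side: Literal["drug", "target"] = "drug",
) -> np.ndarray:
    """Similarity-weighted mean of the K nearest known neighbors' profiles.

    profile_i = sum_u S[i,u] * Y[u, :] / sum_u S[i,u] over the K most
    similar entities u (same side) that have at least one interaction.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    Yv = Y.values if isinstance(Y, InteractionMatrix) else np.asarray(Y, dtype=float)
    Sv = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    profiles = Yv if side == "drug" else Yv.T
    known = profiles.sum(axis=1) > 0
    chosen, w = _neighbor_weights(Sv[index], known, index, K)
    return (w @ profiles[chosen]) / w.sum()


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def gaussian_kernel_matrix(profiles: np.ndarray, phi: float) -> np.ndarray:
    """Gaussian interaction-profile kernel K[i,j] = exp(-||Y_i - Y_j||^2 / phi)."""
    if phi <= 0:
        raise ValueError("bandwidth phi must be positive")
    P = np.asarray(profiles, dtype=float)
    sq = np.sum(P * P, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (P @ P.T)
    d2 = np.maximum(d2, 0.0)
    K = np.exp(-d2 / phi)
    np.fill_diagonal(K, 1.0)
    return (K + K.T) / 2.0


def similarity_to_kernel(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Nearest-PSD projection of a similarity matrix with unit diagonal.

    Symmetrize, clip negative eigenvalues to zero, then rescale
    symmetrically so the diagonal returns to 1.
    """
    Sv = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    A = (Sv + Sv.T) / 2.0
    vals, vecs = np.linalg.eigh(A)
    if vals.min(initial=0.0) < 0.0:
        A = (vecs * np.maximum(vals, 0.0)) @ vecs.T
        A = (A + A.T) / 2.0
    d = np.sqrt(np.maximum(np.diag(A), 1e-12))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return A


def status_matrix(Kmat: np.ndarray) -> np.ndarray:
    """Half-mass-to-self row normalization used as the diffusion state.

    P[i,j] = K[i,j] / (2 * sum_{k != i} K[i,k]) off the diagonal and
    P[i,i] = 1/2, so every row sums to 1.
    """
    K = np.asarray(Kmat, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("status_matrix needs a square matrix")
    if np.abs(K - K.T).max(initial=0.0) > 1e-8:
        raise ValueError("status_matrix needs a symmetric matrix")
    if K.min(initial=0.0) < 0:
        raise ValueError("status_matrix needs a non-negative matrix")
    off = K.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    if np.any(row <= 0.0):
        bad = np.flatnonzero(row <= 0.0)
        raise ValueError(f"rows {bad.tolist()[:10]} have all-zero off-diagonal mass")
    P = off / (2.0 * row[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def local_similarity(P: np.ndarray, K: int) -> np.ndarray:
    """Sparsify each row to its K nearest neighbors and renormalize.

    L[i,j] = P[i,j] / sum_{k in Ni} P[i,k] for j in Ni, else 0, where Ni is
    the set of K largest off-diagonal entries of row i (ties broken by
    lower index).  Rows sum to 1 over Ni.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if not (1 <= K < n):
        raise ValueError("neighbors K must satisfy 1 <= K < n")
    L = np.zeros_like(P)
    idx = np.arange(n)
    for i in range(n):
        cand = idx[idx != i]
        order = np.lexsort((cand, -P[i, cand]))
        Ni = cand[order[:K]]
        mass = P[i, Ni].sum()
        if mass <= 0.0:
            raise ValueError(f"row {i}: top-{K} neighborhood has zero mass")
        L[i, Ni] = P[i, Ni] / mass
    return L


def diffuse(P1: np.ndarray, P2: np.ndarray, K: int, t: int, side: str = "drug") -> DiffusedKernel:
    """Alternating nonlinear diffusion of two status-matrix views.

    The local matrices L1, L2 are computed once from the initial status
    matrices.  Each of t iterations updates, from the previous pair,
    P1 <- L1 @ P2 @ L1' + I and P2 <- L2 @ P1 @ L2' + I (the identity term
    keeps each view symmetric-dominant and well conditioned).  The fused
    kernel is the average of the final pair, symmetrized.
    """
    P1 = np.asarray(P1, dtype=float)
    P2 = np.asarray(P2, dtype=float)
    if P1.shape != P2.shape or P1.ndim != 2:
        raise ValueError("status matrices must share a square shape")
    if t < 1:
        raise ValueError("diffusion steps t must be >= 1")
    L1 = local_similarity(P1, K)
    L2 = local_similarity(P2, K)
    I = np.eye(P1.shape[0])
    for it in range(1, t + 1):
        new1 = L1 @ P2 @ L1.T + I
        new2 = L2 @ P1 @ L2.T + I
        if not (np.all(np.isfinite(new1)) and np.all(np.isfinite(new2))):
            raise FloatingPointError(f"diffusion produced non-finite values at iteration {it}")
        P1, P2 = new1, new2
    fused = (P1 + P2) / 2.0
    fused = (fused + fused.T) / 2.0
    return DiffusedKernel(fused, side)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# latent-factor fitting
# ---------------------------------------------------------------------------

def _smoothed_logits(D: np.ndarray, T: np.ndarray, Sd: np.ndarray, St: np.ndarray,
                     alpha: float, rho: float, tau: float) -> np.ndarray:
    M0 = D @ T.T
    return alpha * M0 + rho * (Sd @ M0) + tau * (M0 @ St)


def _objective(Y: np.ndarray, Z: np.ndarray, c: float, lam_d: float, lam_t: float,
               D: np.ndarray, T: np.ndarray,
               Ld: np.ndarray | None = None, Lt: np.ndarray | None = None,
               eta: float = 0.0) -> float:
    ll = c * Y * log_expit(Z) + (1.0 - Y) * log_expit(-Z)
    obj = ll.sum() - 0.5 * lam_d * np.sum(D * D) - 0.5 * lam_t * np.sum(T * T)
    if eta > 0.0 and Ld is not None and Lt is not None:
        obj -= 0.5 * eta * (np.sum(D * (Ld @ D)) + np.sum(T * (Lt @ T)))
    return float(obj)


def fit_latent_factors(
    Y: InteractionMatrix | np.ndarray,
    Sd: DiffusedKernel | np.ndarray,
    St: DiffusedKernel | np.ndarray,
    config: DnilmfConfig,
) -> LatentFactors:
    """Fit D, T by maximizing the weighted, neighborhood-regularized
    Bernoulli log-likelihood.

    objective = sum_{d,t} [ c*Y*log P' + (1-Y)*log(1-P') ]
                - (lambda_d/2)||D||^2 - (lambda_t/2)||T||^2
                - (eta/2) [ tr(D' L_d D) + tr(T' L_t T) ]

    with P' the smoothed logistic link of ``predict_interactions`` and L_d,
    L_t the graph Laplacians of the diffused kernels (eta is
    ``neighborhood_weight``; the Laplacian term pulls latent rows of
    similar entities together, which is what lets the factorization
    generalize beyond the observed cells).  Ascent uses AdaGrad
    per-parameter steps with a backtracking safeguard so the objective
    never decreases; deterministic given the config seed.
    """
    Yv = (Y.values if isinstance(Y, InteractionMatrix) else np.asarray(Y)).astype(float)
    Sdv = Sd.values if isinstance(Sd, DiffusedKernel) else np.asarray(Sd, dtype=float)
    Stv = St.values if isinstance(St, DiffusedKernel) else np.asarray(St, dtype=float)
    M, N = Yv.shape
    if Sdv.shape != (M, M) or Stv.shape != (N, N):
        raise ValueError("kernel shapes do not match the interaction matrix")
    a, rho, tau = config.alpha, config.rho, config.tau
    c, lam_d, lam_t = config.positive_weight, config.lambda_d, config.lambda_t
    eta = config.neighborhood_weight
    r = min(config.rank, M, N)

    Ld = np.diag(Sdv.sum(axis=1)) - Sdv if eta > 0 else None
    Lt = np.diag(Stv.sum(axis=1)) - Stv if eta > 0 else None

    rng = np.random.default_rng(config.seed)
    D = rng.normal(0.0, 1.0 / np.sqrt(r), size=(M, r))
    T = rng.normal(0.0, 1.0 / np.sqrt(r), size=(N, r))

    accD = np.zeros_like(D)
    accT = np.zeros_like(T)
    eps = 1e-8
    scale = 1.0
    obj = _objective(Yv, _smoothed_logits(D, T, Sdv, Stv, a, rho, tau),
                     c, lam_d, lam_t, D, T, Ld, Lt, eta)
    if not np.isfinite(obj):
        raise FloatingPointError("non-finite objective at initialization")

    for _ in range(config.iterations):
        Z = _smoothed_logits(D, T, Sdv, Stv, a, rho, tau)
        P = expit(Z)
        G = c * Yv * (1.0 - P) - (1.0 - Yv) * P
        H = a * G + rho * (Sdv @ G) + tau * (G @ Stv)
        gD = H @ T - lam_d * D
        gT = H.T @ D - lam_t * T
        if eta > 0:
            gD -= eta * (Ld @ D)
            gT -= eta * (Lt @ T)
        accD_c = accD + gD * gD
        accT_c = accT + gT * gT
        stepD = gD / np.sqrt(accD_c + eps)
        stepT = gT / np.sqrt(accT_c + eps)
        accepted = False
        for _bt in range(40):
            lr = config.learning_rate * scale
            Dn = D + lr * stepD
            Tn = T + lr * stepT
            objn = _objective(Yv, _smoothed_logits(Dn, Tn, Sdv, Stv, a, rho, tau),
                              c, lam_d, lam_t, Dn, Tn, Ld, Lt, eta)
            if np.isfinite(objn) and objn >= obj - 1e-12:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            break  # step underflow: converged
        D, T, obj = Dn, Tn, objn
        accD, accT = accD_c, accT_c
        scale = min(scale * 1.1, 1.0)
    if not np.isfinite(obj):
        raise FloatingPointError("non-finite objective during fitting")
    return LatentFactors(D, T)


def infer_new_latents(
    factors: LatentFactors,
    S: SimilarityMatrix | np.ndarray,
    known_mask: np.ndarray,
    K: int,
) -> LatentFactors:
    """Fill latent rows of cold-start entities from similar known entities.

    Each new entity's row becomes the similarity-weighted average of its K
    nearest known entities' rows (same weighting as profile inference).
    The side (drug or target) is inferred from the similarity matrix size.
    """
    Sv = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    known_mask = np.asarray(known_mask, dtype=bool)
    if not known_mask.any():
        raise ValueError("at least one known entity is required")
    n = Sv.shape[0]
    if n == factors.drug_factors.shape[0]:
        target_attr = "drug_factors"
    elif n == factors.target_factors.shape[0]:
        target_attr = "target_factors"
    else:
        raise ValueError("similarity matrix size matches neither factor side")
    rows = getattr(factors, target_attr).copy()
    for i in np.flatnonzero(~known_mask):
        chosen, w = _neighbor_weights(Sv[i], known_mask, i, K)
        rows[i] = (w @ rows[chosen]) / w.sum()
    if target_attr == "drug_factors":
        return LatentFactors(rows, factors.target_factors.copy())
    return LatentFactors(factors.drug_factors.copy(), rows)


def predict_interactions(
    factors: LatentFactors,
    Sd: DiffusedKernel | np.ndarray,
    St: DiffusedKernel | np.ndarray,
    alpha: float,
    rho: float,
    tau: float,
) -> np.ndarray:
    """Interaction probabilities P' = sigmoid(alpha*DT' + rho*Sd DT' + tau*DT' St)."""
    if abs(alpha + rho + tau - 1.0) > 1e-8:
        raise ValueError("alpha + rho + tau must sum to 1")
    Sdv = Sd.values if isinstance(Sd, DiffusedKernel) else np.asarray(Sd, dtype=float)
    Stv = St.values if isinstance(St, DiffusedKernel) else np.asarray(St, dtype=float)
    Z = _smoothed_logits(factors.drug_factors, factors.target_factors, Sdv, Stv, alpha, rho, tau)
    return expit(Z)


# ---------------------------------------------------------------------------
# pipeline conveniences
# ---------------------------------------------------------------------------

def _side_profiles(Yv: np.ndarray, Sv: np.ndarray, K: int) -> np.ndarray:
    """Per-entity interaction profiles, inferring rows of cold-start entities."""
    profiles = Yv.astype(float).copy()
    known = profiles.sum(axis=1) > 0
    for i in np.flatnonzero(~known):
        try:
            chosen, w = _neighbor_weights(Sv[i], known, i, K)
        except ValueError:
            continue  # isolated entity: keep the zero profile
        profiles[i] = (w @ profiles[chosen]) / w.sum()
    return profiles


def build_diffused_kernels(
    Y: InteractionMatrix | np.ndarray,
    drug_sim: SimilarityMatrix | np.ndarray,
    target_sim: SimilarityMatrix | np.ndarray,
    config: DnilmfConfig,
) -> tuple[DiffusedKernel, DiffusedKernel]:
    """Build the fused drug and target kernels from Y and the similarities."""
    Yv = (Y.values if isinstance(Y, InteractionMatrix) else np.asarray(Y)).astype(float)
    Sdv = drug_sim.values if isinstance(drug_sim, SimilarityMatrix) else np.asarray(drug_sim, dtype=float)
    Stv = target_sim.values if isinstance(target_sim, SimilarityMatrix) else np.asarray(target_sim, dtype=float)
    out = []
    for side, profiles, Sv in (("drug", Yv, Sdv), ("target", Yv.T, Stv)):
        prof = _side_profiles(profiles, Sv, config.neighbors)
        phi = config.bandwidth
        if phi is None:
            phi = float(np.mean(np.sum(prof * prof, axis=1)))
            phi = max(phi, 1e-8)
        Kg = gaussian_kernel_matrix(prof, phi)
        # the PSD projection can leave tiny negative off-diagonals; the
        # diffusion state needs non-negative mass, so clip them here
        Ks = np.maximum(similarity_to_kernel(Sv), 0.0)
        P_sim = status_matrix(Ks)
        P_gauss = status_matrix(Kg)
        K_nn = min(config.neighbors, Sv.shape[0] - 1)
        out.append(diffuse(P_sim, P_gauss, K_nn, config.diffusion_steps, side))
    return out[0], out[1]


@dataclass
class DnilmfModel:
    """Fitted predictor: factors, fused kernels, and the config used."""

    factors: LatentFactors
    Sd: DiffusedKernel
    St: DiffusedKernel
    config: DnilmfConfig
    drug_ids: tuple[str, ...] | None = None
    target_ids: tuple[str, ...] | None = None

    def predict(self) -> np.ndarray:
        c = self.config
        return predict_interactions(self.factors, self.Sd, self.St, c.alpha, c.rho, c.tau)


def fit_dnilmf(
    Y: InteractionMatrix | np.ndarray,
    drug_sim: SimilarityMatrix | np.ndarray,
    target_sim: SimilarityMatrix | np.ndarray,
    config: DnilmfConfig,
) -> DnilmfModel:
    """End-to-end DNILMF fit: kernels, diffusion, then latent factors."""
    Sd, St = build_diffused_kernels(Y, drug_sim, target_sim, config)
    factors = fit_latent_factors(Y, Sd, St, config)
    ids = (
        (Y.drug_ids, Y.target_ids) if isinstance(Y, InteractionMatrix) else (None, None)
    )
    return DnilmfModel(factors, Sd, St, config, ids[0], ids[1])
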