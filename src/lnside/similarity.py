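"""Linear neighborhood (LN/RLN) similarity and classical baselines.

A drug's feature vector is reconstructed as a convex combination of its K
nearest neighbors; the optimal reconstruction weights

    min_w  || X_i − Σ_j w_j X_{i_j} ||²  +  λ ||w||²
    s.t.   Σ_j w_j = 1,  w_j >= 0

serve as directed drug–drug similarities. λ=0 gives LN similarity; λ=1 gives
the regularized RLN form. For binary feature vectors the reconstruction error
is bounded by the dimension p, so a unit ridge keeps the error term dominant
while curing singular Gram matrices (duplicated neighbors make G rank
deficient, on which the λ=0 problem can fail).

Stacking the per-drug weight rows gives the N × N row-stochastic,
zero-diagonal similarity matrix W that drives label propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._qp import SimplexQPError, solve_simplex_qp
from .datasets_io import FeatureMatrix

__all__ = [
    "NeighborSet",
    "GramMatrix",
    "NeighborWeights",
    "SimilarityMatrix",
    "SimilarityConfig",
    "SingularGramError",
    "find_neighbors",
    "compute_gram",
    "solve_neighbor_weights",
    "build_similarity_matrix",
    "baseline_similarity",
    "similarity_to_new",
]

_CLIP_LIMIT = 1e-6  # negative QP weights beyond this are a solver defect, not roundoff


class SingularGramError(RuntimeError):
    """λ=0 (LN) failed on a singular Gram matrix; RLN (λ=1) regularizes it."""


@dataclass
class NeighborSet:
    """K nearest training drugs of a center, by Euclidean distance."""

    center_index: int
    neighbor_indices: np.ndarray
    distances: np.ndarray


@dataclass
class GramMatrix:
    """Gram matrix G of centered difference vectors, G_jk = (X_i−X_j)·(X_i−X_k)."""

    values: np.ndarray


@dataclass
class NeighborWeights:
    """Nonnegative reconstruction weights aligned to a NeighborSet, summing to 1."""

    weights: np.ndarray


@dataclass
class SimilarityConfig:
    """Parameters of LN/RLN similarity construction.

    ``k_neighbors`` is capped at N−1 in-sample (a drug is never its own
    neighbor) and at N out-of-sample. ``lambda_reg`` = 0 selects LN, 1 RLN.
    """

    k_neighbors: int = 400
    lambda_reg: float = 1.0
    method_tag: str = "RLN"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        tag = self.method_tag.upper() if self.method_tag.lower() in ("ln", "rln") else self.method_tag
        self.method_tag = tag


@dataclass
class SimilarityMatrix:
    """N × N drug–drug similarity with zero diagonal.

    For LN/RLN every row is a probability vector over at most K neighbor
    columns (row-stochastic); baseline similarities are dense and unnormalized.
    """

    drug_ids: list[str]
    values: np.ndarray
    method_tag: str = "RLN"
    k_neighbors: int | None = field(default=None)

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]


def _pairwise_sq_dists(X: np.ndarray, center: np.ndarray) -> np.ndarray:
    diff = X - center
    return np.einsum("ij,ij->i", diff, diff).astype(float)


def find_neighbors(X: FeatureMatrix, center_index: int, k_neighbors: int) -> NeighborSet:
    """K nearest neighbors of a training drug, self excluded, ties by index."""
    n = X.n_drugs
    if n < 2:
        raise ValueError("need at least 2 drugs to define neighbors")
    if not 0 <= center_index < n:
        raise IndexError(f"center_index {center_index} out of range [0, {n})")
    k = min(k_neighbors, n - 1)
    d2 = _pairwise_sq_dists(X.values, X.values[center_index])
    d2[center_index] = np.inf
    # stable sort on distance => ties broken by ascending drug index
    order = np.argsort(d2, kind="stable")[:k]
    return NeighborSet(center_index, order, np.sqrt(d2[order]))


def compute_gram(X: FeatureMatrix, nbr: NeighborSet) -> GramMatrix:
    """Gram matrix of difference vectors D_j = X_center − X_{neighbor j}."""
    D = X.values[nbr.center_index][None, :] - X.values[nbr.neighbor_indices]
    D = D.astype(float)
    return GramMatrix(D @ D.T)


def solve_neighbor_weights(G: GramMatrix, lambda_reg: float) -> NeighborWeights:
    """Minimize wᵀ(G+λI)w over the probability simplex.

    Raises :class:`SingularGramError` when λ=0 and the Gram matrix is
    singular — the regularized (RLN, λ=1) variant is the cure.
    """
    Gv = G.values
    k = Gv.shape[0]
    Q = Gv + lambda_reg * np.eye(k)
    try:
        w = solve_simplex_qp(Q)
    except SimplexQPError as exc:
        if lambda_reg == 0.0:
            raise SingularGramError(
                "LN similarity (lambda=0) failed: the neighbor Gram matrix is "
                "singular (e.g. duplicated neighbors). Use RLN similarity "
                "(lambda=1), whose ridge makes the problem strictly convex."
            ) from exc
        raise
    worst = float(w.min())
    if worst < -_CLIP_LIMIT:
        raise SimplexQPError(f"QP returned weight {worst} below the clip limit")
    w = np.clip(w, 0.0, None)
    return NeighborWeights(w / w.sum())


def build_similarity_matrix(X: FeatureMatrix, cfg: SimilarityConfig) -> SimilarityMatrix:
    """Row-stochastic LN/RLN similarity matrix W for all drugs of one view."""
    if cfg.method_tag not in ("LN", "RLN"):
        raise ValueError(f"method_tag {cfg.method_tag!r}: expected LN or RLN")
    n = X.n_drugs
    W = np.zeros((n, n))
    for i in range(n):
        nbr = find_neighbors(X, i, cfg.k_neighbors)
        try:
            w = solve_neighbor_weights(compute_gram(X, nbr), cfg.lambda_reg)
        except (SingularGramError, SimplexQPError) as exc:
            raise type(exc)(f"drug {X.drug_ids[i]!r} (row {i}): {exc}") from exc
        W[i, nbr.neighbor_indices] = w.weights
    return SimilarityMatrix(list(X.drug_ids), W, cfg.method_tag, min(cfg.k_neighbors, n - 1))


def baseline_similarity(X: FeatureMatrix, method_tag: str, gamma: float | None = None) -> SimilarityMatrix:
    """Jaccard / cosine / Gauss similarity, dense, diagonal forced to zero.

    Gauss bandwidth defaults to 1/p. Baselines are not row-normalized; they
    exist to compare graph quality against LN/RLN, not to drive propagation
    guarantees.
    """
    tag = method_tag.lower()
    V = X.values.astype(float)
    n, p = V.shape
    if tag == "jaccard":
        inter = V @ V.T
        row = V.sum(axis=1)
        union = row[:, None] + row[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    elif tag == "cosine":
        norms = np.sqrt((V * V).sum(axis=1))
        denom = norms[:, None] * norms[None, :]
        S = np.where(denom > 0, (V @ V.T) / np.where(denom > 0, denom, 1.0), 0.0)
    elif tag == "gauss":
        if gamma is None:
            gamma = 1.0 / p
        if gamma <= 0:
            raise ValueError("gauss similarity needs gamma > 0")
        sq = (V * V).sum(axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (V @ V.T), 0.0)
        S = np.exp(-gamma * d2)
    else:
        raise ValueError(f"unknown baseline similarity {method_tag!r}")
    np.fill_diagonal(S, 0.0)
    return SimilarityMatrix(list(X.drug_ids), S, tag, None)


def similarity_to_new(
    X_train: FeatureMatrix, x_new: np.ndarray, cfg: SimilarityConfig
) -> np.ndarray:
    """Out-of-sample similarity vector of a new drug to the N training drugs.

    The new drug's K nearest training drugs are found and the same simplex QP
    solved with the new drug as center; weights are scattered to an N-vector
    summing to 1.
    """
    x_new = np.asarray(x_new).ravel()
    n, p = X_train.values.shape
    if x_new.shape[0] != p:
        raise ValueError(f"x_new has dimension {x_new.shape[0]}, expected {p}")
    k = min(cfg.k_neighbors, n)
    d2 = _pairwise_sq_dists(X_train.values, x_new)
    order = np.argsort(d2, kind="stable")[:k]
    D = (x_new[None, :] - X_train.values[order]).astype(float)
    w = solve_neighbor_weights(GramMatrix(D @ D.T), cfg.lambda_reg)
    out = np.zeros(n)
    out[order] = w.weights
    return out
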