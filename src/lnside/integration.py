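"""LNSM-SMI: integrating per-view similarity matrices with simplex weights.

Each feature view k yields its own similarity matrix W_k. The integrated
graph is the linear combination Σ θ_k W_k with θ on the probability simplex.
Fixing the labels at Y⁰ in the propagation objective reduces weight
estimation to

    min_θ  α Cᵀθ + δ‖θ‖²   s.t.  Σθ = 1, θ >= 0,

where c_k = tr((Y⁰)ᵀ(I−W_k)Y⁰) measures how badly view k's graph reconstructs
the observed label matrix (smaller is better). The KKT system of this QP has
a closed-form solution: sort costs ascending, keep the longest prefix whose
costs are low enough to earn positive weight, and assign

    θ_k = (λ − α c_k) / (2δ)  on the prefix,  0 elsewhere,

with λ fixed by Σθ=1. Choosing δ = (α/2) Σ_k (c_max − c_k) (the "auto" rule)
collapses this to the simple form θ_k = (c_max − c_k) / Σ_j (c_max − c_j):
views are weighted by their cost gap to the worst view, which therefore
receives exactly zero weight. Note α cancels in the auto form.

New drugs are scored with the integrated out-of-sample similarity applied to
the raw training labels, Y_new = (Σ θ_k W_new^k) Y⁰.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets_io import AssociationMatrix, DatasetBundle, ScoreMatrix
from .propagation import PropagationConfig, propagate_values
from .similarity import (
    SimilarityConfig,
    SimilarityMatrix,
    build_similarity_matrix,
    similarity_to_new,
)

__all__ = [
    "CostVector",
    "IntegrationSolution",
    "compute_cost",
    "estimate_weights",
    "integrate_similarities",
    "fit_integration",
    "lnsm_smi_predict",
]


@dataclass
class CostVector:
    """Per-view label-reconstruction costs c_k = tr((Y⁰)ᵀ(I−W_k)Y⁰)."""

    costs: np.ndarray
    view_names: list[str]


@dataclass
class IntegrationSolution:
    """Simplex weights over feature views with their KKT multipliers."""

    theta: np.ndarray
    delta: float
    lagrange_lambda: float
    eta: np.ndarray
    costs: np.ndarray
    view_names: list[str]


def compute_cost(W_i: SimilarityMatrix, Y0: AssociationMatrix) -> float:
    """Cost of one view: tr((Y⁰)ᵀ(I−W)Y⁰), without forming the full product.

    Equals Σ_cols yᵀ(I−W)y; zero when every label column is constant (the
    all-ones vector is a fixed point of a row-stochastic W).
    """
    if W_i.drug_ids != Y0.drug_ids:
        raise ValueError("similarity matrix and associations use different drug orders")
    Y = Y0.values.astype(float)
    WY = W_i.values @ Y
    return float(np.einsum("ij,ij->", Y, Y - WY))


def estimate_weights(
    C: CostVector, alpha: float = 0.8, delta: float | str = "auto"
) -> IntegrationSolution:
    """Solve the simplex-weight QP analytically.

    With ``delta="auto"`` the regularizer is set to (α/2)Σ(c_max − c_k), which
    yields the simple closed form θ_k ∝ (c_max − c_k) (α cancels). An explicit
    positive ``delta`` uses the general sorted-prefix KKT solution, where
    smaller δ concentrates weight on fewer (cheaper) views.

    When all costs are equal (including the single-view case) the objective is
    symmetric and the weights degenerate to uniform, with a warning.
    """
    c = np.asarray(C.costs, dtype=float)
    K = c.size
    if K < 1:
        raise ValueError("need at least one view")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    spread = float(c.max() - c.min()) if K else 0.0
    if spread <= 1e-12 * max(1.0, float(np.abs(c).max())):
        if delta == "auto":
            warnings.warn(
                "all view costs are (numerically) equal; weights degenerate to uniform",
                stacklevel=2,
            )
        theta = np.full(K, 1.0 / K)
        d = float(delta) if delta != "auto" else 1.0
        lam = 2.0 * d / K + alpha * float(c.mean())
        eta = 2.0 * d * theta + alpha * c - lam
        return IntegrationSolution(theta, d, lam, eta, c.copy(), list(C.view_names))

    if delta == "auto":
        # δ = (α/2)Σ(c_max − c_k) collapses the sorted-prefix solution to the
        # simple form θ_k ∝ c_max − c_k; computed directly so the worst view
        # gets an exact zero. λ = α·c_max follows from Σθ = 1.
        gaps = c.max() - c
        d = (alpha / 2.0) * float(gaps.sum())
        theta = gaps / gaps.sum()
        lam = alpha * float(c.max())
        eta = np.zeros(K)
        return IntegrationSolution(theta, d, lam, eta, c.copy(), list(C.view_names))
    d = float(delta)
    if d <= 0:
        raise ValueError("delta must be positive")

    order = np.argsort(c, kind="stable")
    cs = c[order]
    # prefix length l: largest n with 2δ + α Σ_{k<=n}(c_k − c_n) >= 0
    l = 1
    for n in range(1, K + 1):
        if 2.0 * d + alpha * float((cs[:n] - cs[n - 1]).sum()) >= -1e-12 * max(1.0, d):
            l = n
    lam = (2.0 * d + alpha * float(cs[:l].sum())) / l
    theta_sorted = np.zeros(K)
    theta_sorted[:l] = np.clip((lam - alpha * cs[:l]) / (2.0 * d), 0.0, None)
    theta = np.zeros(K)
    theta[order] = theta_sorted
    theta /= theta.sum()
    eta = 2.0 * d * theta + alpha * c - lam
    eta[theta > 0] = 0.0  # exact complementary slackness; residual is roundoff
    eta = np.clip(eta, 0.0, None)
    return IntegrationSolution(theta, d, lam, eta, c.copy(), list(C.view_names))


def integrate_similarities(
    W_list: list[SimilarityMatrix], theta: np.ndarray
) -> SimilarityMatrix:
    """Convex combination Σ θ_k W_k; row-stochasticity is preserved."""
    theta = np.asarray(theta, dtype=float)
    if len(W_list) != theta.size:
        raise ValueError("one weight per similarity matrix required")
    ref = W_list[0].drug_ids
    for W in W_list[1:]:
        if W.drug_ids != ref:
            raise ValueError("similarity matrices use different drug orders")
    values = np.zeros_like(W_list[0].values, dtype=float)
    for t, W in zip(theta, W_list):
        values += t * W.values
    return SimilarityMatrix(list(ref), values, "SMI", W_list[0].k_neighbors)


def fit_integration(
    bundle: DatasetBundle,
    sim_cfg: SimilarityConfig | None = None,
    alpha: float = 0.8,
    delta: float | str = "auto",
) -> tuple[list[SimilarityMatrix], IntegrationSolution]:
    """Build per-view similarity matrices and estimate their simplex weights."""
    sim_cfg = sim_cfg or SimilarityConfig()
    W_list = [build_similarity_matrix(v, sim_cfg) for v in bundle.views]
    costs = CostVector(
        np.array([compute_cost(W, bundle.associations) for W in W_list]),
        [v.view_name for v in bundle.views],
    )
    return W_list, estimate_weights(costs, alpha=alpha, delta=delta)


def lnsm_smi_predict(
    bundle: DatasetBundle,
    X_new_views: list[np.ndarray],
    sim_cfg: SimilarityConfig | None = None,
    alpha: float = 0.8,
    delta: float | str = "auto",
    transfer: str = "raw",
    prop_cfg: PropagationConfig | None = None,
    solution: IntegrationSolution | None = None,
) -> tuple[ScoreMatrix, IntegrationSolution]:
    """LNSM-SMI scores for new drugs: Y_new = (Σ θ_k W_new^k) · Y⁰.

    ``X_new_views`` holds one (n_new × p_k) array per view, in the bundle's
    view order. The default multiplies the integrated out-of-sample
    similarity by the raw training labels Y⁰; ``transfer="propagated"``
    substitutes labels propagated over the integrated graph.
    """
    sim_cfg = sim_cfg or SimilarityConfig()
    if len(X_new_views) != len(bundle.views):
        raise ValueError("need one new-drug array per feature view")
    X_new_views = [np.atleast_2d(np.asarray(x)) for x in X_new_views]
    n_new = X_new_views[0].shape[0]
    for x, v in zip(X_new_views, bundle.views):
        if x.shape != (n_new, v.n_descriptors):
            raise ValueError(
                f"new-drug array for view {v.view_name!r} has shape {x.shape}, "
                f"expected ({n_new}, {v.n_descriptors})"
            )
    if solution is None:
        W_list, solution = fit_integration(bundle, sim_cfg, alpha=alpha, delta=delta)
    else:
        W_list = [build_similarity_matrix(v, sim_cfg) for v in bundle.views]

    if transfer == "raw":
        Y = bundle.associations.values.astype(float)
    elif transfer == "propagated":
        W_int = integrate_similarities(W_list, solution.theta)
        Y = propagate_values(
            W_int.values, bundle.associations.values, prop_cfg or PropagationConfig(alpha=alpha)
        )
    else:
        raise ValueError(f"transfer {transfer!r}: expected 'raw' or 'propagated'")

    scores = np.zeros((n_new, Y.shape[1]))
    for r in range(n_new):
        w_combined = np.zeros(bundle.n_drugs)
        for t, view, x_new in zip(solution.theta, bundle.views, X_new_views):
            if t == 0.0:
                continue
            w_combined += t * similarity_to_new(view, x_new[r], sim_cfg)
        scores[r] = w_combined @ Y
    new_ids = [f"new_{r}" for r in range(n_new)]
    return (
        ScoreMatrix(new_ids, list(bundle.associations.side_effect_ids), scores),
        solution,
    )
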