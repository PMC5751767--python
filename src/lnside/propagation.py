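"""LNSM: graph label propagation of side-effect labels (SEND, single view).

Side-effect labels spread over the directed similarity graph: each drug
absorbs its neighbors' labels with probability α and retains its initial
labels with probability 1−α,

    Y ← α W Y + (1−α) Y⁰,

which for a row-stochastic W and 0 <= α < 1 converges to the closed form
Y′ = (1−α)(I−αW)⁻¹Y⁰. Because each update is a convex combination of values
already in [0,1], all propagated scores stay in [0,1].

A new drug is scored out-of-sample: its similarity vector to the training
drugs multiplies the propagated training label matrix, Y_new = W_new · Y′.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets_io import AssociationMatrix, FeatureMatrix, ScoreMatrix
from .similarity import (
    SimilarityConfig,
    SimilarityMatrix,
    build_similarity_matrix,
    similarity_to_new,
)

__all__ = ["PropagationConfig", "propagate", "propagate_values", "lnsm_predict_new"]

_ROW_SUM_TOL = 1e-6


@dataclass
class PropagationConfig:
    """Label-propagation parameters.

    alpha is the absorbing probability (0 keeps the initial labels untouched);
    mode selects the closed-form linear solve or explicit fixed-point
    iteration (both converge to the same limit and exist mainly to
    cross-validate each other).
    """

    alpha: float = 0.8
    mode: str = "closed_form"
    max_iter: int = 1000
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if self.mode not in ("closed_form", "iterative"):
            raise ValueError(f"mode {self.mode!r}: expected closed_form or iterative")


def _check_row_stochastic(W: np.ndarray) -> None:
    if W.min() < -1e-10:
        raise ValueError("similarity matrix has negative entries")
    dev = float(np.abs(W.sum(axis=1) - 1.0).max())
    if dev > _ROW_SUM_TOL:
        raise ValueError(
            f"similarity matrix is not row-stochastic (max row-sum deviation {dev:.3g}); "
            "propagation convergence requires spectral radius <= 1"
        )


def propagate_values(W: np.ndarray, Y0: np.ndarray, cfg: PropagationConfig) -> np.ndarray:
    """Propagate a raw label array over a row-stochastic similarity array."""
    W = np.asarray(W, dtype=float)
    Y0 = np.asarray(Y0, dtype=float)
    if W.shape[0] != W.shape[1] or W.shape[0] != Y0.shape[0]:
        raise ValueError(f"shape mismatch: W {W.shape}, Y0 {Y0.shape}")
    _check_row_stochastic(W)
    a = cfg.alpha
    if a == 0.0:
        return Y0.copy()
    if cfg.mode == "closed_form":
        # linear solve against (I - αW); never an explicit inverse
        A = np.eye(W.shape[0]) - a * W
        return (1.0 - a) * np.linalg.solve(A, Y0)
    Y = Y0.copy()
    for _ in range(cfg.max_iter):
        Y_next = a * (W @ Y) + (1.0 - a) * Y0
        delta = float(np.abs(Y_next - Y).max())
        Y = Y_next
        if delta < cfg.tol:
            break
    return Y


def propagate(W: SimilarityMatrix, Y0: AssociationMatrix, cfg: PropagationConfig) -> ScoreMatrix:
    """Propagate known side-effect labels over the similarity graph."""
    if W.drug_ids != Y0.drug_ids:
        raise ValueError("similarity matrix and associations use different drug orders")
    values = propagate_values(W.values, Y0.values, cfg)
    return ScoreMatrix(list(Y0.drug_ids), list(Y0.side_effect_ids), values)


def lnsm_predict_new(
    X_train: FeatureMatrix,
    Y_train: AssociationMatrix,
    X_new: FeatureMatrix,
    sim_cfg: SimilarityConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    transfer: str = "propagated",
) -> ScoreMatrix:
    """LNSM scores for new drugs: Y_new = W_new · Y.

    ``transfer`` selects the training label matrix Y that the out-of-sample
    similarity vector multiplies: ``"propagated"`` (default) uses the
    converged Y′, reading Y as the updated label matrix; ``"raw"`` uses Y⁰.
    """
    sim_cfg = sim_cfg or SimilarityConfig()
    prop_cfg = prop_cfg or PropagationConfig()
    if X_new.n_descriptors != X_train.n_descriptors:
        raise ValueError("new drugs live in a different descriptor space than training drugs")
    if X_train.drug_ids != Y_train.drug_ids:
        raise ValueError("training features and labels use different drug orders")
    if transfer == "propagated":
        W = build_similarity_matrix(X_train, sim_cfg)
        Y = propagate(W, Y_train, prop_cfg).values
    elif transfer == "raw":
        Y = Y_train.values.astype(float)
    else:
        raise ValueError(f"transfer {transfer!r}: expected 'propagated' or 'raw'")
    scores = np.empty((X_new.n_drugs, Y.shape[1]))
    for r in range(X_new.n_drugs):
        w_new = similarity_to_new(X_train, X_new.values[r], sim_cfg)
        scores[r] = w_new @ Y
    return ScoreMatrix(list(X_new.drug_ids), list(Y_train.side_effect_ids), scores)
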