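"""LNSM-MSE: predicting missing side effects of approved drugs (SEAD).

No chemical or biological features are needed: each drug's binary association
profile A(i,:) over the M side-effect terms serves as its feature vector.
RLN similarity is computed between profiles and the known associations are
propagated over the resulting graph,

    Y = (1−α)(I−αW(A))⁻¹ A.

Where A_ij = 0, the score Y_ij ranks the candidate missing side effects;
where A_ij = 1 the retained initial label guarantees Y_ij >= 1−α.

Association profiles typically have fewer dimensions (M) than drugs (N), so
neighbor Gram matrices are rank deficient and plain LN can fail; RLN is the
default, matching the frame's recommended SEAD configuration (K=800 capped at
N−1, α=0.3).
"""

from __future__ import annotations

import warnings

import numpy as np

from .datasets_io import AssociationMatrix, ScoreMatrix
from .propagation import PropagationConfig, propagate
from .similarity import SimilarityConfig, SimilarityMatrix, build_similarity_matrix

__all__ = ["SEAD_SIM_DEFAULTS", "SEAD_PROP_DEFAULTS", "lnsm_mse_predict", "profile_similarity"]

SEAD_SIM_DEFAULTS = dict(k_neighbors=800, lambda_reg=1.0, method_tag="RLN")
SEAD_PROP_DEFAULTS = dict(alpha=0.3)


def profile_similarity(
    A: AssociationMatrix, sim_cfg: SimilarityConfig | None = None
) -> SimilarityMatrix:
    """LN/RLN similarity computed from association profiles A(i,:)."""
    sim_cfg = sim_cfg or SimilarityConfig(**SEAD_SIM_DEFAULTS)
    zero = np.flatnonzero(A.values.sum(axis=1) == 0)
    if zero.size:
        names = [A.drug_ids[i] for i in zero[:5]]
        warnings.warn(
            f"{zero.size} drug(s) have all-zero association profiles (e.g. {names}); "
            "their neighborhoods are ill-defined but computation proceeds",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the zero-row situation was just reported above
        view = A.as_feature_view()
    return build_similarity_matrix(view, sim_cfg)


def lnsm_mse_predict(
    A: AssociationMatrix,
    sim_cfg: SimilarityConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
) -> ScoreMatrix:
    """Score all drug × side-effect cells from the known associations alone."""
    sim_cfg = sim_cfg or SimilarityConfig(**SEAD_SIM_DEFAULTS)
    prop_cfg = prop_cfg or PropagationConfig(**SEAD_PROP_DEFAULTS)
    W = profile_similarity(A, sim_cfg)
    return propagate(W, A, prop_cfg)
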