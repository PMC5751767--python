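"""Deterministic active-set solver for the simplex-constrained QP.

Solves  min_w  wᵀ Q w   s.t.  Σ w = 1,  w >= 0,  with Q symmetric positive
semidefinite (a Gram matrix, optionally ridged by λI). This is the per-drug
reconstruction problem whose minimizer defines linear neighborhood similarity.

The algorithm is a primal active-set method: on the current free set it solves
the equality-constrained KKT system

    [ 2 Q_FF   -1 ] [ w_F ]   [ 0 ]
    [  1ᵀ       0 ] [  ν  ] = [ 1 ]

then either clamps variables that went negative to zero, or releases
zero-clamped variables whose KKT multiplier η_i = 2(Qw)_i − ν is negative.
Termination is certified by the KKT residual, not by iteration count alone.
For speed, all negative variables are clamped at once while this keeps
progressing; the solver falls back to conservative one-at-a-time pivoting
(which cannot cycle on a positive definite Q) if the fast path stalls.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SimplexQPError", "solve_simplex_qp", "kkt_residuals"]

_SOLVE_RTOL = 1e-8  # relative residual above which an equality solve is deemed singular


class SimplexQPError(RuntimeError):
    """The equality-constrained subproblem is singular or the solver stalled."""


def _equality_solve(Q: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the KKT system restricted to the free index set ``idx``."""
    k = idx.size
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * Q[np.ix_(idx, idx)]
    kkt[:k, k] = -1.0
    kkt[k, :k] = 1.0
    rhs = np.zeros(k + 1)
    rhs[k] = 1.0
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as exc:
        raise SimplexQPError("singular KKT system on the free set") from exc
    scale = max(1.0, float(np.abs(kkt).max()))
    resid = float(np.abs(kkt @ sol - rhs).max())
    if not np.isfinite(sol).all() or resid > _SOLVE_RTOL * scale * max(1.0, k):
        raise SimplexQPError(f"ill-conditioned KKT system (residual {resid:.3g})")
    return sol[:k], float(sol[k])


def kkt_residuals(Q: np.ndarray, w: np.ndarray) -> dict[str, float]:
    """KKT residuals of ``w`` for the simplex QP (diagnostic / certificate).

    Returns the primal-feasibility gap, the most negative weight, and the most
    negative multiplier η_i = 2(Qw)_i − ν on the zero set (with ν estimated
    from the support), plus the worst complementary-slackness product.
    """
    w = np.asarray(w, dtype=float)
    grad = 2.0 * (Q @ w)
    support = w > 1e-12
    nu = float(grad[support].mean()) if support.any() else 0.0
    eta = grad - nu
    return {
        "primal_sum": abs(float(w.sum()) - 1.0),
        "min_weight": float(w.min()) if w.size else 0.0,
        "min_eta_zero_set": float(eta[~support].min()) if (~support).any() else 0.0,
        "max_comp_slack": float(np.abs(eta * w).max()) if w.size else 0.0,
        "stationarity_on_support": float(np.abs(eta[support]).max()) if support.any() else 0.0,
    }


def solve_simplex_qp(Q: np.ndarray, tol: float = 1e-10, max_iter: int | None = None) -> np.ndarray:
    """Minimize wᵀQw over the probability simplex.

    Parameters
    ----------
    Q
        Symmetric PSD matrix (K × K).
    tol
        Feasibility/optimality tolerance on weights and multipliers.
    max_iter
        Pivot budget; defaults to ``10 * K + 50``.

    Raises
    ------
    SimplexQPError
        If an equality subproblem is singular (typical for λ=0 on a singular
        Gram matrix) or the pivot budget is exhausted.
    """
    Q = np.asarray(Q, dtype=float)
    K = Q.shape[0]
    if Q.shape != (K, K):
        raise ValueError("Q must be square")
    if K == 1:
        return np.ones(1)
    if max_iter is None:
        max_iter = 10 * K + 50
    scale = max(1.0, float(np.abs(Q).max()))
    dual_tol = tol * scale * 10.0

    active = np.zeros(K, dtype=bool)  # True = clamped at zero
    block_mode = True  # clamp all negatives at once until that stalls
    n_free_prev = K + 1
    for _ in range(max_iter):
        idx = np.flatnonzero(~active)
        if idx.size == 0:  # pragma: no cover - cannot happen: duals force release
            raise SimplexQPError("all variables clamped")
        w_free, nu = _equality_solve(Q, idx)
        neg = w_free < -tol
        if neg.any():
            if block_mode and neg.sum() > 1 and idx.size - neg.sum() >= 1:
                if idx.size >= n_free_prev:
                    block_mode = False  # stalled: switch to single pivots
                    active[idx[int(np.argmin(w_free))]] = True
                else:
                    n_free_prev = idx.size
                    active[idx[neg]] = True
            else:
                active[idx[int(np.argmin(w_free))]] = True
            continue
        w = np.zeros(K)
        w[idx] = np.clip(w_free, 0.0, None)
        eta = 2.0 * (Q @ w) - nu
        clamped = np.flatnonzero(active)
        if clamped.size:
            worst = clamped[int(np.argmin(eta[clamped]))]
            if eta[worst] < -dual_tol:
                active[worst] = False
                n_free_prev = K + 1  # allow block mode to make progress again
                continue
        s = w.sum()
        return w / s
    raise SimplexQPError(f"active-set solver exhausted {max_iter} pivots")
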