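"""Multi-label / binary metrics and the two 5-fold cross-validation protocols.

SEND protocol: drugs are split into folds; models are fitted on the training
drugs' features and labels and evaluated on the held-out drugs as a
multi-label ranking task.

SEAD protocol: the *known positive cells* of the association matrix are split
into folds; held-out positives are zeroed in the training copy of A before
both similarity computation and propagation (no leakage), and evaluation
pools the held-out positives against cells that are zero in the full A.
Training positives are excluded from the ranked pool — they are knowns, not
predictions.

Ranking conventions (ties): AUC uses Mann–Whitney tie-averaged ranks;
coverage uses average ranks; ranking-loss counts a tied (true, false) pair as
half an error; one-error counts a tie at the top as an error only if no tied
top label is true; per-drug average precision uses stable descending order
(ties broken by lower label index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy.stats import rankdata

from .datasets_io import AssociationMatrix, DatasetBundle, FeatureMatrix, ScoreMatrix
from .integration import CostVector, compute_cost, estimate_weights
from .propagation import PropagationConfig, propagate, propagate_values
from .similarity import SimilarityConfig, build_similarity_matrix, similarity_to_new

__all__ = [
    "FoldSpec",
    "MetricsReport",
    "assign_folds",
    "binary_metrics",
    "multilabel_metrics",
    "SendCV",
    "cross_validate_send",
    "cross_validate_sead",
    "mean_report",
]


@dataclass
class FoldSpec:
    """Deterministic fold assignment for one of the two protocols.

    SEND assigns drugs to folds, SEAD assigns known-positive cells. Sizes
    differ by at most one; assignment is a pure function of (seed, n_units).
    """

    task: str = "SEND"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        t = self.task.upper()
        if t not in ("SEND", "SEAD"):
            raise ValueError(f"task {self.task!r}: expected SEND or SEAD")
        self.task = t
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def assign_folds(n_units: int, n_folds: int, seed: int) -> np.ndarray:
    """Balanced random fold ids (0..n_folds-1), deterministic in the seed."""
    rng = np.random.default_rng(seed)
    ids = np.arange(n_units) % n_folds
    return ids[rng.permutation(n_units)]


@dataclass
class MetricsReport:
    """Flat bag of evaluation metrics; unused fields stay NaN."""

    auc: float = np.nan
    aupr: float = np.nan
    auc_macro: float = np.nan
    aupr_macro: float = np.nan
    hamming_loss: float = np.nan
    one_error: float = np.nan
    coverage: float = np.nan
    ranking_loss: float = np.nan
    average_precision: float = np.nan
    sp: float = np.nan
    sn: float = np.nan
    acc: float = np.nan
    f: float = np.nan
    precision: float = np.nan
    recall: float = np.nan
    n_drugs: int = 0
    n_cells: int = 0
    n_positives: int = 0
    n_skipped_rank: int = 0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def mean_report(reports: list[MetricsReport]) -> MetricsReport:
    """Field-wise NaN-aware mean of per-fold reports (counts are summed)."""
    out = MetricsReport()
    for f in fields(MetricsReport):
        vals = [getattr(r, f.name) for r in reports]
        if f.name.startswith("n_"):
            setattr(out, f.name, int(sum(vals)))
        else:
            arr = np.asarray(vals, dtype=float)
            good = ~np.isnan(arr)
            setattr(out, f.name, float(arr[good].mean()) if good.any() else np.nan)
    return out


# ---------------------------------------------------------------------------
# rank statistics on pooled cells


def _auc_mann_whitney(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC as the tie-averaged Mann–Whitney statistic U / (n1·n0)."""
    pos = truth == 1
    n1 = int(pos.sum())
    n0 = truth.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both positive and negative cells")
    ranks = rankdata(scores)  # ascending, ties averaged
    u = float(ranks[pos].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def _average_precision_step(scores: np.ndarray, truth: np.ndarray) -> float:
    """Non-interpolated AUPR: Σ_t ΔTP(t)·precision(t) / P over score thresholds.

    Tied scores enter the curve as one block, so the value is invariant to
    the order in which tied cells are listed.
    """
    pos = truth == 1
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("AUPR needs at least one positive cell")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = pos[order]
    # block boundaries where the score strictly drops
    boundary = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y)[boundary].astype(float)
    n_at = (boundary + 1).astype(float)
    prec = tp / n_at
    dtp = np.diff(np.r_[0.0, tp])
    return float((dtp * prec).sum() / n_pos)


def binary_metrics(
    scores: np.ndarray, truth: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Confusion-matrix metrics at a threshold plus ranking AUC / AUPR.

    Scores and truth are flat cell vectors; predictions are ``score >=
    threshold``. SN equals recall; undefined ratios (no positive calls, no
    negatives, ...) are reported as 0 for precision/F and raise for AUC/AUPR
    when a class is empty.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same length")
    pred = scores >= threshold
    pos = truth == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    sn = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    acc = (tp + tn) / truth.size
    f1 = 2 * prec * sn / (prec + sn) if (prec + sn) else 0.0
    return MetricsReport(
        auc=_auc_mann_whitney(scores, truth),
        aupr=_average_precision_step(scores, truth),
        sp=sp,
        sn=sn,
        acc=acc,
        f=f1,
        precision=prec,
        recall=sn,
        n_cells=int(truth.size),
        n_positives=int(pos.sum()),
    )


# ---------------------------------------------------------------------------
# multi-label metrics


def multilabel_metrics(
    scores: ScoreMatrix | np.ndarray,
    truth: AssociationMatrix | np.ndarray,
    threshold: float = 0.5,
) -> MetricsReport:
    """Per-drug ranking metrics plus pooled (micro) and per-drug (macro) AUC/AUPR.

    one_error: fraction of drugs whose top-ranked label is false (drugs with
    no true label are excluded). coverage: mean over drugs of (maximum
    average-rank of its true labels − 1), ranks 1-based descending.
    ranking_loss: mean fraction of wrongly ordered (true, false) pairs, ties
    half-weighted; drugs lacking true or false labels are skipped and counted.
    average_precision: mean over drugs of mean precision at each true label's
    rank. hamming_loss: cell misclassification rate at the threshold.
    """
    S = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores, dtype=float)
    Y = truth.values if isinstance(truth, AssociationMatrix) else np.asarray(truth)
    if S.shape != Y.shape:
        raise ValueError(f"shape mismatch: scores {S.shape} vs truth {Y.shape}")
    n, m = Y.shape

    one_err_flags: list[bool] = []
    coverages: list[float] = []
    rloss: list[float] = []
    aps: list[float] = []
    aucs_macro: list[float] = []
    auprs_macro: list[float] = []
    n_skipped = 0

    for i in range(n):
        y = Y[i].astype(bool)
        s = S[i]
        n_true = int(y.sum())
        if n_true == 0:
            n_skipped += 1
            continue
        top = s.max()
        one_err_flags.append(not bool(y[s == top].any()))
        avg_ranks = rankdata(-s)  # 1-based descending, ties averaged
        coverages.append(float(avg_ranks[y].max()) - 1.0)
        # stable descending order; ties broken by lower label index
        order = np.argsort(-s, kind="stable")
        pos_rank = np.empty(m, dtype=int)
        pos_rank[order] = np.arange(1, m + 1)
        true_ranks = np.sort(pos_rank[y])
        aps.append(float((np.arange(1, n_true + 1) / true_ranks).mean()))
        if n_true < m:
            st, sf = s[y], s[~y]
            wrong = (st[:, None] < sf[None, :]).sum() + 0.5 * (st[:, None] == sf[None, :]).sum()
            rloss.append(float(wrong) / (n_true * (m - n_true)))
            aucs_macro.append(_auc_mann_whitney(s, Y[i]))
            auprs_macro.append(_average_precision_step(s, Y[i]))

    pred = S >= threshold
    hamming = float((pred != (Y == 1)).mean())
    flat_s, flat_y = S.ravel(), Y.ravel()
    return MetricsReport(
        auc=_auc_mann_whitney(flat_s, flat_y),
        aupr=_average_precision_step(flat_s, flat_y),
        auc_macro=float(np.mean(aucs_macro)) if aucs_macro else np.nan,
        aupr_macro=float(np.mean(auprs_macro)) if auprs_macro else np.nan,
        hamming_loss=hamming,
        one_error=float(np.mean(one_err_flags)) if one_err_flags else np.nan,
        coverage=float(np.mean(coverages)) if coverages else np.nan,
        ranking_loss=float(np.mean(rloss)) if rloss else np.nan,
        average_precision=float(np.mean(aps)) if aps else np.nan,
        n_drugs=n,
        n_cells=int(flat_y.size),
        n_positives=int((flat_y == 1).sum()),
        n_skipped_rank=n_skipped,
    )


# ---------------------------------------------------------------------------
# SEND cross-validation


class SendCV:
    """Five-fold drug-wise cross-validation with cached similarity structures.

    Fold geometry depends only on the feature views, so the per-fold training
    similarity matrices and out-of-sample weight matrices are computed once;
    :meth:`evaluate` can then rescore cheaply for any label matrix (used by
    the permuted-label null).
    """

    def __init__(
        self,
        bundle: DatasetBundle,
        method: str = "lnsm",
        view_index: int = 0,
        sim_cfg: SimilarityConfig | None = None,
        prop_cfg: PropagationConfig | None = None,
        fold: FoldSpec | None = None,
        transfer: str | None = None,
    ):
        if method not in ("lnsm", "lnsm_smi"):
            raise ValueError(f"method {method!r}: expected lnsm or lnsm_smi")
        self.bundle = bundle
        self.method = method
        self.sim_cfg = sim_cfg or SimilarityConfig()
        self.prop_cfg = prop_cfg or PropagationConfig()
        self.fold = fold or FoldSpec(task="SEND")
        if self.fold.task != "SEND":
            raise ValueError("SendCV requires a SEND fold spec")
        self.transfer = transfer or ("propagated" if method == "lnsm" else "raw")
        views = bundle.views if method == "lnsm_smi" else [bundle.views[view_index]]
        self.view_names = [v.view_name for v in views]

        n = bundle.n_drugs
        self.assignments = assign_folds(n, self.fold.n_folds, self.fold.seed)
        self._folds: list[dict] = []
        for f in range(self.fold.n_folds):
            test_idx = np.flatnonzero(self.assignments == f)
            train_idx = np.flatnonzero(self.assignments != f)
            train_views = [
                FeatureMatrix(
                    [v.drug_ids[i] for i in train_idx],
                    list(v.descriptor_ids),
                    v.values[train_idx],
                    v.view_name,
                )
                for v in views
            ]
            W_list = [build_similarity_matrix(tv, self.sim_cfg) for tv in train_views]
            W_new_list = []
            for v, tv in zip(views, train_views):
                W_new = np.zeros((test_idx.size, train_idx.size))
                for r, t in enumerate(test_idx):
                    W_new[r] = similarity_to_new(tv, v.values[t], self.sim_cfg)
                W_new_list.append(W_new)
            self._folds.append(
                dict(test_idx=test_idx, train_idx=train_idx, W_list=W_list, W_new_list=W_new_list)
            )

    def evaluate(
        self, Y_values: np.ndarray | None = None
    ) -> tuple[list[MetricsReport], MetricsReport, list[np.ndarray]]:
        """Score held-out drugs per fold; returns (per-fold, mean, per-fold θ)."""
        Y_all = self.bundle.associations.values if Y_values is None else np.asarray(Y_values)
        if Y_all.shape[0] != self.bundle.n_drugs:
            raise ValueError("label matrix has wrong number of drugs")
        reports, thetas = [], []
        se_ids = list(self.bundle.associations.side_effect_ids)
        for fd in self._folds:
            Y_train = Y_all[fd["train_idx"]].astype(float)
            if self.method == "lnsm":
                W = fd["W_list"][0]
                theta = np.ones(1)
                if self.transfer == "propagated":
                    Y = propagate_values(W.values, Y_train, self.prop_cfg)
                else:
                    Y = Y_train
                scores = fd["W_new_list"][0] @ Y
            else:
                costs = CostVector(
                    np.array(
                        [
                            compute_cost(
                                W,
                                AssociationMatrix(W.drug_ids, se_ids, Y_all[fd["train_idx"]]),
                            )
                            for W in fd["W_list"]
                        ]
                    ),
                    self.view_names,
                )
                theta = estimate_weights(costs, alpha=self.prop_cfg.alpha).theta
                if self.transfer == "propagated":
                    W_int = sum(t * W.values for t, W in zip(theta, fd["W_list"]))
                    Y = propagate_values(W_int, Y_train, self.prop_cfg)
                else:
                    Y = Y_train
                W_new = sum(t * Wn for t, Wn in zip(theta, fd["W_new_list"]))
                scores = W_new @ Y
            thetas.append(theta)
            reports.append(multilabel_metrics(scores, Y_all[fd["test_idx"]]))
        return reports, mean_report(reports), thetas


def cross_validate_send(
    bundle: DatasetBundle,
    method: str = "lnsm",
    view_index: int = 0,
    sim_cfg: SimilarityConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    fold: FoldSpec | None = None,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Drug-wise 5-CV of LNSM or LNSM-SMI; returns (per-fold reports, mean)."""
    cv = SendCV(bundle, method, view_index, sim_cfg, prop_cfg, fold)
    reports, mean, _ = cv.evaluate()
    return reports, mean


# ---------------------------------------------------------------------------
# SEAD cross-validation


def cross_validate_sead(
    A: AssociationMatrix,
    sim_cfg: SimilarityConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    fold: FoldSpec | None = None,
    threshold: float = 0.5,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Known-positive-wise 5-CV of LNSM-MSE; returns (per-fold reports, mean).

    Held-out positive cells are zeroed in the training association matrix
    before similarity computation and propagation. Each fold is evaluated on
    the pool of held-out positives versus all never-positive cells.
    """
    from .mse import SEAD_PROP_DEFAULTS, SEAD_SIM_DEFAULTS, lnsm_mse_predict

    sim_cfg = sim_cfg or SimilarityConfig(**SEAD_SIM_DEFAULTS)
    prop_cfg = prop_cfg or PropagationConfig(**SEAD_PROP_DEFAULTS)
    fold = fold or FoldSpec(task="SEAD")
    if fold.task != "SEAD":
        raise ValueError("cross_validate_sead requires a SEAD fold spec")

    pos_cells = np.argwhere(A.values == 1)
    if pos_cells.shape[0] < fold.n_folds:
        raise ValueError("fewer known positives than folds")
    ids = assign_folds(pos_cells.shape[0], fold.n_folds, fold.seed)
    neg_mask = A.values == 0
    reports = []
    for f in range(fold.n_folds):
        held = pos_cells[ids == f]
        A_train_values = A.values.copy()
        A_train_values[held[:, 0], held[:, 1]] = 0
        A_train = AssociationMatrix(list(A.drug_ids), list(A.side_effect_ids), A_train_values)
        Y = lnsm_mse_predict(A_train, sim_cfg, prop_cfg).values
        pool_scores = np.r_[Y[held[:, 0], held[:, 1]], Y[neg_mask]]
        pool_truth = np.r_[np.ones(held.shape[0]), np.zeros(int(neg_mask.sum()))]
        reports.append(binary_metrics(pool_scores, pool_truth, threshold))
    return reports, mean_report(reports)
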