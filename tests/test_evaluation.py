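"""Metrics against brute-force oracles; fold protocols; permutation null."""

import numpy as np
import pytest
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

from lnside import AssociationMatrix, FoldSpec, binary_metrics, multilabel_metrics
from lnside.evaluation import (
    SendCV,
    assign_folds,
    cross_validate_sead,
    cross_validate_send,
    mean_report,
)


# ---------------------------------------------------------------------------
# brute-force oracles (explicit loops, independent of the implementation)


def oracle_multilabel(S, Y, threshold=0.5):
    n, m = Y.shape
    one_err, cov, rl, ap = [], [], [], []
    for i in range(n):
        true = [j for j in range(m) if Y[i, j] == 1]
        false = [j for j in range(m) if Y[i, j] == 0]
        if not true:
            continue
        top = max(S[i])
        one_err.append(0 if any(S[i, j] == top for j in true) else 1)
        # average rank of label j among all labels, descending
        def avg_rank(j):
            higher = sum(1 for k in range(m) if S[i, k] > S[i, j])
            tied = sum(1 for k in range(m) if S[i, k] == S[i, j])
            return higher + (tied + 1) / 2
        cov.append(max(avg_rank(j) for j in true) - 1)
        if false:
            wrong = sum(
                1.0 if S[i, t] < S[i, f] else (0.5 if S[i, t] == S[i, f] else 0.0)
                for t in true
                for f in false
            )
            rl.append(wrong / (len(true) * len(false)))
        # stable descending order, ties by label index
        order = sorted(range(m), key=lambda j: (-S[i, j], j))
        rank_of = {j: r + 1 for r, j in enumerate(order)}
        precs = []
        for j in true:
            r = rank_of[j]
            inside = sum(1 for k in true if rank_of[k] <= r)
            precs.append(inside / r)
        ap.append(sum(precs) / len(precs))
    hamming = sum(
        1 for i in range(n) for j in range(m) if (S[i, j] >= threshold) != (Y[i, j] == 1)
    ) / (n * m)
    return dict(
        one_error=np.mean(one_err),
        coverage=np.mean(cov),
        ranking_loss=np.mean(rl) if rl else np.nan,
        average_precision=np.mean(ap),
        hamming_loss=hamming,
    )


def oracle_auc(scores, truth):
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = sum(1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def oracle_aupr(scores, truth):
    # step-curve average precision over distinct thresholds
    thresholds = sorted(set(scores), reverse=True)
    n_pos = sum(truth)
    ap, tp_prev = 0.0, 0
    for t in thresholds:
        called = [i for i, s in enumerate(scores) if s >= t]
        tp = sum(1 for i in called if truth[i] == 1)
        prec = tp / len(called)
        ap += (tp - tp_prev) * prec
        tp_prev = tp
    return ap / n_pos


# ---------------------------------------------------------------------------


class TestBinaryMetrics:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array([1, 1, 0, 0])
        r = binary_metrics(scores, truth)
        for name in ("auc", "aupr", "sn", "sp", "acc", "f", "precision", "recall"):
            assert getattr(r, name) == pytest.approx(1.0), name

    def test_constant_scores_auc_half(self):
        r = binary_metrics(np.full(10, 0.3), np.array([1, 0] * 5))
        assert r.auc == pytest.approx(0.5)

    def test_hand_instance_matches_closed_forms(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2]
        truth = [1, 0, 1, 1, 0, 0, 1, 0]
        r = binary_metrics(np.array(scores), np.array(truth))
        assert r.auc == pytest.approx(oracle_auc(scores, truth))
        assert r.aupr == pytest.approx(oracle_aupr(scores, truth))
        # tie-free case: must also agree with sklearn
        assert r.auc == pytest.approx(roc_auc_score(truth, scores))
        assert r.aupr == pytest.approx(average_precision_score(truth, scores))

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_vs_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        truth = rng.integers(0, 2, n)
        if truth.sum() in (0, n):
            truth[0], truth[-1] = 1, 0
        r = binary_metrics(scores, truth)
        assert r.auc == pytest.approx(oracle_auc(list(scores), list(truth)))
        assert r.aupr == pytest.approx(oracle_aupr(list(scores), list(truth)))

    def test_confusion_counts(self):
        scores = np.array([0.9, 0.6, 0.4, 0.1])
        truth = np.array([1, 0, 1, 0])
        r = binary_metrics(scores, truth, threshold=0.5)
        assert r.sn == pytest.approx(0.5)  # TP=1 FN=1
        assert r.sp == pytest.approx(0.5)  # TN=1 FP=1
        assert r.precision == pytest.approx(0.5)
        assert r.acc == pytest.approx(0.5)

    def test_no_positives_raises(self):
        with pytest.raises(ValueError):
            binary_metrics(np.array([0.1, 0.2]), np.array([0, 0]))

    def test_auc_monotone_invariance(self, rng):
        scores = rng.random(30)
        truth = rng.integers(0, 2, 30)
        truth[0], truth[1] = 1, 0
        a1 = binary_metrics(scores, truth).auc
        a2 = binary_metrics(np.exp(5 * scores), truth).auc
        assert a1 == pytest.approx(a2)


class TestMultilabelMetrics:
    def test_perfect_predictor(self, rng):
        Y = rng.integers(0, 2, (6, 5))
        Y[:, 0] = 1
        Y[:, 1] = 0
        r = multilabel_metrics(Y.astype(float), Y)
        assert r.one_error == 0 and r.ranking_loss == 0 and r.hamming_loss == 0
        assert r.average_precision == pytest.approx(1.0)
        assert r.auc == pytest.approx(1.0) and r.aupr == pytest.approx(1.0)

    def test_coverage_single_label_at_rank_3(self):
        S = np.array([[0.9, 0.8, 0.7, 0.6, 0.5]])
        Y = np.array([[0, 0, 1, 0, 0]])
        r = multilabel_metrics(S, Y)
        assert r.coverage == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_random_instances_vs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 9)), int(rng.integers(2, 7))
        S = np.round(rng.random((n, m)), 1)
        Y = rng.integers(0, 2, (n, m))
        Y[0, 0] = 1  # at least one positive overall
        if (Y.ravel() == 0).sum() == 0:
            Y[0, 1] = 0
        r = multilabel_metrics(S, Y)
        o = oracle_multilabel(S, Y)
        for name, want in o.items():
            got = getattr(r, name)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want), name
        assert r.auc == pytest.approx(oracle_auc(list(S.ravel()), list(Y.ravel())))
        assert r.aupr == pytest.approx(oracle_aupr(list(S.ravel()), list(Y.ravel())))

    def test_all_true_drug_skipped_in_ranking_loss(self):
        S = np.array([[0.2, 0.9], [0.4, 0.1]])
        Y = np.array([[1, 1], [1, 0]])
        r = multilabel_metrics(S, Y)
        assert r.ranking_loss == pytest.approx(0.0)  # only drug 1 contributes


class TestFolds:
    def test_partition_and_balance(self):
        ids = assign_folds(23, 5, seed=3)
        sizes = np.bincount(ids, minlength=5)
        assert sizes.sum() == 23 and sizes.max() - sizes.min() <= 1

    def test_deterministic_in_seed(self):
        a = assign_folds(40, 5, seed=9)
        b = assign_folds(40, 5, seed=9)
        c = assign_folds(40, 5, seed=10)
        assert np.array_equal(a, b) and not np.array_equal(a, c)


class TestSendCV:
    def test_each_drug_tested_once(self, small_bundle):
        cv = SendCV(small_bundle, "lnsm", fold=FoldSpec("SEND", 2, 0))
        tested = np.concatenate([f["test_idx"] for f in cv._folds])
        assert sorted(tested) == list(range(small_bundle.n_drugs))

    def test_deterministic_metrics(self, small_bundle):
        fold = FoldSpec("SEND", 3, 5)
        _, m1 = cross_validate_send(small_bundle, "lnsm", fold=fold)
        _, m2 = cross_validate_send(small_bundle, "lnsm", fold=fold)
        assert m1.as_dict() == m2.as_dict()

    def test_smi_runs_and_weights_on_simplex(self, small_bundle):
        cv = SendCV(small_bundle, "lnsm_smi", fold=FoldSpec("SEND", 3, 5))
        reports, mean, thetas = cv.evaluate()
        for t in thetas:
            assert abs(t.sum() - 1) < 1e-10 and t.min() >= 0
        assert 0 < mean.aupr <= 1

    def test_permuted_labels_drop_to_null(self, small_bundle):
        cv = SendCV(small_bundle, "lnsm", fold=FoldSpec("SEND", 3, 5))
        _, real, _ = cv.evaluate()
        rng = np.random.default_rng(0)
        nulls = []
        for _ in range(5):
            perm = rng.permutation(small_bundle.n_drugs)
            _, m, _ = cv.evaluate(small_bundle.associations.values[perm])
            nulls.append(m.aupr)
        pos_rate = small_bundle.associations.values.mean()
        assert real.aupr > np.mean(nulls) + 0.1
        assert abs(np.mean(nulls) - pos_rate) < 0.1


class TestSeadCV:
    def test_heldout_sets_partition_positives(self, small_bundle):
        A = small_bundle.associations
        pos = np.argwhere(A.values == 1)
        ids = assign_folds(pos.shape[0], 5, seed=2)
        seen = set()
        for f in range(5):
            cells = {tuple(c) for c in pos[ids == f]}
            assert not (seen & cells)
            seen |= cells
        assert seen == {tuple(c) for c in pos}

    def test_alpha_zero_scores_heldout_zero(self, small_bundle):
        from lnside.propagation import PropagationConfig
        from lnside.similarity import SimilarityConfig

        reports, mean = cross_validate_sead(
            small_bundle.associations,
            SimilarityConfig(10, 1.0, "RLN"),
            PropagationConfig(alpha=0.0),
            FoldSpec("SEAD", 5, 2),
        )
        assert mean.sn == 0.0  # held-out positives all score 0 at threshold 0.5

    def test_recovery_beats_baseline(self, small_bundle):
        reports, mean = cross_validate_sead(
            small_bundle.associations, fold=FoldSpec("SEAD", 5, 2)
        )
        pool_rate = np.mean([r.n_positives / r.n_cells for r in reports])
        assert mean.aupr > 2 * pool_rate


def test_mean_report_nan_aware():
    from lnside.evaluation import MetricsReport

    r1 = MetricsReport(auc=0.8, ranking_loss=np.nan, n_cells=10)
    r2 = MetricsReport(auc=0.6, ranking_loss=0.2, n_cells=5)
    m = mean_report([r1, r2])
    assert m.auc == pytest.approx(0.7)
    assert m.ranking_loss == pytest.approx(0.2)
    assert m.n_cells == 15
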