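import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import random_dataset
from sixma.evaluate import (
    ConfusionCounts,
    compute_metrics,
    confusion_counts,
    cross_validate,
    delta_acc,
    mcnemar_test,
    metrics_from_predictions,
    roc_auc,
    stratified_kfold,
)


class TestStratifiedKfold:
    def test_balanced_folds(self, rng):
        data = random_dataset(rng, 40, 40)
        folds = stratified_kfold(data, k=10, seed=0)
        y = data.labels()
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(80))  # disjoint cover
        for tr, te in folds:
            assert y[te].sum() == 4 and len(te) - y[te].sum() == 4
            assert set(tr) & set(te) == set()

    def test_uneven_quota_within_one(self, rng):
        data = random_dataset(rng, 23, 19)
        folds = stratified_kfold(data, k=5, seed=1)
        y = data.labels()
        for _, te in folds:
            assert abs(y[te].sum() - 23 / 5) <= 1
            assert abs((len(te) - y[te].sum()) - 19 / 5) <= 1

    def test_seed_reproducibility(self, rng):
        data = random_dataset(rng, 30, 30)
        f1 = stratified_kfold(data, k=5, seed=9)
        f2 = stratified_kfold(data, k=5, seed=9)
        for (a, b), (c, d) in zip(f1, f2):
            assert np.array_equal(a, c) and np.array_equal(b, d)

    def test_small_class_rejected(self, rng):
        data = random_dataset(rng, 5, 40)
        with pytest.raises(ValueError, match="fewer than"):
            stratified_kfold(data, k=10)


class TestMetrics:
    def test_perfect_prediction(self):
        rep = compute_metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert rep.ACC == 1.0 and rep.MCC == 1.0 and rep.SN == 1.0 and rep.SP == 1.0

    def test_all_predicted_positive_on_balanced_set(self):
        with pytest.warns(RuntimeWarning, match="MCC"):
            rep = compute_metrics(ConfusionCounts(TP=10, TN=0, FP=10, FN=0))
        assert rep.SN == 1.0 and rep.SP == 0.0
        assert rep.ACC == 0.5 and rep.MCC == 0.0

    def test_hand_worked_confusion(self):
        rep = compute_metrics(ConfusionCounts(TP=8, FN=2, TN=9, FP=1))
        assert rep.SN == pytest.approx(0.8)
        assert rep.SP == pytest.approx(0.9)
        assert rep.ACC == pytest.approx(0.85)
        assert rep.MCC == pytest.approx(70 / np.sqrt(9900), abs=1e-12)
        assert rep.MCC == pytest.approx(0.7035, abs=1e-3)

    def test_needs_both_classes(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(TP=5, TN=0, FP=0, FN=5))

    @settings(max_examples=60, derandomize=True)
    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        tn=st.integers(0, 50), fp=st.integers(0, 50),
    )
    def test_balanced_acc_identity(self, tp, fn, tn, fp):
        """On class-balanced data ACC == (SN + SP) / 2 exactly."""
        if tp + fn != tn + fp or tp + fn == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rep = compute_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
        assert rep.ACC == pytest.approx((rep.SN + rep.SP) / 2, abs=1e-12)

    def test_confusion_counts_total(self, rng):
        y = (rng.random(40) < 0.5).astype(int)
        p = (rng.random(40) < 0.5).astype(int)
        c = confusion_counts(y, p)
        assert c.total == 40


class TestRocAuc:
    def test_perfect_separation(self):
        auc, points = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert points.shape[1] == 2

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = (rng.random(2000) < 0.5).astype(int)
        s = rng.random(2000)
        auc, _ = roc_auc(s, y)
        assert abs(auc - 0.5) < 0.05

    def test_matches_pairwise_mann_whitney_oracle(self):
        rng = np.random.default_rng(3)
        y = (rng.random(150) < 0.5).astype(int)
        s = np.round(rng.random(150), 1)  # coarse scores force ties
        auc, _ = roc_auc(s, y)
        pos, neg = s[y == 1], s[y == 0]
        pairs = sum(
            1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
        )
        assert auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])


class TestMcNemar:
    def test_symmetric_disagreement(self):
        y = np.zeros(10, dtype=int)
        a = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        b = np.array([0, 0, 1, 1, 0, 0, 0, 0, 0, 0])
        stat, p = mcnemar_test(a, b, y)
        assert stat == 0.0 and p == 1.0

    def test_ten_zero_discordance(self):
        y = np.zeros(20, dtype=int)
        a = y.copy()
        b = y.copy()
        b[:10] = 1  # A right, B wrong on 10 records
        stat, p = mcnemar_test(a, b, y)
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(stats.chi2.sf(10, 1), rel=1e-9)
        assert p == pytest.approx(0.00157, abs=2e-5)

    def test_swap_invariance(self, rng):
        y = (rng.random(50) < 0.5).astype(int)
        a = (rng.random(50) < 0.5).astype(int)
        b = (rng.random(50) < 0.5).astype(int)
        _, p_ab = mcnemar_test(a, b, y)
        _, p_ba = mcnemar_test(b, a, y)
        assert p_ab == pytest.approx(p_ba)

    def test_identical_predictions(self, rng):
        y = (rng.random(30) < 0.5).astype(int)
        a = (rng.random(30) < 0.5).astype(int)
        assert mcnemar_test(a, a, y) == (0.0, 1.0)

    def test_exact_small_sample(self):
        y = np.zeros(5, dtype=int)
        a = y.copy()
        b = np.array([1, 1, 1, 0, 0])  # b = 3, c = 0
        _, p = mcnemar_test(a, b, y, method="exact")
        assert p == pytest.approx(2 * stats.binom.cdf(0, 3, 0.5))
        _, p_auto = mcnemar_test(a, b, y, method="auto")
        assert p_auto == p


class TestDeltaAcc:
    def test_identical_reports_zero(self):
        rep = compute_metrics(ConfusionCounts(8, 9, 1, 2))
        assert delta_acc(rep, rep) == 0.0

    def test_percentage_points_and_symmetry(self):
        r1 = compute_metrics(ConfusionCounts(88, 88, 12, 12))  # ACC 0.88
        r2 = compute_metrics(ConfusionCounts(89, 88, 12, 11))  # ACC 0.885
        assert delta_acc(r1, r2) == pytest.approx(0.5)
        assert delta_acc(r2, r1) == pytest.approx(0.5)


class TestCrossValidate:
    def test_pipeline_cv_on_small_strong_fixture(self):
        from sixma.ensemble import PipelineConfig
        from sixma.learners import ClassifierSpec
        from sixma.simdata import SimConfig, generate

        data = generate(
            SimConfig(n_pos=40, n_neg=40, motif_rate_pos=1.0, motif_rate_neg=0.0, seed=4)
        )
        config = PipelineConfig(
            encodings=("MBE", "KMER"),
            classifiers=("SVM",),
            folds=3,
            seed=4,
            sfs=False,
            specs={"SVM": ClassifierSpec("SVM", {"C": (1.0, 32.0), "gamma": (2.0**-7,)}, 4)},
        )
        rep = cross_validate(config, data, k=3, seed=4)
        assert rep.counts.total == 80  # pooled counts cover the dataset
        assert rep.ACC >= 0.75
        assert rep.AUC is not None and rep.AUC >= 0.8
        macro = cross_validate(config, data, k=3, seed=4, macro=True)
        assert macro.ACC == pytest.approx(rep.ACC, abs=0.1)

    def test_out_of_fold_predictions_are_fold_external(self, rng):
        # bookkeeping guard: every record is predicted exactly once, by the
        # fold that held it out
        data = random_dataset(rng, 15, 15)
        folds = stratified_kfold(data, k=3, seed=0)
        seen = np.zeros(len(data), dtype=int)
        for tr, te in folds:
            assert set(tr) | set(te) == set(range(len(data)))
            seen[te] += 1
        assert np.all(seen == 1)
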