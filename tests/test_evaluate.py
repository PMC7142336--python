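"""Metrics, AUC, ROC and the three evaluation protocols."""

import numpy as np
import pytest

from hmmdbp import (
    ConfusionCounts,
    EvalSettings,
    FeatureSpec,
    LabeledDataset,
    SyntheticSpec,
    compute_auc,
    compute_metrics,
    evaluate_cv,
    evaluate_independent,
    make_dataset,
    roc_points,
)
from hmmdbp.evaluate import trapezoid_auc


class TestComputeMetrics:
    def test_independent_benchmark_worked_example(self):
        """Counts implied by the published independent-test rates on a
        93 + 93 set reproduce ACC 0.8118 and MCC 0.648."""
        counts = ConfusionCounts(tp=88, fn=5, fp=30, tn=63)
        m = compute_metrics(counts)
        assert m["sn"] == pytest.approx(0.9462, abs=5e-5)
        assert m["sp"] == pytest.approx(0.6774, abs=5e-5)
        assert m["acc"] == pytest.approx(0.8118, abs=5e-5)
        assert m["mcc"] == pytest.approx(0.648, abs=1e-3)

    def test_all_positive_degenerate_denominator(self):
        m = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=0, fn=0))
        assert m["sn"] == 1.0 and m["acc"] == 1.0 and m["mcc"] == 0.0

    def test_balanced_coin_flip(self):
        m = compute_metrics(ConfusionCounts(tp=25, fp=25, tn=25, fn=25))
        assert m["sn"] == m["sp"] == m["acc"] == 0.5
        assert m["mcc"] == 0.0

    def test_acc_is_exact_ratio(self):
        c = ConfusionCounts(tp=7, fp=2, tn=5, fn=3)
        assert compute_metrics(c)["acc"] == (7 + 5) / 17

    def test_mcc_invariant_under_class_swap(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(0, 50, size=4)
            if tp + fp + tn + fn == 0:
                continue
            m1 = compute_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            m2 = compute_metrics(ConfusionCounts(int(tn), int(fn), int(tp), int(fp)))
            assert m1["mcc"] == pytest.approx(m2["mcc"], abs=1e-12)

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError, match="zero samples"):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))


class TestAuc:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([0.3] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_pair_enumeration_example(self):
        # positives (0.9, 0.4), negatives (0.5, 0.1): 3 of 4 pairs concordant
        assert compute_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc([0.1, 0.2], [1, 1])

    def test_pairwise_auc_equals_trapezoidal_roc_area(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            roc = roc_points(scores, labels)
            assert compute_auc(scores, labels) == pytest.approx(
                trapezoid_auc(roc), abs=1e-9
            )

    def test_roc_endpoints_and_monotonicity(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        roc = roc_points(rng.normal(size=50), labels)
        assert tuple(roc[0]) == (0.0, 0.0)
        assert tuple(roc[-1]) == (1.0, 1.0)
        assert (np.diff(roc[:, 0]) >= 0).all()
        assert (np.diff(roc[:, 1]) >= 0).all()


def small_dataset(n=40, effect=1.5, seed=0, lag=2):
    spec = SyntheticSpec(
        n_pos=n // 2, n_neg=n // 2, length_range=(40, 80),
        effect_size=effect, seed=seed,
    )
    return make_dataset(spec, FeatureSpec(max_lag=lag))


class TestEvaluateCv:
    def test_jackknife_tests_every_sample_exactly_once(self):
        ds = small_dataset(n=16)
        report, _ = evaluate_cv(ds, "jackknife", EvalSettings(), seed=0)
        assert report.counts.total == 16
        assert report.protocol == "jackknife"

    def test_tenfold_pools_to_n_and_is_deterministic(self):
        ds = small_dataset(n=30, seed=1)
        r1, roc1 = evaluate_cv(ds, "tenfold", EvalSettings(), seed=5)
        r2, roc2 = evaluate_cv(ds, "tenfold", EvalSettings(), seed=5)
        assert r1.counts.total == 30
        assert r1.counts == r2.counts
        np.testing.assert_array_equal(roc1, roc2)

    def test_strong_signal_reaches_high_pooled_accuracy(self):
        accs = []
        for seed in range(5):
            ds = small_dataset(n=200, effect=2.5, seed=seed)
            report, _ = evaluate_cv(ds, "tenfold", EvalSettings(), seed=seed)
            accs.append(report.acc)
        assert min(accs) >= 0.95

    def test_label_permutation_stays_at_chance_in_leakage_safe_mode(self):
        """Within-fold ranking on label-permuted data must not leak: mean CV
        accuracy stays near 0.5."""
        accs = []
        for seed in range(5):
            ds = small_dataset(n=40, effect=1.5, seed=seed, lag=1)
            rng = np.random.default_rng(seed)
            yperm = rng.permutation(ds.y)
            permuted = LabeledDataset(X=ds.X, y=yperm)
            settings = EvalSettings(
                select_method="xgboost", select_k=20, rank_scope="fold"
            )
            report, _ = evaluate_cv(permuted, "tenfold", settings, seed=seed)
            accs.append(report.acc)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_too_few_samples_rejected(self):
        ds = small_dataset(n=8)
        with pytest.raises(ValueError, match="at least 10"):
            evaluate_cv(ds, "tenfold", EvalSettings(), seed=0)

    def test_unknown_protocol_rejected(self):
        ds = small_dataset(n=20)
        with pytest.raises(ValueError, match="protocol"):
            evaluate_cv(ds, "fivefold", EvalSettings(), seed=0)


class TestEvaluateIndependent:
    def test_test_equals_train_matches_resubstitution(self):
        ds = small_dataset(n=30, seed=2)
        with pytest.warns(UserWarning, match="both train and test"):
            report, _ = evaluate_independent(ds, ds, EvalSettings(), seed=0)
        from hmmdbp import train as fit

        model = fit(ds, "svm")
        _, labels = model.predict_scores(ds.X)
        assert report.acc == (labels == ds.y).mean()

    def test_flipped_test_labels_complement_accuracy(self):
        full = small_dataset(n=50, seed=3)
        idx = np.arange(50)
        tr, te = full.subset(idx[idx % 3 != 0]), full.subset(idx[idx % 3 == 0])
        r1, _ = evaluate_independent(tr, te, EvalSettings(), seed=0)
        flipped = LabeledDataset(X=te.X, y=1 - te.y)
        r2, _ = evaluate_independent(tr, flipped, EvalSettings(), seed=0)
        assert r1.acc == pytest.approx(1.0 - r2.acc, abs=1e-12)

    def test_same_generator_test_acc_close_to_cv_acc(self):
        # one generator run split in two, so train and test share the
        # run-level column baselines (as real train/test benchmarks share
        # amino-acid composition)
        full = small_dataset(n=100, effect=2.0, seed=5)
        idx = np.arange(100)
        tr, te = full.subset(idx[idx % 5 != 0]), full.subset(idx[idx % 5 == 0])
        cv_report, _ = evaluate_cv(tr, "tenfold", EvalSettings(), seed=0)
        ind_report, _ = evaluate_independent(tr, te, EvalSettings(), seed=0)
        assert abs(ind_report.acc - cv_report.acc) <= 0.1

    def test_overlapping_ids_error_in_strict_mode(self):
        ds = small_dataset(n=20, seed=7)
        with pytest.raises(ValueError, match="both train and test"):
            evaluate_independent(ds, ds, EvalSettings(), seed=0, strict=True)
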