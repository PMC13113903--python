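"""Fold plans, metrics, bootstrap, threshold sweep, paired tests, protocol."""

import numpy as np
import pytest

import eegclassify as eeg
from eegclassify.evaluation import (FoldPlan, LeakageError, aggregate_subjects,
                                    bh_adjust, bootstrap_ci,
                                    classification_metrics, make_folds,
                                    paired_fold_test, run_protocol,
                                    threshold_sweep)


def _subject_ids(n_subjects, epochs_per_subject, prefix="s"):
    out = []
    for i in range(n_subjects):
        out += [f"{prefix}{i:02d}"] * epochs_per_subject
    return out


class TestMakeFolds:
    def test_loso_28_subjects_gives_28_folds(self):
        sids = _subject_ids(28, 10)
        plan = make_folds("loso", sids)
        assert len(plan.folds) == 28

    def test_loso_disjoint_and_covering(self):
        sids = _subject_ids(7, 5)
        plan = make_folds("loso", sids)
        seen = np.sort(np.concatenate([te for _, te in plan.folds]))
        np.testing.assert_array_equal(seen, np.arange(len(sids)))
        arr = np.asarray(sids)
        for tr, te in plan.folds:
            assert not set(arr[tr]) & set(arr[te])

    @pytest.mark.filterwarnings(
        "ignore:The least populated class:UserWarning")
    def test_kfold_partitions_rows(self):
        sids = _subject_ids(5, 2)
        labels = ["control"] * 4 + ["patient"] * 6
        plan = make_folds("kfold_epoch", sids, {"k": 5}, labels=labels)
        sizes = [len(te) for _, te in plan.folds]
        assert sizes == [2] * 5
        pooled = np.sort(np.concatenate([te for _, te in plan.folds]))
        np.testing.assert_array_equal(pooled, np.arange(10))

    def test_random_split_stratified_half(self):
        labels = ["control"] * 40 + ["patient"] * 40
        sids = _subject_ids(8, 10)
        plan = make_folds("random_split", sids, {"test_frac": 0.5},
                         labels=labels)
        (tr, te), = plan.folds
        assert len(te) == 40
        arr = np.asarray(labels)
        assert sorted(np.unique(arr[te], return_counts=True)[1]) == [20, 20]

    @pytest.mark.parametrize("n_subjects,epochs", [(3, 4), (6, 2), (10, 7)])
    def test_randomized_loso_invariants(self, n_subjects, epochs, rng):
        sids = list(rng.permutation(_subject_ids(n_subjects, epochs)))
        plan = make_folds("loso", sids)
        plan.validate(sids)  # raises on violation
        assert len(plan.folds) == n_subjects

    def test_single_subject_loso_rejected(self):
        with pytest.raises(ValueError):
            make_folds("loso", ["a"] * 5)

    def test_malformed_plan_rejected(self):
        idx = np.arange(10)
        plan = FoldPlan("kfold_epoch", [(idx, idx)], {}, 0)
        with pytest.raises(LeakageError):
            plan.validate()


def _oracle_metrics(y_true, y_pred):
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    def prf(tp_, fp_, fn_):
        p = tp_ / (tp_ + fp_) if tp_ + fp_ else 0.0
        r = tp_ / (tp_ + fn_) if tp_ + fn_ else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f

    pos = prf(tp, fp, fn)
    neg = prf(tn, fn, fp)
    return {"accuracy": (tp + tn) / len(y_true),
            "pos": pos, "neg": neg, "cm": [[tn, fp], [fn, tp]]}


class TestClassificationMetrics:
    def test_macro_precision_from_per_class_values(self):
        """Per-class precisions 0.738 / 0.780 average to macro 0.759."""
        assert (0.738 + 0.780) / 2 == pytest.approx(0.759, abs=5e-4)

    def test_f1_from_precision_recall(self):
        p, r = 0.686, 0.680
        assert 2 * p * r / (p + r) == pytest.approx(0.683, abs=5e-4)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = classification_metrics(y, y, probs=[0.1, 0.9, 0.2, 0.8])
        assert m["accuracy"] == 1.0
        assert m["macro"]["f1"] == 1.0
        assert m["roc_auc"] == 1.0

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            n = int(rng.integers(10, 60))
            y_true = rng.integers(0, 2, size=n)
            if len(np.unique(y_true)) < 2:
                continue
            y_pred = rng.integers(0, 2, size=n)
            m = classification_metrics(y_true, y_pred)
            o = _oracle_metrics(y_true, y_pred)
            assert m["accuracy"] == pytest.approx(o["accuracy"])
            pc = m["per_class"]["patient"]
            assert (pc["precision"], pc["recall"], pc["f1"]) == \
                pytest.approx(o["pos"])
            cc = m["per_class"]["control"]
            assert (cc["precision"], cc["recall"], cc["f1"]) == \
                pytest.approx(o["neg"])
            assert m["confusion_matrix"] == o["cm"]

    def test_auc_omitted_without_probs(self):
        m = classification_metrics([0, 1], [0, 1])
        assert "roc_auc" not in m


class TestAggregateSubjects:
    def test_mean_probability_rule(self):
        out = aggregate_subjects([0.9, 0.8, 0.1], ["a", "a", "a"])
        assert out["a"]["score"] == pytest.approx(0.6)
        assert out["a"]["pred"] == 1

    def test_tie_goes_positive(self):
        out = aggregate_subjects([0.5, 0.5], ["a", "a"])
        assert out["a"]["pred"] == 1

    def test_23_of_28_gives_8214_percent(self):
        """23 correct subjects of 28 is the 82.14% subject-level accuracy."""
        probs, sids, truth = [], [], []
        for i in range(28):
            true = int(i < 14)
            correct = i < 23  # 23 correct, 5 wrong
            p = 0.9 if (true == 1) == correct else 0.1
            if true == 0:
                p = 0.1 if correct else 0.9
            probs += [p] * 3
            sids += [f"s{i:02d}"] * 3
            truth += [true] * 3
        agg = aggregate_subjects(probs, sids, y_true=truth)
        acc = np.mean([v["correct"] for v in agg.values()]) * 100
        assert acc == pytest.approx(82.14, abs=0.01)


class TestBootstrapCI:
    def test_all_correct_degenerate(self):
        lo, hi = bootstrap_ci(np.ones(10), B=500, seed=0)
        assert (lo, hi) == (100.0, 100.0)

    def test_matches_exact_binomial_oracle(self):
        """n=4 with 2 correct: resampled mean is Binomial(4, 1/2)/4; the
        2.5th and 97.5th percentiles of that distribution are 0 and 1."""
        lo, hi = bootstrap_ci([1, 1, 0, 0], B=100_000, seed=1)
        assert lo == 0.0
        assert hi == 100.0

    def test_bounds_monotone_in_success_count(self):
        prev = (-1.0, -1.0)
        for k in range(0, 29):
            lo, hi = bootstrap_ci([1] * k + [0] * (28 - k), B=400, seed=7)
            assert lo >= prev[0] - 1e-9 and hi >= prev[1] - 1e-9
            prev = (lo, hi)

    def test_too_few_outcomes_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1], B=10)


def _oracle_threshold_curve(probs, y_true, grid):
    precision, recall, f1 = [], [], []
    for t in grid:
        pred = (probs >= t).astype(int)
        tp = np.sum((pred == 1) & (y_true == 1))
        fp = np.sum((pred == 1) & (y_true == 0))
        fn = np.sum((pred == 0) & (y_true == 1))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precision.append(p)
        recall.append(r)
        f1.append(2 * p * r / (p + r) if p + r else 0.0)
    return precision, recall, f1


class TestThresholdSweep:
    def test_perfectly_separated_scores(self, rng):
        probs = np.concatenate([rng.uniform(0, 0.3, 50),
                                rng.uniform(0.7, 1.0, 50)])
        y = np.array([0] * 50 + [1] * 50)
        res = threshold_sweep(probs, y)
        assert res["best_f1"] == pytest.approx(1.0)
        assert res["best_threshold"] <= 0.301

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([0.2, 0.8], [1, 1])

    def test_matches_brute_force_oracle(self, rng):
        probs = rng.uniform(size=200)
        y = rng.integers(0, 2, size=200)
        res = threshold_sweep(probs, y, step=0.01)
        grid = np.array(res["thresholds"])
        p, r, f = _oracle_threshold_curve(probs, y, grid)
        np.testing.assert_allclose(res["precision"], p, atol=1e-12)
        np.testing.assert_allclose(res["recall"], r, atol=1e-12)
        np.testing.assert_allclose(res["f1"], f, atol=1e-12)


class TestPairedFoldTest:
    def test_all_positive_differences_give_w_zero(self):
        a = np.linspace(0.7, 0.9, 28)
        b = a - 0.02
        res = paired_fold_test({"ens_vs_rf": (a, b)})
        assert res["ens_vs_rf"]["W"] == 0.0
        assert res["ens_vs_rf"]["p"] < 0.001

    def test_identical_vectors_warn_p_one(self):
        a = np.full(10, 0.8)
        with pytest.warns(UserWarning):
            res = paired_fold_test({"same": (a, a.copy())})
        assert res["same"]["p"] == 1.0

    def test_bh_adjustment_hand_computed(self):
        adj = bh_adjust([0.01, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04], atol=1e-12)

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(ValueError):
            paired_fold_test({"bad": (np.ones(5), np.ones(6))})


class TestRunProtocol:
    def test_train_equals_test_rejected(self, small_features, fast_ensemble):
        idx = np.arange(small_features.n_epochs)
        plan = FoldPlan("kfold_epoch", [(idx, idx)], {}, 0)
        with pytest.raises(LeakageError):
            run_protocol(small_features, plan, {"chain": ["variance"]},
                         fast_ensemble, bootstrap_B=50)

    def test_deterministic_reports(self, small_features, fast_ensemble):
        plan = make_folds("loso", small_features.subject_ids)
        kw = dict(selection={"chain": ["variance", "mrmr"], "k": 10},
                  ensemble=fast_ensemble, seed=3, bootstrap_B=100)
        a = run_protocol(small_features, plan, **kw)
        b = run_protocol(small_features, plan, **kw)
        assert a.probs == b.probs
        assert a.fold_accuracies == b.fold_accuracies
        assert a.bootstrap == b.bootstrap

    def test_loso_pools_every_epoch_once(self, small_features, fast_ensemble):
        plan = make_folds("loso", small_features.subject_ids)
        rep = run_protocol(small_features, plan, {"chain": ["variance"]},
                           fast_ensemble, bootstrap_B=50)
        assert len(rep.y_pred) == small_features.n_epochs
        assert len(rep.probs) == sum(len(te) for _, te in plan.folds)

    def test_strong_effect_weak_subject_gives_high_loso_accuracy(
            self, small_features, fast_ensemble):
        """Planted strong class effect, weak subject effect: LOSO epoch
        accuracy is high (>= 0.8)."""
        plan = make_folds("loso", small_features.subject_ids)
        rep = run_protocol(small_features, plan,
                           {"chain": ["variance", "mrmr"], "k": 20},
                           fast_ensemble, seed=0, bootstrap_B=100)
        assert rep.epoch_accuracy >= 0.8

    def test_report_json_round_trip(self, tmp_path, small_features,
                                    fast_ensemble):
        plan = make_folds("kfold_epoch", small_features.subject_ids,
                          {"k": 3}, labels=small_features.labels)
        rep = run_protocol(small_features, plan, {"chain": ["variance"]},
                           fast_ensemble, bootstrap_B=50)
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json
        loaded = json.loads(path.read_text())
        assert loaded["scheme"] == "kfold_epoch"
        assert loaded["epoch_metrics"]["accuracy"] == rep.epoch_accuracy
        assert "lower_pct" in loaded["bootstrap"]
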