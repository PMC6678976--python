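import math

import numpy as np
import pandas as pd
import pytest

from gbmpanel import synth
from gbmpanel.fastemc import (
    BestSetList,
    CentroidModel,
    ConfusionMatrix,
    FastEMCConfig,
    FeatureSet,
    LabeledDataset,
    accept_move,
    combine_signatures,
    cv_objective,
    evaluate_predictions,
    fit_nearest_centroid,
    fscore,
    mutate,
    per_class_classifiers,
    predict_nearest_centroid,
    run_fastemc,
)
from gbmpanel.types import ExprMatrix, ScaleTag


class TestFscore:
    def test_perfect_diagonal_is_one(self):
        cm = ConfusionMatrix(["a", "b", "c"], np.diag([5, 3, 2]))
        assert fscore(cm) == 1.0

    def test_binary_uses_positive_class_f1(self):
        # TP=1, FN=1 / FP=1, TN=0 -> precision = recall = 0.5
        cm = ConfusionMatrix(["pos", "neg"], [[1, 1], [1, 0]])
        assert fscore(cm) == pytest.approx(0.5)

    def test_zero_diagonal_is_zero(self):
        cm = ConfusionMatrix(["a", "b"], [[0, 4], [3, 0]])
        assert fscore(cm, positive_class="a") == 0.0

    def test_never_predicted_class_contributes_zero(self):
        # class c: zero true positives and zero predictions -> F1 of 0
        cm = ConfusionMatrix(["a", "b", "c"], [[3, 0, 0], [0, 2, 0], [1, 0, 0]])
        # a: precision 3/4, recall 1 -> F1 6/7; b: 1; c: 0
        assert fscore(cm) == pytest.approx((6 / 7 + 1.0 + 0.0) / 3)

    def test_confusion_row_sums_and_accuracy_identity(self):
        truth = ["a", "a", "b", "b", "b"]
        pred = ["a", "b", "b", "b", "a"]
        cm, acc = evaluate_predictions(pred, truth)
        assert cm.counts.sum(axis=1).tolist() == [2, 3]
        assert acc == pytest.approx(np.trace(cm.counts) / cm.total)


class TestCVObjective:
    def _separable(self):
        X = np.zeros((3, 40))
        y = ["a"] * 20 + ["b"] * 20
        X[0] = [0.0] * 20 + [5.0] * 20  # perfectly separating feature
        X[1:] = np.random.default_rng(0).normal(size=(2, 40))
        expr = ExprMatrix(X, genes=["sep", "n1", "n2"],
                          samples=[f"s{i}" for i in range(40)],
                          scale_tag=ScaleTag.ZSCORE)
        return LabeledDataset(expr=expr, labels={f"s{i}": y[i] for i in range(40)})

    def test_separating_feature_scores_one(self):
        data = self._separable()
        assert cv_objective(data, ["sep"], seed=0) == pytest.approx(1.0)

    def test_same_seed_is_deterministic(self):
        data = self._separable()
        s1 = cv_objective(data, ["sep", "n1"], seed=3)
        s2 = cv_objective(data, ["sep", "n1"], seed=3)
        assert s1 == s2

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(0)
        scores = []
        for seed in range(50):
            data, _ = synth.make_labeled_dataset(
                synth.LabeledSpec(n_genes=30, n_samples=80, n_markers=0, seed=seed)
            )
            scores.append(cv_objective(data, list(range(10)), seed=seed))
        # 4 balanced classes: chance macro-F1 is ~0.25
        assert abs(np.mean(scores) - 0.25) < 0.04

    def test_too_small_class_for_folds_raises(self):
        data = self._separable()
        with pytest.raises(ValueError, match="stratified"):
            cv_objective(data, ["sep"], folds=30, seed=0)


class TestMoves:
    def test_mutation_preserves_size_and_membership_rules(self):
        rng = np.random.default_rng(0)
        fs = frozenset(range(20))
        for _ in range(200):
            out = mutate(fs, 100, rng)
            assert len(out) == 20
            assert out <= frozenset(range(100))

    def test_full_swap_possible_and_single_swap_bounds(self):
        rng = np.random.default_rng(1)
        overlaps = set()
        fs = frozenset(range(5))
        for _ in range(500):
            overlaps.add(len(fs & mutate(fs, 50, rng)))
        # u is uniform on 1..m: overlap m-u spans 0..m-1
        assert overlaps == {0, 1, 2, 3, 4}

    def test_mutation_stream_reproducible(self):
        fs = frozenset(range(10))
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            seqs.append([mutate(fs, 30, rng) for _ in range(20)])
        assert seqs[0] == seqs[1]

    def test_pool_not_larger_than_set_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            mutate(frozenset(range(10)), 10, np.random.default_rng(0))

    def test_nonnegative_delta_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(accept_move(d, 0.03, rng) for d in [0.0, 0.01, 1.0])

    def test_metropolis_rate_at_minus_gamma(self):
        rng = np.random.default_rng(7)
        gamma = 0.03
        rate = np.mean([accept_move(-gamma, gamma, rng) for _ in range(10_000)])
        assert rate == pytest.approx(math.exp(-1), abs=0.02)

    def test_vanishing_gamma_rejects_downhill(self):
        rng = np.random.default_rng(0)
        accepts = sum(accept_move(-0.1, 1e-9, rng) for _ in range(1000))
        assert accepts == 0


class TestBestSetList:
    def _fs(self, ids, full):
        return FeatureSet(frozenset(ids), fast_score=0.0, full_score=full)

    def test_keeps_top_scores_sorted_and_bounded(self):
        bl = BestSetList(3)
        for i, s in enumerate([0.5, 0.9, 0.1, 0.7, 0.3]):
            bl.offer(self._fs([i], s))
        scores = [e.full_score for e in bl.entries]
        assert scores == [0.9, 0.7, 0.5]

    def test_duplicate_sets_rejected(self):
        bl = BestSetList(3)
        assert bl.offer(self._fs([1, 2], 0.5))
        assert not bl.offer(self._fs([2, 1], 0.8))
        assert len(bl) == 1

    def test_minimum_monotonically_nondecreasing(self):
        rng = np.random.default_rng(0)
        bl = BestSetList(5)
        minima = []
        for i in range(50):
            bl.offer(self._fs([i], rng.random()))
            if len(bl) == 5:
                minima.append(bl.min_score)
        assert all(b >= a for a, b in zip(minima, minima[1:]))


class TestRunFastEMC:
    SMALL = dict(n_outer=15, n_inner=5, best_list_size=10, init_size=5,
                 final_signature_size=10)

    def test_identical_seed_gives_identical_result(self):
        data, _ = synth.make_labeled_dataset(
            synth.LabeledSpec(n_genes=40, n_samples=60, n_markers=4, seed=3)
        )
        cfg = FastEMCConfig(rng_seed=11, **self.SMALL)
        r1, r2 = run_fastemc(data, cfg), run_fastemc(data, cfg)
        assert r1.final_signature == r2.final_signature
        assert r1.trace.equals(r2.trace)
        assert [e.features for e in r1.best_list.entries] == [
            e.features for e in r2.best_list.entries
        ]

    def test_feature_set_size_invariant_and_frequency_bounds(self):
        data, _ = synth.make_labeled_dataset(
            synth.LabeledSpec(n_genes=40, n_samples=60, n_markers=4, seed=4)
        )
        cfg = FastEMCConfig(rng_seed=0, **self.SMALL)
        res = run_fastemc(data, cfg)
        assert all(len(e.features) == cfg.init_size for e in res.best_list.entries)
        assert res.feature_frequency.max() <= len(res.best_list)

    def test_degenerate_pool_equal_to_set_size(self):
        data, _ = synth.make_labeled_dataset(
            synth.LabeledSpec(n_genes=5, n_samples=40, n_markers=2, seed=5)
        )
        cfg = FastEMCConfig(init_size=5, n_outer=4, n_inner=3, best_list_size=5,
                            final_signature_size=5, rng_seed=0)
        res = run_fastemc(data, cfg)
        assert len(res.best_list) == 1  # one unique set exists
        assert sorted(res.final_signature) == sorted(data.expr.genes)

    def test_zero_outer_iterations_rejected(self):
        with pytest.raises(ValueError, match="n_outer"):
            FastEMCConfig(n_outer=0)

    def test_best_list_minimum_never_decreases_over_outer_iterations(self):
        data, _ = synth.make_labeled_dataset(
            synth.LabeledSpec(n_genes=40, n_samples=60, n_markers=4, seed=6)
        )
        res = run_fastemc(data, FastEMCConfig(rng_seed=1, **self.SMALL))
        # replay: offered full scores; running minimum of kept top-B is monotone
        fulls = res.trace["full_score"].tolist()
        bl = BestSetList(10)
        minima = []
        for i, f in enumerate(fulls):
            bl.offer(FeatureSet(frozenset([i]), 0.0, f))
            if len(bl) == bl.capacity:
                minima.append(bl.min_score)
        assert all(b >= a for a, b in zip(minima, minima[1:]))


class TestPerClass:
    def test_binary_runs_are_complementary_and_union_bounded(self):
        data, _ = synth.make_labeled_dataset(
            synth.LabeledSpec(n_genes=30, n_samples=60, n_classes=2, n_markers=4,
                              effect=2.0, seed=8)
        )
        cfg = FastEMCConfig(n_outer=8, n_inner=4, best_list_size=5, init_size=5,
                            final_signature_size=10, rng_seed=0)
        results = per_class_classifiers(data, cfg)
        assert set(results) == set(data.classes)
        union = combine_signatures(results)
        assert len(union) == len(set(union)) <= cfg.final_signature_size

    def test_per_class_markers_recovered(self):
        data, truth = synth.make_labeled_dataset(
            synth.LabeledSpec(n_genes=60, n_samples=80, n_classes=4, n_markers=8,
                              effect=3.0, marker_mode="per_class", seed=9)
        )
        cfg = FastEMCConfig(n_outer=40, n_inner=10, best_list_size=20, init_size=8,
                            final_signature_size=40, rng_seed=2)
        results = per_class_classifiers(data, cfg)
        hits = total = 0
        for cls, res in results.items():
            markers = set(truth.genes_with_role(f"class_marker:{cls}"))
            top_k = set(res.feature_frequency.index[: max(10, len(markers))])
            hits += len(markers & top_k)
            total += len(markers)
        assert hits / total >= 0.7

    def test_class_smaller_than_folds_rejected(self):
        data, _ = synth.make_labeled_dataset(
            synth.LabeledSpec(n_genes=20, n_samples=12, n_classes=3, n_markers=0, seed=1)
        )
        with pytest.raises(ValueError, match="cv_folds"):
            per_class_classifiers(data, FastEMCConfig(cv_folds=5))


class TestNearestCentroid:
    def _toy(self):
        X = np.array([[0.0, 0.0, 4.0, 4.0], [0.0, 0.0, 4.0, 4.0]])
        expr = ExprMatrix(X, genes=["g1", "g2"], samples=["s1", "s2", "s3", "s4"],
                          scale_tag=ScaleTag.ZSCORE)
        return LabeledDataset(expr=expr, labels={"s1": "a", "s2": "a", "s3": "b", "s4": "b"})

    def test_sample_at_centroid_predicted_to_its_class(self):
        data = self._toy()
        model = fit_nearest_centroid(data, ["g1", "g2"])
        labels, dist = predict_nearest_centroid(model, data.expr)
        assert labels == ["a", "a", "b", "b"]
        assert dist.loc["s1", "a"] == pytest.approx(0.0)

    def test_equidistant_tie_resolves_to_first_class(self):
        data = self._toy()
        model = fit_nearest_centroid(data, ["g1", "g2"])
        midpoint = ExprMatrix(np.array([[2.0], [2.0]]), genes=["g1", "g2"],
                              samples=["mid"], scale_tag=ScaleTag.ZSCORE)
        labels, _ = predict_nearest_centroid(model, midpoint)
        assert labels == ["a"]

    def test_unseen_feature_at_predict_time_rejected(self):
        data = self._toy()
        model = fit_nearest_centroid(data, ["g1", "g2"])
        other = ExprMatrix(np.zeros((1, 1)), genes=["g1"], samples=["x"],
                           scale_tag=ScaleTag.ZSCORE)
        with pytest.raises(KeyError, match="g2"):
            predict_nearest_centroid(model, other)

    def test_strong_separation_accuracy_above_ninety_percent(self):
        data, truth = synth.make_labeled_dataset(
            synth.LabeledSpec(n_genes=60, n_samples=120, n_markers=12, effect=3.0, seed=10)
        )
        markers = truth.genes_with_role("class_marker")
        # split: even samples train, odd samples held out
        ids = data.expr.sample_ids
        train = LabeledDataset(expr=data.expr.subset_samples(ids[::2]), labels=data.labels)
        model = fit_nearest_centroid(train, markers)
        held_out = data.expr.subset_samples(ids[1::2])
        labels, _ = predict_nearest_centroid(model, held_out)
        cm, acc = evaluate_predictions(
            labels, [data.labels[s] for s in held_out.sample_ids]
        )
        assert acc >= 0.9
        assert cm.counts.sum() == 60
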