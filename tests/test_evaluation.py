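"""Metric suite, ROC, threshold optimisation, folds, and paired tests."""

import math

import numpy as np
import pytest

from easemm.evaluation import (
    ConfusionCounts, category_breakdown, confusion, cross_validate,
    make_unseen_protein_folds, metrics, optimize_threshold, paired_ttest,
    roc_auc, asa_four_bin, asa_two_bin, ddg_bin,
)


def brute_force_metrics(tp, tn, fp, fn):
    """Independent direct-arithmetic implementation of the metric equations."""
    total = tp + tn + fp + fn
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    rate = lambda a, b: 100.0 * a / b if b else float("nan")
    return {
        "MCC": mcc, "Q2": 100.0 * (tp + tn) / total,
        "Se": rate(tp, tp + fn), "Sp": rate(tn, tn + fp),
        "PPV": rate(tp, tp + fp), "NPV": rate(tn, tn + fn),
    }


def pair_counting_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle: P(random positive outscores a random
    negative), ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_negative_predictions(self):
        c = confusion([1, 0, 1, 0], [0, 0, 0, 0])
        assert c.tp == 0 and c.fp == 0 and c.fn == 2 and c.tn == 2

    def test_hand_tally(self):
        labels = [1, 1, 1, 0, 0, 0, 1, 0, 1, 0]
        preds = [1, 0, 1, 1, 0, 0, 1, 1, 0, 0]
        c = confusion(labels, preds)
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 3, 2, 2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(5, 5, 0, 0))
        assert m.mcc == pytest.approx(1.0)
        assert m.q2 == m.se == m.sp == pytest.approx(100.0)

    def test_chance(self):
        m = metrics(ConfusionCounts(25, 25, 25, 25))
        assert m.mcc == pytest.approx(0.0) and m.q2 == pytest.approx(50.0)

    def test_derived_example(self):
        m = metrics(ConfusionCounts(tp=3, fn=1, tn=4, fp=2))
        expected = brute_force_metrics(3, 4, 2, 1)
        for k, v in expected.items():
            assert m.as_dict()[k] == pytest.approx(v)

    def test_zero_denominator_conventions(self):
        m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m.mcc == 0.0
        assert math.isnan(m.se) and math.isnan(m.ppv)  # undefined-marked

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_separation(self):
        _, _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == pytest.approx(1.0)

    def test_all_ties(self):
        _, _, auc = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_six_point_fixture_vs_oracle(self):
        scores = [0.9, 0.8, 0.8, 0.4, 0.3, 0.1]
        labels = [1, 0, 1, 1, 0, 0]
        _, _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        labels[0], labels[1] = True, False
        _, _, a1 = roc_auc(scores, labels)
        _, _, a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestOptimizeThreshold:
    def test_separable(self):
        t = optimize_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert 0.2 < t <= 0.8
        m = metrics(confusion([0, 0, 1, 1], np.array([0.1, 0.2, 0.8, 0.9]) >= t))
        assert m.mcc == pytest.approx(1.0)

    def test_single_top_positive(self):
        scores = [0.9, 0.5, 0.4, 0.3]
        labels = [1, 0, 0, 0]
        t = optimize_threshold(scores, labels)
        m = metrics(confusion(labels, np.asarray(scores) >= t))
        assert m.mcc > 0

    def test_anti_separated_reported_honestly(self):
        scores = [0.9, 0.8, 0.1, 0.2]
        labels = [0, 0, 1, 1]
        t = optimize_threshold(scores, labels)
        m = metrics(confusion(labels, np.asarray(scores) >= t))
        assert m.mcc <= 0  # no silent score flipping

    def test_optimum_dominates_all_candidates(self, rng):
        for trial in range(20):
            r = np.random.default_rng(trial)
            scores = r.normal(size=30)
            labels = r.random(30) < 0.3
            labels[:2] = [True, False]
            t = optimize_threshold(scores, labels)
            best = metrics(confusion(labels, scores >= t)).mcc
            u = np.unique(scores)
            for cand in np.concatenate([[u[0] - 1], (u[:-1] + u[1:]) / 2, [u[-1] + 1]]):
                assert best >= metrics(confusion(labels, scores >= cand)).mcc - 1e-12


class TestFolds:
    def test_singletons_pigeonhole(self):
        sizes = {f"c{i}": 1 for i in range(10)}
        pos = {f"c{i}": i % 2 for i in range(10)}
        fa = make_unseen_protein_folds(sizes, pos, k=10, seed=0)
        assert sorted(fa.assignment.values()) == list(range(1, 11))

    def test_cluster_integrity_and_exhaustiveness(self, rng):
        sizes = {f"c{i}": int(rng.integers(1, 9)) for i in range(30)}
        pos = {c: int(rng.binomial(n, 0.28)) for c, n in sizes.items()}
        fa = make_unseen_protein_folds(sizes, pos, k=10, seed=3)
        assert set(fa.assignment) == set(sizes)
        assert all(1 <= f <= 10 for f in fa.assignment.values())

    def test_size_balance_bound(self, rng):
        sizes = {f"c{i}": int(rng.integers(1, 6)) for i in range(40)}
        pos = {c: int(rng.binomial(n, 0.3)) for c, n in sizes.items()}
        fa = make_unseen_protein_folds(sizes, pos, k=10, seed=1)
        fold_n = np.zeros(10)
        for c, f in fa.assignment.items():
            fold_n[f - 1] += sizes[c]
        assert fold_n.max() - fold_n.min() <= max(sizes.values())

    def test_too_few_clusters(self):
        with pytest.raises(ValueError):
            make_unseen_protein_folds({"a": 1}, {"a": 0}, k=2)


class TestCrossValidate:
    def make_problem(self, rng, n_clusters=12, per=10, signal=2.0):
        clusters = np.repeat([f"c{i}" for i in range(n_clusters)], per)
        n = len(clusters)
        y = rng.random(n) < 0.3
        X = rng.normal(size=n) + signal * y

        def fit(train_idx):
            mu1 = X[train_idx][y[train_idx]].mean() if y[train_idx].any() else 0.0
            mu0 = X[train_idx][~y[train_idx]].mean()
            return lambda idx: (X[idx] - mu0) / max(mu1 - mu0, 1e-9)

        return y, clusters, fit

    def test_determinism(self, rng):
        y, clusters, fit = self.make_problem(rng)
        r1 = cross_validate(y, clusters, fit, k=4, reps=2, seed=9)
        r2 = cross_validate(y, clusters, fit, k=4, reps=2, seed=9)
        for m1, m2 in zip(r1.replicates, r2.replicates):
            assert m1.as_dict() == m2.as_dict()

    def test_signal_recovered(self, rng):
        y, clusters, fit = self.make_problem(rng, signal=3.0)
        r = cross_validate(y, clusters, fit, k=4, reps=3, seed=0)
        assert r.mean("AUC") > 0.9
        assert r.mean("MCC") > 0.5

    def test_aggregate_is_mean_of_replicates(self, rng):
        y, clusters, fit = self.make_problem(rng)
        r = cross_validate(y, clusters, fit, k=4, reps=5, seed=2)
        assert r.mean("AUC") == pytest.approx(np.mean([m.auc for m in r.replicates]))


class TestBreakdown:
    def test_bin_edges(self):
        assert ddg_bin(1.0) == "small"     # closed interval [-1, 1]
        assert ddg_bin(-1.0) == "small"
        assert ddg_bin(-1.5) == "large"
        assert asa_two_bin(0.25) == "<=25%"
        assert asa_two_bin(0.250001) == ">25%"
        assert asa_four_bin(0.199) == "0-20%"
        assert asa_four_bin(0.20) == "20-40%"
        assert asa_four_bin(0.60) == ">60%"

    def test_single_bin_equals_global(self, rng):
        labels = rng.random(40) < 0.4
        labels[:2] = [True, False]
        preds = rng.random(40) < 0.5
        scores = rng.random(40)
        out = category_breakdown(labels, preds, scores, {"ss": ["helix"] * 40})
        m = out[("ss", "helix")]
        g = metrics(confusion(labels, preds))
        assert m.mcc == pytest.approx(g.mcc) and m.q2 == pytest.approx(g.q2)

    def test_bins_cover_and_empty_marked(self, rng):
        labels = [1, 0, 1, 0]
        preds = [1, 0, 0, 0]
        scores = [0.9, 0.1, 0.4, 0.2]
        bins = {"ddg": ["small", "small", "large", "large"]}
        out = category_breakdown(labels, preds, scores, bins)
        assert out[("ddg", "small")] is not None
        with pytest.raises(ValueError):
            category_breakdown(labels, preds, scores, {"ss": ["helix"] * 3})


class TestPairedTTest:
    def test_identical_series(self):
        with pytest.warns(UserWarning):
            t, p = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_shift_limit(self):
        with pytest.warns(UserWarning):
            t, p = paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert t == math.inf and p == 0.0

    def test_textbook_formula(self, rng):
        a = rng.normal(0.5, 1.0, 10)
        b = rng.normal(0.0, 1.0, 10)
        t, p = paired_ttest(a, b)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert t == pytest.approx(t_hand)
        from scipy import stats
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), len(d) - 1))
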