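import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from contrast_gate import threshold_analysis as ta
from contrast_gate.errors import (
    ConfigError,
    DegenerateClusteringError,
    EmptyDatasetError,
)
from contrast_gate.seg_metrics import ConfusionCounts, SliceEvaluation


def make_eval(sid, det=1, dsc=0.8, hd=5.0, raad=0.0):
    return SliceEvaluation(
        sid, det, dsc, hd, raad, dsc >= 0.1, hd <= 60, abs(raad) <= 0.5
    )


# ---------------------------------------------------------------------------
# brute-force oracles


def silhouette_brute(X, labels, metric):
    D = cdist(X, X, metric=metric)
    n = len(X)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        other = [j for j in range(n) if labels[j] != labels[i]]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([D[i, j] for j in same])
        b = np.mean([D[i, j] for j in other])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def best_two_partition(X, metric):
    """Exhaustive optimal 2-partition by within-cluster distance-to-mean sum."""
    n = len(X)
    best_labels, best_obj = None, None
    for bits in range(1, 2 ** (n - 1)):  # fix point 0 in cluster 0
        labels = np.array([(bits >> i) & 1 for i in range(n)])
        obj = 0.0
        for k in (0, 1):
            members = X[labels == k]
            if len(members) == 0:
                obj = np.inf
                break
            c = members.mean(axis=0, keepdims=True)
            obj += cdist(members, c, metric=metric).sum()
        if best_obj is None or obj < best_obj:
            best_labels, best_obj = labels, obj
    return best_labels


# ---------------------------------------------------------------------------


class TestBinPerformance:
    def _fixture(self):
        evals, contrasts = [], {}
        for i in range(20):
            f = 0.01 + 0.02 * i
            det = 0 if f < 0.05 else 1
            evals.append(make_eval(f"s{i}", det=det, dsc=0.05 if det == 0 else 0.8))
            contrasts[f"s{i}"] = f
        return evals, contrasts

    def test_failure_fraction_matches_loop(self):
        evals, contrasts = self._fixture()
        out = ta.failure_fraction_below(evals, contrasts, 0.05)
        failing = [e for e in evals if e.detection == 0]
        expected = sum(contrasts[e.slice_id] < 0.05 for e in failing) / len(failing)
        assert out["detection"] == pytest.approx(expected)

    def test_all_failures_below_threshold(self):
        evals, contrasts = self._fixture()
        out = ta.failure_fraction_below(evals, contrasts, 0.06)
        assert out["detection"] == 1.0

    def test_no_failures_is_undefined(self):
        evals = [make_eval(f"s{i}") for i in range(5)]
        contrasts = {f"s{i}": 0.1 for i in range(5)}
        out = ta.failure_fraction_below(evals, contrasts, 0.05)
        assert np.isnan(out["detection"])

    def test_bin_aggregates(self):
        evals, contrasts = self._fixture()
        table = ta.bin_performance(evals, contrasts, [0.0, 0.05, 0.5])
        low = table.iloc[0]
        assert low["n"] == 2 and low["detection_mean"] == 0.0
        assert table["n"].sum() == 20


class TestRocSweep:
    def test_lowest_threshold_recovers_whole_set_rates(self):
        conf = {
            "a": ConfusionCounts(10, 2, 5, 83),
            "b": ConfusionCounts(20, 1, 10, 69),
        }
        contrasts = {"a": 0.02, "b": 0.2}
        pts = ta.roc_sweep(conf, contrasts, [0.01])
        assert pts[0].n_slices == 2
        assert pts[0].tpr == pytest.approx(30 / 45)
        assert pts[0].fpr == pytest.approx(3 / 155)

    def test_threshold_between_slices_keeps_survivor_only(self):
        conf = {
            "a": ConfusionCounts(10, 2, 5, 83),
            "b": ConfusionCounts(20, 1, 10, 69),
        }
        contrasts = {"a": 0.02, "b": 0.2}
        pts = ta.roc_sweep(conf, contrasts, [0.1])
        assert pts[0].n_slices == 1
        assert pts[0].tpr == pytest.approx(20 / 30)
        assert pts[0].fpr == pytest.approx(1 / 70)

    def test_rates_stay_in_unit_interval(self):
        rng = np.random.default_rng(0)
        conf, contrasts = {}, {}
        for i in range(30):
            tp, fp, fn = rng.integers(0, 50, 3)
            conf[f"s{i}"] = ConfusionCounts(int(tp), int(fp), int(fn), 100)
            contrasts[f"s{i}"] = float(rng.random())
        for p in ta.roc_sweep(conf, contrasts, np.linspace(0, 1, 21)):
            assert 0.0 <= p.tpr <= 1.0 and 0.0 <= p.fpr <= 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            ta.roc_sweep({}, {}, [])


class TestElbow:
    def test_single_point_returns_its_threshold(self):
        assert ta.elbow_threshold([ta.RocPoint(0.07, 0.5, 0.01, 9)]) == 0.07

    def test_hand_computed_distances_pick_the_knee(self):
        sweep = [
            ta.RocPoint(0.01, 0.2, 0.0, 30),
            ta.RocPoint(0.05, 0.9, 0.1, 20),
            ta.RocPoint(0.20, 1.0, 1.0, 5),
        ]
        assert ta.elbow_threshold(sweep) == 0.05

    def test_constant_axis_contributes_nothing(self):
        sweep = [
            ta.RocPoint(0.01, 0.2, 0.5, 30),
            ta.RocPoint(0.05, 0.9, 0.5, 20),
        ]
        assert ta.elbow_threshold(sweep) == 0.05  # decided by TPR alone

    def test_empty_sweep_rejected(self):
        with pytest.raises(EmptyDatasetError):
            ta.elbow_threshold([])


class TestClustering:
    @pytest.mark.parametrize("distance", ta.DISTANCES)
    def test_separated_blobs_recovered_under_every_distance(self, distance):
        rng = np.random.default_rng(1)
        lo = 0.05 + 0.05 * rng.random((6, 2))
        hi = 0.9 + 0.1 * rng.random((6, 2))
        X = np.vstack([lo, hi])
        truth = np.array([0] * 6 + [1] * 6)
        for algorithm in ("kmeans", "hierarchical"):
            res = ta.cluster_slices(X, algorithm, distance, seed=0)
            agree = np.mean(res.labels == truth)
            assert agree in (0.0, 1.0)  # perfect up to label swap
            assert res.silhouette > 0.8

    @pytest.mark.parametrize("distance", ta.DISTANCES)
    def test_kmeans_matches_exhaustive_partition_search(self, distance):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0.2, 0.05, (5, 3)), rng.normal(0.8, 0.05, (5, 3))])
        res = ta.cluster_slices(X, "kmeans", distance, seed=3)
        oracle = best_two_partition(X, ta._SCIPY_METRIC[distance])
        agree = np.mean(res.labels == oracle)
        assert agree in (0.0, 1.0)

    @pytest.mark.parametrize("distance", ta.DISTANCES)
    def test_silhouette_matches_brute_force(self, distance):
        rng = np.random.default_rng(4)
        X = rng.random((60, 4))
        res = ta.cluster_slices(X, "kmeans", distance, seed=1)
        brute = silhouette_brute(X, res.labels, ta._SCIPY_METRIC[distance])
        assert res.silhouette == pytest.approx(brute, abs=1e-9)

    def test_fixed_seed_reproduces_labels(self):
        rng = np.random.default_rng(5)
        X = rng.random((40, 5))
        a = ta.cluster_slices(X, "kmeans", "canberra", seed=42)
        b = ta.cluster_slices(X, "kmeans", "canberra", seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_kmeans_assignment_is_a_fixed_point(self):
        rng = np.random.default_rng(6)
        X = rng.random((50, 3))
        res = ta.cluster_slices(X, "kmeans", "euclidean", seed=0)
        d = cdist(X, res.centroids, metric="euclidean")
        np.testing.assert_array_equal(np.argmin(d, axis=1), res.labels)

    def test_identical_points_rejected(self):
        with pytest.raises(DegenerateClusteringError):
            ta.cluster_slices(np.ones((10, 3)), "kmeans", "euclidean")


class TestClusterQuality:
    def test_perfect_split_purity(self):
        f = np.array([0.01, 0.02, 0.03, 0.2, 0.3, 0.4])
        res = ta.ClusterResult(
            "kmeans", "euclidean", np.array([0, 0, 0, 1, 1, 1]),
            np.zeros((2, 1)), 0.9, 0,
        )
        purity, sil = ta.cluster_quality(res, f, 0.05)
        assert purity == 1.0

    def test_hand_counted_purity(self):
        f = np.array([0.01] * 5 + [0.2] * 5)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 0])  # 8 of 10 agree
        res = ta.ClusterResult("kmeans", "euclidean", labels, np.zeros((2, 1)), 0.5, 0)
        purity, _ = ta.cluster_quality(res, f, 0.05)
        assert purity == pytest.approx(0.8)

    def test_relabeling_invariance(self):
        f = np.array([0.01] * 5 + [0.2] * 5)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 0])
        a = ta.ClusterResult("kmeans", "euclidean", labels, np.zeros((2, 1)), 0.5, 0)
        b = ta.ClusterResult("kmeans", "euclidean", 1 - labels, np.zeros((2, 1)), 0.5, 0)
        assert ta.cluster_quality(a, f, 0.05)[0] == ta.cluster_quality(b, f, 0.05)[0]

    def test_one_sided_reference_is_undefined(self):
        f = np.full(6, 0.2)
        res = ta.ClusterResult(
            "kmeans", "euclidean", np.array([0, 0, 0, 1, 1, 1]),
            np.zeros((2, 1)), 0.9, 0,
        )
        purity, _ = ta.cluster_quality(res, f, 0.05)
        assert np.isnan(purity)


class TestR2Sweep:
    def _results(self, labels_list, sils):
        return [
            ta.ClusterResult("kmeans", f"d{i}", np.asarray(l), np.zeros((2, 1)), s, 0)
            for i, (l, s) in enumerate(zip(labels_list, sils))
        ]

    def test_linear_purity_silhouette_relation_reaches_one(self):
        f = np.array([0.01, 0.02, 0.03, 0.04, 0.2, 0.3, 0.4, 0.5])
        perfect = [0, 0, 0, 0, 1, 1, 1, 1]
        one_off = [0, 0, 0, 1, 1, 1, 1, 1]
        two_off = [0, 0, 1, 1, 1, 1, 1, 1]
        results = self._results(
            [perfect, one_off, two_off], sils=[0.9, 0.8, 0.7]
        )
        curve, selected = ta.r2_threshold_sweep(results, f, [0.05, 0.1, 0.25])
        at_gap = curve.set_index("threshold").loc[0.1, "r2"]
        assert at_gap == pytest.approx(1.0)
        assert selected == 0.05  # ties between 0.05 and 0.1 resolve low

    def test_degenerate_thresholds_excluded_from_argmax(self):
        f = np.array([0.01, 0.02, 0.2, 0.3])
        same = [0, 0, 1, 1]
        diff = [0, 1, 1, 1]
        results = self._results([same, same, same, diff], sils=[0.9, 0.8, 0.7, 0.6])
        curve, selected = ta.r2_threshold_sweep(results, f, [0.05, 0.1, 0.4])
        by_t = curve.set_index("threshold")["r2"]
        assert np.isnan(by_t.loc[0.4])  # one-sided reference split
        assert selected in (0.05, 0.1)

    def test_all_thresholds_degenerate_raises(self):
        f = np.array([0.01, 0.02, 0.2, 0.3])
        same = [0, 0, 1, 1]
        results = self._results([same, same, same], sils=[0.9, 0.8, 0.7])
        with pytest.raises(DegenerateClusteringError):
            ta.r2_threshold_sweep(results, f, [0.05, 0.1, 0.4])

    def test_too_few_results_rejected(self):
        f = np.array([0.01, 0.2])
        results = self._results([[0, 1]], sils=[0.5])
        with pytest.raises(ConfigError):
            ta.r2_threshold_sweep(results, f, [0.05])


class TestValidateThreshold:
    def _tiny_world(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        from conftest import make_sample

        samples, contrasts = [], {}
        for i in range(n):
            informative = i % 3 != 0
            s = make_sample(
                rng,
                side=32,
                patient_id=f"p{i % 6}",
                slice_index=i,
                lesion_mean=28.0 if informative else 39.5,
            )
            samples.append(s)
            contrasts[s.slice_id] = 0.2 if informative else 0.01
        return samples[: n - 6], samples[n - 6 :], contrasts

    def test_threshold_below_min_gives_identical_runs(self):
        train, test, contrasts = self._tiny_world()
        report = ta.validate_threshold(
            train, test, contrasts, contrasts, threshold=0.001, seeds=[0, 1]
        )
        t = report.table.set_index(["training", "test"])
        for test_name in ("all",):
            full = t.loc[("all", test_name)]
            filt = t.loc[("f_ge_threshold", test_name)]
            for m in ("detection", "dsc", "hd", "raad"):
                assert full[f"{m}_mean"] == filt[f"{m}_mean"]
        assert report.reduction_fraction == 0.0

    def test_reduction_fraction_matches_count_oracle(self):
        train, test, contrasts = self._tiny_world()
        report = ta.validate_threshold(
            train, test, contrasts, contrasts, threshold=0.05, seeds=[0]
        )
        kept = sum(1 for s in train if contrasts[s.slice_id] >= 0.05)
        assert report.reduction_fraction == pytest.approx(1 - kept / len(train))
        assert report.n_train_filtered == kept

    def test_empty_filtered_training_rejected(self):
        train, test, contrasts = self._tiny_world()
        with pytest.raises(EmptyDatasetError):
            ta.validate_threshold(
                train, test, contrasts, contrasts, threshold=99.0, seeds=[0]
            )


class TestBaselineSegmenter:
    def test_learns_a_hypodensity_cutoff(self):
        rng = np.random.default_rng(7)
        from conftest import make_sample

        train = [
            make_sample(rng, slice_index=i, lesion_mean=26.0, background_mean=42.0,
                        sd=1.5)
            for i in range(8)
        ]
        seg = ta.IntensityThresholdSegmenter().fit(train)
        assert 0.0 < seg.cutoff_ < 1.0
        test = make_sample(rng, slice_index=99, lesion_mean=26.0,
                           background_mean=42.0, sd=1.5)
        pred = seg.predict(test)
        from contrast_gate.seg_metrics import evaluate_slice

        ev = evaluate_slice(pred, test.lesion_mask, "t")
        assert ev.dsc > 0.5

    def test_prediction_confined_to_brain(self):
        rng = np.random.default_rng(8)
        from conftest import make_sample

        train = [make_sample(rng, slice_index=i) for i in range(4)]
        seg = ta.IntensityThresholdSegmenter().fit(train)
        pred = seg.predict(train[0])
        assert not np.any(pred & (train[0].brain_mask == 0))
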