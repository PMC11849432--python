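"""Critical-contrast estimation: ROC elbow, clustering sweep, retrain validation.

Three complementary analyses locate the Fisher's-ratio value below which
slices carry no learnable information for the segmentation task:

* **performance binning** — per-contrast-bin metric aggregates and the
  fraction of metric failures concentrated below a query contrast;
* **graphical (ROC) analysis** — pixel-level TPR/FPR aggregated over the
  slices surviving each contrast threshold, with the elbow (point closest to
  the ideal corner after axis normalization) as the estimate;
* **clustering analysis** — 2-cluster k-means (10 restarts) and
  agglomerative clustering under five distances on normalized
  (detection, DSC, HD, RAAD, F) features, scored by silhouette and by purity
  against an F-cutoff reference; sweeping the cutoff and maximizing the R²
  between purities and silhouettes across method×distance combinations gives
  the second estimate.

The estimate is validated by retraining a pluggable segmenter with and
without the sub-threshold slices; a bundled desk-scale intensity-cutoff
baseline makes this runnable in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import label as cc_label
from scipy.spatial.distance import cdist, pdist
from scipy.stats import pearsonr
from sklearn.metrics import silhouette_score

from .contrast import DEFAULT_HIGH_HU, DEFAULT_LOW_HU, window_and_normalize
from .errors import (
    ConfigError,
    DegenerateClusteringError,
    EmptyDatasetError,
    UnpairedEvaluationsError,
)
from .io_manifest import SliceSample
from .seg_metrics import ConfusionCounts, SliceEvaluation, evaluate_slice

# ---------------------------------------------------------------------------
# distances

_SCIPY_METRIC = {
    "euclidean": "euclidean",
    "sq_euclidean": "sqeuclidean",
    "manhattan": "cityblock",
    "chebyshev": "chebyshev",
    "canberra": "canberra",
}
DISTANCES = tuple(_SCIPY_METRIC)

# The method × distance grid scored in the quality table: k-means under all
# five distances, hierarchical under euclidean / squared euclidean / canberra.
DEFAULT_COMBOS: tuple[tuple[str, str], ...] = tuple(
    [("kmeans", d) for d in DISTANCES]
    + [("hierarchical", d) for d in ("euclidean", "sq_euclidean", "canberra")]
)


def default_threshold_grid(
    start: float = 0.005, stop: float = 0.30, step: float = 0.005
) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


# ---------------------------------------------------------------------------
# performance binning


def bin_performance(
    evals: Sequence[SliceEvaluation],
    contrasts: dict[str, float],
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Per-contrast-bin mean/sd of each metric plus failure counts."""
    _require_paired(evals, contrasts)
    edges = np.asarray(bin_edges, dtype=float)
    f = np.array([contrasts[e.slice_id] for e in evals])
    bins = np.clip(np.digitize(f, edges[1:-1]), 0, len(edges) - 2)
    rows = []
    for k in range(len(edges) - 1):
        sub = [e for e, b in zip(evals, bins) if b == k]
        row = {"bin": k, "bin_low": edges[k], "bin_high": edges[k + 1], "n": len(sub)}
        for m in ("detection", "dsc", "hd", "raad"):
            vals = np.array([getattr(e, m) for e in sub], dtype=float)
            row[f"{m}_mean"] = float(vals.mean()) if vals.size else float("nan")
            row[f"{m}_sd"] = float(vals.std()) if vals.size else float("nan")
        row["n_undetected"] = sum(1 for e in sub if e.detection == 0)
        row["n_dsc_fail"] = sum(1 for e in sub if not e.dsc_ok)
        row["n_hd_fail"] = sum(1 for e in sub if not e.hd_ok)
        row["n_raad_fail"] = sum(1 for e in sub if not e.raad_ok)
        rows.append(row)
    return pd.DataFrame(rows)


_FAIL_PREDICATES: dict[str, Callable[[SliceEvaluation], bool]] = {
    "detection": lambda e: e.detection == 0,
    "dsc": lambda e: not e.dsc_ok,
    "hd": lambda e: not e.hd_ok,
    "raad": lambda e: not e.raad_ok,
}


def failure_fraction_below(
    evals: Sequence[SliceEvaluation],
    contrasts: dict[str, float],
    threshold: float,
) -> dict[str, float]:
    """For each metric, the fraction of failing slices whose F < threshold.

    NaN where no slice fails that metric.
    """
    _require_paired(evals, contrasts)
    out = {}
    for m, fails in _FAIL_PREDICATES.items():
        failing = [e for e in evals if fails(e)]
        if not failing:
            out[m] = float("nan")
            continue
        below = sum(1 for e in failing if contrasts[e.slice_id] < threshold)
        out[m] = below / len(failing)
    return out


def _require_paired(evals: Sequence[SliceEvaluation], contrasts: dict[str, float]) -> None:
    missing = {e.slice_id for e in evals} - set(contrasts)
    if missing:
        raise UnpairedEvaluationsError(f"no contrast for: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# ROC sweep and elbow


@dataclass(frozen=True)
class RocPoint:
    contrast_threshold: float
    tpr: float
    fpr: float
    n_slices: int


def roc_sweep(
    confusions: dict[str, ConfusionCounts],
    contrasts: dict[str, float],
    threshold_grid: Sequence[float],
) -> list[RocPoint]:
    """Aggregate pixel-level TPR/FPR over slices with F ≥ t, for each grid t.

    Thresholds that leave no slice are omitted.
    """
    grid = np.asarray(list(threshold_grid), dtype=float)
    if grid.size == 0:
        raise ConfigError("empty threshold grid")
    if np.any(np.diff(grid) < 0):
        raise ConfigError("threshold grid must be sorted ascending")
    missing = set(confusions) - set(contrasts)
    if missing:
        raise UnpairedEvaluationsError(f"no contrast for: {sorted(missing)[:5]}")
    ids = sorted(confusions)
    f = np.array([contrasts[i] for i in ids])
    points: list[RocPoint] = []
    for t in grid:
        keep = [i for i, fi in zip(ids, f) if fi >= t]
        if not keep:
            continue
        agg = ConfusionCounts(0, 0, 0, 0)
        for i in keep:
            agg = agg + confusions[i]
        tpr = agg.tp / (agg.tp + agg.fn) if (agg.tp + agg.fn) else float("nan")
        fpr = agg.fp / (agg.fp + agg.tn) if (agg.fp + agg.tn) else float("nan")
        points.append(RocPoint(float(t), float(tpr), float(fpr), len(keep)))
    return points


def elbow_threshold(sweep: Sequence[RocPoint]) -> float:
    """Threshold of the sweep point closest to the ideal (FPR 0, TPR 1) corner.

    Both axes are min-max normalized over the sweep first (the FPR axis is
    far more compressed than the TPR axis, so raw distance would be
    degenerate); a constant axis contributes zero.  Ties go to the smaller
    threshold.
    """
    if len(sweep) == 0:
        raise EmptyDatasetError("empty ROC sweep")
    tpr = np.array([p.tpr for p in sweep])
    fpr = np.array([p.fpr for p in sweep])
    thr = np.array([p.contrast_threshold for p in sweep])

    def _norm(x: np.ndarray) -> np.ndarray:
        span = x.max() - x.min()
        return (x - x.min()) / span if span > 0 else np.zeros_like(x)

    d = np.hypot(_norm(fpr) - 0.0, _norm(tpr) - 1.0)
    order = np.lexsort((thr, d))  # min distance, then min threshold
    return float(thr[order[0]])


def crop_sweep(
    sweep: Sequence[RocPoint],
    fpr_max: float | None = None,
    tpr_min: float | None = None,
) -> list[RocPoint]:
    """Optional ROC crop before elbow search (full curve is the default)."""
    out = [
        p
        for p in sweep
        if (fpr_max is None or p.fpr <= fpr_max)
        and (tpr_min is None or p.tpr >= tpr_min)
    ]
    return out


# ---------------------------------------------------------------------------
# clustering

FEATURE_NAMES = ("detection", "dsc", "hd", "raad", "fisher")


def build_feature_matrix(
    evals: Sequence[SliceEvaluation],
    contrasts: dict[str, float],
    include_detection: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Per-slice (detection, dsc, hd, raad, F) matrix, min-max normalized
    per feature.  A constant feature maps to all-zeros."""
    _require_paired(evals, contrasts)
    ids = [e.slice_id for e in evals]
    cols = {
        "detection": [float(e.detection) for e in evals],
        "dsc": [e.dsc for e in evals],
        "hd": [e.hd for e in evals],
        "raad": [e.raad for e in evals],
        "fisher": [contrasts[e.slice_id] for e in evals],
    }
    names = [n for n in FEATURE_NAMES if include_detection or n != "detection"]
    X = np.column_stack([np.asarray(cols[n], dtype=float) for n in names])
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    X = (X - X.min(axis=0)) / span
    return X, ids


@dataclass
class ClusterResult:
    algorithm: str
    distance: str
    labels: np.ndarray
    centroids: np.ndarray
    silhouette: float
    seed: int
    slice_ids: list[str] = field(default_factory=list)
    inertia: float = float("nan")


def _pair_dist(X: np.ndarray, C: np.ndarray, distance: str) -> np.ndarray:
    return cdist(X, C, metric=_SCIPY_METRIC[distance])


def _kmeans_once(
    X: np.ndarray, distance: str, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    idx = rng.choice(n, size=2, replace=False)
    while np.array_equal(X[idx[0]], X[idx[1]]):
        idx = rng.choice(n, size=2, replace=False)
    centroids = X[idx].astype(float).copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d = _pair_dist(X, centroids, distance)
        new_labels = np.argmin(d, axis=1)  # ties -> lower cluster index
        for k in range(2):
            if not np.any(new_labels == k):  # re-seed an emptied cluster
                far = np.argmax(d[np.arange(n), new_labels])
                new_labels[far] = k
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for k in range(2):
            centroids[k] = X[labels == k].mean(axis=0)
    inertia = float(_pair_dist(X, centroids, distance)[np.arange(n), labels].sum())
    return labels, centroids, inertia


def cluster_slices(
    features: np.ndarray,
    algorithm: str = "kmeans",
    distance: str = "euclidean",
    restarts: int = 10,
    seed: int = 0,
    slice_ids: Sequence[str] | None = None,
    linkage_method: str = "average",
) -> ClusterResult:
    """Two-cluster partition of the normalized feature matrix.

    k-means keeps component-wise mean centroids and uses the chosen distance
    for assignment; the best of ``restarts`` seeded runs by within-cluster
    distance sum is returned.  Hierarchical clustering is agglomerative with
    ``linkage_method`` linkage under the chosen distance, cut at two clusters.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise EmptyDatasetError("need at least 2 slices to cluster")
    if distance not in _SCIPY_METRIC:
        raise ConfigError(f"unsupported distance {distance!r}")
    if np.all(X == X[0]):
        raise DegenerateClusteringError("all feature vectors identical")

    if algorithm == "kmeans":
        best: tuple[np.ndarray, np.ndarray, float] | None = None
        for r in range(restarts):
            rng = np.random.default_rng([seed, r])
            labels, centroids, inertia = _kmeans_once(X, distance, rng)
            if best is None or inertia < best[2]:
                best = (labels, centroids, inertia)
        labels, centroids, inertia = best
    elif algorithm == "hierarchical":
        Z = linkage(pdist(X, metric=_SCIPY_METRIC[distance]), method=linkage_method)
        labels = fcluster(Z, t=2, criterion="maxclust") - 1
        if len(set(labels)) < 2:
            raise DegenerateClusteringError("hierarchical cut produced one cluster")
        centroids = np.vstack([X[labels == k].mean(axis=0) for k in range(2)])
        inertia = float(
            _pair_dist(X, centroids, distance)[np.arange(X.shape[0]), labels].sum()
        )
    else:
        raise ConfigError(f"unknown algorithm {algorithm!r}")

    sil = float(silhouette_score(X, labels, metric=_SCIPY_METRIC[distance]))
    return ClusterResult(
        algorithm=algorithm,
        distance=distance,
        labels=np.asarray(labels, dtype=int),
        centroids=centroids,
        silhouette=sil,
        seed=seed,
        slice_ids=list(slice_ids) if slice_ids is not None else [],
        inertia=inertia,
    )


def cluster_quality(
    result: ClusterResult,
    contrasts: np.ndarray,
    purity_threshold: float,
) -> tuple[float, float]:
    """(purity, silhouette) of a 2-cluster result against an F-cutoff reference.

    Reference labels are F < threshold vs F ≥ threshold; purity is the
    accuracy of the better of the two cluster↔label assignments.  Purity is
    NaN when one reference class is empty (reported, not raised).
    """
    f = np.asarray(contrasts, dtype=float)
    if f.shape[0] != result.labels.shape[0]:
        raise UnpairedEvaluationsError("contrasts and labels differ in length")
    ref = (f >= purity_threshold).astype(int)
    if len(set(ref)) < 2:
        return float("nan"), result.silhouette
    acc = float(np.mean(result.labels == ref))
    purity = max(acc, 1.0 - acc)
    return purity, result.silhouette


def run_cluster_battery(
    features: np.ndarray,
    seed: int = 0,
    restarts: int = 10,
    combos: Sequence[tuple[str, str]] = DEFAULT_COMBOS,
    slice_ids: Sequence[str] | None = None,
) -> list[ClusterResult]:
    return [
        cluster_slices(
            features, algorithm=a, distance=d, restarts=restarts, seed=seed,
            slice_ids=slice_ids,
        )
        for a, d in combos
    ]


def purity_table(
    results: Sequence[ClusterResult],
    contrasts: np.ndarray,
    purity_threshold: float,
) -> pd.DataFrame:
    rows = []
    for r in results:
        purity, sil = cluster_quality(r, contrasts, purity_threshold)
        rows.append(
            {
                "algorithm": r.algorithm,
                "distance": r.distance,
                "silhouette": sil,
                "purity": purity,
                "threshold": purity_threshold,
            }
        )
    return pd.DataFrame(rows)


def r2_threshold_sweep(
    cluster_results: Sequence[ClusterResult],
    contrasts: np.ndarray,
    threshold_grid: Sequence[float],
) -> tuple[pd.DataFrame, float]:
    """Sweep the purity cutoff; pick the one whose purities best correlate
    with silhouettes (max squared Pearson R across combinations).

    Thresholds where purity or silhouette has zero variance across
    combinations (or purity is undefined) get NaN and are excluded from the
    argmax; ties go to the smaller threshold.
    """
    if len(cluster_results) < 3:
        raise ConfigError("need at least 3 cluster results for the R² sweep")
    grid = np.asarray(list(threshold_grid), dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ConfigError("threshold grid must be sorted ascending")
    sils = np.array([r.silhouette for r in cluster_results])
    rows = []
    for t in grid:
        purities = np.array(
            [cluster_quality(r, contrasts, t)[0] for r in cluster_results]
        )
        if np.isnan(purities).any() or np.std(purities) == 0 or np.std(sils) == 0:
            rows.append({"threshold": float(t), "r2": float("nan")})
            continue
        r, _ = pearsonr(purities, sils)
        rows.append({"threshold": float(t), "r2": float(r * r)})
    curve = pd.DataFrame(rows)
    valid = curve.dropna(subset=["r2"])
    if valid.empty:
        raise DegenerateClusteringError("R² undefined on the whole grid")
    best = valid.loc[valid["r2"].idxmax()]  # idxmax returns the first maximum
    return curve, float(best["threshold"])


# ---------------------------------------------------------------------------
# validation by retraining


class IntensityThresholdSegmenter:
    """Desk-scale trainable baseline: a global normalized-intensity cutoff.

    The prediction rule is "lesion = largest connected component
    (8-connectivity) of the retained pixels at or below the cutoff" — the
    lesion is hypodense.  ``fit`` picks, over a 64-point grid, the cutoff on
    windowed [0, 1]-normalized intensity that maximizes the mean training
    DSC of that same rule, so slices whose lesion is indistinguishable from
    background contribute essentially no preference to the fit (their
    largest sub-cutoff component is a noise cluster wherever the cutoff
    sits).  Training takes seconds on a few hundred slices.
    """

    def __init__(
        self,
        n_grid: int = 64,
        seed: int = 0,
        low_hu: float = DEFAULT_LOW_HU,
        high_hu: float = DEFAULT_HIGH_HU,
    ) -> None:
        self.n_grid = n_grid
        self.seed = seed
        self.low_hu = low_hu
        self.high_hu = high_hu
        self.cutoff_: float | None = None

    def _normalized(self, sample: SliceSample) -> tuple[np.ndarray, np.ndarray]:
        return window_and_normalize(
            sample.image, sample.brain_mask, self.low_hu, self.high_hu
        )

    def fit(self, samples: Sequence[SliceSample]) -> "IntensityThresholdSegmenter":
        if len(samples) == 0:
            raise EmptyDatasetError("cannot fit on an empty training set")
        cutoffs = np.linspace(0.0, 1.0, self.n_grid)
        structure = np.ones((3, 3), dtype=int)
        total = np.zeros(self.n_grid)
        for s in samples:
            norm, retained = self._normalized(s)
            ret = retained > 0
            gt = s.lesion_mask > 0
            g = float(gt.sum())
            prev_count = -1
            dsc_j = 0.0
            for j, c in enumerate(cutoffs):
                cand = ret & (norm <= c)
                count = int(cand.sum())
                if count != prev_count:  # otherwise the mask is unchanged
                    prev_count = count
                    if count == 0:
                        dsc_j = 0.0
                    else:
                        lab, _ = cc_label(cand, structure=structure)
                        sizes = np.bincount(lab.ravel())[1:]
                        keep = int(np.argmax(sizes)) + 1
                        pred = lab == keep
                        tp = float(np.sum(pred & gt))
                        dsc_j = 2.0 * tp / (pred.sum() + g)
                total[j] += dsc_j
        best = int(np.argmax(total))  # argmax ties -> smaller cutoff
        self.cutoff_ = float(cutoffs[best])
        return self

    def predict(self, sample: SliceSample) -> np.ndarray:
        if self.cutoff_ is None:
            raise ConfigError("segmenter is not fitted")
        norm, retained = self._normalized(sample)
        cand = (retained > 0) & (norm <= self.cutoff_)
        if not cand.any():
            return np.zeros_like(sample.lesion_mask)
        lab, n = cc_label(cand, structure=np.ones((3, 3), dtype=int))
        sizes = np.bincount(lab.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        return (lab == keep).astype(np.uint8)


@dataclass
class ValidationReport:
    table: pd.DataFrame
    reduction_fraction: float
    n_train_full: int
    n_train_filtered: int


def _evaluate_on(
    segmenter, samples: Sequence[SliceSample]
) -> list[SliceEvaluation]:
    return [
        evaluate_slice(segmenter.predict(s), s.lesion_mask, slice_id=s.slice_id)
        for s in samples
    ]


def _metric_means(evals: Sequence[SliceEvaluation]) -> dict[str, float]:
    return {
        m: float(np.mean([getattr(e, m) for e in evals]))
        for m in ("detection", "dsc", "hd", "raad")
    }


def validate_threshold(
    train_samples: Sequence[SliceSample],
    test_samples: Sequence[SliceSample],
    train_contrasts: dict[str, float],
    test_contrasts: dict[str, float],
    threshold: float,
    segmenter_factory: Callable[[int], object] | None = None,
    seeds: Sequence[int] = (0, 1, 2),
) -> ValidationReport:
    """Retrain with vs without sub-threshold slices and compare on a fixed test set.

    Both segmenters are evaluated on the full test set and on its F ≥ threshold
    subset; the table reports per-metric mean ± sd across seeds, and the
    report carries the training-set size reduction.
    """
    if segmenter_factory is None:
        segmenter_factory = lambda seed: IntensityThresholdSegmenter(seed=seed)
    filtered = [
        s for s in train_samples if train_contrasts[s.slice_id] >= threshold
    ]
    if not filtered:
        raise EmptyDatasetError(f"no training slices with F >= {threshold}")
    test_high = [s for s in test_samples if test_contrasts[s.slice_id] >= threshold]
    test_sets = {"all": list(test_samples)}
    if test_high:
        test_sets["f_ge_threshold"] = test_high

    per_seed: dict[tuple[str, str], list[dict[str, float]]] = {}
    for seed in seeds:
        for train_name, train_set in (("all", list(train_samples)), ("f_ge_threshold", filtered)):
            seg = segmenter_factory(seed)
            seg.fit(train_set)
            for test_name, test_set in test_sets.items():
                evals = _evaluate_on(seg, test_set)
                per_seed.setdefault((train_name, test_name), []).append(
                    _metric_means(evals)
                )
    rows = []
    for (train_name, test_name), runs in per_seed.items():
        row = {
            "training": train_name,
            "test": test_name,
            "n_train": len(train_samples) if train_name == "all" else len(filtered),
            "n_test": len(test_sets[test_name]),
            "n_seeds": len(runs),
        }
        for m in ("detection", "dsc", "hd", "raad"):
            vals = np.array([r[m] for r in runs])
            row[f"{m}_mean"] = float(vals.mean())
            row[f"{m}_sd"] = float(vals.std())
        rows.append(row)
    reduction = 1.0 - len(filtered) / len(train_samples)
    return ValidationReport(
        table=pd.DataFrame(rows),
        reduction_fraction=float(reduction),
        n_train_full=len(train_samples),
        n_train_filtered=len(filtered),
    )
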