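"""Per-slice segmentation evaluation and paired model comparison.

Four metrics against a reference lesion mask:

* detection — 1 iff the prediction overlaps the reference by ≥ 1 pixel;
* DSC       — 2·TP / (FN + FP + 2·TP), unacceptable below 0.1;
* HD        — exact symmetric Hausdorff distance between foreground pixel
              sets (Euclidean, in pixels), unacceptable above 60; an empty
              prediction is assigned the 60-pixel cap and flagged degenerate;
* RAAD      — signed relative area difference ((TP+FP) − (TP+FN)) / (TP+FN),
              unacceptable outside ±0.5 (negative = underestimation).

Also provides the Dice+BCE training loss and per-contrast-bin one-tailed
Wilcoxon signed-rank comparison of two models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import wilcoxon as _scipy_wilcoxon

from .errors import (
    DimensionMismatchError,
    EmptyLesionError,
    EmptyMaskPairError,
    UnpairedEvaluationsError,
)

DSC_MIN_OK = 0.1
HD_CAP_PX = 60.0
RAAD_MAX_ABS_OK = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion partition of one slice."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass(frozen=True)
class SliceEvaluation:
    slice_id: str
    detection: int
    dsc: float
    hd: float
    raad: float
    dsc_ok: bool
    hd_ok: bool
    raad_ok: bool
    hd_degenerate: bool = False


def _binary(a: np.ndarray) -> np.ndarray:
    return np.asarray(a) > 0.5


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    p, g = _binary(pred), _binary(gt)
    if p.shape != g.shape:
        raise DimensionMismatchError(f"pred {p.shape} vs gt {g.shape}")
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def detection(pred: np.ndarray, gt: np.ndarray) -> int:
    """1 iff the prediction shares at least one pixel with the reference lesion."""
    p, g = _binary(pred), _binary(gt)
    if p.shape != g.shape:
        raise DimensionMismatchError(f"pred {p.shape} vs gt {g.shape}")
    if not g.any():
        raise EmptyLesionError("ground truth has no lesion (removed in preprocessing)")
    return int(np.any(p & g))


def dice(counts: ConfusionCounts) -> float:
    denom = counts.fn + counts.fp + 2 * counts.tp
    if denom == 0:
        raise EmptyMaskPairError("DSC undefined: both masks empty")
    return 2.0 * counts.tp / denom


def hausdorff(pred: np.ndarray, gt: np.ndarray, cap: float = HD_CAP_PX) -> float:
    """Exact symmetric Hausdorff distance over all foreground pixels.

    An empty prediction returns ``cap`` (the unacceptability penalty); use
    :func:`evaluate_slice` to also get the degenerate flag.  Values above
    ``cap`` are returned as computed.
    """
    p, g = _binary(pred), _binary(gt)
    if p.shape != g.shape:
        raise DimensionMismatchError(f"pred {p.shape} vs gt {g.shape}")
    if not g.any():
        raise EmptyLesionError("ground truth has no lesion")
    if not p.any():
        return float(cap)
    a = np.argwhere(p).astype(float)
    b = np.argwhere(g).astype(float)
    return float(max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0]))


def raad(counts: ConfusionCounts) -> float:
    area_gt = counts.tp + counts.fn
    if area_gt == 0:
        raise EmptyLesionError("ground truth has no lesion")
    return ((counts.tp + counts.fp) - area_gt) / area_gt


def evaluate_slice(
    pred: np.ndarray,
    gt: np.ndarray,
    slice_id: str = "",
    dsc_min: float = DSC_MIN_OK,
    hd_cap: float = HD_CAP_PX,
    raad_max_abs: float = RAAD_MAX_ABS_OK,
) -> SliceEvaluation:
    """All four metrics plus acceptability flags for one prediction."""
    c = confusion_counts(pred, gt)
    det = detection(pred, gt)
    d = dice(c)
    empty_pred = (c.tp + c.fp) == 0
    hd = hausdorff(pred, gt, cap=hd_cap)
    r = raad(c)
    return SliceEvaluation(
        slice_id=slice_id,
        detection=det,
        dsc=d,
        hd=hd,
        raad=r,
        dsc_ok=d >= dsc_min,
        hd_ok=hd <= hd_cap,
        raad_ok=abs(r) <= raad_max_abs,
        hd_degenerate=empty_pred,
    )


def evaluations_frame(evals: Sequence[SliceEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "slice_id": [e.slice_id for e in evals],
            "detection": [e.detection for e in evals],
            "dsc": [e.dsc for e in evals],
            "hd": [e.hd for e in evals],
            "raad": [e.raad for e in evals],
            "dsc_ok": [e.dsc_ok for e in evals],
            "hd_ok": [e.hd_ok for e in evals],
            "raad_ok": [e.raad_ok for e in evals],
            "hd_degenerate": [e.hd_degenerate for e in evals],
        }
    )


def combined_loss(y: np.ndarray, p: np.ndarray, epsilon: float = 1e-7) -> float:
    """Training loss: (1 − soft Dice) + binary cross-entropy (mean per pixel).

    softDice = 2·Σ(y·p) / (Σy + Σp); predictions are clipped to
    [epsilon, 1 − epsilon] before the logs.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape:
        raise DimensionMismatchError(f"y {y.shape} vs p {p.shape}")
    if not np.all(np.isfinite(p)):
        raise DimensionMismatchError("prediction contains non-finite values")
    denom = y.sum() + p.sum()  # raw prediction mass; clipping is only for the logs
    soft_dice = 2.0 * float((y * p).sum()) / float(denom) if denom > 0 else 1.0
    p = np.clip(p, epsilon, 1.0 - epsilon)
    bce = float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))
    return (1.0 - soft_dice) + bce


# Orientation of "model A outperforms model B" per metric: the oriented paired
# difference is positive when A is better on that slice.
_METRIC_DIFFS = {
    "detection": lambda a, b: a.detection - b.detection,
    "dsc": lambda a, b: a.dsc - b.dsc,
    "hd": lambda a, b: b.hd - a.hd,
    "raad": lambda a, b: abs(b.raad) - abs(a.raad),
}


def wilcoxon_one_sided(diffs: np.ndarray, exact_max_n: int = 25) -> float:
    """One-sided signed-rank p-value (alternative: differences > 0).

    Zero differences are dropped; exact null for small n, normal
    approximation otherwise.  Returns NaN when no nonzero difference remains.
    """
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return float("nan")
    method = "exact" if diffs.size <= exact_max_n else "approx"
    res = _scipy_wilcoxon(
        diffs, zero_method="wilcox", alternative="greater", method=method
    )
    return float(res.pvalue)


def wilcoxon_bin_compare(
    evals_a: Sequence[SliceEvaluation],
    evals_b: Sequence[SliceEvaluation],
    contrasts: dict[str, float],
    bin_edges: Sequence[float],
    metrics: Sequence[str] = ("detection", "dsc", "hd", "raad"),
) -> pd.DataFrame:
    """Per-contrast-bin one-tailed Wilcoxon tests that model A beats model B.

    Inputs are paired by slice reference; a bin without a nonzero paired
    difference yields a NaN p-value (reported, not raised).
    """
    by_a = {e.slice_id: e for e in evals_a}
    by_b = {e.slice_id: e for e in evals_b}
    if set(by_a) != set(by_b) or len(by_a) != len(evals_a) or len(by_b) != len(evals_b):
        raise UnpairedEvaluationsError("evaluations cannot be paired by slice_id")
    missing = set(by_a) - set(contrasts)
    if missing:
        raise UnpairedEvaluationsError(f"no contrast for slices: {sorted(missing)[:5]}")
    edges = np.asarray(bin_edges, dtype=float)
    ids = sorted(by_a)
    f = np.array([contrasts[i] for i in ids])
    bins = np.clip(np.digitize(f, edges[1:-1]), 0, len(edges) - 2)
    rows = []
    for k in range(len(edges) - 1):
        members = [i for i, b in zip(ids, bins) if b == k]
        for m in metrics:
            diffs = np.array([_METRIC_DIFFS[m](by_a[i], by_b[i]) for i in members])
            rows.append(
                {
                    "bin": k,
                    "bin_low": edges[k],
                    "bin_high": edges[k + 1],
                    "metric": m,
                    "n_pairs": len(members),
                    "n_nonzero": int(np.sum(diffs != 0)) if len(members) else 0,
                    "p_value": wilcoxon_one_sided(diffs) if len(members) else float("nan"),
                }
            )
    return pd.DataFrame(rows)
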