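"""Fisher's-ratio lesion contrast after HU windowing and per-slice normalization.

The contrast score of a slice is

    F = (mu_lesion - mu_background)^2 / (sigma^2_lesion + sigma^2_background)

computed on [0, 1]-normalized intensities of the pixels surviving the HU
window [low_hu, high_hu] (skull, CSF and calcifications discarded), with the
background taken as healthy tissue in the hemisphere ipsilateral to the
lesion.  F is invariant under any shared affine intensity map, so the
per-slice min-max normalization does not change it; variances use the
population convention (divisor N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateContrastError,
    DegenerateSliceError,
    EmptyBackgroundError,
    EmptyLesionError,
)
from .io_manifest import SliceSample
from .preprocessing import lesion_centroid_column

DEFAULT_LOW_HU = 15.0
DEFAULT_HIGH_HU = 80.0


@dataclass(frozen=True)
class RegionStats:
    """Mean, population variance and pixel count of one intensity region."""

    mean: float
    variance: float
    pixel_count: int

    def __post_init__(self) -> None:
        if self.pixel_count < 0 or self.variance < -1e-12:
            raise DegenerateContrastError(
                f"invalid region stats: n={self.pixel_count}, var={self.variance}"
            )


@dataclass(frozen=True)
class ContrastRecord:
    slice_id: str
    fisher: float
    lesion_stats: RegionStats
    background_stats: RegionStats
    retained_fraction: float


def region_stats(values: np.ndarray) -> RegionStats:
    values = np.asarray(values, dtype=np.float64).ravel()
    n = values.size
    if n == 0:
        return RegionStats(mean=float("nan"), variance=0.0, pixel_count=0)
    return RegionStats(
        mean=float(values.mean()), variance=float(values.var()), pixel_count=int(n)
    )


def window_and_normalize(
    image: np.ndarray,
    brain_mask: np.ndarray,
    low_hu: float = DEFAULT_LOW_HU,
    high_hu: float = DEFAULT_HIGH_HU,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the HU window inside the brain and min-max map survivors to [0, 1].

    Returns (normalized image with NaN outside the retained set, retained
    mask).  Bounds are inclusive: values of exactly ``low_hu``/``high_hu``
    survive and map to 0/1.
    """
    image = np.asarray(image, dtype=np.float64)
    brain = np.asarray(brain_mask) > 0
    if not brain.any():
        raise DegenerateSliceError("brain mask is empty")
    retained = brain & np.isfinite(image) & (image >= low_hu) & (image <= high_hu)
    if not retained.any():
        raise DegenerateSliceError("no brain pixels survive the HU window")
    vals = image[retained]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax - vmin <= 0:
        raise DegenerateSliceError("retained intensities are constant (min = max)")
    norm = np.full(image.shape, np.nan)
    norm[retained] = (image[retained] - vmin) / (vmax - vmin)
    return norm, retained.astype(np.uint8)


def ipsilateral_background(
    brain_mask: np.ndarray, lesion_mask: np.ndarray, retained_mask: np.ndarray
) -> np.ndarray:
    """Healthy-tissue mask: retained pixels in the lesion's hemisphere, minus lesion.

    The hemisphere is the side of the vertical midline containing the
    lesion-mask centroid column.
    """
    lesion = np.asarray(lesion_mask) > 0
    if not lesion.any():
        raise EmptyLesionError("lesion mask is empty")
    retained = np.asarray(retained_mask) > 0
    w = lesion.shape[1]
    col = lesion_centroid_column(lesion.astype(np.uint8))
    cols = np.arange(w)
    hemi = cols < w / 2.0 if col < w / 2.0 else cols >= w / 2.0
    background = retained & hemi[np.newaxis, :] & ~lesion
    if not background.any():
        raise EmptyBackgroundError("no retained healthy tissue in the lesion hemisphere")
    return background.astype(np.uint8)


def fisher_ratio(object_stats: RegionStats, background_stats: RegionStats) -> float:
    """F = (mu_obj - mu_bg)^2 / (var_obj + var_bg); symmetric in its arguments."""
    for name, st in (("object", object_stats), ("background", background_stats)):
        if st.pixel_count < 2:
            raise DegenerateContrastError(
                f"{name} region has {st.pixel_count} pixels; need at least 2"
            )
    denom = object_stats.variance + background_stats.variance
    if denom <= 0:
        raise DegenerateContrastError("zero variance sum: both regions constant")
    return float((object_stats.mean - background_stats.mean) ** 2 / denom)


def score_slice(
    sample: SliceSample,
    low_hu: float = DEFAULT_LOW_HU,
    high_hu: float = DEFAULT_HIGH_HU,
) -> ContrastRecord:
    """Window, normalize and score one slice's lesion contrast."""
    norm, retained = window_and_normalize(sample.image, sample.brain_mask, low_hu, high_hu)
    background = ipsilateral_background(sample.brain_mask, sample.lesion_mask, retained)
    lesion_retained = (retained > 0) & (sample.lesion_mask > 0)
    lesion_stats = region_stats(norm[lesion_retained])
    background_stats = region_stats(norm[background > 0])
    f = fisher_ratio(lesion_stats, background_stats)
    brain_n = int((sample.brain_mask > 0).sum())
    return ContrastRecord(
        slice_id=sample.slice_id,
        fisher=f,
        lesion_stats=lesion_stats,
        background_stats=background_stats,
        retained_fraction=float(retained.sum()) / brain_n,
    )


def contrast_profile(
    samples: Sequence[SliceSample],
    low_hu: float = DEFAULT_LOW_HU,
    high_hu: float = DEFAULT_HIGH_HU,
    bins: int = 20,
    bin_range: tuple[float, float] | None = None,
) -> tuple[list[ContrastRecord], list[tuple[str, str]], tuple[np.ndarray, np.ndarray]]:
    """Score every slice; degenerate slices are reported, never raised.

    Returns (records, degenerates as (slice_id, reason), histogram as
    (bin_edges, counts) over the scored Fisher ratios).
    """
    records: list[ContrastRecord] = []
    degenerates: list[tuple[str, str]] = []
    for s in samples:
        try:
            records.append(score_slice(s, low_hu, high_hu))
        except (DegenerateSliceError, DegenerateContrastError,
                EmptyLesionError, EmptyBackgroundError) as exc:
            degenerates.append((s.slice_id, f"{type(exc).__name__}: {exc}"))
    fs = np.array([r.fisher for r in records], dtype=float)
    if fs.size:
        counts, edges = np.histogram(fs, bins=bins, range=bin_range)
    else:
        edges = np.linspace(0.0, 1.0, bins + 1)
        counts = np.zeros(bins, dtype=int)
    return records, degenerates, (edges, counts)
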