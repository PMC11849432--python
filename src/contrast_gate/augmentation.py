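"""Contrast-targeted intensity augmentation with Fisher-guided acceptance.

Two intensity-only transforms of the lesion, designed to enrich the
under-represented mid/high-contrast range without geometric changes:

1. *darkening* — the lesion interior is lowered by a fixed HU step over
   cumulative rounds while the one-pixel border ring (8-adjacency) keeps its
   original values, avoiding a sharp step at the lesion edge;
2. *homogenization* — for lesions noisier than the healthy tissue, pixels
   below/above the lesion HU median are pulled toward it by a fixed amount.

Candidates are then gated on their recomputed Fisher ratio: only those whose
contrast stays inside the range observed in the original dataset (and above a
configurable floor, since very low contrast is already over-represented) are
kept.  Masks are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

from .contrast import DEFAULT_HIGH_HU, DEFAULT_LOW_HU, ContrastRecord, score_slice
from .errors import ConfigError, EmptyDatasetError, EmptyLesionError
from .io_manifest import SliceSample

_RING_STRUCTURE = np.ones((3, 3), dtype=bool)  # 8-adjacency


def lesion_interior(lesion_mask: np.ndarray) -> np.ndarray:
    """Lesion pixels none of whose 8-neighbours are outside the lesion."""
    lesion = np.asarray(lesion_mask) > 0
    return binary_erosion(lesion, structure=_RING_STRUCTURE, border_value=0)


def darken_lesion(
    sample: SliceSample, step_hu: float = 2.0, rounds: int = 3
) -> list[SliceSample]:
    """Cumulative interior darkening: round k lowers the interior by k·step_hu.

    The border ring and everything outside the lesion are untouched in every
    round.  A lesion with no interior yields an empty list (nothing to
    augment, reported by the caller).
    """
    if step_hu <= 0 or rounds < 0:
        raise ConfigError(f"step_hu must be > 0 and rounds >= 0, got {step_hu}, {rounds}")
    if sample.lesion_mask.sum() == 0:
        raise EmptyLesionError("cannot darken an empty lesion")
    interior = lesion_interior(sample.lesion_mask)
    if not interior.any():
        return []
    out = []
    for k in range(1, rounds + 1):
        s = sample.copy()
        s.image[interior] -= k * step_hu
        s.variant = f"{sample.variant}+dark{k}" if sample.variant else f"dark{k}"
        out.append(s)
    return out


def homogenize_lesion(
    sample: SliceSample, delta_hu: float = 2.0
) -> tuple[SliceSample, bool]:
    """Pull off-median lesion pixels toward the lesion HU median by delta_hu.

    Applied only when the lesion's HU standard deviation exceeds that of the
    healthy tissue (brain minus lesion); otherwise the input is returned
    unchanged with ``applied=False``.  Median-valued pixels are untouched.
    """
    if delta_hu <= 0:
        raise ConfigError(f"delta_hu must be > 0, got {delta_hu}")
    lesion = sample.lesion_mask > 0
    if not lesion.any():
        raise EmptyLesionError("cannot homogenize an empty lesion")
    healthy = (sample.brain_mask > 0) & ~lesion
    lesion_sd = float(sample.image[lesion].std())
    healthy_sd = float(sample.image[healthy].std()) if healthy.any() else 0.0
    if lesion_sd <= healthy_sd:
        return sample.copy(), False
    med = float(np.median(sample.image[lesion]))
    s = sample.copy()
    below = lesion & (sample.image < med)
    above = lesion & (sample.image > med)
    s.image[below] += delta_hu
    s.image[above] -= delta_hu
    s.variant = f"{sample.variant}+homog" if sample.variant else "homog"
    return s, True


@dataclass
class AugmentationReport:
    """Per-slice candidate accounting plus the acceptance band used."""

    table: pd.DataFrame
    accept_min_f: float
    accept_max_f: float


def augment_dataset(
    samples: Sequence[SliceSample],
    contrast_records: Sequence[ContrastRecord],
    accept_min_f: float | None = None,
    accept_max_f: float | None = None,
    floor_quantile: float = 0.5,
    rounds: int = 3,
    step_hu: float = 2.0,
    delta_hu: float = 2.0,
    compose: bool = True,
    low_hu: float = DEFAULT_LOW_HU,
    high_hu: float = DEFAULT_HIGH_HU,
) -> tuple[list[SliceSample], AugmentationReport]:
    """Generate and gate augmentation candidates for a training set.

    For each slice the candidates are the darkening rounds, the homogenized
    original, and (if ``compose``) each darkening round followed by
    homogenization — darkening first, matching the two-step order of the
    procedure.  Every candidate's Fisher ratio is recomputed through the
    contrast module and only candidates inside
    ``[accept_min_f, accept_max_f]`` survive.  Defaults: the ceiling is the
    maximum observed F, the floor the ``floor_quantile`` of the observed F
    distribution (median by default).  Originals are always kept.
    """
    if len(samples) == 0:
        raise EmptyDatasetError("cannot augment an empty dataset")
    fs = np.array([r.fisher for r in contrast_records], dtype=float)
    if fs.size == 0:
        raise EmptyDatasetError("no contrast records supplied")
    if accept_max_f is None:
        accept_max_f = float(fs.max())
    if accept_min_f is None:
        accept_min_f = float(np.quantile(fs, floor_quantile))
    if not accept_min_f < accept_max_f:
        raise ConfigError(
            f"acceptance band empty: [{accept_min_f}, {accept_max_f}]"
        )

    out: list[SliceSample] = []
    rows = []
    for s in samples:
        out.append(s)
        candidates: list[SliceSample] = []
        darkened = darken_lesion(s, step_hu=step_hu, rounds=rounds)
        candidates.extend(darkened)
        homog, applied = homogenize_lesion(s, delta_hu=delta_hu)
        if applied:
            candidates.append(homog)
        if compose:
            for d in darkened:
                dh, dh_applied = homogenize_lesion(d, delta_hu=delta_hu)
                if dh_applied:
                    candidates.append(dh)
        kept = 0
        rejected_low = rejected_high = degenerate = 0
        for c in candidates:
            try:
                f = score_slice(c, low_hu, high_hu).fisher
            except Exception:
                degenerate += 1
                continue
            if f < accept_min_f:
                rejected_low += 1
            elif f > accept_max_f:
                rejected_high += 1
            else:
                kept += 1
                out.append(c)
        rows.append(
            {
                "slice_id": s.slice_id,
                "no_interior": len(darkened) == 0,
                "generated": len(candidates),
                "kept": kept,
                "rejected_low_f": rejected_low,
                "rejected_high_f": rejected_high,
                "degenerate": degenerate,
            }
        )
    report = AugmentationReport(pd.DataFrame(rows), accept_min_f, accept_max_f)
    return out, report


def imbalance_share(fisher_values: Sequence[float], bins: int = 20) -> float:
    """Share of mass in the fullest histogram bin — the skew statistic used to
    check that augmentation reduces the low-contrast dominance."""
    fs = np.asarray(list(fisher_values), dtype=float)
    counts, _ = np.histogram(fs, bins=bins)
    return float(counts.max()) / float(counts.sum())
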