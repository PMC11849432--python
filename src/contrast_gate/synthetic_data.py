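"""CT-like brain phantoms with planted lesion contrast, plus a surrogate segmenter.

The phantom is an elliptical "brain" of Gaussian tissue intensities (HU) with
a connected hypodense lesion blob placed in one hemisphere.  The lesion mean
deficit δ is solved from the Fisher formula in expectation,
δ = sqrt(target_F · 2σ²), and the sampled noise is standardized region-wise
so the ratio *measured through the real contrast module* matches the target
almost exactly.  Default F targets follow a right-skewed exponential law, so
most slices are low-contrast.

The surrogate segmenter imposes a known performance-vs-contrast law — a
sigmoid quality cliff at a planted critical contrast c* — by perturbing the
true lesion mask (erosion + translation) until the measured DSC hits the
target quality.  It is the ground truth against which the threshold-recovery
machinery is tested; it never looks at the image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

from .contrast import score_slice
from .errors import ConfigError, EmptyLesionError, InfeasibleContrastError
from .io_manifest import SliceSample

MAX_SEED = 2**31 - 1


@dataclass
class PhantomConfig:
    """Geometry and intensity statistics of the synthetic CT slice."""

    side: int = 192
    brain_axes: tuple[float, float] = (0.42, 0.36)  # semi-axes, fraction of side
    background_mean_hu: float = 35.0
    background_sd_hu: float = 4.0
    lesion_sd_hu: float | None = None  # None -> equal variances (default law)
    lesion_radius_range: tuple[int, int] = (7, 14)
    f_distribution: str = "exponential"  # exponential | uniform | fixed
    f_scale: float = 0.06
    f_max: float = 0.4
    f_values: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.brain_axes[0] < 1 and 0 < self.brain_axes[1] < 1):
            raise ConfigError(f"brain axes fractions must be in (0,1): {self.brain_axes}")
        if self.background_sd_hu <= 0:
            raise ConfigError("background_sd_hu must be positive")
        r0, r1 = self.lesion_radius_range
        if not (1 <= r0 <= r1 < self.side * min(self.brain_axes)):
            raise ConfigError(f"lesion radius range {self.lesion_radius_range} infeasible")
        if self.f_distribution not in ("exponential", "uniform", "fixed"):
            raise ConfigError(f"unknown f_distribution {self.f_distribution!r}")
        if self.f_distribution == "fixed" and not self.f_values:
            raise ConfigError("f_distribution='fixed' requires f_values")


@dataclass
class SurrogateConfig:
    """Parameters of the planted performance-vs-contrast law.

    ``dsc_floor``/``dsc_ceiling`` bound the planted per-slice sensitivity
    (TP / lesion area), which the measured DSC tracks closely because the
    false-positive budget is small; ``steepness`` sets how sharply quality
    transitions at ``critical_contrast`` (10–90% of the jump happens over
    ≈ 4.4/steepness Fisher-ratio units); ``fp_base``/``fp_ramp`` control the
    relative false-positive area, growing with contrast (overestimation at
    high contrast, underestimation below the cliff); ``hd_offset_max`` is the
    mislocalization distance (pixels) of false positives at zero contrast.
    """

    critical_contrast: float = 0.05
    steepness: float = 400.0
    dsc_floor: float = 0.05
    dsc_ceiling: float = 0.95
    detection_floor: float = 0.2
    noise_sd: float = 0.10
    fp_base: float = 0.02
    fp_ramp: float = 0.10
    fp_ramp_span: float = 0.30
    hd_offset_max: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.critical_contrast <= 0:
            raise ConfigError("critical_contrast must be positive")
        if not self.dsc_floor < self.dsc_ceiling:
            raise ConfigError("dsc_floor must be below dsc_ceiling")
        if self.steepness <= 0 or self.noise_sd < 0:
            raise ConfigError("steepness must be > 0 and noise_sd >= 0")
        if self.fp_base < 0 or self.fp_ramp < 0 or self.fp_ramp_span <= 0:
            raise ConfigError("fp_base/fp_ramp must be >= 0, fp_ramp_span > 0")


def _standardize(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affinely map a sample to exact (population) mean and sd."""
    v = np.asarray(values, dtype=float)
    s = v.std()
    if s == 0:
        return np.full_like(v, mean)
    return mean + sd * (v - v.mean()) / s


def _ellipse_mask(side: int, axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:side, 0:side]
    cy = cx = (side - 1) / 2.0
    a, b = axes[0] * side, axes[1] * side
    return (((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0).astype(np.uint8)


def _lesion_blob(
    brain: np.ndarray, rng: np.random.Generator, radius_range: tuple[int, int]
) -> np.ndarray:
    """Connected union of 2–4 random disks inside one hemisphere of the brain."""
    side = brain.shape[0]
    rr, cc = np.mgrid[0:side, 0:side]
    inner = binary_erosion(brain > 0, np.ones((3, 3)), iterations=4)
    hemi_right = bool(rng.integers(2))
    half = cc >= side / 2.0 if hemi_right else cc < side / 2.0
    allowed = inner & half
    for _ in range(50):
        r0 = int(rng.integers(radius_range[0], radius_range[1] + 1))
        cand = np.argwhere(allowed)
        if cand.size == 0:
            break
        y, x = cand[rng.integers(len(cand))]
        lesion = (rr - y) ** 2 + (cc - x) ** 2 <= r0**2
        for _ in range(int(rng.integers(1, 4))):
            r = int(rng.integers(radius_range[0], radius_range[1] + 1))
            dy, dx = rng.integers(-r0, r0 + 1, size=2)
            lesion |= (rr - (y + dy)) ** 2 + (cc - (x + dx)) ** 2 <= r**2
        lesion &= inner & half
        if lesion.sum() >= 60:
            return lesion.astype(np.uint8)
    raise InfeasibleContrastError("could not place a lesion inside the brain")


def generate_phantom_slice(
    config: PhantomConfig,
    target_f: float,
    seed: int,
    patient_id: str = "phantom",
    slice_index: int = 0,
) -> tuple[SliceSample, float]:
    """One synthetic slice with measured Fisher ratio ≈ target_f.

    Background ~ N(mean, sd²) inside the brain; lesion ~ N(mean − δ, sd²)
    with δ = sqrt(target_f · (σ_lesion² + σ_bg²)).  Noise is standardized
    over the lesion and over the ipsilateral healthy region, so the achieved
    ratio (measured through :func:`contrast.score_slice`) is exact up to HU
    window truncation.  Returns (sample, achieved F).
    """
    if target_f < 0 or target_f > 4.0:
        raise InfeasibleContrastError(
            f"target_f={target_f} outside the achievable range [0, 4]"
        )
    rng = np.random.default_rng(seed)
    side = config.side
    brain = _ellipse_mask(side, config.brain_axes)
    lesion = _lesion_blob(brain, rng, config.lesion_radius_range)

    sd_bg = config.background_sd_hu
    sd_le = config.lesion_sd_hu if config.lesion_sd_hu is not None else sd_bg
    delta = float(np.sqrt(target_f * (sd_bg**2 + sd_le**2)))
    mu_bg = config.background_mean_hu
    if mu_bg - delta - 3 * sd_le < 10.0:
        raise InfeasibleContrastError(
            f"lesion mean {mu_bg - delta:.1f} HU too close to the window floor"
        )

    image = np.zeros((side, side))
    b = brain > 0
    image[b] = mu_bg + sd_bg * rng.standard_normal(int(b.sum()))
    # standardize the ipsilateral healthy region so measured stats are exact
    cols = np.arange(side)
    col = np.nonzero(lesion)[1].mean()
    hemi = cols < side / 2.0 if col < side / 2.0 else cols >= side / 2.0
    ipsi_bg = b & hemi[np.newaxis, :] & (lesion == 0)
    image[ipsi_bg] = _standardize(image[ipsi_bg], mu_bg, sd_bg)
    les = lesion > 0
    image[les] = _standardize(
        mu_bg - delta + sd_le * rng.standard_normal(int(les.sum())), mu_bg - delta, sd_le
    )

    sample = SliceSample(
        image=image,
        brain_mask=brain,
        lesion_mask=lesion,
        patient_id=patient_id,
        slice_index=slice_index,
        spacing=(1.0, 1.0),
    )
    achieved = score_slice(sample).fisher
    return sample, achieved


def _draw_targets(config: PhantomConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.f_distribution == "exponential":
        t = rng.exponential(config.f_scale, size=n)
        for _ in range(100):
            over = t > config.f_max
            if not over.any():
                break
            t[over] = rng.exponential(config.f_scale, size=int(over.sum()))
        return np.minimum(t, config.f_max)
    if config.f_distribution == "uniform":
        return rng.uniform(0.0, config.f_max, size=n)
    vals = np.asarray(list(config.f_values), dtype=float)
    return vals[np.arange(n) % len(vals)]


def generate_synthetic_dataset(
    config: PhantomConfig,
    n_slices: int,
    n_patients: int,
    seed: int | None = None,
) -> tuple[list[SliceSample], pd.DataFrame]:
    """A seeded phantom dataset with its truth table.

    Slices are assigned round-robin to synthetic patients.  The truth table
    has one row per slice: slice_id, patient, target F and the F actually
    measured through the contrast module.
    """
    if not n_slices >= n_patients >= 1:
        raise ConfigError(f"need n_slices >= n_patients >= 1, got {n_slices}, {n_patients}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    targets = _draw_targets(config, n_slices, rng)
    samples: list[SliceSample] = []
    rows = []
    counters = [0] * n_patients
    for i in range(n_slices):
        p = i % n_patients
        pid = f"pat{p:03d}"
        s, achieved = generate_phantom_slice(
            config,
            float(targets[i]),
            seed=int(rng.integers(MAX_SEED)),
            patient_id=pid,
            slice_index=counters[p],
        )
        counters[p] += 1
        samples.append(s)
        rows.append(
            {
                "slice_id": s.slice_id,
                "patient_id": pid,
                "target_f": float(targets[i]),
                "achieved_f": achieved,
            }
        )
    return samples, pd.DataFrame(rows)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def planted_quality(true_f: float, config: SurrogateConfig) -> float:
    """Noise-free planted sensitivity (TP / lesion area) at contrast true_f."""
    span = config.dsc_ceiling - config.dsc_floor
    return config.dsc_floor + span * _sigmoid(
        config.steepness * (true_f - config.critical_contrast)
    )


def detection_probability(true_f: float, config: SurrogateConfig) -> float:
    """1 at and above c*; falls linearly to detection_floor at F = 0."""
    if true_f >= config.critical_contrast:
        return 1.0
    frac = max(true_f, 0.0) / config.critical_contrast
    return config.detection_floor + (1.0 - config.detection_floor) * frac


def planted_fp_fraction(true_f: float, config: SurrogateConfig) -> float:
    """Relative false-positive area: grows linearly with contrast above c*.

    Emulates the trend reversal seen in CT lesion segmentation — lesions are
    underestimated at low contrast and increasingly overestimated (more false
    positives) as contrast grows, so the aggregate FPR rises monotonically
    with any contrast cutoff.
    """
    frac = min(max((true_f - config.critical_contrast) / config.fp_ramp_span, 0.0), 1.0)
    return config.fp_base + config.fp_ramp * frac


def _dsc_masks(pred: np.ndarray, gt: np.ndarray) -> float:
    inter = int(np.sum((pred > 0) & (gt > 0)))
    denom = int(pred.sum()) + int(gt.sum())
    return 2.0 * inter / denom if denom else 0.0


def _take_extreme(mask: np.ndarray, n: int, direction: np.ndarray) -> np.ndarray:
    """The n pixels of ``mask`` most advanced along ``direction`` (one-sided)."""
    coords = np.argwhere(mask)
    proj = coords @ direction
    order = np.lexsort((coords[:, 1], coords[:, 0], -proj))
    keep = np.zeros_like(mask)
    sel = coords[order[:n]]
    keep[sel[:, 0], sel[:, 1]] = True
    return keep


def _erode_to_count(gt: np.ndarray, n_keep: int, direction: np.ndarray) -> np.ndarray:
    """Subset of the lesion with exactly n_keep pixels, shrunk from the rim."""
    struct = np.ones((3, 3))
    core = gt.astype(bool)
    while core.sum() > n_keep:
        nxt = binary_erosion(core, struct)
        if not nxt.any() or nxt.sum() < n_keep:
            boundary = core & ~nxt
            n_remove = int(core.sum()) - n_keep
            drop = _take_extreme(boundary, n_remove, direction)
            core = core & ~drop
            break
        core = nxt
    return core


def surrogate_segment(
    sample: SliceSample,
    true_f: float,
    config: SurrogateConfig,
    seed: int,
) -> tuple[np.ndarray, dict]:
    """Predicted mask realizing the planted performance-vs-contrast law.

    Detection failure (probability rising as F falls below c*) yields an
    empty mask.  Otherwise the prediction is built constructively so every
    planted quantity is exact up to pixel rounding:

    * *sensitivity* — the lesion is shrunk from the rim to exactly
      round(s·area) true positives, where s follows the sigmoid quality law
      (plus Gaussian noise);
    * *false positives* — round(fp·area) pixels outside the lesion, with fp
      ramping up with contrast;
    * *localization* — false positives are the healthy pixels nearest to a
      point whose offset from the lesion grows as contrast falls below c*
      (adjacent boundary overshoot above the cliff, a mislocalized blob
      below it, driving the Hausdorff distance up).
    """
    gt = sample.lesion_mask
    g = int(gt.sum())
    if g == 0:
        raise EmptyLesionError("surrogate needs a non-empty reference lesion")
    rng = np.random.default_rng(seed)
    info: dict = {"true_f": true_f}
    if rng.random() >= detection_probability(true_f, config):
        info.update(detected=False, target_sensitivity=0.0, achieved_dsc=0.0)
        return np.zeros_like(gt), info

    frac = _sigmoid(config.steepness * (true_f - config.critical_contrast))
    s = planted_quality(true_f, config) + rng.normal(0.0, config.noise_sd)
    s = float(np.clip(s, 0.02, 0.98))
    fp_frac = max(planted_fp_fraction(true_f, config) + rng.normal(0.0, 0.02), 0.0)
    angle = rng.uniform(0, 2 * np.pi)
    direction = np.array([np.sin(angle), np.cos(angle)])

    core = _erode_to_count(gt > 0, max(1, int(round(s * g))), direction)

    n_fp = int(round(fp_frac * g))
    pred = core.copy()
    if n_fp > 0:
        offset = (1.0 - frac) * config.hd_offset_max + rng.normal(0.0, 4.0)
        cy, cx = np.argwhere(gt > 0).mean(axis=0)
        center = np.array([cy, cx]) + max(offset, 0.0) * direction
        candidates = (sample.brain_mask > 0) & (gt == 0)
        coords = np.argwhere(candidates)
        if coords.size:
            d2 = ((coords - center) ** 2).sum(axis=1)
            order = np.lexsort((coords[:, 1], coords[:, 0], d2))
            sel = coords[order[:n_fp]]
            pred[sel[:, 0], sel[:, 1]] = True

    achieved = _dsc_masks(pred.astype(np.uint8), gt)
    info.update(
        detected=True,
        target_sensitivity=s,
        fp_fraction=fp_frac,
        achieved_dsc=achieved,
    )
    return pred.astype(np.uint8), info


def surrogate_evaluate_dataset(
    samples: Sequence[SliceSample],
    true_f: dict[str, float],
    config: SurrogateConfig,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Predictions for every slice, seeded reproducibly per slice."""
    base = config.seed if seed is None else seed
    rng = np.random.default_rng(base)
    preds = {}
    for s in samples:
        preds[s.slice_id], _ = surrogate_segment(
            s, true_f[s.slice_id], config, seed=int(rng.integers(MAX_SEED))
        )
    return preds
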