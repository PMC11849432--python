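"""Slice extraction, lesion-area filtering, hemisphere harmonization, resizing.

These are the in-package preprocessing stages for already brain-extracted,
registered volumes: cut axial slices, keep those whose lesion area strictly
exceeds a physical threshold, mirror slices so every lesion sits in the same
hemisphere, and resample to a square grid.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import DimensionMismatchError, EmptyLesionError, MissingSpacingError
from .io_manifest import SliceSample, Volume


def brain_support(image: np.ndarray) -> np.ndarray:
    """Brain mask of a skull-stripped slice: finite, nonzero HU footprint."""
    return (np.isfinite(image) & (image != 0)).astype(np.uint8)


def extract_lesion_slices(
    image: Volume, mask: Volume, min_area_cm2: float = 1.0
) -> list[SliceSample]:
    """Cut a volume into axial slices, keeping lesion areas > ``min_area_cm2``.

    Area is lesion pixel count × in-plane pixel area at native resolution
    (strict inequality, so exactly 1.00 cm² is excluded at the default).
    """
    if image.data.shape != mask.data.shape:
        raise DimensionMismatchError(
            f"image {image.data.shape} vs mask {mask.data.shape}"
        )
    in_plane = (image.spacing[0], image.spacing[1])
    if not all(np.isfinite(s) and s > 0 for s in in_plane):
        raise MissingSpacingError(f"bad in-plane spacing {in_plane}")
    pixel_area_cm2 = in_plane[0] * in_plane[1] / 100.0
    out: list[SliceSample] = []
    for k in range(image.n_slices):
        img2d = image.data[:, :, k]
        les2d = (mask.data[:, :, k] > 0.5).astype(np.uint8)
        if les2d.sum() * pixel_area_cm2 <= min_area_cm2:
            continue
        brain = brain_support(img2d)
        brain |= les2d  # a labeled lesion is brain tissue by definition
        out.append(
            SliceSample(
                image=img2d,
                brain_mask=brain,
                lesion_mask=les2d,
                patient_id=image.patient_id,
                slice_index=k,
                spacing=in_plane,
            )
        )
    return out


def lesion_centroid_column(lesion_mask: np.ndarray) -> float:
    if lesion_mask.sum() == 0:
        raise EmptyLesionError("lesion mask is empty")
    return float(np.nonzero(lesion_mask)[1].mean())


def flip_to_hemisphere(
    sample: SliceSample, reference_hemisphere: Literal["left", "right"] = "left"
) -> SliceSample:
    """Mirror the slice horizontally iff the lesion centroid is on the wrong side.

    Laterality is decided by the lesion-mask centroid column relative to the
    vertical midline (column W/2) of the registered grid.
    """
    w = sample.image.shape[1]
    col = lesion_centroid_column(sample.lesion_mask)
    on_left = col < w / 2.0
    need_flip = on_left if reference_hemisphere == "right" else not on_left
    if not need_flip:
        return sample.copy()
    out = sample.copy()
    out.image = np.flip(out.image, axis=1).copy()
    out.brain_mask = np.flip(out.brain_mask, axis=1).copy()
    out.lesion_mask = np.flip(out.lesion_mask, axis=1).copy()
    return out


def resize_sample(sample: SliceSample, target_side: int = 192) -> SliceSample:
    """Resample to target_side × target_side: bilinear image, nearest masks."""
    if target_side < 1:
        raise DimensionMismatchError(f"target_side must be positive, got {target_side}")
    shape = (target_side, target_side)
    if sample.image.shape == shape:
        return sample.copy()
    img = _sk_resize(
        sample.image, shape, order=1, preserve_range=True, anti_aliasing=False
    )
    brain = _sk_resize(
        sample.brain_mask.astype(float), shape, order=0, preserve_range=True,
        anti_aliasing=False,
    )
    lesion = _sk_resize(
        sample.lesion_mask.astype(float), shape, order=0, preserve_range=True,
        anti_aliasing=False,
    )
    brain_b = (brain > 0.5).astype(np.uint8)
    lesion_b = (lesion > 0.5).astype(np.uint8)
    lesion_b &= brain_b  # nearest-neighbour resampling cannot break the subset relation
    new_spacing = (
        sample.spacing[0] * sample.image.shape[0] / target_side,
        sample.spacing[1] * sample.image.shape[1] / target_side,
    )
    out = sample.copy()
    out.image, out.brain_mask, out.lesion_mask = img, brain_b, lesion_b
    out.spacing = new_spacing
    return out


def harmonize_and_resize(
    sample: SliceSample,
    target_side: int = 192,
    reference_hemisphere: Literal["left", "right"] = "left",
) -> SliceSample:
    """Hemisphere harmonization followed by resizing (the order used throughout)."""
    return resize_sample(
        flip_to_hemisphere(sample, reference_hemisphere), target_side
    )


def preprocess_volume_pair(
    image: Volume,
    mask: Volume,
    min_area_cm2: float = 1.0,
    target_side: int = 192,
    reference_hemisphere: Literal["left", "right"] = "left",
) -> list[SliceSample]:
    """Full preprocessing for one patient: extract → filter → flip → resize."""
    return [
        harmonize_and_resize(s, target_side, reference_hemisphere)
        for s in extract_lesion_slices(image, mask, min_area_cm2)
    ]
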