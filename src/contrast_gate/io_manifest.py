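"""File-driven dataset handling: NIfTI volumes, per-slice containers, CSV manifest.

Slices are stored one compressed ``.npz`` per slice (image, brain_mask,
lesion_mask, spacing, identity) next to a single ``manifest.csv`` indexing
them, so every downstream stage can be re-run from files alone.

Axis convention (global): axial slices are taken along the **last** axis of a
3D volume; in-slice axes are (row, column) with the vertical midline splitting
columns into left (< W/2) and right hemispheres.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    DimensionMismatchError,
    DuplicateSliceError,
    EmptyDatasetError,
    MissingSpacingError,
    NonVolumeError,
    UnreadableFileError,
)

MANIFEST_COLUMNS = [
    "slice_id",
    "file",
    "patient_id",
    "slice_index",
    "lesion_area_cm2",
    "fisher",
    "split",
]


def _check_spacing(spacing: Sequence[float], ndim: int) -> tuple[float, ...]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != ndim:
        raise MissingSpacingError(f"expected {ndim} spacing entries, got {len(spacing)}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise MissingSpacingError(f"spacing must be positive and finite, got {spacing}")
    return spacing


@dataclass(frozen=True)
class Volume:
    """A 3D image (HU values) with physical voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise NonVolumeError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise NonVolumeError(f"degenerate volume shape {self.data.shape}")
        object.__setattr__(self, "spacing", _check_spacing(self.spacing, 3))

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]


def _as_binary(mask: np.ndarray) -> np.ndarray:
    return (np.asarray(mask) > 0.5).astype(np.uint8)


@dataclass
class SliceSample:
    """One axial 2D slice: HU image, brain mask, lesion mask and identity."""

    image: np.ndarray
    brain_mask: np.ndarray
    lesion_mask: np.ndarray
    patient_id: str
    slice_index: int
    spacing: tuple[float, float]
    variant: str = ""  # non-empty for augmented copies, e.g. "dark2"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.brain_mask = _as_binary(self.brain_mask)
        self.lesion_mask = _as_binary(self.lesion_mask)
        if not (self.image.shape == self.brain_mask.shape == self.lesion_mask.shape):
            raise DimensionMismatchError(
                f"image {self.image.shape}, brain {self.brain_mask.shape}, "
                f"lesion {self.lesion_mask.shape} shapes differ"
            )
        if self.image.ndim != 2:
            raise NonVolumeError("SliceSample grids must be 2D")
        if np.any(self.lesion_mask > self.brain_mask):
            raise DimensionMismatchError("lesion_mask must be a subset of brain_mask")
        self.spacing = _check_spacing(self.spacing, 2)

    @property
    def slice_id(self) -> str:
        base = f"{self.patient_id}_s{int(self.slice_index):04d}"
        return f"{base}_{self.variant}" if self.variant else base

    @property
    def lesion_area_cm2(self) -> float:
        """Lesion pixel count times in-plane pixel area (mm² → cm²)."""
        return float(self.lesion_mask.sum()) * self.spacing[0] * self.spacing[1] / 100.0

    def copy(self) -> "SliceSample":
        return dataclasses.replace(
            self,
            image=self.image.copy(),
            brain_mask=self.brain_mask.copy(),
            lesion_mask=self.lesion_mask.copy(),
        )


@dataclass
class DatasetManifest:
    """Index of a slice dataset on disk; one row per slice file."""

    table: pd.DataFrame
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        dup = self.table["slice_id"].duplicated()
        if dup.any():
            raise DuplicateSliceError(
                f"duplicate slice references: {sorted(self.table.loc[dup, 'slice_id'])}"
            )
        splits = set(self.table["split"].dropna()) - {""}
        if not splits <= {"train", "test"}:
            raise DuplicateSliceError(f"invalid split labels: {splits - {'train', 'test'}}")
        self._check_patient_disjoint()

    def _check_patient_disjoint(self) -> None:
        t = self.table
        train = set(t.loc[t["split"] == "train", "patient_id"])
        test = set(t.loc[t["split"] == "test", "patient_id"])
        if train & test:
            raise DuplicateSliceError(
                f"patients in both train and test: {sorted(train & test)}"
            )

    def __len__(self) -> int:
        return len(self.table)

    def save(self, path: str | os.PathLike | None = None) -> Path:
        path = Path(path) if path is not None else self.root / "manifest.csv"
        self.table.to_csv(path, index=False)
        return path


def read_volume(path: str | os.PathLike, patient_id: str | None = None) -> Volume:
    """Load a NIfTI volume; spacing from the header zooms."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except FileNotFoundError:
        raise UnreadableFileError(f"no such file: {path}") from None
    except Exception as exc:  # nibabel raises several parse errors
        raise UnreadableFileError(f"cannot read {path}: {exc}") from exc
    if data.ndim != 3:
        raise NonVolumeError(f"{path} is {data.ndim}D, expected 3D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if patient_id is None:
        patient_id = path.name.split(".")[0]
    return Volume(data=data, spacing=_check_spacing(spacing, 3), patient_id=patient_id)


def read_volume_pair(
    image_path: str | os.PathLike, mask_path: str | os.PathLike
) -> tuple[Volume, Volume]:
    """Load an (image, lesion-mask) volume pair; the mask is binarized at 0.5."""
    image = read_volume(image_path)
    mask = read_volume(mask_path, patient_id=image.patient_id)
    if image.data.shape != mask.data.shape:
        raise DimensionMismatchError(
            f"image {image.data.shape} vs mask {mask.data.shape}"
        )
    if not np.allclose(image.spacing, mask.spacing, rtol=1e-3):
        raise MissingSpacingError(
            f"image spacing {image.spacing} vs mask spacing {mask.spacing}"
        )
    binary = Volume(
        data=_as_binary(mask.data).astype(np.float64),
        spacing=image.spacing,
        patient_id=image.patient_id,
    )
    return image, binary


def save_volume(volume: Volume, path: str | os.PathLike) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))


def write_dataset(
    samples: Sequence[SliceSample],
    directory: str | os.PathLike,
    fisher: dict[str, float] | None = None,
) -> DatasetManifest:
    """Write each slice as a compressed .npz plus a CSV manifest.

    Reloading with :func:`load_dataset` reproduces the arrays bit-identically.
    """
    if len(samples) == 0:
        raise EmptyDatasetError("cannot write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    seen: set[str] = set()
    for s in samples:
        if s.slice_id in seen:
            raise DuplicateSliceError(f"duplicate slice reference {s.slice_id!r}")
        seen.add(s.slice_id)
        fname = f"{s.slice_id}.npz"
        np.savez_compressed(
            directory / fname,
            image=s.image,
            brain_mask=s.brain_mask,
            lesion_mask=s.lesion_mask,
            spacing=np.asarray(s.spacing, dtype=np.float64),
            patient_id=np.asarray(s.patient_id),
            slice_index=np.asarray(s.slice_index),
            variant=np.asarray(s.variant),
        )
        rows.append(
            {
                "slice_id": s.slice_id,
                "file": fname,
                "patient_id": s.patient_id,
                "slice_index": s.slice_index,
                "lesion_area_cm2": s.lesion_area_cm2,
                "fisher": (fisher or {}).get(s.slice_id, np.nan),
                "split": "",
            }
        )
    manifest = DatasetManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS), directory)
    manifest.save()
    return manifest


def load_slice(path: str | os.PathLike) -> SliceSample:
    try:
        with np.load(path, allow_pickle=False) as z:
            return SliceSample(
                image=z["image"],
                brain_mask=z["brain_mask"],
                lesion_mask=z["lesion_mask"],
                patient_id=str(z["patient_id"]),
                slice_index=int(z["slice_index"]),
                spacing=tuple(z["spacing"]),
                variant=str(z["variant"]) if "variant" in z else "",
            )
    except FileNotFoundError:
        raise UnreadableFileError(f"no such slice file: {path}") from None
    except (OSError, ValueError, KeyError) as exc:
        raise UnreadableFileError(f"cannot read slice {path}: {exc}") from exc


def load_dataset(
    manifest_path: str | os.PathLike,
) -> tuple[list[SliceSample], DatasetManifest]:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.csv"
    try:
        table = pd.read_csv(manifest_path, dtype={"split": "string"})
    except FileNotFoundError:
        raise UnreadableFileError(f"no such manifest: {manifest_path}") from None
    table["split"] = table["split"].fillna("")
    manifest = DatasetManifest(table, manifest_path.parent)
    samples = [load_slice(manifest.root / f) for f in table["file"]]
    return samples, manifest


def dataset_manifest_roundtrip(
    samples: Sequence[SliceSample], directory: str | os.PathLike
) -> DatasetManifest:
    """Write then reload a slice dataset, returning the reloaded manifest."""
    write_dataset(samples, directory)
    _, manifest = load_dataset(directory)
    return manifest


def contrast_balanced_split(
    manifest: DatasetManifest,
    test_fraction: float = 0.05,
    n_bins: int = 8,
    seed: int = 0,
) -> DatasetManifest:
    """Assign patient-level train/test labels with a contrast-balanced test set.

    Whole patients are moved to the test split, chosen greedily so the test
    set's Fisher-ratio histogram stays as close to uniform across ``n_bins``
    equal-width bins as the patient structure allows.  Requires the manifest's
    ``fisher`` column to be filled.
    """
    table = manifest.table.copy()
    f = table["fisher"].to_numpy(dtype=float)
    if np.isnan(f).any():
        raise EmptyDatasetError("contrast_balanced_split requires fisher for every slice")
    lo, hi = float(f.min()), float(f.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    bins = np.clip(np.digitize(f, edges[1:-1]), 0, n_bins - 1)
    target_total = max(1, int(round(test_fraction * len(table))))

    rng = np.random.default_rng(seed)
    patients = sorted(set(table["patient_id"]))
    rng.shuffle(patients)
    pat_hist = {
        p: np.bincount(bins[table["patient_id"] == p], minlength=n_bins) for p in patients
    }
    chosen: list[str] = []
    counts = np.zeros(n_bins, dtype=int)
    while counts.sum() < target_total and len(chosen) < len(patients) - 1:
        best, best_score = None, None
        for p in patients:
            if p in chosen:
                continue
            cand = counts + pat_hist[p]
            uniform = cand.sum() / n_bins
            score = float(((cand - uniform) ** 2).sum())
            if best_score is None or score < best_score:
                best, best_score = p, score
        chosen.append(best)
        counts += pat_hist[best]
    table["split"] = np.where(table["patient_id"].isin(chosen), "test", "train")
    return DatasetManifest(table, manifest.root)
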