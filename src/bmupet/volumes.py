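"""Volumetric data model and NIfTI I/O shared by all pipeline stages.

Three containers travel through the pipeline:

* :class:`SuvVolume` — a 3-D scalar field of standardized uptake values
  (SUV, dimensionless) with physical voxel spacing in mm;
* :class:`BoneLabelVolume` — an integer label field on the same grid naming
  individual bones and the liver, with a taxonomy mapping label -> name;
* :class:`BinaryMask` — a boolean field on the same grid.

Grids must match exactly between SUV and label volumes; no resampling is
performed here (PET and CT reconstructions are assumed aligned upstream).
All physical distances downstream are computed in mm from the per-axis
spacing, so anisotropic grids are handled correctly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .anatomy import LIVER, anatomical_class


class GridMismatchError(ValueError):
    """Shapes or spacings of two volumes on the supposedly shared grid differ."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be positive, got {spacing}")
    return spacing


@dataclass
class SuvVolume:
    """3-D standardized-uptake-value field with physical geometry.

    Parameters
    ----------
    values : ndarray
        3-D float array of SUV; all finite and >= 0.
    spacing : tuple of float
        Voxel edge lengths (x, y, z) in mm, all > 0.
    origin : tuple of float
        Physical offset of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        if not np.isfinite(self.values).all():
            raise ValueError("SUV values must all be finite")
        if (self.values < 0).any():
            raise ValueError("SUV values must be >= 0")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (= cm^3); spacing is in mm."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class BinaryMask:
    """Boolean voxel set on a parent grid, with spacing inherited from it."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.voxels.ndim}D")
        self.spacing = _check_spacing(self.spacing)

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_ml(self) -> float:
        return self.count * self.voxel_volume_ml

    def __and__(self, other: "BinaryMask | np.ndarray") -> "BinaryMask":
        ov = other.voxels if isinstance(other, BinaryMask) else np.asarray(other, bool)
        return BinaryMask(self.voxels & ov, self.spacing)

    def __or__(self, other: "BinaryMask | np.ndarray") -> "BinaryMask":
        ov = other.voxels if isinstance(other, BinaryMask) else np.asarray(other, bool)
        return BinaryMask(self.voxels | ov, self.spacing)


@dataclass
class BoneLabelVolume:
    """Integer-labelled volume identifying individual bones and the liver.

    ``taxonomy`` maps each nonzero label to a name from the controlled
    anatomical vocabulary (label 0 is background).  The taxonomy may list
    labels that do not occur in the array, but every nonzero label present
    in the array must be listed.
    """

    labels: np.ndarray
    taxonomy: dict[int, str]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D label volume, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            data = np.asarray(self.labels, dtype=np.float64)
            if not np.allclose(data, np.round(data)):
                raise ValueError("label volume contains non-integer values")
            self.labels = np.round(data).astype(np.int32)
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.taxonomy = {int(k): str(v) for k, v in self.taxonomy.items()}
        if 0 in self.taxonomy:
            raise ValueError("label 0 is reserved for background")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = sorted(present - set(self.taxonomy))
        if missing:
            raise ValueError(
                f"labels present in the volume but missing from the taxonomy: {missing}"
            )
        # validate every name against the controlled vocabulary
        for lbl, name in self.taxonomy.items():
            anatomical_class(name)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def check_grid(self, other: "SuvVolume | BoneLabelVolume | BinaryMask") -> None:
        oshape = other.values.shape if isinstance(other, SuvVolume) else (
            other.labels.shape if isinstance(other, BoneLabelVolume) else other.voxels.shape
        )
        if self.labels.shape != oshape:
            raise GridMismatchError(
                f"grid shape mismatch: {self.labels.shape} vs {oshape}"
            )
        if not np.allclose(self.spacing, other.spacing, rtol=1e-5):
            raise GridMismatchError(
                f"grid spacing mismatch: {self.spacing} vs {other.spacing}"
            )

    def class_of(self, label: int) -> str:
        return anatomical_class(self.taxonomy[int(label)])

    def labels_of_classes(self, classes) -> list[int]:
        classes = set(classes)
        return sorted(
            lbl for lbl, name in self.taxonomy.items()
            if anatomical_class(name) in classes
        )

    def mask_for_classes(self, classes) -> BinaryMask:
        wanted = self.labels_of_classes(classes)
        return BinaryMask(np.isin(self.labels, wanted), self.spacing)

    def bone_labels(self) -> list[int]:
        return sorted(
            lbl for lbl, name in self.taxonomy.items()
            if anatomical_class(name) != LIVER
        )

    def bone_mask(self) -> BinaryMask:
        return BinaryMask(np.isin(self.labels, self.bone_labels()), self.spacing)

    def liver_mask(self) -> BinaryMask:
        return self.mask_for_classes([LIVER])

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


# ---------------------------------------------------------------------------
# NIfTI / CSV I/O
# ---------------------------------------------------------------------------

def _load_nifti(path) -> tuple[np.ndarray, tuple, tuple]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing} in {path}")
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return data, spacing, origin


def read_suv_volume(path) -> SuvVolume:
    """Read a 3-D SUV volume from a NIfTI file (spacing from the header)."""
    data, spacing, origin = _load_nifti(path)
    return SuvVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_suv_volume(vol: SuvVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), vol.affine())
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_taxonomy(path) -> dict[int, str]:
    """Read a two-column ``label,name`` CSV into a taxonomy dict."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["label", "name"]:
        raise ValueError(
            f"taxonomy CSV must have columns 'label,name', got {list(df.columns)}"
        )
    return {int(row[0]): str(row[1]) for row in df.itertuples(index=False)}


def write_taxonomy(taxonomy: dict[int, str], path) -> None:
    pd.DataFrame(
        sorted(taxonomy.items()), columns=["label", "name"]
    ).to_csv(path, index=False)


def read_label_volume(path, taxonomy_path, reference: SuvVolume | None = None) -> BoneLabelVolume:
    """Read a label volume and its taxonomy; optionally check the grid.

    Raises on unknown nonzero labels, non-integer label data, and (when a
    reference SUV volume is given) any shape or spacing mismatch —
    resampling is deliberately not performed.
    """
    data, spacing, origin = _load_nifti(path)
    taxonomy = read_taxonomy(taxonomy_path)
    vol = BoneLabelVolume(data, taxonomy, spacing, origin)
    if reference is not None:
        vol.check_grid(reference)
    return vol


def write_label_volume(vol: BoneLabelVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.labels, dtype=np.int16), vol.affine())
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path, origin=(0.0, 0.0, 0.0)) -> None:
    aff = np.diag(list(mask.spacing) + [1.0])
    aff[:3, 3] = origin
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), aff)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
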