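"""Bone-marrow extraction and spine / other-bones grouping.

The marrow compartment is defined geometrically: from each individual bone,
an edge layer is excluded — 7 mm for the humeri and femora, 5 mm for the
vertebrae and hip bones, and 3 mm for the remaining bones.  Erosion is
performed per bone label, so boundaries between touching bones count as
edges, and distances are Euclidean in physical mm (anisotropy-aware).
A voxel survives when its distance to the nearest voxel outside its bone is
>= the class margin; voxels exactly at the margin are kept.

Bones are then partitioned into two groups with systematically different
diffuse uptake:

* ``spine`` — vertebrae, sacrum, coccyx, plus hip-bone voxels within
  50 mm (surface distance, inclusive) of any of those, i.e. the
  sacroiliac joints;
* ``other`` — humeri, scapulae, clavicles, ribs, sternum, femora, and the
  remaining hip-bone voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .anatomy import DEFAULT_MARGINS_MM, SPINE_CLASSES, anatomical_class
from .volumes import BinaryMask, BoneLabelVolume


@dataclass
class MarrowConfig:
    """Margins (mm) per anatomical class and the sacroiliac inclusion radius."""

    margins_mm: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARGINS_MM)
    )
    sacroiliac_radius_mm: float = 50.0

    def __post_init__(self) -> None:
        for cls, m in self.margins_mm.items():
            if m < 0:
                raise ValueError(f"margin for {cls!r} must be >= 0, got {m}")
        if self.sacroiliac_radius_mm < 0:
            raise ValueError("sacroiliac_radius_mm must be >= 0")

    def margin_for(self, cls: str) -> float:
        try:
            return self.margins_mm[cls]
        except KeyError:
            raise KeyError(f"no erosion margin configured for bone class {cls!r}")


@dataclass
class GroupMasks:
    """Skeleton partition and the marrow restricted to each group."""

    spine: BinaryMask
    other: BinaryMask
    marrow_spine: BinaryMask
    marrow_other: BinaryMask


def erode_mask_mm(mask: np.ndarray, spacing, margin_mm: float) -> np.ndarray:
    """Keep voxels whose Euclidean distance (mm) to the mask's exterior is
    >= ``margin_mm``.

    The grid boundary is treated as exterior, so structures clipped by the
    field of view are eroded at the cut as well.  Computed on the padded
    bounding box for speed; exact (distance-transform based, per-axis
    spacing as sampling).
    """
    mask = np.asarray(mask, dtype=bool)
    if margin_mm <= 0:
        return mask.copy()
    if not mask.any():
        return mask.copy()
    # restrict to the bounding box, padded so the exterior is visible
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sub = mask[tuple(slice(l, h) for l, h in zip(lo, hi))]
    padded = np.pad(sub, 1)
    dist = ndi.distance_transform_edt(padded, sampling=spacing)
    keep_sub = dist[1:-1, 1:-1, 1:-1] >= margin_mm
    out = np.zeros_like(mask)
    out[tuple(slice(l, h) for l, h in zip(lo, hi))] = keep_sub
    return out


def extract_marrow(labels: BoneLabelVolume, config: MarrowConfig | None = None) -> BinaryMask:
    """Derive the bone-marrow mask by per-bone physical erosion.

    Each bone label is eroded independently by its class margin; the marrow
    mask is the union of the surviving cores.  A bone whose inradius is
    smaller than its margin simply contributes nothing.  A bone label whose
    class has no configured margin raises ``KeyError``.
    """
    config = config or MarrowConfig()
    marrow = np.zeros(labels.shape, dtype=bool)
    for lbl in labels.bone_labels():
        cls = anatomical_class(labels.taxonomy[lbl])
        margin = config.margin_for(cls)
        bone = labels.labels == lbl
        if not bone.any():
            continue
        marrow |= erode_mask_mm(bone, labels.spacing, margin)
    return BinaryMask(marrow, labels.spacing)


def assign_groups(
    labels: BoneLabelVolume,
    marrow: BinaryMask,
    config: MarrowConfig | None = None,
) -> GroupMasks:
    """Partition the skeleton into the spine and other-bones groups.

    Hip-bone voxels within ``sacroiliac_radius_mm`` (inclusive) of the
    nearest vertebra/sacrum/coccyx voxel join the spine group; the rest of
    the hip bones go to ``other``.  Raises if the spine core is empty, since
    every downstream statistic is then undefined.
    """
    config = config or MarrowConfig()
    labels.check_grid(marrow)
    spine_core = labels.mask_for_classes(SPINE_CLASSES).voxels
    if not spine_core.any():
        raise ValueError("empty spine group: no vertebra/sacrum/coccyx voxels")
    spine = spine_core.copy()
    hip = labels.mask_for_classes(["hip_bone"]).voxels
    if hip.any():
        # distance from every voxel to the nearest spine-core voxel, in mm
        dist = ndi.distance_transform_edt(~spine_core, sampling=labels.spacing)
        spine |= hip & (dist <= config.sacroiliac_radius_mm)
    bone = labels.bone_mask().voxels
    other = bone & ~spine
    sp = labels.spacing
    return GroupMasks(
        spine=BinaryMask(spine, sp),
        other=BinaryMask(other, sp),
        marrow_spine=BinaryMask(marrow.voxels & spine, sp),
        marrow_other=BinaryMask(marrow.voxels & other, sp),
    )
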