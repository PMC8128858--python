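"""Focal skeleton/bone-marrow uptake detection via the TSAU statistic.

For each bone group (spine, other bones) the detector:

1. computes an abnormality threshold ``THR = SUVmean + 2 SD`` over that
   group's marrow voxels (population SD; the few-thousand-voxel marrow makes
   the sample/population distinction negligible, but it is fixed here for
   reproducibility);
2. builds the abnormal bone region: bone voxels with ``SUV > THR``
   (strict), minus spill-over — every suprathreshold voxel is assigned by a
   watershed transform of the negated SUV to the catchment basin of a local
   SUV maximum, and voxels whose basin maximum lies outside the full
   skeletal mask are assumed to be uptake leaking in from adjacent tissue
   and are removed — minus connected components smaller than 0.1 mL;
3. scores the region:

   ``MSAU = mean of (SUV - THR)^2 over the abnormal region``   (0 if empty)

   ``TSAU = MSAU x (volume of the abnormal region in mL)``

A patient is classified as having focal uptake when the spine TSAU exceeds
0.5 or the other-bones TSAU exceeds 3.0 (strict inequalities; the cut-offs
were tuned on a training cohort towards PPV 65% / NPV 98%, and
:func:`tune_cutoff` reproduces that tuning procedure for new cohorts).

TSAU deliberately up-weights small, very hot lesions relative to total
lesion glycolysis, which would be dominated by large regions of moderate
uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from .marrow import MarrowConfig, assign_groups, extract_marrow
from .volumes import BinaryMask, BoneLabelVolume, SuvVolume


@dataclass
class FocalConfig:
    """Detector parameters with their clinical defaults."""

    sd_multiplier: float = 2.0
    min_region_ml: float = 0.1
    cutoff_spine: float = 0.5
    cutoff_other: float = 3.0
    #: neighbourhood order for maxima detection, watershed and component
    #: labelling: 1 = faces (6-connectivity), 3 = full 26-connectivity
    connectivity: int = 3

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")
        if self.min_region_ml < 0 or self.cutoff_spine < 0 or self.cutoff_other < 0:
            raise ValueError("min_region_ml and cut-offs must be >= 0")
        if self.connectivity not in (1, 2, 3):
            raise ValueError("connectivity must be 1, 2 or 3")


@dataclass
class GroupScore:
    """Per-group threshold, abnormal region and TSAU score."""

    group: str
    thr: float
    abnormal_mask: BinaryMask
    abnormal_volume_ml: float
    msau: float
    tsau: float


@dataclass
class FocalVerdict:
    spine_score: GroupScore
    other_score: GroupScore
    focal: bool


@dataclass
class Basins:
    """Watershed partition of the volume into catchment basins of SUV maxima.

    ``markers`` labels the regional-maximum plateaus (one id per plateau,
    merged over the configured connectivity); ``basin`` assigns every voxel
    the id of the maximum its basin drains to.
    """

    basin: np.ndarray
    markers: np.ndarray


def compute_threshold(
    suv: SuvVolume, group_marrow: BinaryMask | np.ndarray, sd_multiplier: float = 2.0
) -> float:
    """``THR = mean + sd_multiplier * SD`` over the group's marrow voxels."""
    mask = group_marrow.voxels if isinstance(group_marrow, BinaryMask) else np.asarray(group_marrow, bool)
    vals = suv.values[mask]
    if vals.size == 0:
        raise ValueError("threshold undefined: empty marrow mask")
    return float(vals.mean() + sd_multiplier * vals.std(ddof=0))


def watershed_basins(suv: SuvVolume, connectivity: int = 3) -> Basins:
    """Assign every voxel to the catchment basin of a local SUV maximum.

    The watershed runs on the negated SUV over the whole volume (not
    restricted to bone), seeded by the regional maxima of SUV; a plateau of
    equal-valued maxima is merged into a single seed.  The flooding order of
    the underlying implementation is deterministic, so repeated runs give
    identical basins.
    """
    neg = -suv.values
    structure = ndi.generate_binary_structure(3, connectivity)
    maxima = local_minima(neg, connectivity=connectivity)
    markers, _ = ndi.label(maxima, structure=structure)
    basin = watershed(neg, markers=markers, connectivity=structure)
    return Basins(basin=basin, markers=markers)


def remove_small_regions(
    mask: np.ndarray, spacing, min_region_ml: float, connectivity: int = 3
) -> np.ndarray:
    """Drop connected components with volume < ``min_region_ml`` (strict)."""
    mask = np.asarray(mask, bool)
    if min_region_ml <= 0 or not mask.any():
        return mask.copy()
    voxel_ml = float(np.prod(spacing)) / 1000.0
    structure = ndi.generate_binary_structure(3, connectivity)
    comp, n = ndi.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    counts = np.bincount(comp.ravel())
    small = np.flatnonzero(counts * voxel_ml < min_region_ml)
    small = small[small > 0]
    out = mask.copy()
    if small.size:
        out[np.isin(comp, small)] = False
    return out


def extract_abnormal_region(
    suv: SuvVolume,
    group_bone: BinaryMask,
    full_bone: BinaryMask,
    thr: float,
    config: FocalConfig | None = None,
    basins: Basins | None = None,
) -> BinaryMask:
    """Abnormal bone region for one group: threshold, de-spill, size-filter.

    Candidate voxels are the group's bone voxels with ``SUV > thr``
    (strict).  Candidates whose watershed-basin maximum lies outside the
    *full* skeletal mask (both groups — a peak in another bone is not
    soft-tissue spill-over) are removed, then surviving connected
    components smaller than ``min_region_ml`` are dropped.  An empty result
    is valid and scores TSAU = 0.
    """
    config = config or FocalConfig()
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    candidates = group_bone.voxels & (suv.values > thr)
    if not candidates.any():
        return BinaryMask(candidates, suv.spacing)
    if basins is None:
        basins = watershed_basins(suv, config.connectivity)
    in_bone_ids = np.unique(basins.markers[full_bone.voxels & (basins.markers > 0)])
    keep = candidates & np.isin(basins.basin, in_bone_ids)
    keep = remove_small_regions(keep, suv.spacing, config.min_region_ml, config.connectivity)
    return BinaryMask(keep, suv.spacing)


def compute_msau(suv: SuvVolume, thr: float, abnormal_mask: BinaryMask) -> float:
    """Mean of ``(SUV - THR)^2`` over the abnormal region; 0 when empty."""
    vals = suv.values[abnormal_mask.voxels]
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals - thr) ** 2))


def compute_tsau(msau: float, abnormal_volume_ml: float) -> float:
    """``TSAU = MSAU x abnormal-region volume`` (squared-SUV . mL)."""
    if msau < 0 or abnormal_volume_ml < 0:
        raise ValueError("MSAU and volume must be >= 0")
    return float(msau * abnormal_volume_ml)


def classify_focal(
    spine_tsau: float, other_tsau: float, config: FocalConfig | None = None
) -> bool:
    """Focal uptake iff either group's TSAU exceeds its cut-off (strict)."""
    config = config or FocalConfig()
    return bool(spine_tsau > config.cutoff_spine or other_tsau > config.cutoff_other)


def score_group(
    group: str,
    suv: SuvVolume,
    group_bone: BinaryMask,
    group_marrow: BinaryMask,
    full_bone: BinaryMask,
    config: FocalConfig | None = None,
    basins: Basins | None = None,
) -> GroupScore:
    config = config or FocalConfig()
    thr = compute_threshold(suv, group_marrow, config.sd_multiplier)
    abnormal = extract_abnormal_region(suv, group_bone, full_bone, thr, config, basins)
    msau = compute_msau(suv, thr, abnormal)
    tsau = compute_tsau(msau, abnormal.volume_ml)
    return GroupScore(
        group=group,
        thr=thr,
        abnormal_mask=abnormal,
        abnormal_volume_ml=abnormal.volume_ml,
        msau=msau,
        tsau=tsau,
    )


def score_focal(
    suv: SuvVolume,
    labels: BoneLabelVolume,
    marrow_config: MarrowConfig | None = None,
    config: FocalConfig | None = None,
    marrow: BinaryMask | None = None,
) -> FocalVerdict:
    """Full focal-uptake pipeline on one study.

    Extracts marrow, partitions the skeleton, computes the watershed basins
    once, scores both groups and applies the cut-offs.
    """
    config = config or FocalConfig()
    labels.check_grid(suv)
    if marrow is None:
        marrow = extract_marrow(labels, marrow_config)
    groups = assign_groups(labels, marrow, marrow_config)
    full_bone = labels.bone_mask()
    basins = watershed_basins(suv, config.connectivity)
    spine = score_group("spine", suv, groups.spine, groups.marrow_spine,
                        full_bone, config, basins)
    other = score_group("other", suv, groups.other, groups.marrow_other,
                        full_bone, config, basins)
    return FocalVerdict(
        spine_score=spine,
        other_score=other,
        focal=classify_focal(spine.tsau, other.tsau, config),
    )


# ---------------------------------------------------------------------------
# Cut-off tuning
# ---------------------------------------------------------------------------

class CutoffError(ValueError):
    """No candidate cut-off reaches the NPV constraint."""

    def __init__(self, message: str, best_npv: float):
        super().__init__(message)
        self.best_npv = best_npv


@dataclass
class CutoffResult:
    cutoff: float
    ppv: float
    npv: float
    trace: pd.DataFrame = field(repr=False)


def tune_cutoff(
    scores,
    labels,
    ppv_target: float = 0.65,
    npv_target: float = 0.98,
) -> CutoffResult:
    """Tune a TSAU cut-off on a training cohort.

    Candidate cut-offs are the midpoints between consecutive sorted unique
    scores.  For each, PPV and NPV of the rule ``score > cutoff`` are
    computed; among candidates with ``NPV >= npv_target`` the one whose PPV
    is closest to ``ppv_target`` is returned (ties broken towards higher
    NPV, then towards the lower cut-off).  The full PPV/NPV trace is
    attached for inspection.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(labels, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D sequences")
    if not truth.any() or truth.all():
        raise ValueError("need at least one positive and one negative label")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("all scores identical: no candidate cut-offs")
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    rows = []
    for c in cands:
        pred = scores > c
        tp = int(np.sum(pred & truth))
        fp = int(np.sum(pred & ~truth))
        tn = int(np.sum(~pred & ~truth))
        fn = int(np.sum(~pred & truth))
        ppv = tp / (tp + fp) if (tp + fp) else np.nan
        npv = tn / (tn + fn) if (tn + fn) else np.nan
        rows.append((c, tp, fp, tn, fn, ppv, npv))
    trace = pd.DataFrame(
        rows, columns=["cutoff", "tp", "fp", "tn", "fn", "ppv", "npv"]
    )
    ok = trace[(trace["npv"] >= npv_target) & trace["ppv"].notna()]
    if ok.empty:
        best = float(np.nanmax(trace["npv"])) if trace["npv"].notna().any() else float("nan")
        raise CutoffError(
            f"no cut-off reaches NPV >= {npv_target} (best achievable NPV: {best:.3f})",
            best_npv=best,
        )
    ok = ok.assign(dist=(ok["ppv"] - ppv_target).abs())
    ok = ok.sort_values(["dist", "npv", "cutoff"], ascending=[True, False, True])
    row = ok.iloc[0]
    return CutoffResult(
        cutoff=float(row["cutoff"]),
        ppv=float(row["ppv"]),
        npv=float(row["npv"]),
        trace=trace,
    )
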