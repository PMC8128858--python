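"""Diffuse bone-marrow uptake: the spine/liver SUV index.

Diffuse bone-marrow uptake is quantified as the ratio of the median SUV in
the vertebral bone marrow (vertebrae, sacrum, coccyx marrow — hip-bone
voxels that the sacroiliac rule pulls into the spine *group* are excluded
from this median) to the median SUV in the liver.  The median, rather than
the maximum, keeps focal lesions from dominating the statistic.  An index
strictly greater than 1.0 classifies the patient as having high diffuse
uptake.

The liver median is taken over the liver label eroded by a configurable
5 mm margin, mirroring the "excluding the edges" placement of a manual
liver ROI.  :func:`manual_roi_index` emulates the manual quality-control
procedure (a small ROI in the L3/L4 marrow and one in the upper right
liver); :func:`bland_altman` provides the method-comparison statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import LIVER, SPINE_CLASSES
from .marrow import MarrowConfig, erode_mask_mm, extract_marrow
from .volumes import BinaryMask, BoneLabelVolume, SuvVolume


@dataclass
class DiffuseConfig:
    #: erosion applied to the liver label before taking its median, mm
    liver_margin_mm: float = 5.0


@dataclass
class DiffuseResult:
    spine_marrow_median: float
    liver_median: float
    index: float
    high: bool


@dataclass
class RoiSpec:
    """A manually-placed region of interest in physical coordinates.

    ``extent_mm`` is the radius for a sphere, the half-edge for a box.
    """

    center_mm: tuple[float, float, float]
    shape: str = "sphere"
    extent_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "box"):
            raise ValueError(f"ROI shape must be 'sphere' or 'box', got {self.shape!r}")
        if self.extent_mm <= 0:
            raise ValueError("ROI extent must be > 0")


def _as_bool(mask) -> np.ndarray:
    return mask.voxels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)


def compute_diffuse_index(
    suv: SuvVolume,
    spine_marrow: BinaryMask | np.ndarray,
    liver: BinaryMask | np.ndarray,
) -> DiffuseResult:
    """Median spine-marrow SUV over median liver SUV, dichotomized at 1.0.

    Both medians use the even-count midpoint convention; ``high`` is True
    only for an index strictly greater than 1.0.
    """
    sm = _as_bool(spine_marrow)
    lv = _as_bool(liver)
    if not sm.any():
        raise ValueError("empty spine-marrow mask: diffuse index undefined")
    if not lv.any():
        raise ValueError("empty liver mask: diffuse index undefined")
    m_spine = float(np.median(suv.values[sm]))
    m_liver = float(np.median(suv.values[lv]))
    if m_liver == 0:
        raise ValueError("liver median is 0: diffuse index undefined")
    index = m_spine / m_liver
    return DiffuseResult(
        spine_marrow_median=m_spine,
        liver_median=m_liver,
        index=index,
        high=bool(index > 1.0),
    )


def diffuse_from_labels(
    suv: SuvVolume,
    labels: BoneLabelVolume,
    marrow: BinaryMask | None = None,
    marrow_config: MarrowConfig | None = None,
    config: DiffuseConfig | None = None,
) -> DiffuseResult:
    """Automated diffuse index from a label volume.

    Derives the marrow mask (unless supplied), restricts it to vertebrae,
    sacrum and coccyx, erodes the liver by the configured margin, and
    computes the index.
    """
    config = config or DiffuseConfig()
    labels.check_grid(suv)
    if marrow is None:
        marrow = extract_marrow(labels, marrow_config)
    vertebral = labels.mask_for_classes(SPINE_CLASSES).voxels & marrow.voxels
    liver = labels.mask_for_classes([LIVER]).voxels
    if not liver.any():
        raise ValueError("no liver label present")
    liver_core = erode_mask_mm(liver, labels.spacing, config.liver_margin_mm)
    if not liver_core.any():
        raise ValueError(
            f"liver empty after {config.liver_margin_mm} mm erosion; "
            "reduce liver_margin_mm"
        )
    return compute_diffuse_index(suv, vertebral, liver_core)


def roi_mask(suv: SuvVolume, roi: RoiSpec) -> BinaryMask:
    """Voxels whose centers fall inside the ROI; errors if none do."""
    coords = [
        o + np.arange(n) * s
        for o, n, s in zip(suv.origin, suv.shape, suv.spacing)
    ]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]
    cx, cy, cz = roi.center_mm
    if roi.shape == "sphere":
        inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= roi.extent_mm ** 2
    else:
        inside = (
            (np.abs(x - cx) <= roi.extent_mm)
            & (np.abs(y - cy) <= roi.extent_mm)
            & (np.abs(z - cz) <= roi.extent_mm)
        )
    if not inside.any():
        raise ValueError(f"ROI at {roi.center_mm} does not intersect the volume")
    return BinaryMask(inside, suv.spacing)


def manual_roi_index(
    suv: SuvVolume, marrow_roi: RoiSpec, liver_roi: RoiSpec
) -> DiffuseResult:
    """Diffuse index from two manually-placed ROIs (L3/L4 marrow, liver).

    Same computation as :func:`compute_diffuse_index`, over the small ROI
    voxel sets (cm^3-scale) instead of the whole-organ masks.
    """
    return compute_diffuse_index(
        suv, roi_mask(suv, marrow_roi), roi_mask(suv, liver_roi)
    )


@dataclass
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    n: int


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland–Altman agreement between two paired index series (a − b).

    Limits of agreement are mean ± 1.96 × SD of the paired differences
    (sample SD, ddof = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=mean,
        sd_difference=sd,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
        n=int(a.size),
    )


def plot_bland_altman(a, b, path=None, ax=None):
    """Bland–Altman scatter (mean vs difference) with the limits of agreement."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(a, b)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2, a - b, s=18)
    for y, style in ((res.mean_difference, "-"), (res.loa_lower, "--"), (res.loa_upper, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (a - b)")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return res
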