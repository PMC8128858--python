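"""Synthetic FDG-PET phantoms with known ground truth.

The phantom emulates the statistical structure the focal detector assumes
in a whole-body staging scan: a labelled geometric skeleton (vertebral
column with sacrum and coccyx, hip-bone blobs at a configurable distance
from the spine, femora, humeri, rib tubes, sternum, scapulae, clavicles), a
liver ellipsoid, Gaussian marrow and liver uptake, a cortical shell at
lower uptake, soft-tissue background noise, spherical focal lesions added
as plateaus, and a Gaussian point-spread blur applied to the whole volume.
Hot nodes placed just outside a bone therefore leak realistic spill-over
into it — exactly the artefact the watershed step must remove.

Default grid: 96 x 96 x 192 voxels at 3 mm isotropic (a typical PET
reconstruction scale); default marrow uptake Normal(1.5, 0.2) clipped at
0, liver Normal(2.0, 0.2), so the default diffuse index sits at 0.75
(low).  Everything is deterministic for a fixed seed.

A :class:`TruthManifest` accompanies each phantom: per-lesion true and
post-blur suprathreshold volumes (at the stated reference threshold
mu_marrow + 2 sigma_marrow), per-group reference TSAU computed by direct
voxel summation (independent of the watershed pipeline), the analytic
diffuse index, and the expected verdicts under the default cut-offs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .agreement import RatingMatrix
from .focal import FocalConfig
from .marrow import MarrowConfig, assign_groups, extract_marrow
from .volumes import BinaryMask, BoneLabelVolume, SuvVolume

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Lesion:
    """A spherical uptake focus (plateau before the PSF blur)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    peak_suv: float
    inside_bone: bool = True

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be > 0")
        if self.peak_suv < 0:
            raise ValueError("lesion peak SUV must be >= 0")

    @property
    def true_volume_ml(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius_mm ** 3 / 1000.0


@dataclass
class PhantomSpec:
    """Parameters of the synthetic study."""

    shape: tuple[int, int, int] = (96, 96, 192)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mu_marrow: float = 1.5
    sigma_marrow: float = 0.2
    mu_liver: float = 2.0
    sigma_liver: float = 0.2
    soft_tissue_suv: float = 0.7
    soft_tissue_sd: float = 0.1
    cortical_suv: float = 1.0
    cortical_sd: float = 0.1
    psf_fwhm_mm: float = 6.0
    #: gap (mm) between the sacrum surface and the inner edge of each
    #: hip-bone blob; at 7 mm part of the hip falls inside the 50 mm
    #: sacroiliac shell, at > 50 mm the whole hip bone is "other"
    hip_gap_mm: float = 7.0
    lesions: tuple[Lesion, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_marrow", "sigma_marrow", "mu_liver", "sigma_liver",
                     "soft_tissue_suv", "soft_tissue_sd", "cortical_suv",
                     "cortical_sd", "psf_fwhm_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.lesions = tuple(
            l if isinstance(l, Lesion) else Lesion(**l) for l in self.lesions
        )


@dataclass
class LesionTruth:
    center_mm: tuple[float, float, float]
    radius_mm: float
    peak_suv: float
    inside_bone: bool
    group: str | None
    true_volume_ml: float
    #: post-blur volume above the stated threshold, connected to the center
    suprathreshold_volume_ml: float


@dataclass
class TruthManifest:
    """Ground truth recomputed from the post-blur volume."""

    thr_stated: float
    lesions: list[LesionTruth]
    #: reference per-group TSAU at thr_stated, by direct voxel summation
    spine_tsau_ref: float
    other_tsau_ref: float
    expected_focal: bool
    true_diffuse_index: float
    expected_high_diffuse: bool

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

class OverlapError(ValueError):
    """Two labelled structures claim the same voxel."""


def _coords(spec: PhantomSpec):
    x = spec.origin[0] + np.arange(spec.shape[0]) * spec.spacing[0]
    y = spec.origin[1] + np.arange(spec.shape[1]) * spec.spacing[1]
    z = spec.origin[2] + np.arange(spec.shape[2]) * spec.spacing[2]
    return x[:, None, None], y[None, :, None], z[None, None, :]


def _cylinder_z(x, y, z, cx, cy, z0, z1, r):
    return ((x - cx) ** 2 + (y - cy) ** 2 <= r ** 2) & (z >= z0) & (z <= z1)


def _tube_x(x, y, z, x0, x1, cy, cz, r):
    return ((y - cy) ** 2 + (z - cz) ** 2 <= r ** 2) & (x >= x0) & (x <= x1)


def _ellipsoid(x, y, z, c, semi):
    return (
        ((x - c[0]) / semi[0]) ** 2
        + ((y - c[1]) / semi[1]) ** 2
        + ((z - c[2]) / semi[2]) ** 2
    ) <= 1.0


def _sphere(x, y, z, c, r):
    return _ellipsoid(x, y, z, c, (r, r, r))


def build_skeleton(spec: PhantomSpec) -> BoneLabelVolume:
    """Labelled geometric skeleton and liver on the spec's grid.

    Positions are fixed in physical mm (designed for the default
    288 x 288 x 576 mm field of view); structures extending past a smaller
    grid are clipped at the boundary.  Overlapping structures raise
    :class:`OverlapError`.
    """
    x, y, z = _coords(spec)
    cx = cy = 144.0  # body axis of the default field of view
    hip_off = 18.0 + spec.hip_gap_mm + 30.0  # sacrum radius + gap + hip semi-axis

    structures: list[tuple[str, np.ndarray]] = []
    structures.append(("femur_left", _cylinder_z(x, y, z, cx - 60, cy, 20, 150, 12)))
    structures.append(("femur_right", _cylinder_z(x, y, z, cx + 60, cy, 20, 150, 12)))
    structures.append(
        ("hip_bone_left", _ellipsoid(x, y, z, (cx - hip_off, cy, 180), (30, 24, 27)))
    )
    structures.append(
        ("hip_bone_right", _ellipsoid(x, y, z, (cx + hip_off, cy, 180), (30, 24, 27)))
    )
    structures.append(("sacrum", _cylinder_z(x, y, z, cx, cy, 160, 200, 18)))
    structures.append(("coccyx", _sphere(x, y, z, (cx, cy, 150), 8)))
    for i in range(12):
        z0 = 206 + 26 * i
        structures.append(
            (f"vertebra_{i + 1}", _cylinder_z(x, y, z, cx, cy, z0, z0 + 20, 15))
        )
    structures.append(("sternum", (np.abs(x - cx) <= 10) & (y >= 84) & (y <= 94)
                       & (z >= 360) & (z <= 440)))
    for j, zc in enumerate((350, 380, 410, 440)):
        structures.append(
            (f"rib_left_{j + 1}", _tube_x(x, y, z, 40, 110, 104, zc, 5.5))
        )
        structures.append(
            (f"rib_right_{j + 1}", _tube_x(x, y, z, 178, 248, 104, zc, 5.5))
        )
    structures.append(("clavicle_left", _tube_x(x, y, z, 90, 140, 110, 520, 5)))
    structures.append(("clavicle_right", _tube_x(x, y, z, 148, 198, 110, 520, 5)))
    structures.append(
        ("scapula_left", _ellipsoid(x, y, z, (cx - 70, 174, 480), (22, 7, 28)))
    )
    structures.append(
        ("scapula_right", _ellipsoid(x, y, z, (cx + 70, 174, 480), (22, 7, 28)))
    )
    structures.append(("humerus_left", _cylinder_z(x, y, z, cx - 85, cy, 380, 520, 10)))
    structures.append(("humerus_right", _cylinder_z(x, y, z, cx + 85, cy, 380, 520, 10)))
    structures.append(("liver", _ellipsoid(x, y, z, (205, 100, 280), (55, 40, 45))))

    labels = np.zeros(spec.shape, dtype=np.int16)
    taxonomy: dict[int, str] = {}
    for i, (name, mask) in enumerate(structures, start=1):
        clash = mask & (labels != 0)
        if clash.any():
            other = taxonomy[int(labels[clash][0])]
            raise OverlapError(f"structures {name!r} and {other!r} overlap")
        labels[mask] = i
        taxonomy[i] = name
    return BoneLabelVolume(labels, taxonomy, spec.spacing, spec.origin)


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def _center_index(spec: PhantomSpec, center_mm) -> tuple[int, int, int]:
    idx = tuple(
        int(round((c - o) / s))
        for c, o, s in zip(center_mm, spec.origin, spec.spacing)
    )
    for i, n in zip(idx, spec.shape):
        if i < 0 or i >= n:
            raise ValueError(f"lesion center {center_mm} falls outside the grid")
    return idx


def generate_phantom(
    spec: PhantomSpec | None = None, seed: int | None = None
) -> tuple[SuvVolume, BoneLabelVolume, TruthManifest]:
    """Generate the SUV volume, label volume and truth manifest.

    Deterministic for a fixed seed (``seed`` overrides ``spec.seed``).
    Uptake is drawn per compartment (marrow core as carved by the standard
    per-bone erosion, cortical shell, liver, soft tissue), clipped at 0,
    lesions are stamped as spherical plateaus (``max`` with the underlying
    field), and the whole volume is then convolved with the Gaussian PSF.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = build_skeleton(spec)

    lesion_idx = [_center_index(spec, l.center_mm) for l in spec.lesions]

    bone = labels.bone_mask().voxels
    liver = labels.liver_mask().voxels
    marrow_core = extract_marrow(labels, MarrowConfig()).voxels
    shell = bone & ~marrow_core

    values = rng.normal(spec.soft_tissue_suv, spec.soft_tissue_sd, spec.shape)
    values[shell] = rng.normal(spec.cortical_suv, spec.cortical_sd, int(shell.sum()))
    values[marrow_core] = rng.normal(
        spec.mu_marrow, spec.sigma_marrow, int(marrow_core.sum())
    )
    values[liver] = rng.normal(spec.mu_liver, spec.sigma_liver, int(liver.sum()))
    np.clip(values, 0.0, None, out=values)

    x, y, zc = _coords(spec)
    for lesion, idx in zip(spec.lesions, lesion_idx):
        if bool(bone[idx]) != lesion.inside_bone:
            where = "inside" if bone[idx] else "outside"
            raise ValueError(
                f"lesion at {lesion.center_mm} is {where} bone but declared "
                f"inside_bone={lesion.inside_bone}"
            )
        mask = _sphere(x, y, zc, lesion.center_mm, lesion.radius_mm)
        values[mask] = np.maximum(values[mask], lesion.peak_suv)

    if spec.psf_fwhm_mm > 0:
        sigma_vox = [
            spec.psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in spec.spacing
        ]
        values = ndi.gaussian_filter(values, sigma=sigma_vox)

    suv = SuvVolume(values, spec.spacing, spec.origin)
    manifest = _build_manifest(spec, suv, labels, lesion_idx)
    return suv, labels, manifest


def _build_manifest(
    spec: PhantomSpec,
    suv: SuvVolume,
    labels: BoneLabelVolume,
    lesion_idx: list[tuple[int, int, int]],
) -> TruthManifest:
    thr = spec.mu_marrow + 2.0 * spec.sigma_marrow
    bone = labels.bone_mask().voxels
    vv = suv.voxel_volume_ml
    supra = suv.values > thr
    structure = np.ones((3, 3, 3), dtype=bool)
    comp_bone, _ = ndi.label(supra & bone, structure=structure)
    comp_any, _ = ndi.label(supra, structure=structure)
    counts_bone = np.bincount(comp_bone.ravel())

    marrow = extract_marrow(labels, MarrowConfig())
    try:
        groups = assign_groups(labels, marrow, MarrowConfig())
        spine_vox = groups.spine.voxels
    except ValueError:  # spine absent on a heavily clipped grid
        spine_vox = np.zeros(spec.shape, dtype=bool)

    truths: list[LesionTruth] = []
    group_components: dict[str, set[int]] = {"spine": set(), "other": set()}
    for lesion, idx in zip(spec.lesions, lesion_idx):
        if lesion.inside_bone:
            group = "spine" if spine_vox[idx] else "other"
            cid = int(comp_bone[idx])
            vol = float(counts_bone[cid] * vv) if cid > 0 else 0.0
            if cid > 0:
                group_components[group].add(cid)
        else:
            group = None
            cid = int(comp_any[idx])
            vol = float(np.sum(comp_any == cid) * vv) if cid > 0 else 0.0
        truths.append(
            LesionTruth(
                center_mm=tuple(lesion.center_mm),
                radius_mm=lesion.radius_mm,
                peak_suv=lesion.peak_suv,
                inside_bone=lesion.inside_bone,
                group=group,
                true_volume_ml=lesion.true_volume_ml,
                suprathreshold_volume_ml=vol,
            )
        )

    tsau_ref = {"spine": 0.0, "other": 0.0}
    for group, cids in group_components.items():
        if cids:
            sel = np.isin(comp_bone, sorted(cids))
            tsau_ref[group] = float(
                np.sum((suv.values[sel] - thr) ** 2) * vv
            )

    cfg = FocalConfig()
    index = spec.mu_marrow / spec.mu_liver if spec.mu_liver > 0 else float("nan")
    return TruthManifest(
        thr_stated=float(thr),
        lesions=truths,
        spine_tsau_ref=tsau_ref["spine"],
        other_tsau_ref=tsau_ref["other"],
        expected_focal=bool(
            tsau_ref["spine"] > cfg.cutoff_spine or tsau_ref["other"] > cfg.cutoff_other
        ),
        true_diffuse_index=float(index),
        expected_high_diffuse=bool(index > 1.0),
    )


# ---------------------------------------------------------------------------
# Rater fixtures
# ---------------------------------------------------------------------------

def make_rating_fixture(
    n_cases: int,
    n_observers: int,
    flip_prob: float | np.ndarray = 0.1,
    seed: int = 0,
    p_focal: float = 14 / 48,
    p_diffuse: float = 32 / 48,
) -> tuple[RatingMatrix, pd.DataFrame]:
    """Simulated four-category ratings against a latent truth.

    Each case has a latent (focal, diffuse) truth drawn with the given
    prevalences; each observer independently flips each bit with their flip
    probability (scalar = shared by all observers).  Returns the rating
    matrix and the latent truth (columns ``focal``, ``diffuse``).
    """
    if n_cases < 1 or n_observers < 1:
        raise ValueError("need at least one case and one observer")
    fp = np.broadcast_to(np.asarray(flip_prob, dtype=float), (n_observers,)).copy()
    if ((fp < 0) | (fp > 1)).any():
        raise ValueError("flip probabilities must be in [0, 1]")
    if not 0 <= p_focal <= 1 or not 0 <= p_diffuse <= 1:
        raise ValueError("prevalences must be in [0, 1]")
    rng = np.random.default_rng(seed)
    focal = rng.random(n_cases) < p_focal
    diffuse = rng.random(n_cases) < p_diffuse
    data = {}
    for o in range(n_observers):
        f = focal ^ (rng.random(n_cases) < fp[o])
        d = diffuse ^ (rng.random(n_cases) < fp[o])
        data[f"observer_{o + 1}"] = 1 + f.astype(int) + 2 * d.astype(int)
    ratings = pd.DataFrame(
        data, index=pd.Index([f"case_{i + 1}" for i in range(n_cases)], name="case")
    )
    truth = pd.DataFrame(
        {"focal": focal, "diffuse": diffuse}, index=ratings.index
    )
    return RatingMatrix(ratings), truth
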