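# Methods

This note records the model implemented by `bmupet`, the choices made
where the procedure admits more than one faithful reading, and what the
synthetic phantoms do and do not establish.

## Inputs and geometry

The pipeline consumes a 3-D SUV volume and an integer label volume naming
individual bones and the liver, on the *same* grid. No resampling is ever
performed: a shape or spacing mismatch is an error, because any
interpolation choice would silently shift every downstream statistic.
Voxels are indexed internally; every physical quantity (erosion margins,
the 50 mm sacroiliac radius, region volumes) is computed in mm/mL from
the per-axis spacing, so anisotropic grids are handled exactly.

Taxonomy names come from a controlled vocabulary (`vertebra`, `sacrum`,
`coccyx`, `hip_bone`, `humerus`, `scapula`, `clavicle`, `rib`, `sternum`,
`femur`, `liver`), optionally qualified (`vertebra_L3`, `hip_bone_left`);
the class determines the erosion margin and the grouping.

## Marrow definition

Marrow is carved out of **each individual bone label** by Euclidean
erosion: a voxel survives when its distance to the nearest voxel outside
that bone is ≥ the class margin (7 mm humeri/femora, 5 mm vertebrae/hip
bones, 3 mm otherwise). Consequences of this definition:

* boundaries between touching bones count as edges, so marrow never
  bleeds across joints;
* voxels exactly at the margin survive (`≥`, a documented tie-break);
* the grid boundary is treated as exterior — a femur cut by the field of
  view erodes at the cut;
* a bone whose inradius is below its margin contributes nothing, without
  error.

The spine group is vertebrae ∪ sacrum ∪ coccyx plus hip-bone voxels
whose nearest-voxel distance to that set is ≤ 50 mm (inclusive). The
rule is applied voxelwise; the reference set is the union of spine-class
voxels, the simplest reading of "within 50 mm from these locations".

## Focal detector

Per group, `THR = mean + 2·SD` over the group's marrow, with the
**population** SD (ddof = 0). With marrow sets of thousands of voxels the
sample/population difference is far below every tolerance used here; the
choice is fixed for bit-reproducibility. The threshold pass is
non-iterative: lesion voxels inside the marrow mask inflate the mean/SD
slightly, which makes the detector mildly conservative for very large
lesions (visible in the worked example, where the spine THR rises from
≈1.54 to ≈2.31 because the injected lesion overlaps spine marrow).

The abnormal region is built in three ordered steps:

1. candidates: group-bone voxels with `SUV > THR` (strict);
2. spill-over removal: the watershed of the *negated* SUV is computed
   over the whole volume, seeded by the regional maxima of SUV
   (equal-valued plateaus are merged into one seed; the flooding order is
   deterministic). A candidate is removed when its basin's maximum
   plateau has no voxel inside the **full** skeletal mask — a maximum in
   another bone is genuine bone uptake, not soft-tissue spill-over;
3. size filter: 26-connected components (configurable neighbourhood
   order) with volume < 0.1 mL (strict) are dropped. The filter is
   idempotent.

MSAU is the mean of `(SUV − THR)²` pooled over all surviving components
of a group (one region per group); an empty region has MSAU = 0 by
convention so that TSAU = 0 without special-casing. TSAU = MSAU × region
volume, algebraically identical to the voxel sum of
`(SUV − THR)² × voxel volume`. Focal uptake ⇔ spine TSAU > 0.5 or
other-bones TSAU > 3.0, strictly.

`tune_cutoff` reproduces the cut-off calibration for new cohorts: the
candidate family is the midpoints between consecutive sorted unique
training scores; among candidates meeting the NPV floor (default 0.98)
the one with PPV closest to the target (default 0.65) is returned, ties
broken towards higher NPV then the lower cut-off, with the full trace
attached. No candidate meeting the NPV floor is an error that carries
the best achievable NPV.

## Diffuse index

The automated index is the median SUV over the **vertebral** marrow
(vertebra/sacrum/coccyx marrow only — hip-bone voxels that the 50 mm rule
pulls into the spine *group* are excluded, since the quantity is defined
on the vertebral marrow) divided by the median SUV over the liver label
eroded by 5 mm. The liver margin is configurable; 5 mm mirrors the
mid-size bone margin and the "excluding the edges" placement of manual
liver ROIs, and whole-liver medians are insensitive to it. Medians use
the even-count midpoint convention. High diffuse uptake ⇔ index > 1.0,
strictly, so an index of exactly 1.0 is low.

`manual_roi_index` runs the same computation over two small ROIs
(sphere or box, in physical mm), emulating the L3/L4-plus-liver manual
quality-control procedure; `bland_altman` compares the two methods
(mean difference ± 1.96 × SD of differences, sample SD with ddof = 1).

## Agreement statistics

Cohen's κ is the two-rater, two-category form `(Po − Pe)/(1 − Pe)` with
product-of-marginals Pe; multi-rater (Fleiss) κ is out of scope because
the evaluation design reports pairwise values with a mean and range.
κ is undefined exactly when both raters are constant and identical
(Pe = 1); such pairs are flagged and excluded from means with an explicit
count, never coerced to 0 or 1. Display rounding is two decimals,
half-up. Interpretation bands use the conventional closed intervals
(≤ 0.20 slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80
substantial, 0.81–1 almost perfect; < 0 no agreement). Majority votes are
strict; exact splits are reported as ties and excluded from the
denominator of the agreement proportion rather than resolved.

## Phantom

The phantom emulates what the detector assumes about a staging scan, not
anatomy: labelled geometric primitives (cylindrical vertebrae, hip-bone
ellipsoids at a configurable gap from the sacrum so the sacroiliac rule
is exercised on both sides of 50 mm, long-bone tubes, rib tubes, sternum,
scapulae, clavicles, liver ellipsoid) on a default 96×96×192 grid at 3 mm
isotropic spacing (≈ PET reconstruction scale; anisotropy configurable).
Structure positions are fixed in physical mm and are clipped by smaller
fields of view.

Uptake is drawn per compartment — marrow core Normal(1.5, 0.2) (the core
is carved with the same erosion the pipeline uses), cortical shell
Normal(1.0, 0.1), liver Normal(2.0, 0.2), soft tissue Normal(0.7, 0.1) —
clipped at 0. Lesions are spherical plateaus (`max` with the underlying
field); the **whole volume** is then convolved with a Gaussian PSF
(default FWHM 6 mm), which is what creates genuine spill-over skirts from
extra-skeletal nodes. The detector contains no PSF model; it only removes
spill-over. The default marrow/liver means put the true diffuse index at
0.75 (low).

The truth manifest is recomputed from the post-blur volume: per-lesion
suprathreshold volumes and per-group reference TSAU at the stated
threshold μ + 2σ, by direct voxel summation with no watershed — an
independent route against which the detector is compared.

Deliberate simplifications: no attenuation or reconstruction noise
texture (noise is i.i.d. Gaussian before the blur), no irregular lesion
shapes, no degenerative or brown-fat uptake mimics, no anatomical
variability. Passing tests therefore demonstrate correctness of the
*computational* pipeline under its stated model, not reader-level
performance on clinical images — reproducing the clinical endpoint rates
(e.g. positive fractions or physician-vs-method agreement) requires the
original images and readers.

## Verification conditions and problem sizes

* **Threshold recovery** is checked on phantoms generated *without* PSF
  blur: the voxel-level marrow distribution is Normal(μ, σ) only before
  smoothing, so μ + 2σ = 1.9 is the analytic target for the unblurred
  field (20 seeds, observed max error ≈ 0.01 ≪ 0.05).
* **Spill-over discrimination** uses the default blurred phantom with a
  0.9 mL in-vertebra lesion and an equal hot node 3 mm outside another
  vertebra, 20 seeds; success means no abnormal voxel within 15 mm of the
  node and detection at the lesion.
* **Size filter** and the **strict diffuse dichotomy** are checked on
  noise-free, blur-free phantoms, which isolate the rule under test and
  make the expected outcome exact (a 0.05 mL sphere voxelizes below the
  0.1 mL filter at 3 mm spacing; a 0.2 mL sphere above it).
* **Erosion** is cross-checked voxel-exactly against an independent
  nearest-exterior-voxel distance computation (k-d tree) on a 10 mm
  digital sphere with a 3 mm margin, isotropic and anisotropic.
* **κ/PA** are verified against the published observer-pair tables and,
  property-wise, against scikit-learn's independent implementation on
  random tables.

Grid sizes and seed counts above were chosen to make the full suite run
in a few minutes while keeping every Monte-Carlo tolerance at least
several standard errors wide.

## Known limitations

* The CNN segmentations that produce bone/liver masks clinically are out
  of scope; mask quality directly bounds the pipeline's validity.
* The non-iterative THR makes TSAU mildly self-censoring for massive
  marrow involvement (high tumour burden raises the threshold).
* The watershed neighbourhood (default 26-connectivity) and the merged
  plateau seeding are implementation choices; different connectivity can
  reassign boundary voxels of near-flat skirts.
* The vertebral-vs-spine-group median and the 5 mm liver margin are
  documented choices where the procedure is underspecified; both are
  configurable and flagged for sensitivity analysis on real data.
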