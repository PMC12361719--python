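# Methods

This note documents the models, conventions and numerical choices behind
`mtlseg`: what the pipeline computes, what the phantom generator does and
does not emulate, and where genuinely open design questions were decided.

## Coordinate conventions

All per-slice geometry lives on an open polyline tracing the pial surface
of one coronal section in a canonical frame: first coordinate increasing
laterally, second increasing superiorly, vertices ordered from the medial
terminus of the parahippocampal gyrus (PHG) to the lateral terminus beyond
the fusiform gyrus (FG). Opposite-hemisphere contours are mirrored into
this frame upstream (`geometry.canonicalize`); arc lengths, and hence all
landmarks and distances, are mirror-invariant. The axial coordinate is
millimetres anterior to the anterior tip of the hippocampus (positive =
anterior), matching the coronal plane convention of hippocampal-subfield
protocols (perpendicular to the hippocampal long axis).

The fundamental per-slice coordinate is cumulative arc length from the
medial terminus. Border positions, landmark positions and all distances
are arc-length (on-ribbon) quantities, not Euclidean chords: borders live
on the cortical ribbon, and a distance "along the cortex" is what a tracer
measures with a curvature tool. Fractional landmarks ("halfway point of
the medial bank", "1/4th of the lateral bank", crown midpoints) are
likewise arc-length fractions. No published operational definition exists
for these fractions; arc length was chosen once, for the reason above, and
an independent dense-resampling oracle in the test suite pins the
implementation to 1e-6 mm.

Landmark vocabulary (medial to lateral): superior PHG edge, PHG crown
midpoint (arc midpoint superior edge → medial CS mouth), medial CS edge,
medial-bank halfway point, CS fundus, lateral-bank quarter point (closest
quarter to the fundus), fundus–FG midpoint, FG crown midpoint (arc
midpoint lateral CS mouth → lateral terminus, which the phantom places at
the medial mouth of the next sulcus).

**CS depth** is the Euclidean distance from the fundus vertex to the
midpoint of the chord joining the two sulcal mouths; the prior convention
it follows is cited without a formula in the source literature, and the
fundus-to-mouth-chord distance is the natural reading. A sulcus is
*shallow* below 7.0 mm and *deep* at or above it — "below 7 mm" is read
strictly, so exactly 7.0 mm classifies as deep.

## The rule table

The protocol is a structural template with estimated parameters. Fixed
structure (per reference level 10, 9, 7, 5, 4, 2.5 mm anterior): which
landmark anchors which border, which borders are shared between adjacent
regions (BA35 medial = ERC lateral and BA36 medial = BA35 lateral wherever
the medial neighbour exists), and where the BA35 medial flank wraps the
ERC. Estimated parameters: the three region start distances (slice-grid
quantization of the median anterior-extent distance to the chosen anchor)
and the three offset-bearing BA35 medial cells (whole-millimetre rounding
of the median signed border distance to the superior PHG edge at the 9, 7
and 5 mm levels).

Numerical choices, inferred from the three printed quantizations and
applied uniformly because no rounding rule is stated anywhere: starts snap
to the nearest grid multiple and offsets to the nearest whole millimetre,
ties rounding away from zero; SDs use the sample (n−1) formula; the median
of an even-sized cell is the midpoint of the central pair.

Two documented tensions in the source material are handled explicitly:

- **BA36 medial at the 10 mm level.** The printed protocol grid says
  "lateral bank", but the running text and the measurement table feeding
  that cell both say the halfway point of the *medial* bank. The emitted
  rule uses the medial bank; the grid entry is treated as a typo.
- **Offset direction wording.** The measurement sign convention defines
  negative as medial of the landmark, yet two of the three BA35 medial
  medians are positive (lateral) while the protocol grid words all three
  offsets as "medial to the superior PHG edge". The default
  (`offset_direction_mode="table_wording"`) records the grid wording —
  the protocol grid is the deliverable — while the conflicting measured
  medians and signs are preserved in the table's provenance and surfaced
  in the derivation report. `"measured_sign"` derives the direction from
  the median's sign instead; both behaviours are tested.

**Anchor selection** ranks candidate anchor structures by the sum of
between-case SDs of the region-to-anchor extent distances across the three
regions and, among the top two, prefers the one that is easy to identify
on MRI (the amygdala's anterior tip typically wins on raw SD but is hard
to localize, so the hippocampus tip is the expected choice). Fully
degenerate ties (all-zero SDs in noise-free cohorts) resolve by a fixed
canonical preference order, keeping selection invariant to input order.

## The segmentation engine

Given a rule table and the landmark set of a slice, the engine resolves
every border to an arc-length position (offsets walked medially = −s,
laterally = +s; positions clamped to the contour domain with a logged
warning, never wrapped) and assembles the slice into an ordered partition
`[BA35 flank?][ERC][BA35][BA36]` with exactly shared endpoints. Inverted
intervals raise a degenerate-slice error naming the pair.

Dispatch generalizes the six printed columns to arbitrary grids:

- cells encoding *anterior-most-slice* behaviour (ERC medial at the PHG
  crown midpoint, the BA36 bank-based cells, the flank) apply on the first
  — or, for the BA36 lateral transition cell, second — slice on which the
  region is labeled, in grid space rather than at a literal millimetre
  mark (on the default grid these coincide: 10.4 mm is the first and
  9.1 mm the second BA36 slice);
- remaining cells are selected by nearest reference level, equidistant
  ties resolving posterior (the protocol is anchored posteriorly on the
  hippocampus);
- adjacency overrides make the shared borders structural: wherever the
  medial neighbour is present its lateral border *is* the region's medial
  border, so the partition invariant cannot be violated numerically;
- when BA35 exists on a slice without an ERC, its medial border follows
  the level-wise offset track (7 → 10 → 5 mm medial of the superior PHG
  edge); the level-5 value is carried by the flank cell because the
  primary level-5 cell defers to the (absent) ERC.

Labels run from a posterior bound — default 2.6 mm, the first slice
strictly anterior to the 1.3 mm start of the pre-existing posterior atlas
labels — to each region's start; blank protocol columns are region
absence. The engine is fully deterministic.

**Rasterization** paints each labeled interval as a band of configurable
ribbon thickness centred on its piece of contour (flat end caps, so a
straight L-mm interval covers L × thickness of area), assigning voxels
first-come in medial-to-lateral order so adjacent intervals never
double-label; exports are NIfTI volumes plus an ITK-SNAP label-description
file with pinned codes and colours (ERC green, BA35 light blue, BA36 dark
blue).

## The phantom generator

The generator emulates the *statistical* structure the analysis depends
on, not the appearance of tissue:

- **Anterior extents** per region are sampled from location–scale
  distributions matched to the published medians and between-case SDs
  (ERC 4.75/1.58, BA35 9.25/2.60, BA36 10.25/3.84 mm vs the hippocampus
  tip). The default residual is a shifted normal; because the published
  means and medians differ, a skew-normal residual (re-matched to the
  target median and SD) is available per region via `ExtentSpec.skew`.
  Non-positive draws are rejected (100-attempt budget, then a config
  error).
- **Anchor structures** are scalar axial positions: amygdala tip 4 mm
  anterior of the hippocampus tip (its average position relative to the
  reference levels), temporal pole 26.5 mm, limen insulae 5.5 mm,
  CS anterior tip 19.5 mm, each with its own positional SD chosen to
  reproduce the published ordering of distance SDs. A shared per-case
  anterior shift (SD 0.5 mm, included in the stated total extent SDs) is
  added to all extents and to all non-hippocampal anchors; anchor-relative
  distances partially cancel it, which is what places the amygdala's
  distance SDs slightly below the hippocampus-relative ones while the
  distant anchors stay clearly noisier. Reported distance signs follow a
  per-anchor convention (`region_minus_anchor` vs `anchor_minus_region`),
  exposed in the config because the published sign conventions differ by
  anchor (the limen rows are negative for BA35/BA36).
- **Contours** are schematic piecewise quadratic Béziers through the
  medial PHG wall (≥ 12.5 mm of arc, so medial offsets to 10 mm stay
  on-contour), PHG crown, the two CS banks meeting at a fundus whose
  chord-depth equals the case's sampled CS depth, and the FG crown. Depth
  classes are half shallow / half deep by default (Bernoulli per case;
  a stratified option gives exact counts), with depth sampled from
  truncated normals on either side of 7 mm and held constant along the
  stack — consistent with the class at the hippocampus-tip slice.
  Disease status is a pure label (11/20 by default) with no geometric
  effect, providing a true null grouping.
- **Ground-truth borders** reuse the engine's own per-slice rule
  resolution, with region presence taken from the case's sampled extents
  instead of the rule starts and the BA35 flank emitted only where the
  1 mm window behind the case's ERC extent contains the slice. Each
  distinct resolved border is then jittered by Gaussian noise (default
  between-case SD 2.0 mm, the order of the published per-cell SDs),
  re-sorted to keep the partition ordered, and clamped to the contour.
  Sharing the resolution code makes the zero-noise round trip a genuine
  identity rather than a numerical coincidence.

Randomness uses PCG64 with per-case `SeedSequence` substreams keyed on
(seed, case index), so output is platform-stable, byte-identical across
runs, and earlier cases are unchanged when the cohort grows; per-slice
border noise derives from a per-case child seed.

What the phantoms do **not** emulate: MRI intensities, histology
appearance, sulcal branching beyond a single CS, inter-slice contour
correlation beyond per-case shape parameters, hemisphere asymmetries, or
intracranial-volume effects. Tests passing on phantoms therefore
demonstrate the correctness and statistical calibration of the *pipeline*
(measurement, derivation, engine, evaluation), not anatomical validity on
real brains.

## Measurement stage

Distances are measured on the grid slice nearest each reference level
(equidistant ties posterior) and additionally on each region's
anterior-most slice. Cases lacking a region at a level contribute absence
records, so per-cell n varies exactly as in a real cohort. Borders that
coincide with a neighbouring region's border (BA35 medial where the ERC is
present but unflanked; BA36 medial where BA35 is present) are not
independently measurable and are skipped, mirroring the N/A cells of the
published measurement tables. Anterior extents are reported as exact axial
distances: the published medians are treated as parameters of the
continuous extent distribution (the histology slide grid is already folded
into them), so the measurement pipeline does not re-quantize.

With zero border noise, every *rule-defining* distance cell has exactly
zero SD; cells comparing a border to an alternative candidate landmark
(the columns used to choose landmarks) retain anatomy-driven spread, which
is the point of those columns.

## Evaluation stage

DSI is computed in interval mode (arc-length measure, exact) or raster
mode (voxel counts); the two agree to discretization error on the same
label maps. Two segmentations that both leave a label empty are assigned
DSI 1 with a flag — agreeing on absence is agreement; the convention never
arises in the protocol's own range but guards degenerate cohorts.

The landmark-perturbation experiment jitters all landmarks of every slice
with Gaussian noise of scale σ, re-applies the engine, and summarizes DSI
per label against the unperturbed segmentation (mean ± SD over cases ×
repetitions, with a monotonicity check over the σ grid). It is a
methodological stand-in for re-tracing variability — a characterization of
rule-engine sensitivity to landmark placement, *not* a replication of any
intra-rater or automated-vs-manual reliability figure, which would require
the private MRI atlas data and the multi-atlas machinery that are out of
scope here.

Group comparisons (shallow vs deep CS, disease vs no disease) are
descriptive by default (n, median, SD, median difference); a Mann–Whitney
U test is available but off by default, since the stratified analyses this
mirrors were descriptive rule checks. Note that in the phantom, CS depth
mechanically lengthens the sulcal banks and hence BA35/BA36 ribbon areas;
the disease flag is the clean null grouping.

## Problem sizes and tolerances

Default test and acceptance workloads: 20-case cohorts for round-trip and
golden checks, 200 cases for noisy offset recovery (±1 mm), 2000 cases for
distributional recovery (extent median ±0.1 mm, SD ±0.15 mm), 5–10 cases ×
3–5 repetitions for perturbation experiments — sizes at which the medians'
standard errors are comfortably inside the asserted tolerances. Geometric
identities are asserted at 1e-9 mm (rigid-motion invariance), 1e-6 mm
(densification), or exactly (shared interval endpoints); interval-vs-raster
DSI agreement at 0.08 for 0.25 mm voxels.

## Known limitations

- Contours arrive with tagged key vertices; detecting key vertices on raw
  MRI or unannotated polylines is out of scope, as is 3-D reconstruction
  between slices and any real-MRI segmentation.
- The flank window is defined behind the case's true ERC extent (1 mm by
  default); on a 1.3 mm grid a case's first ERC slice can fall outside
  that window, in which case the truth has no flank while the engine
  (which keys the flank to the first labeled ERC slice) places one. The
  zero-noise round trip is unaffected because extents then coincide with
  the grid starts.
- CS depth is constant along a case's stack; real sulci shallow out
  anteriorly.
- Hemisphere is metadata only; all processing is in the canonical frame.
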