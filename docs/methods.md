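# Methods

`synmorph` implements a quantitative serial-section morphometry pipeline for
presynaptic boutons — the measurements behind layer-wise comparisons of
bouton geometry, active-zone (AZ) size, synaptic-cleft width and synaptic
vesicle (SV) pools in cortical neuropil — together with a ground-truth
synthetic scene generator that emulates the two imaging modalities such
studies use (serial ultrathin-section TEM and FIB-SEM z-stacks).  Every
stage of the measurement chain can therefore be validated against known
truth without any real EM data, which are manual annotations of human
biopsy material and are not public.

## The synthetic scene

**Bouton surface.**  A bouton is modelled as a prolate spheroid along the
axon axis (z) — an *en passant* swelling — with an optional smooth random
radial perturbation (a handful of Gaussian-like lobes on the sphere,
default peak amplitude 1.5% of the radius).  Human cortical boutons have
far more membrane per unit volume than a sphere (e.g. 6.09 µm² of surface
on 0.63 µm³), so a sphere cannot satisfy both targets; the transverse and
axial semi-axes are solved numerically — volume is matched exactly through
the scale factor, the aspect ratio by a 1-D root find on the *measured*
mesh area — so the triangulated surface hits both targets to float
precision (validated at ≤2%).

**Active zones.**  Each AZ is a patch of bouton-mesh faces around a surface
point, selected by bisection on a chord-radius until the patch area matches
its target (granularity: one mesh face, ≲1%).  Shape classes are carved in
the patch's tangent frame: `macular` (full disk), `ring` (central hole at
0.55 of the patch radius), `horseshoe` (ring with a 120° sector opened),
`perforated` (two interior holes of 0.24 patch radius).  The postsynaptic
density (PSD) is the PreAZ patch scaled tangentially (area ratio taken from
the requested PSD/PreAZ targets) and translated across the cleft along the
patch normal — a parallel-membrane construction under which the
length-ratio PSD estimator (below) is consistent.  A spherical "spine
head" surface is placed behind the PSD for target-label completeness; it
carries no measurement.

**Cleft widths.**  Measured cleft widths (two lateral edges plus the
centre) are carried as an annotation channel: nominal widths from the scene
parameters plus Gaussian measurement noise, with a perpendicularity flag
(15% of profiles are marked obliquely cut and excluded, mirroring the
protocol's inclusion criterion).  They are not re-derived from the 3-D gap
geometry: the reported human values have central > lateral, which no
convex–convex apposition geometry produces, so the width field is
simulation-level by design.

**Vesicles.**  Pools are defined by the perimeter p — the minimal distance
from a vesicle's centre to the nearest presynaptic density minus its
radius: p ≤ 10 nm (putative readily-releasable pool, strict), 10–20 nm
(loose criterion), 20–60 nm (unnamed in the field's tables; carried
explicitly as "intermediate"), 60–200 nm (recycling pool), > 200 nm
(resting pool).  Integer per-bin counts come from largest-remainder
rounding of the requested fractions, so preset bin counts are exact.
Placement is stratified:

- *Docked* vesicles (a configured fraction of the p10 bin) sit tangent to
  the patch (p = 0) and are flagged.
- *p ≤ 60 nm* bins use blue-noise sites on the patch surface at stratified
  depths (depth below the membrane = radius + p).  Purely random sequential
  placement cannot reach the local densities the human L4 numbers imply
  (≈49 RRP vesicles at a 0.13 µm² AZ is beyond the RSA jamming limit), so
  candidates come from Poisson-disk-thinned sites instead; a pass that
  places nothing twice in a row raises an infeasibility error naming the
  bin.
- *Recycling and resting* vesicles are uniform rejection samples inside the
  eroded bouton, binned by their exhaustively computed point-to-triangle
  distance to the patch.  The resting pool's distance distribution beyond
  200 nm is therefore "uniform over the available interior", a choice the
  source protocols do not constrain.

Every vesicle's recorded perimeter is the exact 3-D distance to the patch
triangles minus its radius, recomputed before acceptance, so the labelled
bin is guaranteed (asserted per scene).  Spheres may overlap by at most a
configured tolerance (4 nm default; 8 nm in the L4 preset, where the
packed RRP shell needs near-contact packing with the membrane flattening
seen at docked vesicles).  Vesicles avoid mitochondria and keep one radius
clear of the membrane except at the AZ.

**Mitochondria** are axis-aligned prolate ellipsoids (aspect ≈ 1:4, capped
at 0.55 of the transverse radius) spaced along the bouton axis; their
semi-axes are solved so the summed analytic volume hits the target volume
fraction (±0.02 validated), and containment is verified on sampled surface
points.

**Presets.**  `preset_from_table1("L4_TLN" | "L5_TLN")` loads the human
temporal-lobe neocortex layer means: surface area 2.50/6.09 µm², volume
0.16/0.63 µm³, PreAZ 0.13/0.23 µm², PSD 0.13/0.28 µm², cleft
lateral/central 14.11/16.47 and 17.24/19.05 nm, total SV 1821/1519 with
pools p10 20/5, p20 49/15, recycling 382/182, resting 1252/1264 (the
remainder, 138/58, is the intermediate 20–60 nm band), SV diameters
30–40 nm, 2/4 mitochondria at 12% volume.  One macular AZ is the default;
counts of 1–3 AZs are supported.

## Observation models

**Serial sections (TEM mode).**  Sections are 55 ± 5 nm (uniform jitter)
half-open slabs [z_lo, z_hi); a sphere tangent to a boundary plane belongs
to the lower section.  Each section carries: closed polygons (bouton,
target, mitochondria) cut at the slab mid-plane from the ground-truth
meshes; open polylines for the pre/postsynaptic densities (the annotation
protocol draws a contour *line* along the membrane whose arc length enters
the PSD estimator — closing it would double l_PreAZ); and vesicle marks
(in-plane centre plus the chord diameter at the mid-plane) in every slab
the sphere intersects.  A vesicle grazing a slab without reaching its
mid-plane yields a mark of diameter 0.  Section loss keeps the lost slab
as an explicit gap; misalignment is an independent per-section in-plane
translation (rotation is out of scope — the protocol's "linear transform"
is modelled as translation only).  Contour vertices are spaced ≤5 nm.

**Voxel grids (FIB-SEM mode).**  The scene is rasterised by voxel-centre
membership at 5 × 5 × 50 nm (the anisotropic acquisition voxel) or
5 × 5 × 5 nm (isotropic mode).  The vesicle detector is deliberately
simple — 26-connected components with a 2-voxel minimum — because its
merging of touching vesicles *is* the partial-volume bias being
demonstrated: at Table-1 densities the anisotropic grid both merges
neighbours and drops vesicles that fall between 50 nm z-planes, so
anisotropic detections ≤ isotropic detections (ordering verified over
seeds; no blur/noise model is included, so this is a purely geometric
bias).

## Measurements

**Alignment** registers consecutive sections by the area-weighted centroid
of matched bouton contours (correspondence gated at 500 nm; an unmatched
consecutive pair is an error naming the pair).  It is anchored at the
first populated section and is idempotent.  Genuine lateral drift of an
oblique axon is flattened by construction; the synthetic axon axis is
normal to the cutting plane, so recovery of injected shifts is exact to
centroid precision (< 2 nm RMS).

**Volume** uses the Cavalieri estimator — Σ contour area × realized slab
thickness — as the primary figure (robust to lost sections, whose areas
are interpolated from the nearest intact neighbours, never silently
dropped).  **Surface area** comes from a lofted mesh: per-section contours
resampled to a common arc-length-uniform vertex count, rotationally
registered by FFT cross-correlation, stitched by shortest-diagonal strips,
and capped at the end contours when the object is complete.  An object
reaching the stack's first/last intact section, or interrupted by a gap
wider than one section, is flagged `truncated`: its model is not bridged
and end caps are omitted (cut faces are not membrane).  The
divergence-theorem volume of the watertight loft is kept as a cross-check
(agrees with Cavalieri within 3% at 55 nm on convex fixtures).

**PreAZ extraction** follows the coverage rule: membrane strictly within
30 nm of a presynaptic density contour, evaluated in-plane per section
(matching the image-by-image workflow).  Each loft face is credited with
the fraction of its vertices passing the strict test; the area is the
coverage-weighted face-area sum.  On a spherical-cap fixture with
10-nm-offset density arcs and 10 nm sections this lands within 1% of the
closed-form cap area.  On 55 nm sections with densities drawn directly on
the membrane the rule systematically over-covers (the 30 nm margin beyond
the density's in-plane ends accumulates, ≈ +30% on the L5 preset); this
measured protocol bias is reported as-is rather than corrected, since the
reference workflow gives no correction either.

**PSD area** uses SA_PSD = SA_PreAZ · l_PSD / l_PreAZ with the summed
per-section contour-line lengths.  Under the generator's
scaled-and-translated PSD construction the summed-length ratio equals the
true area ratio, so the estimator fed the true PreAZ area recovers the
true PSD area within discretization error (≤5%); fed the *extracted*
PreAZ area it inherits that extraction's bias.  A direct tracing estimate
(Σ l_PSD × thickness) is provided as the independent alternative.
l_PreAZ = 0 raises an undefined-ratio error; a missing density annotation
reports zero area with a warning.

**AZ shape** classification projects the patch onto its best-fit plane:
holes ≥1% of the outer area (smaller pinholes are triangulation slivers)
make it `perforated`, or `ring` when a single hole covers ≥15%; a
simply-connected patch with convexity deficit >0.35 (1 − area/hull-area; a
stated threshold, since the source protocols give none) is `horseshoe`,
otherwise `macular`.

**Vesicle pools.**  Perimeters subtract the measured (chord) radius from
the centre-to-density distance; negative values clamp to zero (an
overlapping vesicle is touching).  The strict per-image 2-D distance is
undefined for marks whose section carries no density — most of the resting
pool — so the default mode measures against the density polylines of the
whole stack at their mid-plane z ("3d"); the strict "2d" mode is kept and
the 2-D/3-D discrepancy on co-sectional marks is reported.  Small clear
vesicles get no multi-section de-duplication (each appearance is a mark,
as in the reference protocol); large dense-core vesicles are collapsed
across adjacent sections to their maximal-diameter appearance.  Bin edges:
≤10, ≤20 (cumulative), (20, 60), [60, 200], >200 nm; conservation
(binned + excluded = input) and docked ≤ p10 ≤ p20 hold on every run.

Recovery accuracy: over repeated preset scenes the recovered pool
fractions sit within ±0.03 (absolute, mean over seeds) of the configured
fractions.  The residual bias is outward (resting slightly over,
AZ-proximal bins slightly under) and comes from the observation model, not
the classifier: marks beyond a vesicle's largest appearance carry
underestimated chord radii and quantized z, which inflates their measured
perimeter.

**Statistics.**  Subject aggregation is two-level: within-subject mean
first, then an unweighted mean ± SD across subjects (a subject with no
valid rows is excluded with a warning; one subject gives no SD).  Group
comparisons use Kruskal–Wallis H (tie-corrected rank sums) with post-hoc
two-sided Mann–Whitney U per pair and Bonferroni adjustment — the
reference analysis names post-hoc U tests without an adjustment, so the
adjustment is explicit and configurable.  Null calibration: the rejection
rate at α = 0.05 stays within [0.035, 0.065] over 2000 null simulations at
group sizes 5–100.

## Reproducibility and problem sizes

Every run derives from one integer seed through `numpy` `SeedSequence`
spawning; identical configuration + seed gives byte-identical reports
(CSV floats are written at full precision and read back with round-trip
parsing).  The shipped validation suite uses spheres/cylinders at 10–55 nm
sections for closed-form oracles, 20 preset scenes (10 per layer) for pool
recovery, 20 seeds for the modality-bias ordering, and 4-bouton study runs
per layer in the acceptance script — sizes chosen so the full validation
completes in minutes on one CPU while keeping Monte-Carlo error well below
the tolerances checked.

## What passing tests do and do not show

The generator emulates geometry and sampling, not image formation: there
is no electron-optical blur, noise, charging or stain variability, no
deformable section distortion, no segmentation step (annotations are
inputs), and vesicles are perfect spheres with uniform diameters.  Passing
recovery tests therefore demonstrates that the *measurement chain* —
alignment, Cavalieri/loft estimators, the 30 nm coverage rule, the
radius-subtracted perimeter protocol, pool binning, aggregation — is
unbiased or has known, quantified bias under ideal annotations of
realistic geometry.  They do not certify performance on real micrographs,
where annotation error dominates.  Known limitations: translation-only
alignment; largest-contour lofting (no branching surfaces); the
per-section 30 nm rule over-covers at coarse section thickness; cleft
widths are an annotation channel rather than emergent geometry; the
resting-pool spatial distribution is a modelling choice.
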