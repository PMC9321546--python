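# Methods

## The measurement model

MRPI 2.0 composes six geometric quantities measured on a T1-weighted brain
volume brought into a canonical space:

```
MRPI 2.0 = (pons area / midbrain area) × (MCP / SCP) × (3V / FH)
```

All quantities are absolute millimetres (or mm²), which dictates the central
spatial-normalization decision: the transform into template space is **rigid
(6 DOF — three rotations, three translations), never scaled**. A transform
with scaling would silently renormalize every width and area and destroy the
index's units. Registration is delegated to SimpleITK (Euler3D transform,
Mattes mutual information, 50 histogram bins, 3-level multi-resolution
descent, 25% regular sampling with a fixed seed so results are
deterministic). A `passthrough` mode (the default) skips optimization for
volumes already in canonical pose — synthetic phantoms, or data normalized
upstream — and only resamples to the 1 mm isotropic grid. A schematic
built-in template (the default phantom) removes any download dependency;
real data should be registered to an MNI template supplied by the caller.

Intensity normalization rescales to [0, 1] between the 1st and 99th
percentile of the volume (clipping outside), making thresholds transferable
across scanners and field strengths. Because clipping creates new extreme
values, literal re-application would shift the anchors slightly; the
normalized state is therefore recorded in the volume metadata and
re-application is an exact no-op, which is what makes normalization
idempotent to machine precision.

### Landmarks and the midsagittal plane

Three midline landmarks are detected by threshold + connected-component
analysis. CSF is defined as *dark cavities enclosed by tissue* (fill-holes of
the thresholded tissue mask minus the mask): enclosure is what separates
ventricular CSF from the equally dark background air. The tissue/CSF
threshold is the midpoint between the median bright-class and median
dark-class intensities; with linear interpolation this places sub-voxel
boundary crossings on the geometric tissue/CSF interface.

* **Aqueduct** — the most inferior midline CSF component whose per-slice
  cross-section stays below 30 mm² (wider midline cavities are the third
  ventricle). Its "maximal expansion" point is the centroid of the
  largest-cross-section level.
* **Corpus callosum** — the most superior midline CSF cavity is the ventricle
  body under the callosal arch; the callosal reference point sits just above
  its roof.
* **Upper brainstem** — centroid of tissue in a box anterior-inferior to the
  aqueduct.

Each landmark carries a confidence in [0, 1] (volume or fill-fraction
relative to expectation); any confidence below 0.5 aborts with a
`landmarks`-stage failure rather than risking a silent mismeasurement.

The midsagittal plane is found by a fully deterministic coordinate-descent
search (offsets ±2 mm around the aqueduct in 0.25 mm steps — the plane must
pass within 2 mm of the aqueduct — and tilts up to ±10° about the superior
and anterior axes, refined to 0.25°) minimizing the mean absolute left-right
intensity asymmetry over ~8000 tissue sample points. Ties resolve toward the
aqueduct, then toward the smaller tilt. There is no randomness anywhere in
the pipeline, which is what makes run-to-run ICC exactly 1.

### The axial slab and ventricular measures

The subcallosal line is fit by least squares to the upper boundary of the
subcallosal CSF gap on the midsagittal slice — a reproducible proxy for the
radiological line tangent to the under-surface of the corpus callosum. The
axial slab is 35 slices of 1 mm, parallel to that line, the first slice
tangent to it and the stack extending inferiorly; in canonical space this
covers both the third ventricle and the frontal horns.

The third ventricle is the midline CSF component of each slab slice.
A screening pass measures two left-right widths per slice (at 1/3 and 2/3 of
the component's anteroposterior extent) and selects the slice with the
largest width; the final width is the mean of six equally spaced measures
over the middle 80% of the extent on that slice (the count is the protocol's;
the placement — symmetric, end-avoiding — is this package's convention).
The frontal-horn span is the distance between the outermost lateral borders
of the paired off-midline anterior CSF components, maximized over slices.
All linear measures refine borders by linear interpolation of the threshold
crossing along the measurement ray (sub-voxel); ties across slices resolve
to the inferior-most slice (deterministic, and anatomically the third
ventricle widens inferiorly).

### Brainstem measures

The brainstem profile is the connected tissue component containing the
upper-brainstem landmark on the midsagittal slice, inside an anatomy-anchored
search box (threshold: Otsu within the box, refined to the class-mean
midpoint). The midbrain/pons boundary is a straight line through the
pontomesencephalic junction notch — the deepest anterior concavity of the
profile (longest run of minimal anterior extent; the line passes through its
center, oriented along the anteroposterior slice axis). Areas are pixel
counts × pixel area on a 0.25 mm resampled slice, so midbrain + pons equals
the total mask area exactly (partition conservation).

MCP widths are measured on left/right parasagittal slices at ±12 mm from the
midsagittal plane; SCP widths on a coronal reformat 9 mm posterior to the
aqueduct (obliquity configurable, 0° in canonical space). Each peduncle's
width is the narrowest perpendicular extent over the middle third of its
principal axis — end-flaring cannot inflate it. A side that cannot be
measured is NaN; failure is raised only when neither side is found.

### Failure semantics and QC

Every stage raises a typed `StageFailure` naming itself
(`registration`, `intensity`, `landmarks`, `midsagittal`, `slab`,
`brainstem`, `ventricles`); the subject driver converts this into
`status="failed"` with no numeric fields. Sanity bounds (linear measures in
[0.5, 60] mm, areas in [20, 1500] mm²) stand in for the visual inspection a
human operator would perform. The hydrocephalus screening rule
(Evans Index > 0.32 **and** callosal angle < 100°, both strict) operates on
caller-supplied measurements: neither quantity is measured by this package,
which deliberately keeps its scope to what the automated chain actually
produces.

## The phantom generator

Phantoms are schematic, not anatomically realistic: every structure the
pipeline measures is an axis-aligned box (midbrain and pons profiles extruded
laterally, peduncle bars, a slit-like third ventricle that tapers to 60%
width superiorly, paired frontal horns, an aqueduct channel with a bulged
"maximal expansion", a subcallosal gap under the callosal level), with
two-class T1-like contrast (tissue 0.8, CSF 0.1, background 0) plus optional
Gaussian noise. Since every downstream operator is geometric — thresholds,
connected components, linear/area measures — geometric fidelity is the
fidelity that matters.

Key generator properties:

* **Snapped, recorded truth.** Every requested dimension is snapped to voxel
  boundaries width-preservingly (snap the low edge, carry the width rounded
  to whole voxels), so realized linear dimensions sit within half a voxel of
  the request; profile areas, whose anteroposterior depth compensates the
  aqueduct carve and junction notch, land within one voxel-row of area.
  `GroundTruth` records the *realized* values counted from the rasterized
  canonical-frame geometry, so tests score measurements against exact truth.
* **Pose invariance.** Head tilt is applied analytically (structure
  membership evaluated at back-rotated voxel centers), and truth is defined
  in the canonical frame — identical across tilts by construction.
* **Cavity walls ≥ 2 mm.** Enclosure of the aqueduct must survive
  resampling; thinner walls blur below threshold and the cavity "leaks" into
  the background, which is exactly the failure mode the corruption tests
  exercise deliberately.
* **Determinism.** Identical spec + seed give bit-identical volumes.

Corruption modes emulate acquisition failures: `ghosting` superimposes
±15 mm shifted replicas (motion-like; destroys the enclosed-CSF topology),
`landmark_dropout` fills the aqueduct with tissue, and `intensity_clip`
saturates everything above the 1st percentile of nonzero intensities
(contrast collapse). All three are designed to break landmark detection,
and the tests assert they fail there — with a failed status, never a number.

What the phantoms do **not** emulate: bias fields, k-space artefacts,
anatomical shape variability, partial-volume texture, or multi-contrast
appearance. Passing the phantom suite therefore demonstrates the geometric
and statistical correctness of the measurement chain, not clinical-grade
robustness on arbitrary patient data; the thresholds and search boxes would
need evaluation against expert measurements for clinical use.

The scalar cohort simulator draws per-group MRPI 2.0 values from the
published group Gaussians (PSP-P 3.25 ± 1.32, PD 1.48 ± 0.83, controls
1.20 ± 0.53 in the training cohort; 4.26 ± 2.16 / 1.65 ± 0.76 / 1.47 ± 0.72
in the testing cohort), truncated at zero by redrawing because the index is
a ratio of positive quantities; ages are Gaussian floored at 40 years per
the cohorts' inclusion criteria.

## Statistics

The AUC is the Mann–Whitney pair-counting estimator (ties ½), the optimal
cutoff the observed value maximizing sensitivity + specificity (ties toward
higher specificity — the protocol leaves the tie unbroken). Bootstrap CIs
resample within class (stratified, preserving prevalence; percentile
interval, n = 2000 by default). The De Long test is provided unpaired
(independent cohorts, variance = sum of the two structural-component
variances) and paired (same subjects, covariance form). The logistic model
is a standard single-predictor IRLS fit (statsmodels) whose intercept
reflects observed class proportions — no rebalancing; complete separation is
flagged and the coefficients still reported with a warning status. Age
correction fits value-on-age OLS on controls only and propagates residuals
to all subjects, so control residuals average to zero by construction. The
reproducibility ICC is the two-way absolute-agreement single-measure form
ICC(2,1) built from ANOVA mean squares (absolute agreement, so a constant
offset between runs is penalized); it is cross-checked against an
independent implementation in the test suite.

## Numerical choices and problem sizes

* Canonical grid 1 mm isotropic; midsagittal slice resampled at 0.25 mm,
  slab slices at 0.5 mm, measurement rays at 0.05–0.1 mm with linear
  threshold-crossing interpolation.
* All resampled plane grids are offset by half a pixel step so sample points
  never coincide with voxel-boundary knife edges (where interpolated values
  sit exactly at threshold and mask membership becomes ill-conditioned).
* Phantoms are 110 mm cubes (110³ voxels at 1 mm); a full single-subject
  pipeline takes well under a second, so the validation suite runs
  27-configuration sweeps and repeated-run ICC checks comfortably on one CPU.
* The bootstrap-coverage check uses 200 Monte-Carlo repeats of n = 500+500
  cohorts with 2000 bootstrap iterations each — the same iteration count the
  protocol prescribes.

## Known limitations

* The subcallosal line, the six-measure placement, the peduncle measurement
  planes and the junction-notch definition are reproducible conventions of
  this package; the original clinical toolbox's private conventions are not
  published, so agreement with it can only be established on shared data.
* Evans Index and callosal angle are inputs, not measured here.
* Rigid registration quality is validated on phantoms (recovery of known
  rotations to < 0.1°); real-data registration robustness depends on the
  supplied template and acquisition quality.
* Group-comparison inferential statistics (ANCOVA, nonparametric demographic
  tests, multiplicity ladders) are out of scope; the package covers the
  biomarker-validation statistics listed above.
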