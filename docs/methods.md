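# Methods

## The outline model

The method reduces a 3-D head surface to a one-dimensional, size-free
shape profile.  Its assumptions, in order of appearance:

* **Landmark plane.**  Left/right exocanthion and one porion are
  non-collinear and reproducibly identifiable; the plane through them is a
  stable anatomical reference.  The left porion is the default; for
  left-sided anterior plagiocephaly the right porion is used instead, as
  the side unaffected by the deformity.  The choice is an explicit input,
  never auto-detected.
* **Slice height.**  The analysis plane lies 40 mm above the base plane
  (configurable, `height_mm`).  At that height the slice clears the orbits
  but still crosses the cranial vault.
* **Single closed outline.**  The surface is closed around the vault at
  slice height.  When the slice produces several loops (ears, imaging
  debris), the loop with the largest enclosed area is taken; the method is
  agnostic to whether the surface is bone or skin.
* **Star-shapedness.**  The cross-section is star-shaped about its area
  centroid, so one radius per degree describes it completely.  For
  non-star-shaped polygons the outermost ray crossing is used and a
  `RuntimeWarning` is emitted — a signal that the outline model is being
  stretched.
* **Angular registration.**  The curve starts at the occiput — the
  crossing of the perpendicular bisector of the projected ex–ex segment
  that lies farther from the ex midpoint — and sweeps past the patient's
  right first.  Registration is anatomical, not geometric: two skulls with
  identical outlines but swapped landmarks produce mirrored curves.
* **Size normalization.**  Radii are divided by their arithmetic mean.
  "1.0" is therefore *defined* as the mean radius; alternatives (perimeter
  or area normalization) would decouple the unit from the printed curve
  convention and were rejected.

## Curve variables

All variables operate on the 360-sample relative curve.  Defaults of the
extraction windows and classifier thresholds live in
`craniocurve.features.FeatureConfig`; every one is overridable.

| parameter | default | unit | rationale |
|---|---|---|---|
| `height_mm` | 40 | mm | orbit-free vault slice |
| `forehead_window` | (90°, 270°) | deg | the forehead peak is the anterior half of the sweep |
| `occiput_half_window` | 45 | deg | occiput peak near the start by construction |
| `peak_band_deg` | 12 | deg | 3.5 % of 360° = 12.6°, the conventional asymmetry threshold, rounded; band boundaries inclusive |
| `forehead_drop` | 0.1 | relative radius | level defining the forehead width crossings |
| `t_scapho_length_width` | 1.40 | – | elongation between the control (~1.3) and sagittal-synostosis (~1.5) regimes |
| `t_trigono_forehead_width` | 66 | deg per rel. radius | below the control forehead-width regime |
| `t_brachy_forehead_width` | 110 | deg per rel. radius | above the control regime |
| `brachy_fo_tol` | 0.03 | relative radius | "forehead and occiput peaks of equal height" |
| `trigono_asym_window` | (0.7, 1.6) | – | guards the trigonocephaly rule against grossly asymmetric curves |

Numerical choices:

* Extrema ties (flat plateaus) break toward the nominal angle: 180° for
  the forehead, 90°/270° for the troughs, 0° for the occiput.
* The forehead-width crossings `XFR`/`XFL` are found by walking outward
  from the peak to the first integer degree below `F − 0.1` and linearly
  interpolating, so they carry fractional degrees.  The quantity
  `(XFL−XFR)/(F−0.1)` has the odd unit degrees-per-relative-radius; it is
  implemented exactly as defined because its published group values are
  the comparison points.
* The side-mean subtractions are computed as `O − (R/2 + L/2)` and
  `F − (R/2 + L/2)`.  A printed variant with a minus sign inside the
  bracket circulates, but only the plus sign is consistent with the worked
  group values (1.24 − 0.81 = 0.43); the minus variant remains available
  via `FeatureConfig(strict_table1=True)`.
* A curve with total relief below 1e-6 raises `FlatCurve`; a forehead that
  never drops 0.1 below its peak on one side raises `PeakTooFlat`.  The
  latter is a genuine boundary of the variable definition: extremely round
  skulls with nearly level curves have no defined forehead width.  Cohort
  evaluations (`classify_cohort`) record such subjects as
  `unclassifiable` instead of aborting.
* Mesh–plane intersection, loop chaining and polygon predicates are
  delegated to `trimesh` and `shapely`; ray–segment intersections are
  solved exactly in 2-D with a 1e-9 vertex tolerance so crossings through
  a polygon vertex are not lost to rounding on both adjacent edges.
* The `start_plane` flag ({`base`, `slice`}) records in which plane the
  ex–ex construction is drawn.  Because both planes share a normal and the
  landmarks are projected along it, the two settings give identical
  plane-local coordinates; the flag exists for auditability.

## Statistics

* **ICC(2,1)** is computed from the two-way ANOVA decomposition,
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)` — two-way random
  effects, absolute agreement, single measures.  Reliability reports cover
  each landmark and axis (x, y, z) plus the 3-D Euclidean deviation from
  the per-target mean point, intra-rater (sessions as columns) and
  inter-rater (session-averaged raters as columns); `acceptable` flags
  ICC > 0.75.  Tables without any variance (perfect repetition) yield NaN
  rather than an error inside reports.
* **Group comparison**: one-way ANOVA, Levene's test with mean centring
  (the classical form, not the median-based variant), and Games–Howell
  pairwise post hoc tests — Welch's t with Welch–Satterthwaite degrees of
  freedom referred to the studentized-range distribution with
  `q = t·√2`.  Bonferroni-adjusted p-values (`m` = number of pairwise
  comparisons) are reported alongside and significance is flagged on the
  adjusted value; reporting both is deliberately conservative since the
  two corrections are not usually combined.

## The phantom generator

`craniocurve.synthetic` emulates CT-derived head surfaces as warped
icospheres: every horizontal cross-section is a superellipse with separate
anterior/posterior semi-axes and exponents, multiplied by smooth angular
deformation fields (frontal prominence, narrow apex anchor, occipital
prominence, unilateral frontal flattening/apex skew).  Landmarks are
placed analytically on the surface at base-plane height (exocanthia at
±40° from anterior, poria at ±105°), so the analytic radius function
doubles as a ground-truth oracle for slicing tests.

Phenotype regimes (noise-free, at slice level): control length/width
≈ 1.29 with forehead width ≈ 84; scaphocephaly ≥ 1.45 (occiput the
tallest peak); brachycephaly ≤ 1.22 with near-equal peaks and forehead
width ≈ 127; trigonocephaly with anterior exponent 1.7 giving forehead
width ≈ 40; plagiocephaly with the frontal apex skewed 38° toward the
affected side (XF ≈ 159°/201°).  Amplitudes were chosen to land inside
the qualitative regimes that characterise each phenotype, not fitted to
any particular cohort's numbers.

Per-subject variation in `generate_cohort` multiplies the semi-axes by
Gaussian factors: SD 2.5 % for controls, 0.9 % for synostotic groups.
The asymmetry is intentional and encodes the method's own premise: normal
skulls vary widely, while a fused suture stereotypes the shape.  The
per-degree range statistic of control groups consequently exceeds that of
every synostotic group under matched noise — the phantom analogue of the
clinical observation — but the *magnitude* of phantom variability is not
calibrated to clinical cohorts.  Surface noise (default SD 0.5 mm) is a
smooth random radial field (six azimuthal harmonics with a linear height
modulation) plus a 20 % white-vertex component, mimicking the smooth,
centimetre-scale errors of surface reconstruction rather than white voxel
noise.

What passing phantom tests shows: the geometry, registration,
normalization, feature extraction and classification rules behave
correctly on closed, star-shaped, landmark-consistent surfaces across the
phenotype shape regimes.  What it does not show: performance on real CT
or photogrammetry surfaces with soft-tissue variation, imaging artefacts,
landmark-placement biases of human raters, or patient-level clinical
statistics (landmark ICCs of 0.994–1.000 and group p-values obtained on
patients require the original scans and raters).

## Problem sizes

Default test and acceptance runs use icosphere subdivision 5
(10 242 vertices; slice polygons of 300–400 vertices), five phantoms per
group (mirroring small clinical groups), 1000-replicate null simulations
for the type-I-error check, and 26-target rating tables for reliability
simulations.  These sizes make every documented property measurable with
comfortable margins while keeping a full run in the tens of seconds.

## Known limitations

* Classifier thresholds are heuristics derived from very small group
  regimes; they are validated on phantoms only and must be recalibrated
  before any clinical use.
* The forehead-width variable is undefined (`PeakTooFlat`) for nearly
  level curves and highly sensitive near the brachycephalic regime, where
  the `F − 0.1` level approaches the troughs.
* Non-star-shaped outlines are handled by the outermost-crossing rule but
  the resulting curve no longer encodes the full boundary.
* The plagiocephalic asymmetry-ratio regime of real patients (ipsilateral
  trough shifts) is only partially reproduced by the apex-skew phantom;
  the classifier does not rely on it.
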