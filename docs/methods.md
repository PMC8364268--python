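# Methods

This note records the models, conventions, numerical choices and known
limitations behind `cbctalert`, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinate and intensity conventions

All arrays are indexed `(slice, row, column)` = patient `(z, y, x)` in
an LPS-style frame; `spacing` and `origin` are stored in the same order
and all physical quantities are millimetres. Grids are axis-aligned —
there is no direction-cosine matrix, and oblique DICOM series are
rejected rather than silently re-oriented. Intensities are Hounsfield
units with air at −1000 HU. A single documented convention of this kind
removes the dominant class of medical-imaging bugs (axis swaps and
mm/voxel confusions); every module shares it.

Rigid transforms are stored as a 3×3 rotation plus translation with an
explicit `direction` flag (`moving_to_reference` or its inverse), so a
file of either orientation can be consumed; registration rotations are
supported throughout even though many online matches are
translation-only.

## Gamma comparison

The comparison engine computes a global 3-D gamma index on intensities:
for each masked reference voxel, the minimum over candidate positions
of `sqrt(dist²/Δd² + ΔHU²/ΔHU_crit²)`, with Δd = 3 mm and
ΔHU_crit = 30 HU by default. Specific choices:

* **Mask.** Evaluation is limited to the external contour dilated by a
  10 mm margin. Dilation uses a structuring element built in physical
  mm from the per-axis spacing (an anisotropy-aware ball), so the
  margin is correct on non-isotropic grids.
* **Search extent.** The minimisation runs over a sphere of radius
  `search_radius_mm` (default 3×Δd = 9 mm). Gamma values are otherwise
  uncapped, so the radius bounds the attainable gamma at voxels with no
  nearby intensity match; it is part of the visible configuration for
  exactly that reason.
* **Discretization.** Candidates sit on a regular mm lattice of pitch
  `interp_step_mm` (default `min(spacing)/3`, required ≤ spacing/2),
  with trilinear interpolation of the evaluated volume — standard
  distance-to-agreement practice. An `integer` mode restricts
  candidates to whole-voxel offsets with no interpolation; it exists so
  an exhaustive brute-force search can reproduce the result exactly,
  and the test suite holds the two to 1e-9 agreement. In subvoxel mode
  candidates outside the evaluated array sample air (−1000 HU); in
  integer mode they are skipped, matching the oracle's convention.
* **Search order.** Candidates are visited in increasing distance and a
  voxel retires once the distance term alone exceeds its current best —
  an exact pruning, not an approximation. A compiled (numba) per-voxel
  kernel implements the same arithmetic as the vectorized numpy
  reference path; the suite checks they agree to 1e-9.
* **Percentile.** γ_x is the empirical x-th percentile of the failed
  (γ > 1) values with linear interpolation between order statistics —
  the bin-free limit of a histogram percentile. Anyone comparing
  against coarsely binned histogram readings should expect small
  differences.
* **Empty failed set.** A match with no failed voxels reports the
  sentinel γ_x = 1.0 (the pass/fail boundary). Noise makes this rare in
  practice, but the sentinel guarantees a perfect match can never look
  *worse* than the reference match, so it can never trigger an alert.
* **Non-finite voxels** inside the mask (e.g. outside a limited field
  of view) are excluded from evaluation and from `n_evaluated`, with a
  logged count.
* A 2-D per-slice variant (`in_plane=True`) restricts the search to
  each voxel's axial plane, for single-plane figure reproduction; all
  quantitative results use the 3-D search, which uses all information.

## MQP tracking and alerting

`MQP_{x,i} = γ_{x,ref} − γ_{x,i}`, with the reference match being the
comparison of the first two usable CBCTs; the reference entry is
exactly 0 by construction, and a re-plan starts a new series.
"Consecutive" in the trigger rule means consecutive usable CBCT
*acquisitions*, not calendar fractions — imaging is typically twice
weekly, so fraction gaps inside a run are the norm. The comparison is
strict (`mqp < threshold`); a value equal to the threshold does not
count and resets the run (pinned by a unit test). Usability is an
input-level flag in the plan manifest: the tool does not judge image
usability itself.

After the initial trigger, every later sub-threshold acquisition is
reported as a follow-up event. Classification treats the event list as
the alert record: a positive plan is TP when *any* event lands within
±3 fractions (inclusive) of the re-CT fraction. This matters in two
ways: repeated alerts are the clinical reality while the anatomy stays
changed, and it makes ROC sensitivity monotone in the threshold — the
event set shrinks pointwise as the threshold drops, whereas a
first-trigger-only rule can push the sole trigger out of the window as
the threshold rises. An optional `mute_after_fraction` flags (never
removes) late-course events, mirroring the practice of silencing alerts
in the final week.

Default operating point: x = 80, threshold −0.11, three consecutive
values, ±3-fraction window, 10 mm mask margin — all configurable.

## Synthetic phantom and courses

The generator exists so every downstream stage is testable with known
ground truth; it emulates the *geometry and statistics* of the problem,
not CBCT physics.

* **Anatomy.** An ellipsoidal soft-tissue body (40 HU) in air with a
  bone-like posterior insert and an air-like channel. The default grid
  is 64³ at 3 mm isotropic — a deliberately coarsened stand-in for a
  clinical CBCT matrix, chosen so multi-course experiments run in
  minutes on one CPU; cohort-scale experiments default to a 48³ / 4 mm
  variant for the same reason. Structure surfaces get a ~1.5 mm linear
  partial-volume blend.
* **Anatomy change.** Progressive lateral recession of the two in-plane
  body half-axes: depth `min(rate · max(0, f − onset), max_recession)`
  mm at fraction f. Lateral surface loss is the dominant clinical
  change (weight loss) and gives closed-form ground truth; the
  saturation depth (default 12 mm) keeps the total clinically
  plausible. A course is labelled positive when the total recession
  reaches `clinical_change_mm` (default 5 mm — a cohort convention
  stated in the annotations header, not a clinical constant), and its
  ground-truth re-CT fraction is the first fraction reaching that
  depth.
* **Setup error.** Each acquisition draws a rigid translation (per-axis
  σ = `setup_jitter_mm`, default 2 mm; optional axial rotation) that is
  recorded as the true registration, so online matching is emulated as
  exact. Resampling under the true transform still smooths noise
  through interpolation, as it does clinically.
* **Noise.** Gaussian with σ = 20 HU by default, spatially correlated
  over 0.8 voxel (white noise filtered with a Gaussian, marginal σ
  renormalized). The correlation models the reconstruction kernel; with
  strictly white noise, trilinear resampling shrinks the effective
  noise by up to 2× depending on the sub-voxel phase of the setup
  offset, which makes the match quality swing with jitter phase rather
  than anatomy — an artifact of the noise model, not of the method.
* **Artifacts.** Optional ring texture with per-acquisition random
  phase, placed strictly outside body + mask margin + setup slack, so
  tests can verify that the evaluation mask excludes artifacts (mask
  on/off changes the failed count materially in an artifact-heavy
  fixture).
* **Imaging schedule.** `twice_weekly` (days 1 and 4 of each 5-fraction
  week) is the default, matching departmental practice; `daily` and
  explicit fraction lists are available. The parameter-recovery
  experiments in the test suite use daily imaging so the measured
  trigger latency reflects the detector rather than schedule
  quantization; with twice-weekly sampling the third consecutive
  sub-threshold acquisition mechanically lands ~5 fractions after
  detection onset.
* **Determinism.** Identical specs (including seeds) produce
  bit-identical volumes; cohorts write byte-identical manifests.

What passing tests on this phantom do **not** show: behaviour under
CBCT scatter/beam-hardening, HU drift, deformable change, internal
low-contrast tumour response (a change mode the gamma-on-intensities
approach is known to miss), couch/immobilization differences, or
imperfect online matching. The synthetic re-CT convention (first
fraction at 5 mm recession) is also *earlier* than a clinical decision,
which reflects on the operating point: on synthetic cohorts the −0.11
trigger tends to alert after the synthetic re-CT fraction, so
plan-level sensitivity at that point is pessimistic relative to the
clinical calibration, while the ROC scan (which includes every observed
MQP value as a candidate threshold, so no step of the curve is missed)
recovers high-sensitivity operating points.

## Evaluation conventions

The unit of classification is the plan; re-plans are separate plans.
Sensitivity = TP/(TP+FN) and FPR = FP/(FP+TN) are kept at full
precision internally and displayed with half-up rounding to two
decimals. A cohort with no positives has undefined sensitivity — an
explicit error (or NaN inside ROC frames), never silently 0. The
four-quadrant timing audit against staff review requests uses the same
±window rule for positives and any-time rule for negatives, and
produces counts only.

## Problem sizes in the shipped experiments

Chosen so the full suite runs in a few minutes on one CPU: oracle
equivalence on 100 random pairs up to ~13³; recovery experiments on 20
seeds of 20-fraction daily-imaging courses at 64³; ROC monotonicity on
a 50-plan twice-weekly cohort at 48³; the acceptance script uses 5
recovery runs and a 14-plan cohort.

## Known limitations

* DICOM support covers axial CT series, RTSTRUCT planar contours
  (even-odd filled per slice, no between-slice interpolation) and rigid
  Spatial Registration objects; no DICOM writing of clinical objects,
  no deformable registration, no HU calibration.
* The gamma search radius and interpolation scheme used by any given
  clinical implementation are typically unpublished; absolute γ_x
  values are therefore implementation-dependent, which is why the MQP
  is always a *difference* against a reference match computed by the
  same engine.
* The alert system is a screening safeguard: the reference match
  quality bounds what later comparisons can reveal (a poor reference
  match suppresses contrast between later matches), and intensity-based
  gamma cannot see low-contrast internal change.
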