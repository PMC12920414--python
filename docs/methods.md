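# Methods

This note documents the models, conventions and numerical choices behind
`recurtrack`, and what its synthetic phantoms do and do not establish about
real data.

## Coordinate frame and masks

All volumes live on a `VolumeGrid`: an axis-aligned lattice with world
coordinates in mm, the world position of voxel `(i, j, k)` being
`origin + index * voxel_size`. The default is a 1 mm isotropic grid centered
on the world origin, modeling a template (MNI152-like) space; input masks
are assumed already registered to that space — registration itself is out
of scope. Lesion masks are strictly binary; voxel membership is by
voxel-center inclusion, matching binarized segmentations, with no partial
volume.

The mid-sagittal plane is pinned at world `x = 0`, with negative `x` = left
(configurable). Hemispheric standardization mirrors a mask about that plane
when its *centroid* lies on the left. On grids symmetric about `x = 0` the
mirror is an exact voxel-index reflection, hence an exact involution and
voxel-count preserving; on asymmetric grids world-coordinate reflection with
nearest-voxel assignment is used and a count change raises an error rather
than passing silently.

## Recurrence-specific maps

The recurrence-specific mask is the set difference `recurrent AND NOT
initial` — the voxels newly involved at recurrence. Descriptions of this
construction sometimes phrase it as subtracting the recurrent from the
initial volume and discarding negative voxels, which taken literally yields
the *initial-only* voxels; the implementation follows the stated intent
(voxels specific to recurrence). The result may be empty when the
recurrence lies wholly inside the initial lesion; that is a valid outcome,
not an error.

## Regional distribution statistics

Region tables count lesion voxels per atlas label (any integer label volume
plus a two-column lookup; the module is atlas-agnostic). Proportions are
relative to all lesion voxels, with off-atlas (background) voxels reported
separately and excluded from the test by default, since the question is
about anatomical structures.

The distribution-shift test is a chi-square on the regions × 2-timepoint
contingency table of voxel counts pooled across patients, without continuity
correction (standard for R×C tables), followed by a two-sided Fisher exact
test per region on the 2×2 collapse (this region vs all others). Pooled
voxels are not independent observations — neighboring voxels of one lesion
are strongly correlated — so the p-values describe the pooled-voxel
construction, not patient-level inference; per-patient region proportions
are exposed so users can run patient-level alternatives. Fisher p-values
are unadjusted by default (Holm / Benjamini-Hochberg available as an
option). Chi-square and Fisher computations are delegated to scipy.

## Deterministic tracking

The tracker is a FACT-style single-orientation, fixed-step integrator — not
a reimplementation of generalized q-sampling tractography. The analysis
consumes only streamline-level direction vectors, and externally computed
TRK/TCK tractograms can be substituted where fidelity matters.

Pinned conventions:

* **Step size.** A "0 mm" step in some tools is a sentinel for an adaptive
  default; here the default step is half the smallest voxel dimension
  (0.5 mm on the default grid), configurable.
* **Seeding.** One uniformly distributed point per attempt inside a
  uniformly chosen seed-mask voxel; growth is bidirectional, the two halves
  sharing one arc-length budget (forward grows first, backward spends the
  remainder), then concatenated.
* **Direction lookup** is nearest-voxel, exact on the piecewise-constant
  synthetic fields used in tests. The per-voxel direction is an axis
  (sign-ambiguous); each step follows the sign minimizing the turning angle
  against the incoming direction.
* **Termination.** Leaving the volume; anisotropy below the FA threshold
  (default 0.2); no orientation at the voxel; turning angle above the
  threshold (default 60°, a well-posedness requirement the source protocol
  leaves unstated); or the arc-length budget (default max 25 mm) spent.
* **Acceptance.** Total arc length within [min, max] (defaults 1–25 mm) and
  intersection with the endpoint mask (the seed mask is intersected by
  construction). The fiber-count parameter (default 5000) is the target
  number of *accepted* streamlines, capped by a seed-attempt budget
  (default 100 × target).

Tracking is deterministic given the seed; batches are drawn sequentially
from one generator so runs with identical seeds and budgets are
reproducible bit-for-bit.

## Progression vectors and MACC

Lesion centroids are unweighted means of voxel-center world coordinates.
The progression vector is the unit vector between the two centroids; it is
flagged undefined below 1e-6 mm separation, and such patients are excluded
rather than given an arbitrary direction.

MACC for one (patient, connectome) pair is the mean over streamlines of the
absolute Pearson correlation between the progression vector's 3 components
and each streamline's representative vector's 3 components (the normalized
endpoint displacement). Pearson on 3 components is scale- and
shift-invariant, so unit normalization of inputs does not affect it.
Absolute cosine similarity is provided as the alternative sign-invariant
metric. Streamlines with an undefined similarity (coincident endpoints;
zero component variance under Pearson, i.e. a vector proportional to
(1,1,1)) are excluded from the mean with a logged warning — coercing them
to 0 would bias MACC downward silently.

A patient whose lesion pair yields zero streamlines on every connectome is
flagged *remote*: its matrix entries are 0 (so heatmap-style outputs show
the case) but it is excluded from patient-level values and the cohort test
by default, reproducing the convention that a disconnected recurrence
admits no meaningful alignment measurement. An inclusion toggle retains
such rows for display-oriented aggregation.

## The cohort test and its null

Patient-level MACCs (row means over connectomes) feed a two-sided
one-sample t-test: `t = (mean − null)/(sd/√n)`, df = n − 1, sample SD with
the n − 1 denominator, 95% CI from the central t quantile, Cohen's
d = (mean − null)/sd. The default null mean is 0, reproducing the
conventional analysis. Note, however, that 0 is *not* the chance level of
an absolute similarity: for independent uniformly random unit 3-vectors
E|cos| = 1/2 and E|r| = 2/π ≈ 0.6366. `chance_level` estimates these by
Monte Carlo so users can test against chance instead; the discrepancy is
deliberate and documented rather than resolved.

Degenerate edge: a constant sample exactly at the null carries no
information and raises; a constant sample away from the null (which the
jitter-free synthetic construction produces, e.g. all MACCs exactly 1)
returns the decisive limit t = ±∞, p = 0 rather than failing — the
boundary case of perfect alignment.

## Synthetic cohorts: what they emulate and what they don't

The generator emulates the study geometry the analysis is designed for:
30 patients, one of them a remote recurrence, crossed with 30
orientation-field "connectomes" standing in for normative diffusion
subjects, on a 96×72×72 mm grid.

* **Lesions** are ellipsoids (default radii 8 mm, recurrent growth factor
  1.2): every downstream quantity depends only on voxel sets, so realistic
  tumor shapes would add nothing the tests could detect. Centers are
  snapped to voxel centers and displacements rounded to whole voxels
  (default (8, 4, 2) mm, magnitude ≈ 9 mm), so by lattice symmetry the
  discrete centroid displacement equals the configured displacement
  *exactly* and the progression vector is known analytically. Connected
  displacements are kept under 20 mm so centroid separations stay inside
  the 25 mm tracking limit with margin.
* **Orientation fields** have one principal direction at a configurable
  angle to the shared displacement, with per-voxel angular jitter: a
  rotation by a folded-normal angle (SD = jitter, default 10°) about a
  uniformly random axis perpendicular to the principal direction —
  isotropic dispersion about the principal axis, exactly reproducible, and
  exactly the principal direction at jitter 0. FA is constant (default 0.8).
* **Remote cases** are disconnected *by construction*: the inter-lesion gap
  (default 40 mm) must exceed the maximum tracking length, and the
  generator verifies the exact minimum voxel-center distance, so zero
  connecting streamlines is a geometric guarantee, not a sampling outcome.

Limitations worth stating plainly: voxel-level angular jitter largely
averages out along a streamline's path, so phantom MACCs sit near
|cos(alignment angle)| with little dispersion — much tighter than the
0.60 ± 0.23 spread reported for real cohorts, which reflects
patient-to-patient anatomical heterogeneity the phantom does not model.
Passing tests therefore establish the *estimator machinery* (geometry,
counting, exclusion rules, test arithmetic), not realistic effect sizes.
The generator also does not simulate diffusion MRI signal, crossing fibers,
edema/mass effect, or registration error.

## Problem sizes and numerics

Default test and acceptance runs use the full 30 × 30 cohort with the
streamline target reduced to 200 per pair (the 5000 default is a
production-scale setting; MACC is a mean over streamlines and stabilizes
far below that). Monte-Carlo checks of chance levels use 10⁶ draws
(standard error ≈ 3 × 10⁻⁴). Unit-norm tolerances are 1e-6 for direction
vectors; progression vectors below 1e-6 mm separation are undefined;
Fisher/chi-square delegate to scipy and are verified against exhaustive
hypergeometric enumeration for small margins in the test suite.
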