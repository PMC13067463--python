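# Methods

## Scope and assumptions

The package implements the statistical core of voxel-based
lesion–symptom mapping (VLSM) for extra-axial tumors. It assumes every
input mask is already a binary volume on one shared template grid
(NIfTI-1, nominally 1 mm isotropic, RAS+ with the midsagittal plane at
world x = 0). Spatial normalization, segmentation and DICOM handling are
deliberately out of scope: they are preprocessing steps with their own
established tools, and the inference downstream depends only on the
binary masks. Masks from different grids are rejected, not resampled
(affine agreement to 1e-4 absolute tolerance — loose enough for header
round-off, tight against real misregistration).

## Pipeline

1. **Mirroring.** All masks are reflected to the right hemisphere so
   that left- and right-sided tumors contribute to one statistical map.
   The rule is deterministic: flip along x (index i → X−1−i) iff the
   mask's center of mass lies more than 2 mm left of the midline. The
   2 mm band leaves falcine/parasagittal masks straddling the midline
   untouched; `midline_band_mm=0` selects the strict flip-everything-left
   behavior. Which variant an original study used is usually unstated,
   so both are available.
2. **DAZ extraction.** The dural attachment zone is the voxel-wise
   intersection of the tumor with the dural template (shell + falx +
   tentorium), optionally dilated. The default dilation of 1 voxel
   (26-connectivity) tolerates ~1 mm of registration or segmentation
   jitter that would otherwise miss one-voxel-thick dural sheets;
   dilation 0 is the literal intersection. Tumors with an empty
   intersection are excluded from DAZ analyses with a warning
   (configurable to a hard error); they indicate a segmentation or
   registration problem rather than a valid extra-axial lesion.
3. **Minimum-overlap filter.** Only voxels covered by at least
   `min_overlap` patients (default 10) enter the analysis. Sparsely
   covered voxels let one or two patients drive extreme statistics; the
   filter also caps sensitivity to small normalization errors.
4. **Voxel-wise GLM.** At each included voxel the endpoint is regressed
   on the binary lesion indicator; the one-tailed slope t (df = n−2)
   equals the pooled two-sample t and is computed in that closed form,
   vectorized over voxels. p → z conversion uses the exact Student-t
   survival function and the normal quantile, with |z| clamped at 8.2
   (p ≈ 1e-16) so underflow never produces infinities. Voxels with a
   constant lesion column or zero residual variance (perfect separation)
   are flagged degenerate, carry z = 0, and are excluded from inference;
   this keeps TFCE and permutation maxima finite. The tested direction
   defaults to "observational group enriched at lesioned voxels"
   (β₁ > 0); the opposite tail is selectable. Missing endpoint values
   drop the patient from that analysis only, and the lesion matrix is
   rebuilt so the overlap filter applies to the analyzed subset.
5. **Corrections.** Bonferroni and BH-FDR operate on the analytic
   one-sided p-values; the permutation methods (max-Z, max-TFCE) permute
   the outcome vector jointly across voxels — preserving the spatial
   covariance of the lesion masks — and compare each observed statistic
   with the null distribution of the map maximum. The corrected p is
   (1 + #{null ≥ obs}) / (B + 1): never zero, ties counted as
   exceedances. With a discrete outcome (binary endpoints) ties are
   common and the test is mildly conservative; the null calibration
   experiment measures this directly. m for Bonferroni is the number of
   tested (non-degenerate) voxels.

## TFCE

TFCE(v) = Σ_h e(h,v)^E · h^H · dh over thresholds h = dh, 2dh, … ≤ z(v),
where e(h,v) is the 26-connected component size containing v in the
supra-threshold map. Defaults H = 2, E = 0.5 (the values in universal
use), dh = max(z)/100, connectivity 26 — all exposed as parameters, since
published analyses rarely report the latter two. Negative z is clamped to
0 (one-sided, matching the one-tailed tests); a two-sided analysis can
enhance the map and its negation separately. The discretized sum is a
right-endpoint Riemann sum of a piecewise-constant integrand, so it
deviates from the exact integral (computed between consecutive distinct
heights) by at most one step's contribution per voxel; the relative error
is < 2 % at voxels carrying meaningful enhancement, while voxels whose
height barely clears a single step have scores of order dh with no
meaningful relative error — convergence checks therefore look at the map
maximum and at voxels above half the peak score.

## Phantom

The phantom replaces patient data with a fully specified geometry:

- **Grid and brain**: 64³ default grid at 1 mm, brain as an ellipsoid
  with semi-axes (25, 27, 22) mm centered on the origin — the largest
  that fits the default grid with the required shell + 2-voxel margin. A
  higher-resolution phantom is obtained by scaling grid, brain axes and
  mean tumor volume together (e.g. 1.5× on a 96³ grid).
- **Dura**: a closed shell between the brain ellipsoid and the same
  ellipsoid grown by 2 mm, a one-voxel midline falx above the tentorium
  level, and a horizontal posterior tentorium slab at z = −0.45c; falx
  and tentorium are carved out of the brain so brain and dura are
  disjoint, and all three parts form one 26-connected dural complex. The
  dural domain is partitioned into nine named compartments (falx,
  tentorium, left/right convexity, left/right perirolandic caps,
  frontal/posterior base, a medial-sphenoid analog).
- **Tumors**: balls around sampled dural attachment voxels, clipped to
  brain ∪ dura. No mass-effect deformation is simulated: extra-axial
  tumors displace rather than destroy tissue, and every statistic under
  test depends only on mask geometry. Radii follow a lognormal law on
  tumor volume. At the desk scale the default targets a mean of 1.2 ml
  with coefficient of variation 0.557 — the volume-to-brain ratio (≈2 %
  of the 58 ml phantom brain) and relative spread of surgical meningioma
  cohorts (≈32 ± 18 ml against ~1400 ml intracranial volume); a 1.5×
  scaled phantom pairs with a 4.05 ml mean. Radius and volume are
  linked through an effective clip factor κ = 0.6 (measured on the
  default geometry: surface attachments keep about half the ball,
  falx/tentorium attachments most of it).
- **Attachments**: a compartment is drawn from configurable weights,
  then a voxel inside it, concentrated around the compartment's anchor
  (the voxel nearest its centroid) with a 4 mm Gaussian scale. The
  default weights mimic reported meningioma site frequencies (falcine
  and convexity dominant, skull base next, tentorium rare) and are
  left/right symmetric. The concentration produces the focal
  frequency-map hotspots real cohorts show; it was set so that ≈80 % of
  a compartment's patients cover its anchor voxel, which is what makes a
  ≥10-patient overlap filter meaningful at cohorts of 40–120 patients.
- **Endpoints**: Bernoulli draws with
  logit q = logit(p0) + hot·(logit(p1) − logit(p0)) +
  volume_effect·(volume − mean volume), probabilities clamped to
  [0.001, 0.999] with a warning. Hot regions are compartment names
  (or left/right pairs — masks are mirrored, so implanted location
  effects are bilateral), or spheres in world coordinates.
- **Presets**: `null` (no association, p = 0.3 everywhere, n = 60),
  `hotspot` (p0 = 0.1, p1 = 0.6 at the perirolandic caps, n = 60, with
  the perirolandic attachment weight raised to 0.30 — a cohort enriched
  for the studied location, as a motor-outcome study would be), and
  `volume-confound` (endpoint driven purely by volume,
  volume_effect = 4 logit/ml, n = 120 — sized so that voxels deep enough
  to discriminate tumor volume still clear the 10-patient filter).

A truth sidecar records, per patient, the attachment voxel and
compartment, hot-region membership, radius and endpoint — sufficient to
regenerate each mask deterministically and to audit any analysis without
re-simulation.

What the phantom does **not** emulate: registration error, segmentation
noise, peritumoral edema, mass effect, anatomical variability between
patients, or realistic image intensities. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under ideal masks, not robustness to real-world preprocessing error.

## Numerical and design choices

- Connectivity defaults to 26 everywhere (components, dilation, TFCE),
  the standard for 3D cluster-based inference; 6 and 18 are selectable.
- The max-Z permutation null is computed through the per-permutation
  maximum t: z is strictly increasing in t at fixed df, so only the B
  maxima need the t → z conversion. The max-TFCE route recomputes the
  enhanced map per permutation.
- All cohort randomness flows from one integer seed; child seeds are
  spawned deterministically (`numpy` SeedSequence), and NIfTI outputs are
  written with fixed gzip metadata, so a fixed config + seed reproduces
  bit-identical files and manifest checksums.
- Experiment sizes (200 null cohorts of n = 40 with B = 200; 20
  replicates for recovery and volume-bias studies; 100 BH replicates)
  keep each experiment in the seconds-to-minutes range on one CPU while
  leaving the measured rates' Monte-Carlo error well below the margins
  of interest.

## Known limitations

- Univariable tests only: no covariate adjustment (lesion size,
  age), no multivariable or machine-learning mapping, no
  continuous-outcome rank tests.
- Cluster-forming-threshold methods (cluster extent/mass at a fixed
  height) are intentionally absent; TFCE replaces them.
- The dural template is trusted as given; constructing one from imaging
  is out of scope, and the phantom's template is geometric, not
  anatomical.
- Masks are never resampled between grids; cohorts acquired on
  different templates must be harmonized upstream.
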