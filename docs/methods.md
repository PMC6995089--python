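# Methods

This note documents the models, conventions and numerical choices
behind `facesym`, and what the synthetic-data tests do and do not show
about real stereophotogrammetric data.

## Mirror superimposition

Asymmetry is defined against the patient's own mirror image.  The
surface is reflected across a plane (Householder reflection; face
winding reversed so normals stay outward), bilateral landmark names are
swapped (`endocanthion_left` ↔ `endocanthion_right`, …; midline names
unchanged), and the five mirrored midface landmarks — subnasale plus
both inner and outer eye corners — are registered onto their original
positions by the closed-form least-squares rigid fit (Kabsch via the
centred cross-covariance, determinant-sign corrected).  Conventions and
why:

- **Rigid, no scaling.**  All metrics are absolute millimetre
  distances; isotropic scaling would deflate asymmetry.
- **Reflection applied explicitly, fit kept proper.**  The fitted
  motion always has det(R) = +1, so it is physically interpretable and
  the contract is testable (`det = +1` asserted to 1e-9).
- **Plane independence.**  The composition of the explicit reflection
  with the fitted proper motion is invariant to the reflection plane:
  two choices of plane differ by a rigid motion, which the
  least-squares fit absorbs.  Verified to ≤ 1e-6 mm end to end, along
  with invariance to rigid motions of the input.  The default plane
  (through subnasale, normal along the exocanthion axis) only keeps
  intermediate meshes visually sensible.
- **Equal landmark weights.**  No weighting scheme is documented for
  this kind of midface registration; equal weights are the neutral
  choice.
- **Degeneracy.**  Fewer than three correspondences, or a centred
  configuration whose second singular value is ≤ 1e-9 of the first
  (collinear landmarks), raises a degeneracy error rather than
  returning an underdetermined rotation.

Surface-based refinement (ICP) after landmark seeding is deliberately
absent: the measurement is defined by the five-landmark fit alone.

## Asymmetry metrics

- **HAD (Hausdorff absolute distance) field.**  Directed, per-vertex:
  for every vertex of the lower-face ROI of the *original* surface, the
  exact Euclidean distance to the nearest point (triangle interior,
  edge or vertex) of the *mirrored-registered* surface.  Summaries are
  the arithmetic mean and the maximum.  The directed form avoids
  boundary artefacts from the cropped mirror; a symmetric (two-sided)
  variant can be computed by swapping arguments and combining, but the
  directed form is the default and the one all calibration refers to.
  ROI-to-full-mirror is the default pairing for the same reason.
- **Exactness.**  Closest-point queries prune candidate triangles with
  a k-d tree over triangle centroids using the bound
  d(q, T) ≥ ‖q − centroid(T)‖ − radius(T), seeded by the distance to
  the nearest mesh vertex as an upper bound; surviving candidates are
  resolved with the exact point-triangle projection.  The pruning is
  conservative, so results equal exhaustive search (asserted to
  ≤ 1e-9 mm against an independent brute-force oracle).
- **Chin asymmetry** = distance from pogonion to its mirrored,
  registered image.  The upstream clinical literature never specifies
  the chin measurement precisely; this operationalization captures the
  clinical sign (lateral chin deviation), admits a closed-form oracle
  (a chin apex δ mm off the symmetric position scores exactly 2δ when
  the midface is symmetric), and matches the published 0–6 mm range.
  Regional closest-point summaries were rejected because they
  systematically under-read lateral shifts (a laterally shifted chin
  still lies close to the smooth mirrored surface).
- **Lower-face ROI.**  Half-space crop below the plane through
  subnasale whose normal is the cranio-caudal axis estimated from
  landmarks alone: the component of (subnasale − midpoint of the inner
  eye corners) orthogonal to the inter-exocanthion axis.  This keeps
  the pipeline frame-agnostic — no assumption about how the scanner
  orients the head.  Cropping keeps whole faces only (no triangle
  splitting): it is deterministic, idempotent, and sub-triangle
  precision is immaterial at millimetre scale.
- **Chin overlay region.**  A 15 mm-radius sphere around pogonion,
  used only for visualization; the chin score does not depend on it.
- Distances are reported at full precision internally; display
  rounding (0.1 mm, whole percent, two-decimal p-values) happens only
  at render time.

## Cohort statistics

- **Asymmetry classification.**  With three MRI levels per joint, a
  patient has *asymmetrical osseous destruction* when exactly one joint
  shows destruction, and *asymmetrical inflammatory activity* when
  exactly one joint is affected at all.  The destruction rule uniquely
  reproduces the published joint count (12 left-only + 15 right-only +
  8 bilateral = 27 asymmetric of 76, with 20/23 destroyed joints per
  side).  The printed count for asymmetrical inflammatory activity (31)
  is *not* reproducible from the printed marginals under the
  exactly-one-affected rule (which yields 10 on the only joint table
  consistent with all destruction constraints); the rule is kept
  because it is the destruction rule's natural analogue, and the
  discrepancy is documented rather than patched.
- **Pearson χ² without continuity correction** — the uncorrected
  statistic reproduces the published two-decimal p-values from the
  printed 2×2 cells; Yates-corrected values do not.
- **ROC.**  Positive call when score ≥ threshold.  Sensitivity and
  specificity are reported on the 1–6 mm grid; the AUC integrates the
  full empirical curve (all distinct cutpoints) and therefore equals
  the tie-aware pair-counting estimator.  Cutpoint selection maximizes
  the Youden index over the grid, ties resolved to the smallest
  threshold.  Closest-to-corner selection would be an easy swap but is
  not implemented as a config option because nothing downstream uses it.
- **Mann-Whitney U.**  Midranks for ties.  Exact enumeration when the
  combined sample is ≤ 20 *and* tie-free; otherwise the normal
  approximation with tie-corrected variance and no continuity
  correction.  The exact and uncorrected-asymptotic p-values agree to
  ~0.02 on average at n = 12 + 12 (single draws can differ by up to
  ~0.03 near p ≈ 0.8, where the uncorrected approximation is weakest).
- **Logistic regression** is the standard Newton/IRLS MLE
  (statsmodels), one continuous predictor at a time; non-convergence or
  exploding coefficients (perfect separation) raise rather than return
  garbage.  A zero-variance predictor short-circuits to the null model
  (slope 0, R² 0).  **Cox & Snell R²** = 1 − exp(2(ℓ₀ − ℓ₁)/n).
- **ICC(2,1)** — two-way random effects, absolute agreement, single
  measure — from the ANOVA mean squares:
  (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n).  An all-identical
  table returns 1 by convention (perfect agreement, zero variance).
- **No multiple-testing correction**; α = 0.05 throughout.  This
  mirrors the analysis the package reproduces and is deliberate.

## Synthetic faces

The face is a clipped half-ellipsoid height field z(x, y) (semi-axes
75 × 95 × 55 mm) plus Gaussian bumps: a nose (amplitude 12 mm, σ 9 mm),
a chin prominence (10 mm, σ 12 mm) centred δ mm off the midline, and
optional per-side antegonial notches (negative bumps at ±48 mm).  Grid
resolution is forced odd so the midline is a grid line, and the quad
diagonal direction flips between the two halves, making the
triangulated surface an *exactly* reflection-symmetric point set when
δ = σ = 0 — symmetric faces measure zero to machine precision, not just
to mesh resolution.  Landmarks are placed analytically on the surface;
midface landmark heights come from the symmetric surface so the
registration basis is exactly bilateral and the 2δ chin oracle is
closed-form.  Vertex noise σ jitters mesh vertices only (not
landmarks); measured HAD mean rises monotonically with σ.

This is a parametric phantom, not a statistical face-shape model: it
gives exact ground truth but does not emulate photogrammetric artefacts
(holes, hair occlusion, expression, landmark placement error).  Passing
the synthetic suite therefore demonstrates correctness of the geometry
and statistics, not robustness to real capture noise — landmark
placement error in particular feeds 1:1 into the chin score and is out
of scope here.

## Synthetic cohorts

Defaults are calibrated to the published cohort structure:

- Joint MRI levels are drawn from a 3×3 left×right table whose margins
  match the published per-side counts (19/37/20 left, 15/38/23 right of
  76) with 12 both-unaffected and the forced 12/15/8 destruction split
  (27/76 ≈ 35.5% asymmetrical destruction — the published table prints
  "27 (34.2%)", an internal inconsistency; the count is taken as
  authoritative).  The inflammation-level cross-structure is only
  partially constrained by the margins; the remaining cells are a
  documented choice.
- Chin and HAD values are log-normal conditional on destruction status,
  matched to the published medians and IQRs (chin 2.0 (3.0) vs
  4.0 (2.0) mm; HAD mean 1.5 (0.6) vs 1.7 (0.9) mm; HAD max 14.3 (10.4)
  vs 13.7 (5.3) mm), reported at 0.1 mm granularity.  Log-normal:
  positive, right-skewed, consistent with the reported non-normality,
  and the simplest two-parameter family matching a median/IQR pair.
- The clinical chin flag thresholds the true digital value at 4 mm with
  a 10% symmetric misclassification rate (a plausible palpation error
  rate; prevalence lands near the published 32%).  The gonion flag has
  no digital counterpart and is Bernoulli given status with the
  published conditional rates.  Treatment (none/systemic/local at
  16/31/29 of 76) is independent of asymmetry by default, with an
  optional log-odds-per-mm knob to induce the observed local-treatment
  association.
- All randomness flows from one seed through per-patient spawned
  streams, so any individual record is reproducible.

Two documented consequences of this calibration, verified analytically
and by simulation, are worth knowing:

- **Mann-Whitney power** for the chin-vs-destruction contrast at n = 76
  is ≈ 95% — comfortably consistent with the published significant
  contrast.
- **The Youden-optimal cutpoint is 2–3 mm, not the published 4 mm.**
  Under the median/IQR-matched log-normals the population Youden index
  is ≈ 0.47 at 2 mm, ≈ 0.44 at 3 mm and ≈ 0.25 at 4 mm, so simulated
  cohorts essentially never select 4 mm.  The published distributions
  evidently differ from any log-normal matched to their medians and
  IQRs in exactly the tail region that drives cutpoint selection.  The
  calibration is kept (it is the defensible choice given only printed
  summaries) and the divergence is documented instead of being tuned
  away; the corresponding acceptance check is expected to fail and says
  so in its docstring.
- Group sample medians at n = 76 have SE ≈ 0.36 mm, so parameter
  recovery of the 2/4 mm medians within ±0.5 mm holds per cohort about
  70% of the time jointly (84% per group) and is unbiased; tests assert
  those supportable rates.

## The published-count fixture

`fixture_published_counts()` reconstructs a deterministic 76-patient cohort
reproducing every printed 2×2 cell (gonion 26/19, clinical chin 11/13,
digital chin 16/17 positives by status), the 33-positive digital count,
and the treatment cross-tabulation (29 local, 16 of them positive; 16
untreated, 6 positive).  The joint assignment of treatment × digital ×
destruction is underdetermined by the printed margins; one integer
solution is fixed.  Continuous chin values are filled at 5.0/2.0 mm
consistent with the binary flags, which makes the fixture's rank-based
AUC 0.652 — with a binary score the AUC equals (sens + spec)/2 at the
single operating point.  The fixture reproduces the printed χ²
p-values (0.14/0.02/0.01) and PPVs (42/54/52%) exactly; the printed
p = 0.07 for the local-treatment contrast is *not* reproducible from
its printed cells (uncorrected Pearson gives 0.104) and is left as is.

## Problem sizes

Synthetic faces default to a 61×61 grid (~3.7k vertices, ~7.2k faces;
41×41 in the fastest tests), enough for sub-0.05 mm agreement with the
closed-form oracles.  Oracle equivalence is asserted on ~500-face
meshes, cohort calibration at n = 10,000, and power/cutpoint behaviour
over 200 cohorts of n = 76.

## Known limitations

- The chin score assumes pogonion is reliably identified; landmark
  error propagates directly (doubled) into the score.
- HAD max is sensitive to mesh boundary effects if the ROI extends to
  the scan edge; the whole-face crop mitigates but does not remove
  this on ragged real scans.
- The cohort generator conditions the continuous metrics on the
  destruction status only; it does not model within-patient coupling
  between chin and HAD beyond that shared conditioning.
- Binary PLY and XML-VTK are not parsed; OBJ/ASCII-PLY/legacy-ASCII-VTK
  cover the common photogrammetry toolchain.
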