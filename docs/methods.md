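# Methods

This note documents the models, algorithms and numerical choices behind
`uterovasc`, what the synthetic generators do and do not emulate, and the
known limitations of each stage.

## 1. Imaging markers

### Inputs

A scan is a 3D power-Doppler amplitude grid (arbitrary units, ≥ 0) on an
isotropic voxel lattice plus a binary placental-segment mask of the same
shape. Only isotropic spacing is supported: the length and thickness markers
multiply voxel counts by a single voxel edge length, which has no meaning on
an anisotropic lattice, so anisotropic NIfTI files are rejected rather than
silently resampled. The default voxel edge length for phantoms is 0.5 mm
(configurable); acquisition voxel size is scanner-dependent and must be taken
from the image header for real data. Scans graded 3 on the 0 (optimal) to 3
(unusable) quality scale are excluded from analysis.

### Volumes

- **PV** = mask voxel count × spacing³ / 1000 (cm³). The mask stands in for
  an expert tracing of the placental segment.
- **uPVV** = count of voxels with amplitude **strictly greater** than the
  threshold, inside the mask, × spacing³ / 1000. The Doppler threshold used
  by the original acquisition chain is not published, so the threshold is a
  required, logged parameter (0 suffices on noiseless phantoms). Thresholding
  is monotone: a larger threshold selects a subset.

### Skeletonization

The uPVS is produced by round-based thinning of the binary uPVV:

- **Connectivity.** 26-connectivity for foreground/skeleton adjacency and
  component counting throughout (the standard choice for 3D curve skeletons;
  it is also what makes degree-4 crossing voxels attainable).
- **Rounds and sub-iterations.** Border candidacy is frozen once per round
  (a voxel qualifies only if it has a background face neighbour *at round
  start*), so each round peels exactly one shell of the current object. The
  round is split into six directional sub-iterations (+z, −z, +y, −y, +x, −x)
  processed in fixed lexicographic order, which makes the output
  deterministic and orientation-robust.
- **Deletion rule.** A candidate is deleted only if it is a *simple point*
  on the current image — its removal changes neither the number of
  26-connected foreground components in its 3×3×3 neighbourhood nor the
  number of 6-connected background components of the 18-neighbourhood that
  touch it (Malandain–Bertrand characterization) — and it has at least two
  foreground neighbours (line ends are never deleted). Deletion is
  sequential with re-checking, so topology preservation is exact by
  construction, not just empirically.
- **Peel depth.** After round *r* completes, every surviving voxel
  26-adjacent to a voxel deleted in round *r* is stamped with depth *r*.
  A structure that is already one voxel wide keeps depth 0 everywhere; the
  centerline of a tube of radius *R* voxels ends with depth ≈ *R*. Whether
  the original instrument counts the first peeled layer as 0 or 1 is
  unpublished; "rounds survived" is fixed here and validated against tube
  phantoms (radius 1.0 mm recovers thickness 1.0 ± 0.5 mm at 0.5 mm
  spacing).
- **Spur pruning (default on).** Thinning a thick junction bulge or an
  aliased tube surface leaves short terminal spurs that are discretization
  artifacts. Terminal branches no longer than (max peel depth + 1) voxels
  that end at a junction are removed; spurs born from surface bumps cannot
  exceed the local tube radius in voxels, so the bound is data-driven. Whole
  components are never pruned, keeping component counts intact. On noiseless
  tree phantoms this step (plus consolidation, below) raised exact
  end/bifurcation-count recovery from 5/24 to 24/24 runs.
- **Junction consolidation (default on).** Where a vessel branches, the
  digital skeleton frequently contains a *triangle*: three mutually adjacent
  voxels, each of degree 3, created by a diagonal shortcut edge. No triangle
  member is a simple point, so thinning cannot reduce it, yet the true branch
  node is a single voxel. One triangle vertex with a single external
  neighbour is relocated to a free position (inside the original foreground)
  that reattaches its arm through the surviving junction voxel; the rewrite
  is accepted only if the relocated voxel's neighbours are exactly the arm
  and the junction, so connectivity and component counts are preserved by
  construction. Irreducible clusters that admit no such rewrite are left
  untouched (and counted as they stand).

### Skeleton classification and derived markers

Each skeleton voxel is classified by its count of 26-adjacent skeleton
voxels: 1 → end point, 2 → vessel point, 3 → bifurcation point, ≥ 4 →
crossing point. Degree 0 (isolated voxel) is counted as an end point and
degree > 4 as a crossing point so the partition is exhaustive — the
enumerated rule covers only degrees 1–4.

- total vascular length = skeleton voxel count × voxel edge length. This
  literal rule **underestimates** diagonally running vessels by up to √3
  (measured −8% to −19% against continuous truth on default tree phantoms).
  An optional Euclidean step-length correction (√2/√3 per edge/corner step;
  ±7% on the same phantoms) is provided but **off by default** to keep the
  printed definition.
- average vascular thickness = mean peel depth × voxel edge length. Under
  the literal formula a one-voxel-wide vessel has thickness 0; an optional
  "+0.5 voxel" offset is available but off by default.
- branching densities = end/bifurcation/crossing counts ÷ uPVV (n/cm³).

## 2. Vascular phantoms

Trees are generated in continuous millimetre space first and rasterized
second, so ground truth (tip/bifurcation/crossing counts, centerline length,
mean radius) is independent of any lattice; tests can therefore separate
algorithmic from discretization error. Defaults: trunk 16 mm × 1.2 mm
radius, per-generation length decay 0.75 and radius decay 0.8, branch angle
35°, binary splits with uniformly random azimuth. A tree with *d* full
binary generations has 2^d leaves (+1 tip for the trunk origin) and 2^d − 1
bifurcation nodes.

Crossing nodes cannot arise in a strict binary tree; on request a straight
"crossing bar" pierces a segment at its midpoint perpendicular to it,
producing a degree-4 skeleton voxel.

Tubes are **capsules** (cylinders with hemispherical caps), the standard CSG
tube primitive: caps keep junction elbows gap-free and terminal vessels
rounded. This choice matters: flat-capped cylinders erode skeleton tips by
about one radius (the true medial axis of a flat-ended cylinder stops a
radius short of the cap), which loses endpoints and length. Rasterization
marks a voxel foreground when at least half of a 2×2×2 sub-sample of its
volume lies inside a capsule; analytic volume comparisons are made against
the capsule volume πr²L + 4/3·πr³ per segment (junction overlap not
subtracted). Measured discretization bias at spacing = radius/3 is ≈ +13%
and shrinks as spacing decreases. Tubes thinner than the voxel spacing are
not resolvable and trigger a warning.

Noise is additive Gaussian on amplitude, clipped at 0, off by default — a
deliberately crude stand-in for Doppler speckle. The mask is the tree's
bounding box dilated by a margin. Fixed seeds give bit-identical phantoms
and rasters.

## 3. Synthetic cohort

The generator produces the statistical structure the association stage
assumes; it does **not** produce images (an optional route through the
phantom generator exists for single scans, but cohort-scale marker values
are simulated directly).

Stated world, chosen once:

- **Size and schedule.** 185 subjects; visits at 49/63/77 days GA with ±3
  days uniform jitter; one of the three visits dropped with probability 0.15
  (every subject keeps at least two).
- **Trajectories.** On each marker's analysis scale, a quadratic in centred
  GA passes exactly through anchor values at 7/9/11 weeks chosen from
  realistic first-trimester ranges (e.g. PV 10 → 25 → 60 cm³, uPVV 0.5 →
  1.5 → 4 cm³, total length 400 → 800 → 1400 mm; branching densities decline
  as the vascular volume outgrows the junction counts).
- **Noise.** Subject random intercept SD = 10% and visit residual SD = 8% of
  the 9-week transformed level per marker. These fractions keep transformed
  values ≳ 3 SDs above zero, so inverting the transform (squaring/cubing)
  virtually never needs the floor-at-zero guard; floored values are counted
  in `visits.attrs`.
- **Biomarkers.** Lognormal, constant within subject (drawn once, as at the
  11-week blood draw), with ln-scale moments matched to the printed cohort
  summaries (PlGF 41.6 ± 17.4 pg/mL, sFlt-1 1332.6 ± 489 pg/mL, sEng
  8.6 ± 2.8 ng/mL) and mild ln-scale correlations (0.3 PlGF–sFlt-1, 0.1
  otherwise). Ratios are computed exactly from the drawn values.
- **Coupling.** `effects[(biomarker, marker)] = β` adds β × (transformed
  biomarker − its true mean) to the marker's transformed value — the same
  scales the mixed model fits, so injected and recovered coefficients are
  directly comparable. Centring keeps marker levels on the anchor
  trajectory and does not change the regression coefficient.
- **Covariates.** Frequencies follow the source cohort's baseline table
  (age 32.3 ± 4.4 y, BMI 26.0 ± 5.2, 57.8% nulliparous, 57.8% IVF/ICSI,
  49.2% male fetus, 14.6% smoking, 28.1% alcohol, 83.8% folic acid). Default
  covariate effects: smoking −0.3 and alcohol −0.1 between-subject SDs on
  every marker. Covariates are independent of the biomarkers, so omitting
  them does not confound β; they give model 2 something real to adjust for.
- **Outcomes.** Latent clinical variables (peak blood pressures, 24-h
  proteinuria, two fetal growth percentiles, birth-weight percentile, GA at
  birth) are drawn with marginally calibrated distributions, all coupled to
  one standard-normal liability that correlates −0.3 with standardized ln
  PlGF (higher risk where PlGF is low). The published definitions are then
  applied verbatim: PIH = SBP ≥ 140 and/or DBP ≥ 90 after 20 weeks; PE =
  PIH + ≥ 300 mg/24 h proteinuria; FGR = growth percentile < 10 or a
  > 20-percentile drop between measurements; SGA = birth weight < 10th
  percentile; PTB = birth < 37+0 weeks. Latent distributions were calibrated
  so ~25% of subjects carry any complication (subtype rates ≈ 7/2/8/10/10%),
  matching the source cohort's 24.9%. GA at birth uses an offset-gamma
  (280 − Gamma(2, 5.3) days): the printed mean ± SD ("38+5 ± 20 days") is
  irreconcilable with the printed 9.7% preterm rate under normality, and a
  left-skewed GA distribution is the standard description.
- **Pregnancy dating** implements the cohort's rules: LMP dating only for
  regular 25–35-day cycles; CRL-based GA wins when it differs from LMP
  dating by > 6 days; fresh IVF/ICSI = oocyte pick-up + 14 days; cryo
  transfer = transfer date + 19 days.
- **Enrollment/exclusions.** A manifest helper reproduces the study flow
  (241 enrolled; 1 withdrawal, 22 miscarriages, 4 oocyte donations, 29
  missing serum → 185 analysable), and `apply_exclusions` drops any subject
  with a recorded reason, reporting counts per reason.

What a green test on this generator does *not* establish: robustness to real
Doppler speckle and flash artifacts, to segmentation error in the placental
mask, to informative missingness (visits here are missing completely at
random), or to within-subject biomarker dynamics (a single 11-week draw is
assumed, as in the source design).

## 4. Association stage

- **Transforms.** Volumes → cube root; counts, lengths, thickness → square
  root; densities and ratios → natural log; PlGF and sFlt-1 → natural log;
  sEng enters untransformed (following the published analysis scales).
  Zero counts under a log (possible only for zero branching counts) are
  offset by half the smallest positive observed value of that column, with
  the offset and count recorded in the frame's provenance attributes.
- **Mixed model.** Fixed effects: centred GA (weeks), GA², the transformed
  biomarker, and for model 2 the nine adjustment covariates (age, BMI,
  nulliparity, conception mode, fetal sex, smoking, alcohol, folic acid;
  categorical terms dummy-coded). Random effects: subject intercept only —
  with 2–3 visits per subject a random slope is weakly identified.
  Estimation: REML (statsmodels MixedLM); Wald 95% CIs; convergence reported
  honestly (`converged=False`, never a silent fallback). GA is centred at 63
  days before squaring to decorrelate the trend terms; the exposure
  coefficient is unaffected by centring. No biomarker × GA interaction is
  fitted (a single β per pair implies a constant trajectory shift), and no
  multiple-testing correction is applied, matching the published analysis.
- **Group comparison.** Equal-variance Student's t between subjects with and
  without placenta-related complications, with mean/SD and median/IQR per
  group.
- **Stratified correlations.** Unadjusted Pearson r per stratum (conception
  mode, fetal sex, complication status) between the transformed biomarker
  and the subject-mean transformed marker; between-stratum differences by
  Fisher r-to-z (the original subgroup-difference method is unstated; this
  is a package decision). Perfect correlations have undefined z and report
  NaN.
- **Parameter recovery.** `recover_parameters` generates ≥ 50 (default 200)
  seeded replicate cohorts with a known injected β, refits the model, and
  reports mean recovered β, bias, empirical SE, Monte-Carlo SE of the mean,
  95% CI coverage and the non-convergence rate (> 10% is flagged). Under the
  defaults the estimator is unbiased within Monte-Carlo error and coverage
  sits in [0.92, 0.98].

## 5. Numerical choices and degenerate inputs

- Empty mask → PV 0 with a warning; empty thresholded volume → empty
  skeleton and all-zero metrics; a non-empty skeleton with zero uPVV is an
  inconsistency error.
- Isolated skeleton voxels count as end points; they contribute one voxel
  length under the optional Euclidean length correction.
- NIfTI round-trips are bit-exact for integer dtypes; spacing is compared
  with 1e-3 relative tolerance when checking isotropy.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; replicate seeds are derived affinely and kept
  below 2³¹.

## 6. Known limitations

- Equivalence with the original instrument's unpublished thinning cannot be
  claimed — only consistency with its verbal description and with phantom
  ground truth.
- The voxel-count length bias (−8…−19% on phantoms) is inherent to the
  printed definition; trend analyses are unaffected (the bias is
  orientation-, not GA-, dependent), but absolute lengths are conservative.
- Junction clusters that are not triangles (e.g. degree-4 smears from true
  crossings) are not consolidated; crossing-point counts on real data remain
  a cluster-level proxy.
- The cohort generator's between-/within-subject variance split is a package
  choice (the source reports no within-subject correlation); recovery
  results are insensitive to the split, but CI widths are not comparable to
  the published ones.
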