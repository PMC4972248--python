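# Methods

This note documents the models, numerical choices, and defaults behind
`airwaymorph`, and what the synthetic phantoms do and do not emulate.

## Coordinate and geometry conventions

All geometry is computed in physical millimetres.  Voxel indices are
0-based and the physical position of voxel *i* is
`origin + (i + 0.5) · spacing` (voxel-centre convention).  This matters
because the target acquisitions are strongly anisotropic
(0.5 × 0.5 × 3.3 mm): index-space geometry would distort every moment,
length and distance by up to a factor 6.6 along the slice axis.

Masks are stored per object, not as one exclusive label map, because the
four composite objects (ph, tn, at, pm) are defined as voxel unions of
their components and therefore overlap them by construction.

## Object size: principal-axis dispersions

The size measure sums the three principal-axis dispersions of the
object's voxel-centre cloud: `λᵢ := sqrt(eigᵢ(Σ))` where Σ is the
(population) covariance of the coordinates in mm.  Taking square roots —
rather than using the covariance eigenvalues directly — is a deliberate
choice: eigenvalues of a coordinate covariance carry mm², and only their
square roots make the normalized size `S_λ = (λ₁+λ₂+λ₃)/L` unit-less, as
the measure is defined to be.  The λᵢ are then the standard deviations of
the object's mass along its principal axes, which is also what makes the
"sum of axis lengths of an approximating ellipsoid" reading work: for a
uniform ellipsoid with semi-axes (a, b, c) the dispersions are
(a, b, c)/√5, so the dispersion sum is proportional to the semi-axis sum.
This closed form anchors the calibration tests (2% tolerance at 0.5 mm
isotropic digitization).

## Normalization length L

`L` is the diagonal of the axis-aligned bounding box of the mandible in
physical coordinates, with per-axis extent `(i_max − i_min + 1) ·
spacing` so that a single-voxel object has the extent of one voxel.  The
box is axis-aligned (not a minimal oriented box): it is deterministic,
requires no orientation search, and is used purely as a per-subject body
size surrogate.  All of `S_λ`, `S_V`, `S_A` and the inter-object
distances are normalized by the appropriate power of L, making them
invariant under a global isotropic scaling of the subject (mandible
included); the test suite verifies this invariance to 2% on an
isotropic-resolution phantom, which isolates digitization error from
resampling effects.

## Surface mesh, volume, and sphericity

Surfaces are extracted by marching cubes at the 0.5 iso-level of the
binary mask, after cropping to the object's bounding box (plus a
background pad so the surface closes).  The binary grid is pre-smoothed
with a Gaussian of σ = 1 voxel before iso-surfacing: marching cubes on a
raw binary volume yields a staircase surface whose area overestimates a
smooth boundary by ~9% in-plane and by ~25% across 3.3 mm slices, while
after smoothing a digitized sphere's area and volume agree with the
closed forms to well under 1% at isotropic resolution.  Objects so small
that smoothing pulls the whole field below the iso-level (a few voxels)
fall back to the raw binary surface.  Volume is the divergence-theorem
integral over the closed mesh (trimesh); area is the summed triangle
area; meshes failing the watertight check raise an error naming the
object.

Sphericity is `S_P = ∛(36π V²)/A`, exactly 1 for a sphere and smaller
for every other shape (the isoperimetric inequality); it is invariant to
whether raw or L-normalized V and A are supplied.  A digitized sphere at
0.5 mm isotropic resolution evaluates to within 0.03 of 1.

Known limitation: across 3.3 mm slices the meshed surface area of an
anatomically sized object retains a systematic ≈ 4–5% excess relative to
the isotropic-grid value even after smoothing, and sphericity inherits
it.  Cross-resolution agreement is therefore verified at a 5% tolerance
on an object spanning a reasonable number of slices; features compared
*within* a cohort share the same acquisition grid and are unaffected by
this bias.

## Intensity standardization

MR intensities have no tissue-specific numeric meaning across subjects.
The standardization module implements the classical two-stage landmark
scheme: for each training volume, the intensities at the percentiles
(1, 10, 20, …, 90, 99) of the foreground histogram (foreground = the
`sk` body mask) are computed; each volume's [p1, p99] is mapped linearly
onto the fixed standard scale [0, 4095]; the standard landmarks are the
per-percentile means, nudged to strict monotonicity.  A volume is
standardized by piecewise-linear interpolation sending its own landmarks
onto the standard ones, with linear continuation outside [p1, p99] and
clipping to the scale.  The transform is monotone non-decreasing, removes
per-subject affine (gain/offset) distortions exactly (percentiles are
equivariant under increasing affine maps), and is idempotent to well
under 1% of the scale.

Two structural caveats follow from the construction and are reflected in
the phantom design below: (a) a *global* intensity shift of the whole
body is, by design, removed by standardization — only shifts that are
local relative to the histogram survive; (b) absolute standardized values
depend on the training cohort, so only group *contrasts* within a cohort
are meaningful.

## Salient-feature selection

Correlations are Pearson, computed over all subjects with groups pooled;
zero-variance features get correlation 0 with a warning.  `U(δ, M_L)`
counts, for each feature, the *other* features whose correlation lies in
[−δ, δ] (self-correlation excluded) and admits those with count ≥ M_L.
Group separation uses the two-tailed Welch (unequal-variance) t-test with
strict `p < α`, α = 0.05, and deliberately no multiple-testing
correction — the screen is a filter feeding an intersection, not an
inferential endpoint; a Benjamini–Hochberg option exists but is off by
default.  Degenerate features with zero variance in both groups take the
convention t = 0 (p = 1 when the means agree).

The salient set is `ϕ = U ∩ Q`.  Since U is monotone in δ at fixed M_L,
the ϕ sets are nested along a δ grid (default 0.01…1.00 step 0.01), which
defines the importance order: members of Q sorted by the δ at which they
first enter ϕ (ties broken by p-value, then catalog order), followed by
non-members of Q sorted by p-value.  The reported ϕ uses the smallest
grid δ whose ϕ attains the best cross-validated accuracy; only the
distinct nested sets (at most |Q| + 1) are evaluated.

Defaults M_L = 100 and the δ-sweep over the full grid follow the
procedure the pipeline operationalizes; both are configurable.

## Predictability testing

Logistic regression is fitted on features z-scored with training-set
statistics, with a small ridge penalty (default 1e-3 on standardized
coefficients, intercept unpenalized).  The penalty is a numerical
necessity, not a tuning knob: ~16 features on 24 training subjects are
linearly separable with probability near 1, and the unpenalized maximum
likelihood diverges.

Validation draws, in each of 30 repeats, a uniformly random test subset
of n = 6 of the m = 30 subjects (fresh draw each repeat — not a
partition, and class balance is not enforced), fits on the remaining 24,
and predicts the held-out 6.  All 180 test predictions are pooled before
computing accuracy, TP (sensitivity) and FP (100 − specificity) at the
0.5 probability threshold; pooling is what gives the metrics a
granularity finer than 1/6.  ROC curves sweep all distinct pooled
probabilities; AUC is trapezoidal and equals the normalized Mann–Whitney
U statistic (verified in tests).  The identity
`accuracy = (TP·n₁ + (100−FP)·n₀)/(n₁+n₀)` over pooled counts is asserted
on every result.  The feature set is fixed across repeats, so the
estimate carries the optimistic bias of selecting ϕ on the full cohort;
the package reports it as such rather than re-selecting per fold.

## Synthetic phantoms: what they emulate

`generate_phantom_cohort` builds two groups of subjects on a
160 × 160 × 36 grid at 0.5 × 0.5 × 3.3 mm (an 80 × 80 × 118.8 mm field),
each subject an assembly of ten axis-aligned ellipsoids in a schematic
but anatomically inspired arrangement: midline airway tubes
(high-eccentricity ellipsoids), paired tonsils lateral to them, fat pad
posterolateral, adenoid posterosuperior, all inside a large body
ellipsoid.  Between-subject variability: 4% CV on semi-axes, 1.5 mm SD
centre jitter, 3% CV on object mean intensity, truncated at ±2.5 SD so
every draw provably fits the grid.  Intensities are T2-like (air dark,
fat bright), with voxel noise (SD 60) and a per-subject affine
gain/offset distortion (gain 0.85–1.25, offset ±80) that the
standardization stage must remove.

Default group-1 effects follow the directionality reported for pediatric
OSAS — larger adenoid (+6% size, with an intensity shift), larger fat pad
displaced toward the tongue, an elongated/narrowed (less spherical)
oropharynx, and a tonsil intensity shift — with magnitudes chosen to give
per-feature standardized contrasts of roughly 1.5–2 SD, the same order as
the published group contrasts while retaining power at the desk-scale
cohort of 15 + 15.  Two design constraints are deliberate: intensity
effects sit on objects occupying a small fraction of the body histogram
(adenoid, one tonsil), because standardization absorbs shifts that move
the histogram landmarks themselves; and the bright-tissue fraction of the
histogram is kept clear of the p90 landmark so the landmark map is not
group-coupled.  Ground truth records the generative parameters, six
headline target features, and the full set of features causally
downstream of the effects (including propagation into composite objects,
whose geometry, intensity and centroids inherit component changes) — the
set used when tests check that the δ-sweep recovers planted structure.

What the phantoms do **not** emulate: MR physics (bias fields, partial
volume, coil profiles), non-ellipsoidal or deformable anatomy,
segmentation error, and the real covariance structure of anatomical
measurements.  Passing end-to-end tests therefore demonstrates that the
pipeline recovers group structure of the planted kind at realistic effect
sizes and cohort sizes — not that it would attain any particular accuracy
on clinical data.

`generate_feature_table` bypasses imaging entirely: multivariate Gaussian
features with unit variance, optional compound-symmetry correlation
blocks, and a planted mean shift Δ on chosen features for group 1.  It is
the workhorse for statistical-calibration tests (null rejection rates,
power, cross-validation behaviour under the null) where the quantity of
interest is distributional, not geometric.

## Problem sizes used in the shipped tests

The default test suite runs one full phantom cohort (30 subjects,
160 × 160 × 36 grids) end to end, 1000 brute-force selection
enumerations on 10-feature tables, 500-replicate calibration simulations
at n = 15 per group, and 25-replicate null cross-validation runs — about
a minute of compute in total, chosen to keep the statistical assertions
sharp (2 SE bands) at interactive runtimes.
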