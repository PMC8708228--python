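# Methods

This note documents the models, algorithms and numerical conventions
implemented in `mandiblefit`, the choices that were genuinely open, and the
limits of what the synthetic validation can show.

## Problem setting

Preformed (population-shaped) osteosynthesis plates are designed once, from
a training cohort of mandibular surface meshes, and must then fit unseen
patients well enough that a surgeon does not have to bend them: the working
criterion is that the largest gap between the plate's bone-facing surface
and the bone stays within 1.5 mm, while the plate must not penetrate the
bone. The package implements both halves of that workflow:

1. **Design**: corresponded cohort → per-region statistical shape model →
   S/M/L design surfaces → plate back-surface geometry.
2. **Evaluation**: virtual fitting of every plate to every specimen of a
   test cohort, followed by fit-percentage tables.

## Synthetic cohorts

Clinical CT cohorts cannot be redistributed, so all validation runs on a
parametric stand-in (`synthetic` module). The template is a horseshoe
ribbon: a semi-elliptical dental-arch centreline (half-width 52 mm, depth
55 mm, arch half-angle 130°) that rises posteriorly by 35 mm into two rami,
swept vertically from the lower border (v = 0) to the upper border (v = 1)
with a sinusoidal lateral bulge of 4 mm to give the cross-section curvature.
It is triangulated on an (nu × nv) quad grid (default 81 × 10; 81 is odd so
a vertex column lies exactly on the midline) and is bilaterally symmetric
about x = 0. Named regions (symphysis, body, angle, condyle; the latter
three in left/right pairs) are u-interval bands of the grid; two
mental-foramen analogues on the body serve as keep-out zones; eight named
landmarks anchor registration.

Specimens are drawn as

    vertices_k = template + Σ_m s_km · field_m + ε,  ε ~ N(0, noise_sd²) i.i.d.

with three fixed analytic displacement fields:

| mode | meaning | field | default score sd |
|---|---|---|---|
| 1 | allometric size | 2.5% isotropic growth about the centroid **plus** 0.35 mm·v disproportionate ramus-height growth per unit score | 2.0 (≈5% centroid-size CV) |
| 2 | arch width | 2% lateral (x) scaling per unit score | 1.0 |
| 3 | gonial flare | outward bulge of the angle region, Gaussian in arch parameter, 1 mm per unit | 0.5 |

Mode 1 deliberately couples size with shape so that the first principal
component of the un-size-standardised shape space carries allometry — the
structure the design method relies on. Group structure is additive mean
shifts on the mode scores: sex ±1.2 on mode 1 (sexual dimorphism in size),
population group ±0.4 on mode 2. Default cohort compositions mirror the
study design this package replicates: a training cohort of 127 (37
European: 14 M/23 F; 90 Asian: 48 M/42 F) and a test cohort of 50 (30
European: 18 M/12 F; 20 Asian: 6 M/14 F). Per-vertex noise defaults to
0.05 mm (below CT voxel scale). Everything is reproducible from one seed.

One source inconsistency is worth recording: the cohort is described in one
place as 115 scans and elsewhere as 127 mandibles with the 37 + 90
breakdown; the generator follows the detailed breakdown (127).

**What the generator does *not* emulate** — and therefore what passing
tests cannot show about clinical data: local surface detail (muscle
attachment rugosity, tori, alveolar ridge irregularity), asymmetry beyond
measurement noise, age-related atrophy, segmentation artefacts, and
non-rigid inter-subject variation beyond the three smooth modes. Because
the synthetic surfaces are smooth and the test cohort is drawn from the
same population as the training cohort, synthetic fit percentages are far
higher (≈100% at default variance) than the 47–90% per-cell rates observed
on clinical CT cohorts; the synthetic study validates the *machinery*
(correspondence, model fitting, quantile design, constrained fitting,
aggregation), not clinical fit rates.

## Correspondence

The template is brought onto each raw target mesh in three steps: rigid
Kabsch alignment over shared landmark names; a 3D thin-plate-spline warp
(biharmonic kernel U(r) = r, exact interpolation at λ = 0, optional ridge
λ > 0) of the template onto the target landmarks; and closest-point
projection of every warped vertex onto the target surface. This is a
simplified, fully specified stand-in for elastic surface registration: it
is adequate here because the downstream statistics only require *a*
consistent correspondence, and the synthetic cohort provides exact ground
truth to test it against (registering a rigidly scattered corresponded
specimen returns its own vertices). Projections farther than 5 mm are
reported as outliers; specimens without usable landmarks are skipped with a
warning. The 8-landmark scheme is a package convention, not a claim about
the original clinical procedure.

## Statistical shape model

Per region, in order:

* **Region extraction** keeps faces whose three vertices all belong to the
  region and reindexes densely, retaining the map back to template indices.
* **Generalized Procrustes analysis** (rigid only — *no scaling*, so size
  and hence allometry stay in the data): all specimens are centred, then
  iteratively re-aligned to the evolving consensus mean until the mean's
  RMS displacement falls below 1e-8 mm (max 100 iterations; exceeding the
  cap raises an error with diagnostics). The output frame is defined only
  up to one global rotation; invariance tests therefore compare alignments
  after removing that single rotation.
* **PCA** via SVD of the centred data matrix (rank ≤ n−1 handled
  naturally). Component signs are fixed deterministically; in the assembled
  region model PC1 is additionally oriented so its score increases with
  centroid size, making "higher quantile = larger plate" hold by
  construction.
* **Allometric regression**: per-coordinate OLS of aligned shape on the PC1
  score (slope = Cov/Var; when the regressors are the data's own PC1
  scores the slope vector equals the first component exactly, which is used
  as a test oracle).
* **Quantile surfaces**: the design surface for size S/M/L is the
  regression prediction at the 20/50/80% empirical quantile of PC1 scores
  (linear interpolation between order statistics — any quantile convention
  would be defensible; this one is documented and fixed). Because the
  regression is on an allometric axis, the sizes differ in shape, not just
  scale.

Per-region (rather than whole-mandible) Procrustes alignment is used: each
region's vertex subset is aligned independently before its PCA.

## Plate design

A plate is represented by exactly what the fit analysis measures: the
sampled point set of its bone-facing back surface with outward normals —
not a solid mesh. The layout follows the two-miniplate principle: an upper
bar in the tension zone and a lower bar in the pressure zone, joined by
evenly spaced connectors, traced in the region's unit parameter square and
evaluated on the triangulated quantile surface (piecewise-linear within
each grid triangle, so back points lie exactly on the design surface).
Three labelled start points (both lower-bar ends, upper-bar midpoint) are
carried for initial positioning, along with their layout parameters so the
matching ending points can be evaluated on any corresponded specimen.

No published plate dimensions exist, so bar placement (v ≈ 0.2–0.72),
margins and connector counts are versioned package defaults; the fit
analysis depends on the back-surface footprint, not manufacturing detail.
Types condyle/body/angle come in S/M/L; the symphysis plate in M/L only.
Right-side plates are sagittal mirrors of left-side designs.

## Virtual fitting

Per test, in the order of the emulated procedure:

1. **Three-point initial positioning**: Kabsch fit of the three plate start
   points onto their ending points on the bone.
2. **Keep-out correction** (deterministic replacement for manual
   repositioning): while any back point lies inside a keep-out sphere
   (mental foramen analogue, radius 3 mm), translate the plate in 0.25 mm
   steps along the bone-tangent component of the direction away from the
   zone centre; failing to clear within 10 mm total records the test as a
   failure.
3. **Tolerance-constrained best-fit**: iterative closest point with a
   penetration penalty. Each iteration matches transformed back points to
   their closest surface points and solves a weighted Kabsch step in which
   points penetrating beyond `penetration_tol` (default 0.1 mm) are
   up-weighted by `w_pen` = 10. The weighted objective cannot increase for
   fixed matches; the phase ends when the pose update's RMS falls below
   1e-6 mm, or when the objective improves by less than 0.1% for eight
   consecutive iterations (binary penalty weights otherwise lock the
   iteration into small limit cycles), keeping the best pose seen. Because
   point-to-point steps constrain tangential sliding only weakly, a
   point-to-plane Gauss–Newton polish (damped, line-searched, monotone in
   the weighted squared signed distances) then refines the pose. Finally,
   any residual penetration beyond tolerance is projected out by
   translating along the area-weighted mean bone normal of the penetrating
   contacts by the minimal restoring amount.
4. **Measurement and classification**: signed distances (positive = gap,
   negative = penetration; angle-weighted pseudonormals disambiguate edge
   and vertex feet) of every back point to the bone; a plate *fits* when
   the maximum gap is ≤ 1.5 mm (inclusive at the boundary, a declared
   convention) — penetration is bounded separately by the tolerance and
   does not count as misfit. All back points enter the criterion.

The study driver runs 20 tests per specimen (9 bilateral type-sizes × both
sides + 2 midline symphysis sizes). Right-side tests fit the left design to
the sagittally mirrored specimen re-expressed in template correspondence
(u-columns flipped, x negated) — equivalent to fitting the mirrored plate,
and exactly symmetric on noiseless specimens. Per-test errors are recorded
as failures and the run continues.

Geometric queries use exact point-triangle distances with a KD-tree over
triangle centroids for candidate pruning: an upper bound from the k nearest
candidates is widened by the largest triangle circumradius, so results
equal the brute-force minimum (verified against an independent brute-force
implementation) at sublinear cost.

## Reporting

Percent fit per type × size cell, pooled per-type totals, and subgroup
tables by side/sex/group are rounded half-up to integers; the pooled
overall rate is reported to one decimal. With equal per-size counts the
pooled type total equals the mean of the per-size percentages, which is how
the published table's Total column is reproduced from its cells. Subgroup
differences use Fisher's exact test (two levels; the original analysis
names no test — this is a package convention, validated against a
hypergeometric enumeration oracle). Every summary is recomputable from the
raw per-test CSV; there is no hidden state.

## Problem sizes and determinism

Default template resolution 81 × 10 (810 vertices, 1440 faces), chosen so
regions resolve 5–14 grid columns and a full 1000-test study completes in a
few minutes on one CPU; unit tests use a 40 × 8 template. The acceptance
script runs the full study design (127 + 50 specimens, 1000 tests) plus
100-trial pose-recovery loops. All randomness flows through explicit seeds;
repeated runs are byte-identical.

## Known limitations

* The correspondence stand-in assumes landmarks are available and roughly
  uniform coverage; it does not optimise correspondence (no sliding
  semi-landmarks, no MDL).
* The ICP capture range relies on the three-point initialisation being on
  the correct anatomy; there is no global search.
* Fit percentages on the synthetic population are near the ceiling at the
  default variance; they respond to variance (doubling mode sds lowers
  them) but are not calibrated to clinical rates, for the reasons above.
* The keep-out rule translates only (no rotation) and handles zones one at
  a time; pathological zone configurations can be declared unfixable that
  a human repositioning could resolve.
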