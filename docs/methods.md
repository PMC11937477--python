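# Methods

`bronchowall` quantifies bronchial-wall inflammation from multimodal chest
imaging the way a CT/MRI airway study would: airway geometry is measured on
a CT-like volume, a UTE-like volume serves as the common reference frame,
and a T2w-like volume carries the inflammation-sensitive signal.  Because
no patient data ship with the package, every stage is driven and validated
by a synthetic phantom whose ground truth is analytic.

## The phantom

The airway is a symmetric dichotomous tree: trachea (generation 0) plus
three generations of branches, branch angle 35°, generation length ratio
0.9, trachea length 15 mm, with the bifurcation plane rotated 90° at each
generation so the eight terminal branches do not collide on a
96³ × 0.625 mm grid (the CT voxel size of typical chest protocols).  Each
branch is a capsule tube with per-generation lumen radius
(3.0, 2.5, 2.1, 1.8 mm) and wall thickness (2.0, 1.8, 1.65, 1.5 mm).  Two
geometry constraints matter and are deliberate:

- walls stay well above one voxel everywhere, including under the shear of
  the default deformation, so the rendered shell is watertight for
  face-connected region growing;
- terminal branches are at least two lumen diameters long so the two
  measurement sites at 1/3 and 2/3 of the arc length clear the bifurcation
  zones.

The four generation-2 branches carry the lobar labels (RUL, RLL, LUL, LLL,
assigned by laterality and superior–inferior position); each lobe's
designated measured path is its child-0 generation-3 branch.

Intensities are CT-like in HU-analog units (lumen −1000, wall 0,
parenchyma −850), UTE-like and T2w-like in arbitrary units; the T2w wall
mean is the subject's ground-truth inflammation signal `wall_t2_signal`
(default 60 Au).  Rendering is analytic and anti-aliased: material
intensities blend linearly over one voxel across each surface, a
partial-volume model without which interpolated isocontours acquire
lattice-orientation-dependent offsets (up to ~0.4 voxel) that masquerade as
ellipticity on oblique cross-sections.

Parenchyma carries a smooth random texture (a sum of 32 random 3D cosines,
wavelengths 4–12 mm, shared across a subject's modalities and evaluated
analytically so it warps exactly with the scene).  This emulates vascular
texture and is a well-posedness requirement, not decoration: a featureless
tube constrains only the displacement component normal to its wall (the
aperture problem), so without texture no registration could recover the
axial component of the deformation.

The inter-modality deformation is a low-frequency sinusoidal displacement
field (default amplitude 3 mm, period 40 mm, phases drawn from the seed);
the amplitude is validated against the strict fold-free bound
A·2π/P < 1.  The CT-like and T2w-like volumes sample the scene at the
pre-image of each fixed-grid point under the warp (computed by fixed-point
iteration on the analytic field to 10⁻⁴ mm), so the stored field on the
fixed grid is exactly what registration should recover.  Noise is additive
Gaussian on the CT-like volume and Rician on the MR-like volumes; a single
`noise_sigma` dial (default 6 Au on T2w, i.e. wall SNR ≈ 10) scales all
three with fixed ratios.  Mucus plugging fills the proximal third of a
named lobe's designated branch with wall-level intensity behind a flat
plug face, which disconnects the distal lumen — the algorithmically
detectable surrogate for the study's visual exclusion criterion.

Everything stochastic descends from the single integer seed; two calls with
equal specs are bit-identical.

## Normalization

T2w volumes are normalized with f(x) = (x − μₓ)/σₓ + 3σₓ, where μₓ and σₓ
are the mean and population SD over *all* voxels of the original volume,
background included (the literal whole-image reading).  The output
therefore has SD exactly 1 and mean 3σₓ; constant volumes raise a
degenerate-input error rather than dividing by zero.  The +3σₓ offset makes
the normalized wall signal depend on the original global SD; the formula is
implemented exactly as printed and the scale question is left to the
statistics, which are invariant to monotone per-cohort rescaling.
Normalization runs on the native T2w volume before registration (the
transform is affine in intensity, so the order does not affect the result,
but this matches the stated processing order).

## Registration

The moving volume (CT-like or normalized T2w-like) is histogram-matched to
the UTE-like reference — legitimate because UTE contrast is monotonically
CT-like, which is exactly why UTE is the common frame — and aligned with
multiresolution diffeomorphic demons: 3 levels with an anti-aliased
(smooth-then-shrink) pyramid, iterations (60, 40, 25) coarse-to-fine,
displacement-field smoothing 1.2 mm (diffusion regularization).  The field
is fold-free by construction and verified via the Jacobian determinant.

An earlier variant ran demons directly on compressed edge-magnitude maps;
it plateaued at ~2.3 voxels endpoint error on the 3 mm warp because the
compressed maps give weak, plateaued forces.  The histogram-matching route
reaches a mean endpoint error of ~0.8 voxel over the airway in about 10 s
at 96³.

The contract that similarity never decreases across levels is enforced
explicitly: after every level a contrast- and polarity-invariant
edge-overlap score (the magnitude-weighted mean squared cosine between the
two gradient-vector fields within the dilated high-gradient mask) is
evaluated at full resolution and the best field so far is kept.  The same
score backs `check_alignment`, the automated QC that replaces the study's
visual misalignment call (default flag threshold 0.5; a well-aligned
phantom scores ≥ 0.95, a 10 mm misalignment ~0.3).

For cohort throughput the pipeline default uses lighter iterations
(30, 20, 10); the residual ~1–2 voxel error there is absorbed by the
wall-mask margin at the biomarker stage (below).

## Airway tree

Lumen segmentation is thresholded region growing (CT-like < −500
HU-analog) from a tracheal seed with *face* (6-) connectivity: full
26-connectivity can jump a wall thinner than the voxel diagonal
(√3·0.625 = 1.08 mm), which the deformation's shear produces, and leaks
into the parenchymal air on every deformed subject.  Segmentation runs on
the crisp native CT and the mask is carried into the UTE frame through the
recovered field (nearest-neighbor), because interpolation plus noise on the
warped CT can punch sub-voxel holes in thin walls.

The mask is skeletonized (medial-axis thinning), the skeleton voxel graph
reduced to a BFS spanning tree, terminal twigs shorter than 3 mm pruned
iteratively, and the root placed at the remaining endpoint nearest the
tracheal seed.  Maximal non-branching paths become branches with
Gaussian-smoothed coordinates; tangents come from centered finite
differences.  Generations count bifurcations from the trachea (0); a node
with a single child continues its parent's generation, so labeling is
idempotent.  On clean phantoms the centerline is accurate to ~0.2 mm and
the topology is exact (1, 2, 4, 8 branches per generation).

Path selection maps each lobe's reference point (phantom ground truth, or
user-supplied for real data) to the nearest generation-3 branch within a
4 mm gate.  A selected path is dropped with an exclusion record when the
mean CT intensity over its proximal third exceeds −300 HU-analog (mucus
plug surrogate); a lobe whose branch is missing from the tree is probed at
its reference point — soft-tissue intensity or an air pocket disconnected
from the seeded lumen also means plugging, anything else raises a selection
error naming the missing lobes.

Cross-sections are resampled perpendicular to the local tangent by
trilinear interpolation at half the voxel size, with deterministic in-plane
axes; out-of-volume samples are NaN-padded and flagged.  Measurement sites
sit at 1/3 and 2/3 of the branch arc length (midpoint when one site is
requested); branches shorter than two lumen diameters are rejected.

## Wall quantification

On each section, the lumen region is flood-filled from the section center
below the lumen/wall midpoint intensity and its centroid taken.  The
scale-normalized LoG (σ²·∇²G) is computed at scales {0.3, 0.5, 0.8} mm, and
along each of 64 radial rays the wall is the innermost strong negative
extremum (≥ 30% of the section's peak response) bracketed by zero
crossings.  The crossings are found with hysteresis — the walk from the
extremum continues until the profile rises convincingly positive (10% of
the peak), skipping weak noise blips inside the wall band — and
interpolated to sub-sample precision.  Pairs wider than 3 mm (the widest
plausible wall at these generations) are rejected so the walk cannot land
on a neighbouring branch.  Failed rays are filled by periodic interpolation
from their neighbours; a section fails (recorded, not fatal) when more than
25% of rays fail.

Two numerical corrections matter at these radii:

- a first-order curvature correction, since the LoG zero-crossing of a
  circular edge of radius R sits outward of the true edge by ≈ σ²/(2R);
- scale selection by cross-scale consensus (keep the scale whose LA/WA are
  nearest the cross-scale median) rather than by maximal response: the
  response-maximizing rule prefers scales too coarse to resolve the wall
  and biases WA by ~+7% on the reference annulus, while the consensus rule
  keeps errors within ~2% on clean and SNR-10 sections.

Boundary polygons give LA (inner area, shoelace formula) and WA (outer
minus inner); WA% = 100·WA/(WA+LA).  Wall masks are rasterized as
2.5 mm-thick slabs around each section with a 0.25 mm inward margin on both
boundaries (partial-volume guard), lumen voxels excluded; each (path, site)
gets its own label.  The biomarker is the mean normalized T2w intensity
over each mask, aggregated site → path → patient with unweighted means.
WA% aggregates over the same sites.  On noise-free phantoms the patient
value matches the analytically normalized ground-truth wall signal to
within ~0.3% of the wall–parenchyma contrast.

## Cohort generator and statistics

Synthetic cohorts draw each severity group from a multivariate Gaussian
whose marginals reproduce the study's printed group summaries (biomarker
74 ± 12 vs 49 ± 14 Au; PFT, FeNO and eosinophil distributions from the
cohort table, the latter two log-normal with geometric means/SDs).
Correlations with the biomarker use a single-factor model — each covariate
loads on the biomarker's latent factor with its target correlation — which
guarantees a positive semi-definite joint correlation matrix and exact
target marginals by construction; defaults follow the severe-group
correlation column (e.g. −0.53 with FEV₁ %pred, +0.52 with log
eosinophils).  Exacerbation counts are Poisson with log-rate linear in the
biomarker (slope ln 1.11 per Au; intercept set so the group medians are
~2 vs 0), and the frequent-exacerbator flag is count ≥ 2.

The statistics layer implements the study's battery:

- Shapiro–Wilk gating at α = 0.05 with natural-log transforms and
  geometric summaries on back-transform;
- two-sided Student's (pooled-variance) t-tests, also from summary
  statistics; Fisher's exact test when any expected cell is < 5, else
  chi-square;
- ROC with AUC as the normalized Mann–Whitney statistic (ties ½), DeLong
  variance for the AUC interval, the Youden operating point with ties
  broken toward the lowest cutoff (favoring sensitivity), and exact
  Clopper–Pearson intervals for sensitivity/specificity (closed forms at
  the boundaries);
- forward/backward stepwise logistic regression (p-enter 0.05, p-remove
  0.10, Wald criteria; separation flagged and reported via an L2-penalized
  fallback);
- Pearson correlations on gated values;
- ICC(A,1) — two-way, absolute agreement, single measure — from the ANOVA
  mean squares with McGraw–Wong F-based intervals, labeled with the
  printed agreement bands (≥ 0.95 "almost perfect", etc.), cross-checked
  against pingouin in the tests;
- Bland–Altman mean difference with t-based CI and 1.96·SD limits of
  agreement;
- quartile grouping by inclusive linear interpolation (boundary values to
  the lower group) with one-way ANOVA and Tukey HSD.

No multiple-testing correction is applied, matching the analysis it
mirrors.  One calibration note: forward selection over four independent
noise candidates at p-enter 0.05 leaves the model empty with probability
0.95⁴ ≈ 0.815 — the type-I control test asserts that binomial expectation,
since backward elimination cannot evict a variable that entered below the
stricter threshold.

## Pipeline

`run_subject` executes phantom → normalize → register → segment → measure →
biomarker in that order, isolating per-path failures as exclusion records
and writing a manifest (per-stage status, array checksums, seed, config
hash).  A lobe whose generation-3 path the skeleton cannot resolve (under
unlucky deformation draws a compressed sibling twig can fall below the
prune length and merge two generations; roughly one lobe in a hundred) is
excluded and the subject continues on the remaining paths — the automated
analogue of the study's per-bronchus exclusions; the subject fails only if
no lobe resolves.  `run_cohort` generates the cohort table, renders one phantom per
row with the subject's true biomarker as the wall signal, processes
subjects in a seed-shuffled order (the randomized, blinded measurement
protocol), adds a second reading with ±0.8 mm site jitter from the same
registered volumes to emulate reader variability for the reproducibility
analyses, and runs the statistics on the measured table.  In `table-only`
mode the statistics run directly on the generated table.  A TOML file
drives a full run; the `bronchowall` CLI exposes `phantom`, `cohort`,
`measure`, `stats` and `run-all`.

Under a fixed seed the whole phantom+table path is bit-reproducible
(single-threaded demons included), verified by comparing manifests of
repeated runs.

## What the phantom does and does not show

Passing tests demonstrate that every algorithmic stage meets its contract
on geometry and signal structure it was designed for: tubes with annular
walls, monotone inter-modality contrast, smooth invertible deformations,
Rician/Gaussian noise, vascular-like texture.  Real airways taper, branch
asymmetrically, neighbor vessels of wall-like intensity, and carry motion
and reconstruction artifacts none of which the phantom emulates; absolute
accuracies reported here are therefore upper bounds on real-data
performance, and the lobe labels that the phantom provides as ground truth
must come from a human or an atlas on real CT.

## Problem sizes

Default experiments use 96³ volumes at 0.625 mm, 15 + 15 subjects per
cohort (the study's arm sizes), n = 10000 per group for generator
round-trip checks, 2000 replicates for type-I calibration, and 100 random
instances for the AUC-oracle equivalence; the scaled-down end-to-end run in
the acceptance script uses 8 + 8 subjects.
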