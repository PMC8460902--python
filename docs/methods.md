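# Methods

## The problem

In adolescent idiopathic scoliosis (AIS), a mild curve at first
examination (Cobb angle 10–25°, Risser sign 0–2, age 10–18) either
stabilizes or progresses during the growth spurt. The study design this
package implements asks whether biomechanical quantities obtained from a
musculoskeletal simulation of relaxed upright stance — intervertebral
lateral shear and trunk-muscle activation asymmetry — improve the binary
prediction of progression over anthropometric and geometrical descriptors
alone. Because no subject-level data are public, the pipeline runs on a
synthetic cohort generator calibrated to the published group statistics;
everything downstream (descriptors, simulation, classification) operates
on the generated subjects exactly as it would on real ones.

Outcome labels follow the clinical follow-up rule: *stable* = Risser > 2
with a Cobb increase below 10°, *progressive* = Risser 0–2 with an
increase above 10°; any other combination is indeterminate and excluded.

## Cohort generator

### Margins

Each of the 23 predictors has a per-group marginal distribution calibrated
to the published mean (SD) or counts:

* Bounded continuous quantities (age on [10, 18], Cobb on [10, 25], TK,
  SS, PI, axial rotation, F_lat ≥ 0, activity ratios on [−1, 1]) are
  truncated normals whose *underlying* parameters are solved numerically
  so that the truncated distribution reproduces the target mean exactly
  and the target SD as closely as the family allows. On [10, 25] a
  truncated normal cannot exceed SD ≈ 4.33 (the uniform limit), so the
  stable-group Cobb SD calibrates to ≈ 4.2 rather than the printed 6.1;
  the mean is exact. This is a structural limit of any unimodal truncated
  family on that interval, not a solver artifact.
* Integer scores (Risser on {0, 1, 2}, number of curves on {1, 2, 3}) use
  discrete distributions solved from the first two moments — this matches
  the printed mean and SD exactly, which rounding a truncated normal does
  not.
* Sex is Bernoulli from the group counts; Lenke type is categorical from
  the per-type counts.

### Dependence

The anthropometric and geometrical margins are coupled by a Gaussian
copula. The only non-zero default rank correlation is age ↔ Risser = 0.6
(skeletal maturity tracks age); the matrix is user-overridable and checked
for positive semi-definiteness. Correlations induced on the integer
margins are attenuated by discretization (measured ≈ 0.51 for a 0.6
target), which is inherent to coupling a latent Gaussian to a 3-point
score.

### Biomechanical block: the redundancy mechanism

The eleven biomechanical predictors are generated, by default, as
group-independent linear functions of the Cobb angle and age plus noise:

    value = clip(α + b·cobb + c·age + σ·ε, lo, hi)

* `b` is set from the published Cobb correlation of each feature (0.63,
  0.29, 0.67 for F_lat at the upper end, apex, lower end; the smaller
  printed values for the activity ratios).
* `α` and `c` are solved by Monte-Carlo moment matching (200,000 draws per
  group) so that the per-group means of the *clipped* value reproduce the
  published group statistics exactly.
* `σ` is group-independent, chosen from the residual variance left after
  the cobb/age terms (capped so that clipping at a hard bound stays rare).
* `ε` is half a subject-level common factor, half feature-specific: all
  eleven features come from one simulation of one reconstructed geometry
  scaled by one predicted body mass, so simulation error is shared across
  features. The equal split keeps every marginal standard normal.

Rationale: the coefficients carry no group information, so the
biomechanical block adds no label information beyond what curve severity
and body size (age) already provide — the redundancy structure that the
study design's central negative finding implies. The alternative
`biomech_coupling="margins"` samples the biomechanical block directly from
the group-conditional margins through the copula; that reproduces the
printed SDs as well, but makes the block independently informative, which
contradicts the design's premise. Under the redundant mechanism the group
means are exact and the SDs are best-effort (exact group SDs are
unattainable with group-independent coefficients — e.g. the printed F_lat
upper-end SDs, 41.2 vs 21.4 N, differ by a factor two).

### Geometry mode

`sample_spine_geometry` realizes per-subject targets (TK, LL, SS, PI,
Cobb, apex, axial rotation, curve count) as smooth per-vertebra
orientation chains: the sagittal channel interpolates the control
vertebrae that define TK and LL; the coronal channel places half-cosine
lobes whose end-vertebra tilts are ±Cobb/2 with the tilt zero crossing at
the apex; the axial channel is a bump peaking at the apex. Descriptors
recomputed from the realized chain reproduce the targets within 1° (the
round-trip contract, tested). At most two curves are realized — a
three-curve spine is rare in the calibration (≤ 7.5%) and not reliably
packable into 17 levels at the chosen spans — so the detected curve count
in geometry mode is 1 or 2. Follow-up duration is sampled per group as
N(27, 13) / N(25, 12) months truncated at 6. True stature and mass are
generated from a linear age/sex model with residual SDs of 4.3 cm and
3.9 kg, matching the reported accuracy of radiographic height/weight
predictors, so that refitting those predictors on a generated cohort
recovers a comparable goodness of fit.

### Sign conventions

Global frame: X anterior, Y subject-left, Z cranial. Coronal tilt positive
tips the vertebral top to the subject's right; sagittal tilt positive is a
*posterior* inclination, so a normal alignment runs from an anteriorly
tilted T1 to a posteriorly tilted thoracolumbar junction. With these
conventions TK = sag(T12) − sag(T1), LL = SS + sag(L1), both positive in
normal alignment, and the realized postures are statically plausible
(gravity demands extension over most of the chain).

## Geometrical descriptors

Curve detection splits the stacked frontal-plane chain into contiguous
same-sign runs of lateral deviation (2 mm dead band); within each run,
extended by one transition vertebra at each boundary (adjacent curves may
share it), the end vertebrae are the most-tilted vertebrae in either
direction — equivalent to maximizing the pairwise tilt difference, the
classical Cobb convention — and the apex is the vertebra farthest from the
end-to-end chord. Runs below the 10° Cobb threshold, or with apex
deviation under 2 mm, are transition zones. The torsion index of a curve
is the mean of the two magnitudes of summed intervertebral axial rotations
(lower end → apex, apex → upper end). The Lenke type is a deterministic
approximation from apex locations and curve count (thoracic apex T2–T11;
thoracolumbar/lumbar T12–L4): single thoracic → 1, double thoracic → 2,
thoracic main with lumbar minor → 3, triple with thoracic main → 4, single
thoracolumbar/lumbar → 5, lumbar dominant → 6. Side-bending films and
sagittal modifiers of the full clinical scheme are not available from a
single standing acquisition and are ignored.

## Musculoskeletal model

The spine is a chain of rigid segments T1–L5 on a sacrum fixed to the
ground. Segment heights (~22–33 mm cranio-caudally) scale with stature;
per-level lumped masses follow a cumulative supported-mass fraction,
linear from 0.14 at T1 (head and neck included) to 0.57 at L5; segment
centres of mass sit 50 mm anterior of the vertebral centres (trunk-slice
centroids, chest and abdominal mass included). The raised arms contribute
two loads of 5% body weight at T1. Intervertebral joints are ideal
spherical joints with zero passive moment (neutral upright posture).

Muscle fascicles are straight lines with maximum force PCSA × 90 N/cm²
and PCSA scaled linearly with age (factor 0.75 at 8 y to 1.35 at 18 y):

* **ES** (erector spinae): one fascicle per side per level, sacrum →
  vertebra, posterior offset 40 mm, lateral offset 35 mm lumbar / 25 mm
  thoracic, 1.0 cm².
* **MF** (multifidus): two-level spans, posterior 30 mm, medial-to-lateral
  slant (15 → 30 mm), 0.8 cm², including lumbosacral fascicles anchoring
  L4/L5 to the sacrum.
* **RT** (rotator analogue): the mirror-slant of MF (30 → 15 mm), so both
  signs of axial torque are available on each side.
* **AB** (anterior flexors: psoas / abdominal wall / ribcage load path):
  two-level spans 40 mm anterior of the vertebral bodies with alternating
  oblique slants, 2.5 cm².

Only ES and MF enter the activity-ratio predictors; RT and AB exist
because moment equilibrium is otherwise structurally infeasible: with
posterior extensors alone, the extension demand must be monotone down the
nested crossing-sets, while real sagittal profiles produce flexion demands
in the lordotic segments and axial torque demands wherever vertebrae are
rotated. With this architecture every cohort geometry tested (hundreds of
sampled subjects) is solvable.

Recruitment minimises Σ activationᵖ (p = 3, configurable) plus a tiny
quadratic ridge (10⁻⁶) subject to the three moment-equilibrium equations
of each joint and activations in [0, 1]. The ridge makes the optimum
unique — the cubic criterion alone is flat at zero activation, leaving
barely recruited fascicles with arbitrary left/right splits. Feasibility
is established by bounded least squares (BVLS); an irreducible residual
above 10⁻⁵ of the load scale raises an infeasibility error naming the
joint. The optimum is then refined by SLSQP from the feasible point;
accepted solutions have moment residuals below 10⁻⁶ of the load scale
(typically 10⁻¹⁰). Joint reactions follow by force balance of everything
cranial to each joint, muscle pulls included, and are expressed in the
local frame of the caudal vertebra; F_lat is the absolute lateral
component. Activity sums per group/side/level add the activations of
fascicles whose span crosses the vertebral mid-plane; the normalized ratio
(convex − concave)/(convex + concave) maps double-zero (below 10⁻⁸ total)
to 0.

## Classification harness

Predictors are used unstandardized; sex and Lenke type are dummy-coded
against the first level present in the data (levels absent from the data
contribute no columns). The six classifiers and their fixed
hyperparameters:

| code | classifier | tuned choice |
|------|------------|--------------|
| SVM | support vector machine | linear kernel, box constraint 10 |
| PDA | penalized linear discriminant | shrinkage γ = 0.6 toward the *diagonal* of the pooled covariance |
| BAY | kernel naive Bayes | pooled-spread Silverman bandwidths per class size |
| DET | decision tree | at most 4 splits (5 leaves) |
| KNN | k-nearest neighbours | k = 7, Euclidean |
| ENS | bagged trees | 30 estimators |

Two implementation notes, both consequences of unstandardized mixed-scale
predictors: PDA shrinks toward the covariance diagonal rather than a
scaled identity (which is not scale-equivariant and collapses here), and
BAY derives kernel bandwidths from the pooled feature spread scaled by the
class sample size — per-class bandwidths produce degenerate density
spikes on dummy levels absent from one class.

Pre-selection runs 10 repetitions of stratified 4-fold cross-validation
(folds of 15 stable / 10 progressive at n = 100), identical folds for
every classifier: 40 accuracies each. Comparison runs 100 stratified 80/20
holdout splits (test sets of 12 stable / 8 progressive), identical splits
for every classifier and both predictor sets, recording sensitivity
(correct progressive rate) and specificity (correct stable rate).
Decision-tree predictor importance sums the mean-squared-error decrease of
every split per predictor and divides by the number of branch nodes (for
a binary outcome, node MSE is p(1−p)).

Statistics: Shapiro–Wilk (α = 0.05) gates t-test vs Wilcoxon rank-sum for
group contrasts and Pearson vs Spearman for correlations (Spearman
significance uses the analytic two-sided p rather than a permutation
distribution); chi-squared vs Fisher's exact (expected count < 5, 2×2) for
proportions; Kruskal–Wallis across classifiers with Tukey–Kramer
post-hocs on mean ranks via the studentized-range distribution.

## What the synthetic cohort does and does not show

The generator reproduces the published per-group means (exactly, by
construction) and proportions, the strong published correlations, the
inclusion rules, and — through the redundancy mechanism — the qualitative
finding that adding simulated biomechanical predictors leaves the
classification medians unchanged. It does not reproduce: the full
dependence structure of real radiographic cohorts (only the printed
correlations are targeted), the printed group SDs where those are
structurally unattainable (Cobb under truncation; F_lat under
group-independent coefficients), within-curve level-to-level coupling of
the biomechanical features beyond a single common factor, or measurement
error of manual Cobb/Risser reading. Passing the harness tests on this
cohort therefore validates the *pipeline* — calibration, simulation
mechanics, split bookkeeping, test selection — not clinical
generalization. One finite-sample effect is worth noting: even though the
biomechanical block carries no extra label information, appending eleven
noisy columns measurably perturbs individual classifiers on some cohorts,
so paired rank-sum tests on 100 holdout iterations can flag small
reduced-vs-full differences (in either direction) that the coarse medians
do not show.

## Problem sizes

Defaults mirror the study: 100 subjects (60/40), 10×4-fold pre-selection,
100 comparison iterations. Calibration-recovery checks use 10,000 draws
per group; the coupling coefficients are solved on 200,000 draws. The test
suite runs the geometry-and-statics chain on cohorts of 10–120 subjects
(≈ 0.2 s per subject on one core) and the full harness on five replicate
cohorts.
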