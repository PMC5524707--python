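# Methods

This note documents the models, conventions and design choices behind
`cardiomorph`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Shape-space conventions

Configurations are k×m landmark matrices (m = 3 for heart data; the
core routines also accept m = 2). Shape space removes translation,
rotation and scale; size-and-shape space keeps scale. Rotations are
restricted to SO(m) everywhere: anatomical landmark sets have a fixed
chirality, so reflections are never admitted. Note that a *planar*
configuration embedded in 3-D can still be mirrored by a 3-D rotation;
the pi/2-maximal-distance property of a triangle versus its mirror
image therefore holds only for 2-D configurations under SO(2), which is
how the distance routine treats k×2 input.

GPA iterates optimal rotations against the evolving consensus until the
consensus root-mean-square displacement falls below 1e-8 (at most 200
iterations; non-convergence raises with the shift trace). In shape
space every configuration is pre-scaled to unit centroid size and the
consensus is re-normalized each iteration. Because GPA only fixes
orientation up to a global rotation, the converged consensus is rotated
into its principal-axis frame with a deterministic sign convention, so
results do not depend on input ordering. Configurations with centroid
size below 1e-12 of their coordinate scale are rejected as degenerate.

Tangent-space maps use the orthogonal projection at the pole,
`v = x − ⟨x, p⟩p`, not the stereographic one: the linear-shift transport
does plain subtraction/addition in the tangent plane, and the
orthogonal projection is the linear map consistent with that
arithmetic. The inverse map reconstructs `x = sqrt(1 − |v|²)p + v`,
exact for unit-size shapes within pi/2 of the pole.

## Homologous times and resampling

Four annotated events (R peak, LV end-systole, mitral-valve opening,
P peak) subdivide the cycle; three equally spaced times inside each
cyclic gap give 16 homologous times, with the R peak as time 0
(end-diastole). The subject's frames are first aligned by GPA in
size-and-shape space — size is still meaningful at this stage — and
each of the 3k coordinates is then interpolated by a cubic spline with
periodic boundary conditions over one cycle (a heartbeat is cyclic; the
first frame is reused as the closing knot one period later).
Interpolation therefore acts on aligned coordinates, not raw device
coordinates.

## Linear-shift transport

Per subject, the local template (LT) is the shape-space GPA consensus
of its 16 shapes; the common template (CT) is the consensus of all
16·n shapes pooled. Rotation management is deliberately rigid: one
rotation per subject — the OPA rotation of its LT onto the CT — is
applied to all 16 of its aligned shapes, keeping the within-cycle
deformation coherent; no per-frame re-rotation is done. All transport
arithmetic happens in the tangent plane at the CT on unit-size shapes
(size re-enters the analysis only through trajectory centroid size).

Residuals are defined as each projected shape minus the per-subject
*mean of the projected shapes*. Subtracting the projection of the
renormalized LT instead would differ only at second order in the
deformation magnitude but would leave a per-subject mean residual of
that same order; the mean-of-projections form makes "the local mean
maps to zero" exact to machine precision, which downstream PCA and PLS
assume.

## Trajectories

The motion trajectory is the 16×3 configuration of the first three PC
scores of the transported deformations (three components keep the
trajectory representable; they carry the large majority of variance on
both synthetic and clinical-scale data). End-diastole is the R-peak
slot (index 0) and end-systole the LV-end-systole slot (index 4); the
chord between them gives the PC1/PC2 and PC1/PC3 orientation angles via
the two-argument arctangent, in degrees in (−180, 180]. PC signs are
fixed by making each loading vector's largest-magnitude entry positive,
so angles are reproducible run to run. Angles are treated as linear
quantities in the ANOVA (consistent with how such angles are usually
reported); a circular-statistics treatment was deliberately not
substituted.

Group tests are permutational: R² = between-group SS over total SS
(Euclidean, summed over columns in the multivariate case), p from label
permutations with the observed statistic counted in the null set
(defaults 9999 permutations, seeded). At p ≫ n a classical parametric
MANOVA is not applicable; the permutation form is exact for
exchangeable nulls and reduces to the squared point-biserial
correlation in the scalar case.

## Covariation

Two-block PLS is the SVD of the cross-covariance (divisor n−1) of the
column-centered blocks, computed in the observation space so that
3891-column shape blocks with n = 16 rows never materialize a p×q
matrix. Within each singular pair, the block-A vector's
largest-magnitude loading is made positive and the block-B vector flips
with it (singular values stay non-negative): MA slopes are
sign-sensitive and need a fixed orientation. The integration z-score
standardizes the observed first-pair score correlation against its
row-permutation distribution (999 permutations at the individual level,
where n is fixed at 16 for every subject, so cross-subject
comparability is not a concern; no Fisher transform is applied).
Blocks are centered but not column-standardized: shape coordinates
share units.

The major-axis slope is the first-eigenvector slope of the 2×2
covariance of the paired SW1 scores — symmetric regression, orthogonal
residuals, `slope(x,y)·slope(y,x) = 1`. LA scores go on the vertical
axis, so slope > 1 means the LA changes faster per unit LV shape
change. Isotropic score clouds raise an indeterminate-slope error.

At the trajectory level, per-chamber pipelines (transport + PCA run on
LV-only and LA-only data) produce one trajectory shape per subject per
chamber; within each group a PLS links the GPA-aligned trajectory
coordinates. Group differences in z and in the MA slope are tested by
permuting group labels, with z re-estimated inside each label
permutation from a smaller inner permutation count (defaults 199/99;
the nested design is the cost of keeping the test fully
permutational).

## Disintegration

The bending-energy matrix is the upper k×k block of the inverse TPS
system matrix built from the 3-D biharmonic kernel U(r) = −r (stated
explicitly because the 2-D kernel r² log r differs); its k−4 positive
eigenvalues and eigenvectors are the partial warps. One basis, built on
the common template, is shared by all subjects for cross-subject
comparability. Per warp, the score variance across the 16 shapes
(summed over the three coordinates) is regressed log-log on the
eigenvalue; warps with variance below 1e-15 of the largest are excluded
(log-of-zero guard). Slope −1 is self-similarity; the slope is
invariant to global rescaling of the series.

## Classification

Per repetition, fixed per-class training counts are drawn without
replacement (defaults 35 Controls / 17 HCM of a 46/20 cohort, 1000
repetitions), features are standardized with training-split statistics
only, and an RBF SVM with C = 1 and the 1/(d·variance) bandwidth
convention is fitted; AUC comes from the decision scores with HCM as
the positive class, specificity is Control accuracy, sensitivity HCM
accuracy. Constant feature columns are dropped with a log notice.
Reproducibility helpers: percent coefficient of variation of absolute
replica differences (identical replicas are reported as 0 with a
degenerate flag), and the Procrustes distance between two replicas'
trajectory shapes normalized by pi/2.

## Synthetic cohorts

The generator emulates a 3DSTE left-heart acquisition, not myocardial
biophysics. Geometry: LV as a prolate half-ellipsoid (semiaxes
21/21/45 mm), LA as an oblate dome (21/21/18 mm), stacked base-to-base
on a shared annulus plane; 36 circles × 36 landmarks + apex per chamber
(1297; 2594 per left heart). The LA annulus ring is rotated by half a
landmark spacing so the two rings interleave on the shared plane —
a connected cloud without coincident landmarks (coincident points would
make the TPS kernel singular).

Deformation: two unit-norm displacement-field pairs driven by smooth
periodic von-Mises-shaped activations (kappa = 8) — LV contraction with
LA reservoir expansion peaking at end-systole, and LV twist with the LA
booster-pump contraction peaking at the P wave (the secondary mode at
0.35× the primary amplitude makes trajectories elliptical rather than
degenerate). Chamber fields are orthogonal to their own chamber's
translations and rotations; per-chamber volumetric (scaling) components
are retained — they are genuine shape changes of the whole left heart,
and give the LV its systolic volume minimum — but are balanced across
the chambers of each mode so the combined field carries no global-scale
component and passes through Procrustes alignment untouched. Mode 2 is
orthogonalized against mode 1 within each chamber; without matched
orthonormal block bases the first singular pair would mix the modes
asymmetrically and the planted LA:LV rate would not be recoverable.
Activations are centered over the 16 homologous phases so a cycle's
time-average sits at the base geometry; otherwise the common template
is displaced along the planted fields and the tangent projection leaks
a template-direction component into the measured blocks, biasing the
recovered slope.

Defaults are the study conditions: cohort sizes 46 Control / 20 HCM;
beat rate 77 ± 13.16 bpm; frame interval 41.6 ms with 2 ms timing
jitter; event phases 0 / 0.30 / 0.45 / 0.85 of the cycle (R peak,
end-systole, mitral-valve opening, P peak — systole about a third of
the cycle at rest, the P wave late in diastole); Control LV amplitude
0.12 of base centroid size vs 0.08 for HCM; planted covariation slopes
1.25 vs 0.89; subject shape variation 5% (semiaxis jitter plus
low-order harmonic surface modulation); landmark noise 0.5 mm
(sub-millimeter device jitter); a random rigid device pose per subject.

What the generator does *not* model: myocardial wall mechanics and
regional strain heterogeneity, valve-plane motion, ECG waveform shape,
septal hypertrophy as a baseline shape contrast, pathology-severity
variance, or per-subject variation of the covariation slope itself
(within a group all subjects share the planted rate; slope spread comes
from noise alone). Passing tests therefore demonstrate that the
*pipeline* recovers planted effects of realistic magnitude under
realistic sampling — not that real HCM hearts behave like the
generator.

## Numerical choices and problem sizes

- GPA tolerance 1e-8 RMS, max 200 iterations; degenerate threshold
  1e-12; tangent round trips are exact to ~1e-8, limited by arccos
  resolution near zero distance.
- PLS reduced-rank cutoff: singular values below 1e-12 of the leading
  one are treated as null space.
- All stochastic stages draw from `numpy.random.default_rng` seeded
  from one master seed; repeated runs are checksum-identical.
- The packaged checks run the full-resolution (1297 landmarks/chamber)
  pipeline for the 30-subject isometry recovery, and a reduced 12×12
  layout with 12+12 subjects for the 20-run group-contrast recovery —
  the contrast recovery is resolution-independent well above ~100
  landmarks per chamber, and the reduced size keeps the default test
  run short. The 100-landmark reference for the self-similarity check
  (9 circles × 11 points + apex) matches the basis-size regime where
  dense eigendecomposition is exact and fast.

## Known limitations

- The linear shift is a small-deformation approximation of parallel
  transport; for cardiac-scale deformations (Procrustes magnitudes
  ~0.1–0.2) its agreement with exact Riemannian transport is good but
  not exact, and no geodesic machinery is provided.
- One OPA rotation per subject is an explicit choice; per-frame
  re-rotation would change residuals at second order.
- The trajectory-level covariation test is doubly permutational and
  therefore noisy at small group sizes; its inner/outer permutation
  counts trade accuracy for runtime.
- The bending-energy basis costs a dense (k+4)² inverse and
  eigendecomposition — fine at k = 2594, prohibitive far beyond.
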