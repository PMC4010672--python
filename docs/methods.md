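# Methods

This note documents the models, the estimation choices, and what the
synthetic experiments do and do not demonstrate.

## Signal model and the contamination problem

A voxel's diffusion-weighted signal is modelled as two non-exchanging
compartments: an anisotropic tissue tensor `D_t` and isotropic free water
with fixed diffusivity `d_w`:

    S(g, b) = S0 · [ f · exp(−b gᵀ D_t g) + (1 − f) · exp(−b d_w) ]

`f ∈ [0, 1]` is the tissue volume fraction; `d_w` defaults to
3.0×10⁻³ mm²/s (free water at body temperature) and is configuration, not a
hard-coded constant. Because signals — not diffusivities — mix, a
single-tensor fit of a contaminated voxel is *not* the volume-weighted mean
of the compartments: MD/AD/RD are inflated and FA depressed, more strongly
for diffusivities than for FA in relative terms (asserted per voxel in the
test suite across `f ∈ (0, 1)`).

Noise is Rician: the magnitude of a complex Gaussian perturbation of the
noise-free signal. The default SNR is `s0/σ = 25` at b=0, which puts the
diffusion-weighted tissue signal at SNR ≈ 2–10 — the regime where magnitude
bias and log-transform noise genuinely matter.

## The phantom and cohorts

The default head is a 16×14×8 grid of 2.4 mm voxels: a ventricle-like CSF
slab; a three-voxel-wide bundle directly against it (fornix analogue,
eigenvalues (1.7, 0.3, 0.3)×10⁻³ mm²/s); a deep bundle more than four
voxels from CSF (parahippocampal-cingulum analogue); and isotropic
background tissue (0.7×10⁻³ mm²/s). The tissue fraction declines
logistically from 1 to 0 over two voxels of distance to CSF, so the
bundle's border column sits at `f ≈ 0.5` and the interior at `f = 1`.
Geometry primitives (boxes, cylinders, arcs) cover straight and curved
bundles; the phantom deliberately omits crossing fibres, real anatomy and
susceptibility artefacts, so passing tests demonstrate correct *mechanics*
of the estimators under the stated model, not robustness to everything a
scanner produces.

Two-group cohorts (default 25 "patients" vs 20 "controls") apply two kinds
of effect to patients: *intrinsic* change (fractional eigenvalue scaling)
and *atrophy* (the f profile pulled toward CSF; default 0.5 voxel for the
fornix analogue, which produces uncorrected tract effects of the magnitude
reported for the fornix in elderly case-control data, d ≈ 1–2.5).
Between-subject biological variability is a 12% multiplicative jitter drawn
independently for the axial and radial eigenvalues — matching the
coefficient of variation of tract-mean diffusivity in elderly cohorts, and
varying both MD and FA across subjects. The jitter table is shared between
groups (common random numbers): subject *i* of either group carries the
same draw, so an atrophy-only cohort has identical group tissue-tensor
samples *by construction* and any corrected-domain group difference is
estimator error, not sampling noise of the generator. Per-subject noise
realisations remain independent.

## Single-tensor fit

Weighted log-linear least squares of `log S` against the b-matrix with the
log-baseline as a seventh unknown; weights are the squared (clamped)
signals. Signals below `1e−6·S0` are clamped before the log and counted in
diagnostics. Metrics follow the standard closed forms; negative eigenvalues
are clipped to zero (flagged), and an all-zero tensor gets FA = 0 rather
than NaN. The fit is exact on noise-free data, which the suite checks to
1e−10.

## Free-water fit

Single-shell free-water elimination is ill-posed pointwise: with 30
directions at one b-value, noise opens a long, shallow valley in (f, D)
along which the fit is nearly flat, with two non-physical escape branches
(an inflated tensor absorbing the water, and a negative-definite
pseudo-tensor at the lower f bound). The implementation addresses this in
layers:

- **Per-voxel fit** (`fit_bitensor_voxel`, and the field fit at
  `lambda_reg=0`): golden-section search on the objective profiled over f
  — for each f the tissue attenuation `(A − (1−f)E_w)/f` is floored and
  the tensor solved log-linearly, eigenvalues projected into a plausible
  tissue range ([0.1, 2.5]×10⁻³ mm²/s) — followed by a closed-form f polish
  and explicit evaluation of both f bounds, every candidate accepted only
  where it lowers the objective. This is exact on noise-free data (the
  suite pins f=0.6 recovery to ±0.005 against an exhaustive grid-search
  oracle) but remains degenerate under noise, as expected.
- **Field fit** (`fit_bitensor_field`, default): adds the smoothness term
  `λ Σ_pairs ‖D_i − D_j‖²_F` over the 6-neighbourhood (λ default 10⁶ in
  mm²/s Frobenius units, calibrated by seeded parameter recovery). Each
  sweep solves the coupled tensor system exactly through a cached sparse
  factorisation, projects eigenvalues, and updates f by its closed form
  (solved unclipped, optionally spatially pooled, then clipped). The fit is
  *anchored*: it starts from the attenuation-based f prior (isotropic
  tissue MD 0.6×10⁻³ mm²/s) and runs a fixed, small number of sweeps
  (8). Early stopping is deliberate — descending the regularised objective
  to convergence measurably drifts along the degenerate valley (the
  objective's optimum has ≈ −7% MD bias), while the prior-anchored
  fixed-sweep alternation recovers f with mean absolute error ≈ 0.04 and
  corrected-MD bias ≈ −3% at SNR 25. This mirrors the fixed-iteration
  descent used by variational free-water methods; the Frobenius regulariser
  itself is a deliberate simplification of their manifold smoothing,
  validated by parameter recovery only.
- **Edge preservation**: neighbour coupling can be restricted to tissue
  classes (`smoothing_classes`, e.g. a segmentation), so thin anisotropic
  bundles are not blended into isotropic surroundings; and the tensor data
  term can be down-weighted by CSF proximity (`data_weights`; the cohort
  pipeline zeroes it within a 2-voxel rim), letting the smoothness term
  interpolate tensors where the post-subtraction tissue signal is
  noise-dominated while f stays locally estimated. Both structures are
  shared across subjects of a cohort, which keeps the factorisation cache
  effective.
- An optional two-pass Rician de-biasing (`rician_correction`) subtracts
  the model-predicted magnitude inflation (exact Rice mean via scaled
  Bessel functions, σ estimated from the b=0 repeats) and refits. It
  reduces f bias at very low f but slightly worsens mid/high-f recovery,
  so it is off by default.

Voxels whose fitted f sits within 0.01 of the lower bound (default bounds
(0.05, 1]) are flagged as effectively pure CSF; their corrected metrics are
missing and excluded from all downstream statistics rather than
zero-filled.

Known residual limitation: corrected MD carries an f-dependent bias
(≈ −6.5% at f=1 versus ≈ −1.4% at f=0.5 on constant-f phantoms at SNR 25),
traced to the interaction of log-domain noise and Rician bias in the tensor
solve; spatial pooling of f does not remove it. Group comparisons are
affected only to the extent that groups differ in f, which is why the
cohort pipeline interpolates rim tensors.

## Tractography

Deterministic streamline integration along the principal eigenvector of the
trilinearly interpolated tensor (interpolate-then-decompose), bidirectional
from every seed-voxel centre, midpoint (RK2) steps of 0.5 mm. Termination:
interpolated FA below 0.1, turning angle above 60° per step, or leaving the
mask. Streamlines shorter than 4 steps are discarded as seed stubs. RK2
matters: chord stepping makes curved paths spiral outward, while the
midpoint rule reconstructs a 20 mm-radius arc's length to well under 1%.
Waypoint plans keep streamlines that touch every AND mask and no NOT mask
(nearest-voxel membership). Tract means weight every 0.5 mm sample equally
(step-weighted, not streamline-weighted; recorded in bundle metadata), and
samples whose trilinear support touches a missing voxel are excluded.

## Skeleton statistics

The skeleton is the discrete crest of the mean-FA ridge: a voxel survives
if its FA beats both neighbours along the discrete direction of local
variation (largest |FA difference| across the 13 axis pairs; strongest
concavity as the fallback on symmetric crests), above an FA threshold
(default 0.2), with ties broken toward the lower linear index so flat
crests come out single-voxel wide and runs are deterministic. Projection
searches up to 4 voxels perpendicular for the subject's maximal-FA voxel
and reuses that source index for every other metric, corrected maps
included. Registration is bypassed: phantom subjects share one grid.

TFCE integrates `e(h,v)^E · h^H` over thresholds (defaults H=2, E=1, 100
integration steps placed at bin midpoints so no value sits exactly on a
threshold; 26-connectivity restricted to skeleton voxels; numba kernels).
Family-wise corrected p-values come from the permutation distribution of
the map-maximum TFCE under group-label exchange (sampled, or enumerated
exactly when the design allows fewer assignments than requested
permutations; statistics are quantised at 1e−9 relative before comparison
so float summation order cannot flip ties). The suite calibrates the
family-wise error to 0.05 ± 0.02 over 200 null cohorts at 500 permutations
(the production default is 5000).

On severe-atrophy cohorts the skeleton comparison shows the expected
pattern — uncorrected MD/RD/FA significant at the contaminated bundle, with
a marked (>40%) collapse of the maximal effect size after correction. A
strict corrected-nonsignificance flip is asserted at the *tract* level
(where it holds in 20/20 seeded replicates) but not voxelwise, because the
residual f-dependent corrected-MD bias noted above reaches d ≈ 1 at the
crest in the severe-atrophy regime. The uncorrected FA effect is the
*largest* on this phantom, not the smallest: at b=1200 with f ≈ 0.5,
contamination depresses FA by ~40% while biological FA variation is only a
few percent — the relative-error ordering (MD above FA) holds per voxel,
but effect-size orderings depend on the variability structure of the
cohort.

## Histograms

Fixed binning: FA over [0, 1] in 0.005 steps (200 bins); MD/AD/RD over
[0.10, 3.00]×10⁻³ mm²/s in 0.01 steps (290 bins); bins left-closed,
right-open, final bin closed. Heights are normalised by the number of
in-mask, in-range voxels — out-of-range values leave both the counts and
the denominator. The mean is the raw in-range voxel mean (not the binned
mean; the difference is below half a bin width); the mode is the centre of
the tallest bin, ties toward the lower bin. The white-matter mask comes
from phantom ground-truth labels, standing in for a T1 segmentation.

## Group statistics and attribution

Pooled-variance two-tailed t-tests (the printed df of 43 for 25-vs-20
comparisons implies pooled, not Welch), Cohen's d with (n−1)-weighted
pooled SD in the absolute-value convention and no small-sample correction
(the uncorrected d reproduces the published values within rounding), and a
classical sums-of-squares 2×2 mixed ANOVA (cross-checked against an
independent implementation to 1e−8, for both balanced and 25/20 designs).
Subjects with missing values are excluded per comparison, not listwise.

Attribution uses the control-group mean as the denominator of the relative
difference — the only convention that reproduces all six published
percentages simultaneously. Percentages are rounded half-away-from-zero to
integers at the reporting layer only.

## Problem sizes

The cohort experiments run on the 16×14×8 default grid with 33 volumes per
subject and 20 replicate cohorts of 45 subjects; permutation calibration
uses 200 null cohorts of 16 subjects on a 40-voxel skeleton at 500
permutations. These sizes were chosen so the complete suite and the
reproduction script each run in minutes on a single CPU while keeping every
estimate comfortably inside its tolerance.
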