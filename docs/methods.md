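# Methods

This note documents the models, defaults and numerical choices behind
`gaitbrain`, and what its synthetic-data tests do and do not demonstrate.

## Behavioral pipeline

**Gait parameters.** Four spatiotemporal parameters are evaluated at each
heel strike of the swing foot, all in millimetres (integrals in mm·s).
The body centre of mass is proxied by the mediolateral midpoint of the two
posterior hip markers.  *CoM* is that midpoint's ML position at the
strike; *Step-CoM* the swing heel's ML displacement from it; *Step Length*
the AP distance from trailing to leading heel; *∫CoP-CoM* the CoP−CoM ML
displacement integrated over the stance foot's single-stance phase.
Because toe-off is not instrumented, the single-stance interval of the
stance foot is approximated by the inter-strike interval ending at the
swing foot's strike; the first strike of a recording integrates over
whatever pre-strike window exists (possibly truncated), so its integral
should be treated as provisional.  ∫CoP-CoM uses the trial's own CoM
proxy trace as the displacement reference, computed per step — the
alternative reading (a fixed reference displacement carried over from the
slow-baseline trial) is not implemented; output metadata and this note
flag the chosen reading.

**Event detection.** Heel strikes are local maxima of a heel marker's AP
position relative to the hip-midpoint AP position, found per foot with a
prominence threshold of 10% of the trace's range and merged in time
order (they must alternate between feet).  Values at event times are
linearly interpolated between samples; integrals use the trapezoidal rule
on the recorded sampling grid with interpolated end points.  Pre-detected
event streams may be supplied directly, bypassing detection.

**Δ, symmetry, plateau.** For each foot and parameter, Δₖ =
100·(xₖ − b̄)/b̄ with b̄ the mean of that foot's baseline-slow steps (an
explicit error is raised when b̄ = 0).  The symmetry series is the
slow-stance minus fast-stance Δ, paired by within-condition step ordinal
(unmatched trailing steps dropped); it is a raw difference, not a
normalised ratio, and flips sign under foot swap.  The plateau of a
series is the mean of its final 50 values; the band SD is the *sample*
standard deviation (ddof = 1) of the same 50 values — a choice the rule
itself leaves open — and the series reaches plateau at the first step
whose next 9 consecutive values (itself included) stay within 2 band SDs
of the plateau.  The scan runs forward over every candidate start (not
only a single "next window"), so the first qualifying index wins and
tie-breaking is deterministic; when the band SD is 0 the criterion
collapses to exact equality.  If no window qualifies, steps-to-plateau is
reported as the series length with a `reached_plateau = False` flag.  All
three constants (50, 9, 2) are configurable.  The magnitude-at-plateau of
the split-condition symmetry series is the per-subject behavioral score;
only the split condition is scored.

## Voxelwise brain-behavior models

Subject maps sharing one grid and mask are regressed voxel by voxel:
Y = Xβ + ε with t = cᵀβ̂ / √(σ̂²·cᵀ(XᵀX)⁻¹c), df = n − rank(X).  All
selected symmetry scores enter one model jointly; age group and sex are
always covariates, TIV (mean-centred) optionally for volumetric metrics.
Q1 uses shared slopes with a unit contrast on one score; Q2 adds
group-specific slope columns per score and tests their difference.
Voxels with numerically zero residual variance get t = 0 and are counted.

**TFCE.** TFCE(v) = ∫₀^{t_v} e_v(h)^E h^H dh with the literature-standard
H = 2, E = 0.5 and 26-connectivity for volumetric lattices (exponents and
connectivity configurable).  The integral is a midpoint Riemann sum at
heights (i−½)·dh with dh = max|t|/200 by default (adaptive per map,
configurable).  The extent term is a step function of h, so the
quadrature error is first order in dh; 200 steps keeps the worst-case
deviation from a 10× finer evaluation below 1% of the map's peak enhanced
value on smooth random maps (per-voxel *relative* error is not a
meaningful target near zero: voxels below the first height get exactly 0
under any finite-step rule).  Negative statistics are enhanced on the
negated map and re-signed.  The implementation activates voxels in
descending height order into a union-find structure (numba-compiled), and
is verified in the tests against an independent relabel-everything oracle
at identical heights (agreement to machine precision) and against the
fine-step oracle.

**Permutation FWE.** Inference is Freedman–Lane: Y is residualised
against the nuisance columns (zero contrast weight), residual rows are
permuted, the nuisance fit is added back, the full model refitted, and
the image-wide maximum |TFCE| recorded; corrected p(v) =
(1 + #{perm max ≥ |TFCE_obs(v)|}) / (n_perm + 1).  The leading 1 is the
unpermuted member of the null ensemble, so p ≥ 1/(n_perm+1).  Using
|TFCE| makes the test two-sided with both directions sharing one
correction.  Permutations are drawn from a generator seeded only by
(seed), so results are bit-reproducible; when n_perm is not below n!,
a warning is issued and all n! permutations are enumerated exactly.
The default n_perm is 5,000.  Whether the behaviour of other permutation
toolboxes matches Freedman–Lane exactly is not guaranteed; this package's
scheme is stated here precisely for that reason.

**Clusters and atlas labels.** Connected components of {p < α} (α = .05)
are reported with extent K_E, the minimum-p voxel as peak (ties broken by
array order, then largest |TFCE|), world coordinates via the affine, and
the percentage of cluster voxels overlapping each atlas label; labels
under 5% are suppressed (threshold configurable).  Atlases on a different
grid are resampled nearest-neighbour via the affines.

## Synthetic cohorts

The generator emulates the study conditions the package targets: 31
younger and 19 older adults (sex drawn with the observed 17/31 and 10/19
female proportions), baseline slow/fast trials at 0.7/1.4 m/s and a split
trial with the left belt fast.  Defaults: 600 split steps per foot (≈10
minutes at the ~0.6 s step period used by the trial builder; per-subject
step counts are not published, so this is an assumption) and 120 baseline
steps (≈2-minute trials).

Per subject and parameter a true plateau symmetry s\* is drawn from the
group's Normal(mean, SD); the defaults are the published group values
(e.g. Step-CoM 29.0±16.0% younger, 3.2±23.4% older).  The split Δ series
of the two feet get opposite halves ±s\*/2 plus an opposite-signed
dual-rate transient A_fast·e^(−k/τ_fast) + A_slow·e^(−k/τ_slow)
(defaults 15% and 10%, τ = 15 and 100 steps) and i.i.d. Gaussian step
noise (default SD 5%); the study only requires that series "reach
plateau", so the dual-rate form is a modelling choice that provides known
ground truth.  Baseline series fluctuate around fixed raw-unit baselines
(CoM 20 mm, ∫CoP-CoM 30 mm·s, Step-CoM 120 mm, Step Length 600 mm —
plausible slow-walking magnitudes, nonzero so percent change is defined)
with zero systematic asymmetry, making Δ and symmetry interpretable
against zero.  Noise is i.i.d. across steps — real step series are
autocorrelated, so passing tests say nothing about autocorrelation
robustness.

**Marker trials.** Continuous trajectories are built so the extraction
stage reproduces the step series exactly in the zero-noise case: strikes
fall on sampling instants (100 Hz, 0.6 s steps), marker traces are
piecewise linear through per-strike knots carrying the target values
(plus an ML sway sinusoid vanishing at the knots), and the CoP−CoM
displacement is a triangle over each single-stance interval whose area is
the target integral — piecewise-linear with grid-aligned vertices, so
trapezoidal integration is exact.  These trials exercise the geometry of
the definitions, not realistic biomechanics (no double support, no
kinetic content, no soft-tissue noise).

**Brain maps.** Voxel value = baseline + slope·score·1[ROI] + group, sex
and TIV nuisance effects + Gaussian noise, optionally smoothed with a
Gaussian kernel (FWHM→σ via 2√(2·ln 2)) and rescaled so the *post*-
smoothing per-voxel SD equals `noise_sd` — this keeps planted per-voxel
R² interpretable.  The default grid is a 12×14×12 box with a one-voxel
border mask, 2 mm isotropic affine centred at the origin, and a 3³ ROI;
a synthetic octant atlas accompanies it.  These maps stand in for
preprocessed outputs; nothing about acquisition or preprocessing is
modelled.

## Problem sizes and verification

The test suite verifies, among other properties: exact agreement of the
plateau detector with a brute-force literal scan on 1,000 random series
of length 100–600; recovery of the configured Step-CoM symmetry mean by a
31-subject synthetic younger cohort within 2·SEM; GLM t vs the
closed-form correlation t to 1e-10 over 10⁴ voxels; the TFCE closed form
h³/3 and fine-step-oracle agreement on 100 random 12³ maps; family-wise
error calibration over 200 null cohorts (n = 40, 1,000-voxel mask, 500
permutations each; the binomial 95% interval around 0.05 is
[0.022, 0.089]); ≥80% power over 50 replicates on a planted 27-voxel,
per-voxel-R²≈0.3 effect at n = 50 with 1,000 permutations; and the
zero-noise marker-trial round trip to 1e-6 relative tolerance.
`scripts/acceptance.py` recomputes the same quantities from a
command-line seed, with the two permutation studies at 100 null cohorts
and 20 planted replicates (500 permutations each) so a full run stays in
the ten-minute range on one CPU.

## Known limitations

- The behavioral stage assumes complete, gap-free step series; no marker
  dropout handling.
- Event detection is tailored to treadmill-like periodic data; it is not
  a validated general-purpose gait event detector.
- Permutation inference assumes exchangeable errors after nuisance
  residualisation; heteroscedastic groups are not modelled (no variance
  smoothing, no cluster-extent inference).
- Surface (vertexwise) statistics are out of scope; the statistical stage
  operates on volumetric lattices only.
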