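# Methods

This note documents the models, numerical choices and limitations of the
qsmsci pipeline. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Digital phantom and simulated acquisition

The phantom (`qsmsci.phantom`) is a nested-ellipsoid brain on the GRE grid
(default 64³ voxels at 1.15 mm isotropic): a 3 mm cortical gray-matter
shell around white matter, a central CSF ventricle and two deep-gray
nuclei. Default tissue values, all configurable:

| tissue     | χ offset (ppm) | R2* (s⁻¹) | M0 (a.u.) |
|------------|---------------:|----------:|----------:|
| white matter | −0.03        | 19.2      | 850       |
| cortex GM    | 0.0          | 15.0      | 900       |
| ventricle CSF| +0.02        | 1.0       | 1000      |
| deep GM      | +0.05        | 30.0      | 850       |

Lesions are ellipsoids inside white matter with offsets relative to WM;
the defaults (+0.0086 ppm, −2.5 s⁻¹) equal the group-mean SCI-vs-NAWM
contrasts the analysis targets, so recovery tests address those numbers
directly. They are working values for synthetic data, not claims about
lesion tissue truth — the real measurements are outcomes, not generative
parameters. The standard 10-lesion fixture places all lesions in one
hemisphere (so mirrored control positions are lesion-free by construction)
with varied sizes (one below the 3 mm gate) and T1w pass fractions
spanning 0–1 (so the stringent definition removes some lesions entirely).

The ME-GRE signal model is mono-exponential with a linear-in-TE phase; the
field is the dipole convolution of the χ map, computed in k-space with
D(k) = 1/3 − k_z²/|k|², D(0) = 0, after zero-padding to twice the FOV to
suppress wrap-around. γ̄ = 42.577 MHz/T, so 1 ppm ↔ 127.73 Hz at 3 T.
Complex Gaussian noise is set by the requested first-echo white-matter SNR;
one seed in the protocol governs all draws. Optional multi-coil output uses
smooth low-order polynomial sensitivity magnitudes with distinct constant
phase offsets. FLAIR (0.65 × 0.65 × 1 mm³) and T1w (1 mm isotropic) volumes
are piecewise-constant tissue intensities on their native grids; lesion
voxels are set to `flair_contrast` × the cortical FLAIR mean, and exactly
`round(t1_pass_fraction · n)` of each lesion's T1w voxels are placed below
the hypointensity threshold. This bookkeeping is returned so tests can
count against generator truth. The simulation deliberately omits realistic
anatomy, k-space artifacts, motion, flow and slice profiles: passing tests
validate the estimators and decision rules under the stated signal model,
not robustness to those real-data effects.

## Field mapping

`fit_field_nonlinear` fits A, R2*, φ0, f per voxel by Gauss–Newton on the
complex data, initialized from magnitude²-weighted least squares on
adjacent-echo phase differences plus a log-linear magnitude fit. Per-voxel
backtracking (up to 10 halvings) makes the residual non-increasing at every
iteration; convergence is declared at relative residual change < 1e−8 or
when the residual energy falls below 1e−24 of the data energy (noiseless
fits hit machine precision in a few iterations). Voxels with a singular
normal system fall back to the initializer and are flagged. With uniform
ΔTE = 4 ms the field is identifiable only modulo 250 Hz; fits are reported
in (−125, +125] Hz.

Wrap removal uses a Laplacian/DCT unwrapper: the true-phase Laplacian is
estimated via cos φ·∇²(sin φ) − sin φ·∇²(cos φ) with reflecting boundaries
(the operator the DCT-II basis diagonalizes), the Poisson equation is
solved spectrally, and congruence is restored by rounding the correction to
integer multiples of the period per connected mask component. This is a
documented substitute for region-growing unwrappers: it is exact for
smooth wrapped surfaces up to a global constant and degrades gracefully
with noise (RMS < 0.05 rad at phase-noise level 0.02 rad in the tests).

`align_to_b0` rotates grids so z ∥ B0 (Rodrigues rotation about the grid
center; nearest-neighbour for masks — exact for axis-aligned rotations —
trilinear for continuous maps) and records the transform in the affine.
Brain masks for real data come from Otsu thresholding of the first-echo
magnitude plus largest-component and closing; phantom runs use the truth
mask.

## Background removal and inversion

PDF fits exterior-supported sources to the total field inside the mask by
LSMR (tol 1e−4, 100 iterations) and subtracts the explained part; the local
field is demeaned over the mask. The exact projection is idempotent, but
its operator has a continuum of vanishing singular values, so any practical
stopping rule leaves ~1–2 % of re-fittable content; re-applying PDF changes
the local field by below 2 % RMS on the reference fixture (verified in the
suite), and exterior-source fields are removed to < 1 % RMS. The mask must
keep a ≥ 2-voxel margin so exterior sources exist.

The dipole inversion solves the Tikhonov problem by conjugate gradients on
the normal equations (relative tolerance 1e−6, 300 iterations; binary mask
weighting by default, magnitude weighting optional). The default
α = 0.013. The quadratic penalty attenuates each k-component by
D²/(D²+α), underestimating χ globally; the map is therefore rescaled by
1/⟨D²/(D²+α)⟩ (≈ 1.55 at α = 0.013 on a 64³ grid), the standard correction
used with iterative Tikhonov inversion. `bias_correction=False` returns the
raw penalized solution, whose norm vanishes as α → ∞. Maps are referenced
by demeaning over the brain mask (recorded on the result), consistent with
χ maps being intrinsically water-referenced up to a constant. Hz→ppm
conversion (f/γ̄B0·10⁻⁶) happens once on entry to this module.

L-curve selection scans an increasing α grid (≥ 5 points over ≥ 3 decades),
computes ‖W(Dχ̂−f)‖ and ‖χ̂‖ on the *raw* minimizer (whose norms are
provably monotone in α; the masked, demeaned map's are not), smooths the
log-log curve with cubic splines and selects the interior maximum of the
right-bend curvature; endpoint curvature is a spline artifact and is
excluded, ties go to smaller α. On noisy fixtures the corner lands within
one grid step of the RMSE-optimal α. For noiseless, exactly consistent
data the L-curve has no noise corner: its maximum-curvature point sits
where regularization begins to suppress signal (large α), so corner
selection is only meaningful for noisy data.

Two observations about accuracy worth keeping in mind: recovery of a
sphere's Δχ is within ~7 % when the field is observed over the whole FOV,
but restricting observation to a tight brain mask discards the external
dipole tails and costs a further ~15–20 % regardless of α — a property of
the data, not the solver. The end-to-end lesion contrast is nevertheless
recovered within 20 % because the mirrored-NAWM comparison cancels shared
bias.

## Segmentation and pairing

Seed ROIs emulate generous manual drawings: truth masks dilated by 2
voxels. Thresholds use ≥ for FLAIR (hyperintense) and ≤ for T1w
(hypointense) at exactly 1.02 × the cortical mean (equality retained, both
factors configurable). The 3 mm greatest-dimension rule is the maximum
axis-aligned extent in mm and is re-checked after each definition is
applied. ROIs are moved between grids by pull-resampling through the known
affines at voxel centers (nearest-neighbour for masks); after interpolation
into the GRE grid, ROIs of ≤ 2 voxels are excluded. NAWM controls are the
lesion mask reflected across the grid mid-sagittal plane, then shifted
in-plane (same transverse slices) to the nearest position — distance-
then raster-ordered, within ±20 voxels — fully inside white matter and
disjoint from every lesion; voxel count is always preserved, and pairs with
no valid position are excluded with a recorded reason.

White-matter depth uses Euclidean distance transforms to the ventricle and
cortex masks: periventricular = within the 5th percentile of
distance-to-ventricle over WM; juxtacortical (among the rest) = within the
25th percentile of distance-to-cortex; remainder deep; precedence
periventricular > juxtacortical > deep. The percentile rule for
juxtacortical voxels is directionally ambiguous in the source description
(a 75th percentile of a distance map selects cortex-*distal* voxels); the
default implements the anatomically sensible proximity reading, and
`cortex_reading="distal"` gives the literal one. Lobes come from
majority vote over an atlas (the pipeline supplies a synthetic quadrant
atlas; ties and off-atlas ROIs give "other").

## Statistics

Lesions are the unit of analysis and are treated as independent, as in the
source analysis; within-subject clustering is not modeled (a known caveat —
subjects contribute different lesion counts). Excluded lesions never enter
statistics; reasons are exported. Paired t-tests are classical (zero
variance → flagged undefined); Bland–Altman limits are bias ± 1.96 sample
SD, and the bias is identically the paired-t Δ. Age correction residualizes
on ln(age) pooled across groups and restores the grand mean. The
multi-factor ANOVA uses sequential (type-I) sums of squares computed from
nested OLS fits in the fixed order ln(age), group, lobe, ln(volume) —
formula interfaces silently reorder categorical terms, which would change
the type-I decomposition — with type-II available by flag. Group
comparisons use Student's t (2 groups) or one-way ANOVA + Tukey HSD;
correlations are Pearson with two-sided p. All tests are two-sided with no
multiple-testing correction.

## Problem sizes and determinism

The standard fixture is a 64³ phantom (~75k brain voxels); a full
noiseless pipeline run takes a few seconds and the whole test suite a few
minutes on one CPU. Monte-Carlo checks use 200 draws (estimator bias) and
1000 replicates (null calibration). Every random draw flows from a single
seed (protocol or run config); rerunning with the same config is
byte-identical in all CSV/JSON outputs.
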