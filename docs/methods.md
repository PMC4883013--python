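# Methods

## Reliability: Cronbach's alpha as ICC

For one region, measurements form a subjects × raters matrix; "raters"
are scan sessions, scanner platforms, or segmentation-algorithm
versions. The statistic is

α = N·c̄ / (v̄ + (N−1)·c̄),

with N rater columns, c̄ the mean off-diagonal and v̄ the mean diagonal
entry of the between-rater covariance matrix, estimated with the
unbiased (n−1) divisor. This equals the average-measures consistency
ICC of a two-way mixed model, ICC(3,k). Two consequences users should
be aware of:

* **Consistency, not absolute agreement.** Adding a constant to one
  rater, or rescaling all raters by a common factor, leaves α
  unchanged. A between-version comparison in which one algorithm
  systematically over-segments by a fixed offset can therefore have
  α = 1. The absolute-agreement forms ICC(2,1)/ICC(2,k) are
  deliberately out of scope.
* **Average-measures.** For two raters, α = 4c/(v₁+v₂+2c), the
  Spearman–Brown "stepped-up" version of the single-measure
  consistency correlation r = c/v: α = 2r/(1+r) under equal variances.

α is capped at 1 only by arithmetic (c̄ ≤ v̄ by Cauchy–Schwarz on
average); it is never clipped, and strongly discordant raters can give
negative values. A table with zero total variance has no defined α and
raises an error.

**Confidence intervals** use Feldt's argument: (1−α̂)/(1−α) ~
F(n−1, (n−1)(k−1)), inverted at the two tail quantiles of the requested
level. The Feldt interval was chosen because it is the classical
closed-form interval for alpha in this design; other conventions
(bootstrap, Fisher-z) give slightly different bounds, so reported CIs
should be compared across studies with care. At α̂ = 1 the interval
degenerates to (1, 1).

**Cross-version matrices.** Between-version agreement is computed per
(new-version region, old-version region) pair of a harmonization map.
The shipped map pairs like-named regions and cross-pairs the three
cornu-ammonis sectors against all three legacy CA labels (CA1, CA2_3,
CA4_DG), because the version-6 boundary revision moved tissue between
sectors; the four regions new in v6.0 (parasubiculum, molecular layer,
GC-ML-DG, HATA) are unpaired. Pipeline order for between-version input
preparation: legacy volumes are divided by 8 (0.5-mm voxel basis →
mm³), then left/right averaged, then correlated.

**Median summaries** are plain sample medians (mean of the two central
values for even counts).

## Overlap: Dice coefficient

DSC = 2|A∩B|/(|A|+|B|) on voxel counts, per label, requiring identical
grid shape and voxel size (no resampling — the intended comparison is
two segmentations of the same image, where grids match by
construction; mismatched grids raise rather than silently
interpolate). A label absent from both volumes gives an *undefined*
DSC reported as NaN, not 0 or 1: an absent structure carries no overlap
information. The whole-structure DSC uses the union of foreground
labels on each side, excluding the hippocampal fissure by default
(a CSF cleft, not tissue); the exclusion list is configurable.

## Heritability: AE maximum-likelihood variance decomposition

Model: y ~ N(Xβ, Ω), Ω = 2Φσg² + Iσe², block-diagonal over families.
The pairwise multiplier 2Φ is the expected additive-genetic covariance
fraction: 1 for MZ co-twins, 0.5 for DZ co-twins (the full-sibling
kinship coefficient Φ = 1/4 doubled), 1 on the diagonal, 0 between
families. h² = σg²/(σg²+σe²). The model is AE: no shared-environment
(C) or dominance component, matching the standard polygenic model for
twin-pair volume data; with only MZ/DZ pairs, A and C are not both
identifiable without additional structure, and the AE restriction is a
modelling commitment, not a test result.

Fixed effects default to intercept, age, sex (indicator, F = 0/M = 1)
and age×sex. No phenotype transform is applied beyond this covariate
adjustment.

**Likelihood and optimisation.** For twin pairs each family block is
2×2, so the log-likelihood reduces to per-zygosity sufficient
statistics (cross-products of y and X within and across co-twins),
making one evaluation O(p²) independent of cohort size. β is profiled
out by GLS at each (σg², σe²). The two variance components are
maximized by L-BFGS-B *as fractions of the OLS residual variance* —
an O(1) parameterization chosen so finite-difference gradients are
well-scaled for phenotypes in any units (mm³-scale variances of order
10⁵ defeat absolute-step numerical gradients). Bounds: σg² ≥ 0,
σe² ≥ 10⁻¹⁰·σ̂². Three starts: Falconer-informed (h² seeded from
2(r_MZ − r_DZ) on OLS residuals, clipped to [0.02, 0.95]), an even
split, and a near-null start; the best optimum is kept, and a full fit
that ends below the (closed-form) null fit raises a convergence error.
The null model σg² = 0 is ordinary regression with ML residual
variance, computed in closed form. Fitting requires ≥ 20 families.

**Significance.** Λ = 2(ll_full − ll_null) is referred to the 50:50
mixture of χ²₀ and χ²₁, because σg² is tested on the boundary of its
parameter space: p = ½·P(χ²₁ ≥ Λ) for Λ > 0 and p = ½ at Λ = 0.
Small negative Λ within numerical tolerance is treated as 0; larger
negative values raise (the null is nested, so they indicate optimiser
failure). Finite-sample note: the mixture reference is asymptotic.
In simulations it is well calibrated for balanced designs with an
intercept-only mean model (empirical type-I error ≈ 0.05 at 50 + 50
pairs over 1000 replicates), and mildly conservative (≈ 0.03) when
four fixed effects are estimated from a 132/232-unbalanced cohort;
the package's calibration test uses the balanced intercept-only
design for this reason.

**Standard error of h².** Delta method on the observed information of
(σg², σe²), obtained by central finite differences of the profile
negative log-likelihood at the optimum (step 10⁻⁵·σ̂p², reflected at
the σg² = 0 boundary), inverted by pseudo-inverse. Near the boundary
the SE is a rough guide only; the LRT, not the Wald ratio, is the
inferential statement.

**Multiple testing.** Per-region p-values are compared with α/m
(Bonferroni) across the m regions of a report; m = 13 regions at
α = 0.05 gives 3.846 × 10⁻³.

**Falconer cross-check.** `falconer_h2` computes 2(r_MZ − r_DZ) from
double-entry Pearson twin correlations (optionally on OLS residuals).
It is a moment estimator with a known O(1/n_pairs) downward
finite-sample bias (≈ 0.02–0.03 at a 132 + 232-pair design); it is
used as an optimizer seed and an independent order-of-magnitude check,
not as the estimator of record.

## Synthetic data

The generator draws what the analyses need, under the models they
assume:

* **Twin cohorts** (`simulate_twin_cohort`): per region and family,
  pair phenotypes are bivariate normal with mean μ + Xβ, common
  variance σp² = SD² and covariance 2Φ·h²·σp² — exactly the AE model.
  Defaults describe a young-adult twin imaging study: 132 MZ + 232 DZ
  pairs, pair-shared ages ~ N(22.65, 2.73²) years, 64% female, MZ
  pairs sex-matched, and 13 regions (whole hippocampus + 12 subfields)
  with means at published bilateral volume scales (whole hippocampus
  3200 mm³ … parasubiculum 61 mm³) and generative h² spanning
  0.56–0.88. Regional SDs are not published alongside the means; the
  default SD is 12% of the regional mean, a typical coefficient of
  variation for automated subfield volumes. Covariate effects default
  to zero and can be switched on to test covariate adjustment.
* **Test-retest tables** (`simulate_retest`): two sessions = latent
  base + independent Gaussian error with σ²_err = 2σ²_base(1−t)/t,
  so the *expected two-column consistency alpha* equals the target t
  (the single-session reliability relative to the latent base is then
  2t/(1+t) > t; the calibration is deliberately in units of the
  statistic the package reports).
* **Cross-version pairs** (`simulate_version_pair`): second column
  with set Pearson correlation and multiplicative scale offset;
  consistency ICC reproduces the correlation only at scale 1.
* **Label pairs** (`simulate_label_pair`): voxelized ellipsoids, the
  second an exact integer-voxel translate of the first, so expected
  DSC values are computable by brute-force voxel enumeration.

Randomness is hierarchical (`numpy` SeedSequence spawning): one master
seed, one substream for cohort structure, one per region — adding a
region leaves existing regions' draws untouched; all generators are
bit-reproducible given a seed.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: MRI intensities and artefacts, scanner
and site effects, segmentation failure modes, non-Gaussian or skewed
volume distributions, age trends in variance, shared (C) environment,
assortative mating, and anatomically realistic region shapes (overlap
fixtures are geometric). Closed-loop recovery demonstrates estimator
correctness under the assumed model, not robustness to violations of
it.

## Problem sizes in the shipped checks

The simulation-based checks use: 100 simulated cohorts per generative
h² ∈ {0.2, 0.5, 0.8} at the 132 + 232-pair design for parameter
recovery (tolerance 0.02 on the mean); 1000 null replicates of 50 + 50
pairs for LRT calibration (three-sigma binomial band around 0.05);
n = 500 subjects for the test-retest closed loop (±0.05 around target
0.9); and exact voxel-count oracles for all overlap fixtures. These
sizes keep the full suite to a couple of minutes while leaving
Monte-Carlo error well inside each tolerance.

## Known limitations

* Only twin-pair families are fitted (the kinship container represents
  larger sibships, but the likelihood fast path assumes pairs).
* Consistency ICC only; no absolute-agreement variants, no
  Bland–Altman analysis.
* No image registration or resampling; Dice requires grid-matched
  inputs.
* The AE model cannot separate shared environment from additive
  genetics in MZ/DZ data; reported h² is an upper-bound-flavoured
  estimate under the purely additive assumption.
* Missing data are handled complete-case per analysis.
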