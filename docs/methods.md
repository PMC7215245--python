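# Methods

## Scientific setting

Sport-related concussion triggers a neurometabolic cascade that outlasts
symptom resolution. Single-voxel MR spectroscopy (SVS) of the primary
motor cortex quantifies N-acetyl aspartate (NAA, a neuronal-integrity
marker) and myo-inositol (Ins, a glial osmolyte) relative to creatine
(Cr) or choline (Cho). The scientific questions this package's analyses
address are (1) how metabolite log-ratios evolve from the acute phase of
injury (ACU, 1–7 days) through medical clearance to return-to-play (RTP)
and one month / one year post-RTP (1MO, 1YR), moderated by history of
concussion (HOC), days post-injury (dACU) and days to clearance (dRTP);
and (2) whether metabolite levels correlate voxelwise with white-matter
microstructure (FA, MD) and motor-cortex functional connectivity (Fconn).

Because no cohort of this design is publicly deposited, the package ships
a synthetic-cohort generator whose defaults encode the study conditions:
66 controls scanned once, 33 concussed athletes scanned at four sessions
with per-session retention 27/25/25/13, dropout rank-correlated with dRTP
(target ρ = 0.5, the observed order of attrition correlations), and
metabolite trajectories drawn from the same mixed model the analysis
fits, using the published longitudinal effect sizes for Ins/Cr and NAA/Cr
as generating truth.

## Metabolite preparation

Left/right motor-cortex ratios are log-transformed and averaged
(`log_ratio_average`); if one side is missing the other is used.
Log-ratios are winsorized with 5% total tail mass over the pooled
analysis sample per metabolite. The clip bounds are order statistics
(nearest rank, rounding outward) rather than interpolated percentiles:
interpolated bounds shift inward once the tails are clipped, so repeated
winsorization would keep eating into the sample, whereas order-statistic
bounds make the operation exactly idempotent. Moments are reported as ML
(biased) sample skewness and non-excess kurtosis (Normal = 3), matching
the convention in which post-winsorization kurtosis is expected near 3.

dACU is centered at 5 days (the cohort mean). dRTP is strongly
right-skewed (generator draws have skewness ≈ 2), so it is mapped to
normal scores, Φ⁻¹((rank − ½)/n) with average ranks for ties, then
mean-centered. The transform is applied per fitted cohort. We read
"inverse empirical distribution transform" as rank-based inverse-normal
(not inverse-uniform): the stated purpose is to control heavy tails
before use as a linear-model covariate, which the normal-scores version
accomplishes while the uniform version leaves a bounded but non-Gaussian
covariate. This is a documented interpretation, not a reported detail.

`normative_logratio_ci` implements the generic propagation-of-error
half-width 1.96·√(cv₁² + cv₂² − 2·corr·cv₁·cv₂) for a two-component
ratio on the log scale. The test-retest CVs needed to reproduce any
specific published normative interval are not available, so only the
formula is provided.

## The longitudinal mixed model

For concussed athlete *i* at session *t*:

    y_it = x_it' β + b_i + e_it,  b_i ~ N(0, σ_b²),  e_it ~ N(0, σ_e²)

with 12 fixed effects in fixed order: intercept (ACU reference), RTP,
1MO, 1YR indicators, session×HOC for all four sessions, ACU×dACU, and
session×dRTP for the three post-acute sessions. Interaction columns are
simple effects: each is nonzero only on its session's rows. Controls
never enter this model; they appear only in cross-sectional contrasts.

Fitting is maximum likelihood (the convention of the mixed-model fitters
this design is usually run through; REML would differ negligibly at these
sizes and is not provided). β and σ_e are profiled out analytically,
leaving a 1-D problem in the variance ratio θ = σ_b²/σ_e² solved by
bounded Brent search on [0, 10⁴] with tolerance 1e-8; θ = 0 is checked
explicitly so σ_b = 0 solutions land exactly on the boundary. Each
profiled evaluation uses per-subject sufficient statistics, so a fit
costs ~1 ms — what makes the resampling studies below feasible. The
returned log-likelihood equals the blockwise multivariate-normal density
at the estimates (tested against a direct dense evaluation and against
statsmodels MixedLM). Rank-deficient designs (e.g. a bootstrap replicate
that loses an HOC stratum) drop collinear columns with a warning by
default; dropped coefficients are reported as NaN.

Model-based simulation supports two modes. *Marginal* draws a fresh
intercept per subject; *conditional* (the imputation default) draws from
the subject's posterior intercept given its observed sessions — BLUP mean
n_i σ_b²/(n_i σ_b² + σ_e²) × mean residual, conditional variance
σ_b² σ_e²/(n_i σ_b² + σ_e²) — so imputed values respect the subject's own
level. Conditional imputation preserves observed subject means better in
simulation; the original choice is not recorded, so both are exposed via
configuration.

## Boot-MI inference

The resampling unit is the athlete: each of B replicates draws n subjects
with replacement, a drawn subject contributing all its sessions, observed
and missing. Within a replicate the imputation LMM is re-fitted to the
replicate's observed rows (propagating imputation-model uncertainty; a
frozen full-data fit is available by argument), M complete datasets are
simulated, the estimator applied to each, and the M estimates averaged
into one point. The B points form an ordinary bootstrap distribution:
point estimate = mean, 95% CI = 2.5/97.5 percentiles, BSR = mean/SD,
two-sided empirical p = 2·min(#{b*≤0}, #{b*≥0})/B floored at 1/(B+1) so
BH-FDR never sees a zero. Defaults are B = 1000, M = 10. FDR families
follow the reporting tables: per metabolite, the 11 non-reference
longitudinal terms; and the 8 session×stratum cross-sectional contrasts.
Replicates in which a term becomes inestimable are kept with that term
skipped rather than redrawn.

Cross-sectional contrasts resample concussed and control subjects
independently within matched HOC strata; missing concussed sessions are
imputed from the within-replicate model fit (with the stratum-constant
HOC columns dropped), and the statistic is the difference of session
means.

## Voxelwise correlation mapping

Missing subject maps are completed with SOFT-IMPUTE before any
correlation analysis: alternately fill missing entries with the current
estimate and soft-threshold the singular values by λ, with column means
re-estimated from observed residuals at each sweep (an exact coordinate
step, keeping the objective monotone and making noiseless low-rank
recovery exact — one-shot pre-centering leaves a biased fixed point).
The matrix layout is subjects × voxels for one parameter. λ is chosen by
held-out reconstruction error along a geometric path from λ_max; the
configuration of the original imputation is not described anywhere
recoverable, so layout and selection are design choices of this package.

The statistic map is the voxelwise Spearman correlation between the
subject metabolite value and the parameter map (average ranks for ties).
Voxelwise p-values come from a subject bootstrap (B = 1000 default):
two-sided tail mass of the per-voxel ρ distribution about zero, floored
at 1/(B+1). The bootstrap resampling is computed by an exact
count-weighted ranking identity rather than re-ranking the matrix per
replicate.

Cluster-extent correction: smoothness is estimated per axis from
neighbour differences of the subject maps residualized on the group mean
(FWHM = Δ·√(−2 ln 2 / ln r), r = 1 − var(diff)/(2 var); axes rougher than
any Gaussian field report a below-voxel sentinel). A Monte-Carlo null
smoothed to that FWHM inside the mask is thresholded two-sided and the
minimum cluster size is the smallest extent whose familywise exceedance
is ≤ α. One calibration detail matters: the empirical bootstrap voxel
test is anti-conservative at its achievable levels (at n = 60, B = 200
the null probability of p < 0.005 is ≈ 0.009–0.011, because "p below
0.005" is the event that all bootstrap replicates agree in sign, and the
bootstrap spread slightly understates sampling spread). The Monte-Carlo
null is therefore calibrated at the bootstrap test's *measured* effective
voxel level (`bootstrap_voxel_level`), not the nominal one; without this
the familywise rate roughly doubles. Clusters are formed with
face (6-neighbour) connectivity after splitting suprathreshold voxels by
the sign of ρ, so abutting positive and negative clusters never merge;
centers of mass are |ρ|-weighted and reported in the map's own mm space
(synthetic grids are not MNI; no atlas lookup is attempted).

Regional summaries average the parameter over all surviving cluster
voxels per subject and report the Spearman correlation, the HOC-partial
Spearman correlation (rank all three variables, residualize the x- and
y-ranks on the covariate ranks, Pearson of residuals), and the change in
absolute correlation |pcorr| − |corr| with a bootstrap CI and a one-sided
p for reduction. The connectivity-gradient statistic pairs, across mask
voxels, the control group's mean connectivity with the concussed group's
metabolite–Fconn ρ map and reports their Spearman correlation with a
subject-bootstrap CI (the ρ map is recomputed per replicate).

## Synthetic data: what it emulates and what it does not

Days to RTP are log-normal with μ = ln 22 and σ = ln(95/22)/Φ⁻¹(0.75)
(median 22, upper quartile ≈ 95 days), truncated at 365 by resampling and
kept continuous — rounding to whole days piles ties onto the
short-recovery end and defeats rank transforms. Dropout per session is
assigned to the k largest values of w·z + ε (z the standardized dRTP
rank), with w calibrated by Monte Carlo to the target rank correlation
and k chosen to hit the retention counts exactly. HOC is assigned
independently of dRTP (recovery time was not prolonged with HOC).
Missingness is applied strictly after outcome generation, so complete-
data estimators on the pre-mask columns are unbiased by construction
(missing-at-random given dRTP).

The generating variance components σ_b = 0.10, σ_e = 0.15 (log-ratio
units) are assumptions — no variance components are published — chosen so
simulated 95% CIs at n = 33 have roughly the published widths.  Control
means equal the concussed ACU intercept (−0.50 for Ins/Cr, 0.30 for
NAA/Cr, plausible log-ratio scales), with small HOC shifts (0.086, 0.046)
matching the reported non-significant control HOC effects. Cho-referenced
ratios are the Cr-referenced values plus N(0, 0.05²) jitter, mirroring
the reported near-equivalence of the two references.

Voxel maps are white noise smoothed to 6 mm FWHM on 3 mm voxels and
standardized across subjects per voxel; inside planted clusters the value
is w·z_i + √(1−w²)·noise with z_i the subject's metabolite normal score
and w solved from the bivariate-normal identity ρ_s = (6/π)·asin(w/2) so
the expected Spearman correlation hits the target. The generator does not
simulate acquisition physics, registration error, physiological noise
structure, or anatomically realistic masks — so passing tests demonstrate
calibration of the *statistical* machinery under the assumed data model,
not robustness to real-data artifacts.

## Validation studies and problem sizes

The test suite runs (sizes chosen to keep the full suite within a desk-
scale run; `neurometab.validation` takes sizes as arguments):

- Recovery: 50 cohorts, Boot-MI B = 60, M = 2; mean estimates within
  ±0.05 of generating values for all 12 terms.
- Coverage: 200 cohorts at B = 200, M = 2; pooled 95% CI coverage within
  [0.90, 0.98].
- Type-I: 200 null cohorts; FDR-flagged fraction ≤ 0.07 (observed rate is
  near zero — the empirical-p floor at B = 200 makes the smallest BH
  threshold unreachable, a deliberate conservatism).
- Cluster familywise error within the binomial 95% band around 0.05 over
  200 fresh null fields on a 24³ mask; planted ρ = 0.7 cluster detected
  in ≥ 90% of 50 end-to-end runs at n = 60 with false-cluster runs at no
  more than the nominal rate.
- SOFT-IMPUTE masked-entry relative error < 1% on a noiseless rank-2
  60×20 matrix with 30% missing; monotone objective.
- Transform properties (winsorization idempotence and kurtosis reduction,
  rank-inverse-normal symmetrization of dRTP) and exact oracle
  equivalences (Spearman vs rank-then-Pearson, BH step-up by hand, LMM
  likelihood vs direct MVN density).
- Connectivity gradient: planted negative relation recovered with correct
  sign in ≥ 95% of 50 seeds.

## Known limitations

- The LMM has random intercepts only; random slopes or heteroscedastic
  residuals are out of scope by design.
- Percentile-bootstrap CIs at n = 33 lean on symmetry; BCa corrections
  are not implemented.
- The empirical-p floor makes very small p-values unattainable at small
  B; users wanting FDR resolution below ~1/B must raise B.
- Winsorization is fitted on the pooled sample per metabolite, so
  repeated analyses of subsets inherit the pooled clip bounds.
- Synthetic imaging masks are rectangular; mask geometry effects on
  cluster thresholds are exercised only through the mask argument.
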