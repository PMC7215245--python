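# neurometab

Longitudinal analysis of brain neurometabolites after sport-related
concussion, with bootstrap + multiple-imputation inference and voxelwise
correlation mapping — plus a synthetic-cohort simulator that makes every
stage testable without access to clinical data.

## The problem

Single-voxel MR spectroscopy (SVS) of the motor cortex quantifies
N-acetyl aspartate (NAA) and myo-inositol (Ins) relative to creatine
(Cr).  In concussed athletes scanned at acute injury (ACU, 1–7 days),
medical clearance to return-to-play (RTP), one month and one year
post-RTP (1MO, 1YR), two questions arise:

1. How do metabolite log-ratios change across recovery, allowing for
   history of concussion (HOC), days post-injury (dACU) and days to
   clearance (dRTP) — when a third of the cohort misses sessions, and the
   longer an athlete takes to be cleared the likelier they are to drop
   out?
2. Do metabolite levels correlate, voxel by voxel, with white-matter
   microstructure (FA/MD) and motor-cortex functional connectivity
   (Fconn)?

## The model

For concussed athlete *i* at session *t* the log-ratio follows a
random-intercept linear mixed model

    y_it = x_it' β + b_i + e_it,   b_i ~ N(0, σ_b²),  e_it ~ N(0, σ_e²)

with fixed effects of session relative to ACU and simple-effect
interactions session×HOC, ACU×dACU and session×dRTP (12 terms).  The
fitter profiles β and σ_e analytically and solves a 1-D maximum-likelihood
problem in σ_b²/σ_e² (~1 ms per fit).  Inference is **Boot MI**: B subject
bootstraps carrying missing sessions along, M model-based imputations per
replicate averaged into one point estimate; the B points give percentile
95% CIs, bootstrap ratios (mean/SE) and empirical p-values with
Benjamini–Hochberg FDR at 0.05.  Imaging analyses use SOFT-IMPUTE matrix
completion, voxelwise Spearman maps with bootstrap p-values, and
cluster-extent correction calibrated by a Gaussian-field Monte-Carlo null
at the bootstrap test's measured effective voxel level.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```sh
python analysis/01_simulate.py 42          # cohort + voxel stack -> results/
python analysis/02_fit_longitudinal.py 42  # Boot-MI coefficient report
python analysis/03_cross_sectional.py 42   # concussed-vs-control contrasts
python analysis/04_voxelwise.py 42         # cluster-corrected Spearman maps
python analysis/05_calibration.py 42       # quick calibration report
```

`01_simulate.py` builds 66 controls and 33 concussed athletes with
retention 27/25/25/13 across ACU/RTP/1MO/1YR, dropout rank-correlated
with days to RTP, and Ins/Cr values generated with a transient elevation
(+0.230 at RTP, +0.276 at 1MO) that is suppressed in athletes with prior
concussion (−0.278, −0.347).  `02_fit_longitudinal.py` (B=1000, M=10)
then prints, for seed 42:

```
6 terms significant at FDR 0.05:
  naa_cr 1MO:HOC: b=+0.159 [+0.032, +0.280], BSR=2.58, p=0.010
  naa_cr 1YR:HOC: b=+0.263 [+0.042, +0.446], BSR=2.58, p=0.016
  naa_cr ACU:dACU: b=+0.061 [+0.034, +0.087], BSR=4.47, p=0.001
  naa_cr 1MO:dRTP: b=-0.141 [-0.207, -0.071], BSR=-4.03, p=0.001
  ins_cr 1MO: b=+0.275 [+0.165, +0.382], BSR=5.01, p=0.001
  ins_cr 1MO:HOC: b=-0.334 [-0.473, -0.188], BSR=-4.56, p=0.001
```

i.e. this realization recovers the generating Ins/Cr elevation at 1MO
(+0.275 vs true +0.276) and its HOC suppression (−0.334 vs −0.347); the
flagged NAA/Cr interactions likewise sit near their generating values.
`04_voxelwise.py` recovers the planted 257-voxel cluster (254 voxels
survive correction, peak ρ = 0.85) with no false clusters:

```
smoothness [5.96 6.   5.96] mm; min cluster extent 16 voxels
 cluster  com_x_mm  com_y_mm  com_z_mm  size_mm3  n_voxels  peak_rho
       1    36.157    36.112    35.783    6858.0       254     0.854
```

The same stages are available as a CLI (`neurometab simulate`,
`fit-longitudinal`, `compare-cross-sectional`, `voxelwise`, `report`)
with YAML configuration and exit codes 0/2/3 for success / config error /
data error.

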