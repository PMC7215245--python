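"""Simulation studies validating the inference machinery end to end.

Each study generates synthetic cohorts or fields from known truth, runs
the corresponding analysis stage, and reduces the outcome to a small dict
of calibration numbers (bias, CI coverage, type-I rate, familywise error,
detection rate).  They back both the acceptance test suite and
``scripts/acceptance.py``; problem sizes are arguments so callers choose
their precision/runtime trade-off.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, stats

from neurometab import bootmi, lmm, voxel
from neurometab.cohort import (
    CohortConfig,
    PlantedClusterSpec,
    default_ins_cr_truth,
    generate_voxel_stack,
    null_truth,
    simulate_study,
)


def _cohort_data(seed: int, truth) -> bootmi.LongitudinalData:
    df = simulate_study(CohortConfig(seed=seed), ins_truth=truth,
                        cho_variants=False)
    conc = lmm.prepare_covariates(df[df.group == "concussed"])
    return bootmi.LongitudinalData(lmm.build_design(conc, response="ins_cr"))


def recovery_study(n_cohorts: int = 50, B: int = 60, M: int = 2,
                   seed: int = 0) -> dict:
    """Boot-MI point-estimate recovery of the generating fixed effects.

    Simulates cohorts with the reference Ins/Cr effect sizes and the
    standard attrition pattern, runs Boot-MI per cohort and averages the
    point estimates.  Returns per-term means, the truth, and the largest
    absolute bias.
    """
    truth = default_ins_cr_truth()
    beta = np.asarray(truth.beta)
    points = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in range(n_cohorts):
            data = _cohort_data(seed * 100_000 + c, truth)
            rng = np.random.default_rng(np.random.SeedSequence([seed, 1, c]))
            dist = bootmi.boot_mi(data, B, M, rng)
            points.append(np.nanmean(dist, axis=0))
    mean = np.mean(points, axis=0)
    return {
        "terms": list(lmm.DESIGN_COLUMNS),
        "mean_estimates": mean,
        "truth": beta,
        "max_abs_bias": float(np.max(np.abs(mean - beta))),
        "n_cohorts": n_cohorts,
    }


def coverage_study(n_cohorts: int = 200, B: int = 200, M: int = 2,
                   seed: int = 0) -> dict:
    """Coverage of 95% percentile Boot-MI CIs, pooled over the 12 terms."""
    truth = default_ins_cr_truth()
    beta = np.asarray(truth.beta)
    hits = 0
    total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in range(n_cohorts):
            data = _cohort_data(seed * 100_000 + c, truth)
            rng = np.random.default_rng(np.random.SeedSequence([seed, 2, c]))
            dist = bootmi.boot_mi(data, B, M, rng)
            for j in range(dist.shape[1]):
                d = dist[:, j]
                d = d[np.isfinite(d)]
                if d.size < B // 2:
                    continue
                lo, hi = np.percentile(d, [2.5, 97.5])
                hits += lo <= beta[j] <= hi
                total += 1
    return {"coverage": hits / total, "n_cohorts": n_cohorts, "n_intervals": total}


def type1_study(n_cohorts: int = 200, B: int = 200, M: int = 2,
                seed: int = 0) -> dict:
    """Fraction of FDR-flagged terms under an all-null generator."""
    flagged = 0
    total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in range(n_cohorts):
            data = _cohort_data(seed * 100_000 + 50_000 + c, null_truth())
            rng = np.random.default_rng(np.random.SeedSequence([seed, 3, c]))
            dist = bootmi.boot_mi(data, B, M, rng)
            summaries = bootmi.summarize_family(dist, lmm.DESIGN_COLUMNS)
            flagged += sum(s.fdr_significant for s in summaries[1:])
            total += len(summaries) - 1
    return {"type1_rate": flagged / total, "n_cohorts": n_cohorts, "n_tests": total}


def soft_impute_study(seed: int = 0) -> dict:
    """Noiseless rank-2 completion: masked-entry error and monotonicity."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    M = rng.normal(size=(60, 2)) @ rng.normal(size=(2, 20))
    X = M.copy()
    hole = rng.random(M.shape) < 0.3
    X[hole] = np.nan
    out, fit = voxel.soft_impute(X, lam=0.01, tol=1e-10, max_iter=5000)
    rel = float(np.linalg.norm(out[hole] - M[hole]) / np.linalg.norm(M[hole]))
    return {
        "masked_rel_error": rel,
        "objective_monotone": bool(np.all(np.diff(fit.objective_trace) <= 1e-9)),
        "n_masked": int(hole.sum()),
    }


def cluster_fwe_study(seed: int = 0, fwhm: float = 6.0, shape=(24, 24, 24),
                      n_sims: int = 1000, n_fresh: int = 200,
                      voxel_p: float = 0.005, alpha: float = 0.05) -> dict:
    """Self-calibration of the Monte-Carlo cluster-extent threshold.

    FWHM is estimated from a handful of smoothed null maps, the minimum
    cluster size derived, then the familywise false-positive rate measured
    on fresh null fields thresholded the same way.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    mask = np.ones(shape, dtype=bool)
    vs = (3.0, 3.0, 3.0)
    maps = np.stack([
        voxel.smooth_noise_field(shape, fwhm, vs, rng) for _ in range(6)
    ])
    fw = voxel.estimate_fwhm(maps, mask, vs)
    thr = voxel.cluster_size_threshold(mask, fw, voxel_p=voxel_p, alpha=alpha,
                                       n_sims=n_sims, rng=rng, voxel_size=vs)
    zcrit = stats.norm.ppf(1 - voxel_p / 2)
    struct = ndimage.generate_binary_structure(3, 1)
    fp = 0
    for _ in range(n_fresh):
        f = voxel.smooth_noise_field(shape, fwhm, vs, rng)
        z = (f - f[mask].mean()) / f[mask].std()
        hit = False
        for signed in (z > zcrit, z < -zcrit):
            lab, n = ndimage.label(signed & mask, structure=struct)
            if n and np.bincount(lab.ravel())[1:].max() >= thr:
                hit = True
        fp += hit
    return {
        "fwe_rate": fp / n_fresh,
        "threshold_voxels": thr,
        "fwhm_estimate": fw,
        "n_fresh": n_fresh,
    }


def detection_study(n_runs: int = 50, n_subjects: int = 60, B: int = 200,
                    seed: int = 0, target_rho: float = 0.7) -> dict:
    """End-to-end planted-cluster recovery through the full map pipeline.

    A 257-voxel sphere with target Spearman correlation ``target_rho`` is
    planted in smoothed noise; the run counts as detected when a surviving
    cluster overlaps the true region, and as a false-cluster run when any
    surviving cluster lies wholly outside its dilation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    spec = PlantedClusterSpec(clusters=[((12, 12, 12), 4, target_rho)])
    truemask = spec.cluster_mask()
    grown = ndimage.binary_dilation(truemask, iterations=2)
    p_eff = voxel.bootstrap_voxel_level(n_subjects, B, 0.005, rng)
    thr = voxel.cluster_size_threshold(spec.mask, spec.smoothing_fwhm,
                                       voxel_p=p_eff, n_sims=1000, rng=rng,
                                       voxel_size=spec.voxel_size)
    detected = 0
    false_runs = 0
    for r in range(n_runs):
        run_rng = np.random.default_rng(np.random.SeedSequence([seed, 7, r]))
        x = run_rng.normal(size=n_subjects)
        stack = generate_voxel_stack(x, spec, run_rng)
        rho = voxel.spearman_map(x, stack)
        p = voxel.bootstrap_p_map(x, stack, B, run_rng)
        clusters = voxel.extract_clusters(rho, p, stack, min_size=thr)
        detected += any(
            np.any(truemask[tuple(c.member_voxels.T)]) for c in clusters
        )
        false_runs += any(
            not np.any(grown[tuple(c.member_voxels.T)]) for c in clusters
        )
    return {
        "detection_rate": detected / n_runs,
        "false_cluster_rate": false_runs / n_runs,
        "threshold_voxels": thr,
        "effective_voxel_p": p_eff,
        "n_runs": n_runs,
    }


def gradient_study(n_seeds: int = 50, n_subjects: int = 50, B: int = 100,
                   seed: int = 0) -> dict:
    """Sign recovery of a planted negative connectivity-metabolite gradient.

    Voxels with low control-mean connectivity get the strongest positive
    metabolite correlation (a monotone-decreasing relation), so the
    voxel-paired Spearman statistic must come back negative.
    """
    shape = (12, 12, 12)
    rhos = []
    for s in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 8, s]))
        x = rng.normal(size=n_subjects)
        ctl = voxel.smooth_noise_field(shape, 9.0, (3, 3, 3), rng)
        rho_map = np.clip(-0.8 * (ctl - ctl.mean()) / ctl.std(), -0.9, 0.9)
        spec = PlantedClusterSpec(grid_shape=shape, clusters=[])
        stack = generate_voxel_stack(x, spec, rng, rho_map=rho_map)
        rho, _, _ = voxel.connectivity_gradient(ctl[stack.mask], x, stack,
                                                B=B, rng=rng)
        rhos.append(rho)
    rhos = np.asarray(rhos)
    return {
        "sign_correct_rate": float(np.mean(rhos < 0)),
        "mean_rho": float(rhos.mean()),
        "n_seeds": n_seeds,
    }
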