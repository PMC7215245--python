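"""End-to-end analysis stages tying the modules together.

Each stage takes a cohort table (and, for imaging, a voxel stack), applies
the preparation -> model -> inference chain and returns report tables.
The command-line interface and the numbered analysis scripts are thin
wrappers around these functions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from neurometab import bootmi, lmm, prep, voxel
from neurometab.io import DataError, RunConfig, cluster_table, summaries_table

log = logging.getLogger("neurometab")

STRATA = ((0, "no HOC"), (1, "HOC"))


def _winsorized_column(df: pd.DataFrame, metabolite: str, tail: float) -> pd.Series:
    """Winsorize a metabolite over the pooled analysis sample (all groups,
    all observed sessions) — one clipping window per metabolite."""
    if metabolite not in df.columns:
        raise DataError(f"cohort table has no column {metabolite!r}")
    return pd.Series(prep.winsorize(df[metabolite].to_numpy(float), tail),
                     index=df.index)


def longitudinal_data(
    df: pd.DataFrame, metabolite: str, cfg: RunConfig
) -> bootmi.LongitudinalData:
    """Concussed sessions -> winsorized response -> 12-column design."""
    df = df.copy()
    df["_resp"] = _winsorized_column(df, metabolite, cfg.winsor_tail)
    conc = df[df["group"] == "concussed"]
    if conc.empty:
        raise DataError("no concussed rows in cohort table")
    conc = lmm.prepare_covariates(conc)
    design = lmm.build_design(conc, response="_resp")
    return bootmi.LongitudinalData(design)


def fit_longitudinal(
    df: pd.DataFrame,
    metabolite: str,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Longitudinal fixed-effect report for one metabolite.

    Boot-MI over subjects (B replicates, M imputations per replicate),
    percentile CIs, bootstrap ratios, empirical p-values, and BH-FDR at
    ``cfg.fdr_q`` over the 11 non-reference terms.
    """
    data = longitudinal_data(df, metabolite, cfg)
    dist = bootmi.boot_mi(data, cfg.B, cfg.M, rng,
                          imputation_mode=cfg.imputation_mode)
    summaries = bootmi.summarize_family(dist, lmm.DESIGN_COLUMNS, q=cfg.fdr_q)
    table = summaries_table(summaries)
    table.insert(0, "metabolite", metabolite)
    log.info("longitudinal fit of %s: %d/%d replicates usable", metabolite,
             int(np.isfinite(dist[:, 0]).sum()), cfg.B)
    return table


def cross_sectional(
    df: pd.DataFrame,
    metabolite: str,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Concussed-vs-control mean contrasts at each session, HOC-stratified.

    Eight contrasts (4 sessions x 2 strata) form the FDR family.  A
    stratum empty at a session is skipped with a warning.
    """
    df = df.copy()
    df["_resp"] = _winsorized_column(df, metabolite, cfg.winsor_tail)
    rows = []
    dists = []
    for hoc, label in STRATA:
        conc = df[(df["group"] == "concussed") & (df["hoc"] == hoc)]
        ctl = df[(df["group"] == "control") & (df["hoc"] == hoc)]
        if conc.empty or ctl.empty:
            log.warning("stratum %s empty; skipped", label)
            continue
        conc = lmm.prepare_covariates(conc)
        data = bootmi.LongitudinalData(lmm.build_design(conc, response="_resp"))
        ctl_vals = ctl["_resp"].to_numpy(float)
        for session in lmm.SESSIONS:
            obs_at = conc[(conc["session"] == session) & conc["observed"]]
            if obs_at.empty:
                log.warning("no observed %s data in stratum %s; skipped",
                            session, label)
                continue
            dist = bootmi.two_sample_boot(
                data, session, ctl_vals, cfg.B, cfg.M, rng,
                imputation_mode=cfg.imputation_mode,
            )
            dists.append(dist)
            rows.append({"metabolite": metabolite, "session": session,
                         "stratum": label})
    summaries = [bootmi.summarize(d, term=f"{r['session']} ({r['stratum']})")
                 for d, r in zip(dists, rows)]
    flags = bootmi.fdr_adjust([s.p for s in summaries], q=cfg.fdr_q)
    out = summaries_table(summaries)
    out["fdr_significant"] = flags
    meta = pd.DataFrame(rows)
    return pd.concat([meta.reset_index(drop=True),
                      out.drop(columns="term").reset_index(drop=True)], axis=1)


def voxelwise(
    metabolite_values,
    stack: voxel.VoxelStack,
    cfg: RunConfig,
    rng: np.random.Generator,
    hoc=None,
    control_mean_map=None,
    soft_impute_lambda: float | None = None,
) -> dict:
    """Voxelwise correlation analysis of one parameter at one session.

    Missing entries in the stack are completed with SOFT-IMPUTE before any
    correlation analysis (penalty chosen by holdout unless given).  The
    Spearman map is thresholded with bootstrap p-values at ``cfg.voxel_p``
    and cluster-extent corrected at ``cfg.cluster_alpha`` using the
    Monte-Carlo null calibrated to the smoothness of the residualized
    subject maps.  If ``hoc`` is given, regional correlation summaries
    (with HOC-partial correlations) are added; if ``control_mean_map`` is
    given, the connectivity-gradient statistic is added.
    """
    x = np.asarray(metabolite_values, dtype=float)
    if x.size != stack.n_subjects:
        raise DataError("metabolite values and stack subjects differ in length")
    keep = np.isfinite(x)
    if not keep.all():
        log.warning("dropping %d subjects with missing metabolite value",
                    int((~keep).sum()))
        x = x[keep]
        stack = voxel.VoxelStack(data=stack.data[keep], mask=stack.mask,
                                 voxel_size=stack.voxel_size, origin=stack.origin)
        if hoc is not None:
            hoc = np.asarray(hoc, dtype=float)[keep]
    if x.size < 4:
        raise DataError("need >= 4 subjects with metabolite values")
    data = stack.data
    if np.any(~np.isfinite(data)):
        lam = soft_impute_lambda
        if lam is None:
            lam = voxel.choose_lambda(data, rng)
        data, si_fit = voxel.soft_impute(data, lam)
        log.info("SOFT-IMPUTE: lambda=%.3g rank=%d converged=%s",
                 lam, si_fit.rank, si_fit.converged)
        stack = voxel.VoxelStack(data=data, mask=stack.mask,
                                 voxel_size=stack.voxel_size, origin=stack.origin)

    rho_map = voxel.spearman_map(x, stack)
    p_map = voxel.bootstrap_p_map(x, stack, cfg.B, rng)

    # smoothness proxy: subject maps residualized on the group mean
    resid = stack.data - stack.data.mean(axis=0, keepdims=True)
    vols = np.stack([stack.unflatten(r) for r in resid[: min(8, len(resid))]])
    vols = np.nan_to_num(vols)
    fwhm = voxel.estimate_fwhm(vols, stack.mask, stack.voxel_size)
    # the MC null is calibrated at the bootstrap test's *achieved* voxel
    # level, which exceeds the nominal one at these sample sizes
    p_eff = voxel.bootstrap_voxel_level(
        stack.n_subjects, cfg.B, cfg.voxel_p, rng
    )
    min_size = voxel.cluster_size_threshold(
        stack.mask, fwhm, voxel_p=p_eff, alpha=cfg.cluster_alpha,
        n_sims=cfg.cluster_n_sims, rng=rng, connectivity=cfg.connectivity,
        voxel_size=stack.voxel_size,
    )
    clusters = voxel.extract_clusters(
        rho_map, p_map, stack, voxel_p=cfg.voxel_p, min_size=min_size,
        connectivity=cfg.connectivity,
    )
    out = {
        "rho_map": rho_map,
        "p_map": p_map,
        "fwhm_mm": fwhm,
        "min_cluster_voxels": min_size,
        "clusters": clusters,
        "cluster_table": cluster_table(clusters),
        "stack": stack,
    }
    if hoc is not None and clusters:
        out["regional"] = voxel.regional_summary(
            x, stack, clusters, hoc, B=cfg.B, rng=rng
        )
    if control_mean_map is not None:
        rho, ci, p = voxel.connectivity_gradient(
            control_mean_map, x, stack, B=cfg.B, rng=rng
        )
        out["gradient"] = {"rho": rho, "ci": ci, "p": p}
    return out
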