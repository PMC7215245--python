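"""Synthetic longitudinal concussion cohort with informative attrition.

Generates data with the statistical structure the downstream analysis
assumes: 66 control athletes (one baseline scan each) and 33 concussed
athletes scanned at the acute phase (ACU, 1-7 days post-injury), medical
clearance (RTP), one month post-RTP (1MO) and one year post-RTP (1YR),
with per-session retention 27/25/25/13 of 33 and a dropout mechanism that
is rank-correlated with days to return-to-play.  Metabolite log-ratios are
drawn from the same random-intercept mixed model the analysis fits, so
estimator recovery can be checked against known truth.  Voxel maps are
smoothed Gaussian noise with clusters in which voxel values are blended
with the subjects' metabolite normal scores to hit a target Spearman
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from neurometab.lmm import DESIGN_COLUMNS, SESSIONS, build_design, prepare_covariates
from neurometab.voxel import VoxelStack, smooth_noise_field

RETENTION_DEFAULT = (27, 25, 25, 13)


@dataclass(frozen=True)
class CohortConfig:
    """Design of a simulated study cohort.

    ``drtp_median`` / ``drtp_q3`` parameterize a log-normal distribution of
    days to return-to-play (median 22 days, upper quartile ~95 days,
    truncated at 365), matching the heavy right tail of observed
    recovery times.  ``attrition_drtp_rho`` is the target rank correlation
    between dRTP and the per-session dropout indicator.
    """

    n_control: int = 66
    n_concussed: int = 33
    hoc_fraction_control: float = 31 / 66
    hoc_fraction_concussed: float = 19 / 33
    retention: tuple = RETENTION_DEFAULT
    drtp_median: float = 22.0
    drtp_q3: float = 95.0
    drtp_max: float = 365.0
    dacu_range: tuple = (1, 7)
    attrition_drtp_rho: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.hoc_fraction_control <= 1:
            raise ValueError("hoc_fraction_control must be in [0, 1]")
        if not 0 <= self.hoc_fraction_concussed <= 1:
            raise ValueError("hoc_fraction_concussed must be in [0, 1]")
        if len(self.retention) != len(SESSIONS):
            raise ValueError("retention needs one count per session")
        if any(r > self.n_concussed or r < 0 for r in self.retention):
            raise ValueError("retention counts must be within [0, n_concussed]")
        if self.drtp_median <= 0 or self.drtp_q3 <= self.drtp_median:
            raise ValueError("need 0 < drtp_median < drtp_q3")


@dataclass(frozen=True)
class GeneratorTruth:
    """Generating parameters for one metabolite log-ratio.

    ``beta`` follows :data:`~neurometab.lmm.DESIGN_COLUMNS` order.  The
    variance components ``sigma_b`` (between-subject) and ``sigma_e``
    (within-subject residual) are simulator assumptions in log-ratio
    units, not published quantities.
    """

    beta: tuple
    sigma_b: float = 0.10
    sigma_e: float = 0.15
    control_mean: float = 0.0
    control_hoc_shift: float = 0.0

    def __post_init__(self):
        if len(self.beta) != len(DESIGN_COLUMNS):
            raise ValueError(f"beta must have {len(DESIGN_COLUMNS)} entries")
        if self.sigma_b < 0 or self.sigma_e <= 0:
            raise ValueError("need sigma_b >= 0 and sigma_e > 0")


def default_ins_cr_truth(sigma_b: float = 0.10, sigma_e: float = 0.15) -> GeneratorTruth:
    """Reference effect sizes for the Ins/Cr log-ratio generator.

    Myo-inositol rises transiently at RTP (+0.230) and one month post-RTP
    (+0.276) and resolves by one year; the response is largely absent in
    athletes with a prior history of concussion (HOC interactions -0.278
    and -0.347 at those sessions).  Time-post-injury effects are near zero.
    """
    return GeneratorTruth(
        beta=(-0.50, 0.230, 0.276, 0.021,
              -0.031, -0.278, -0.347, -0.225,
              -0.034, -0.004, 0.005, -0.032),
        sigma_b=sigma_b,
        sigma_e=sigma_e,
        control_mean=-0.50,
        control_hoc_shift=0.086,
    )


def default_naa_cr_truth(sigma_b: float = 0.10, sigma_e: float = 0.15) -> GeneratorTruth:
    """Reference effect sizes for the NAA/Cr log-ratio generator: no
    significant longitudinal change, a weak acute days-post-injury slope."""
    return GeneratorTruth(
        beta=(0.30, 0.095, -0.101, -0.121,
              0.034, -0.034, 0.151, 0.265,
              0.061, -0.001, -0.082, -0.121),
        sigma_b=sigma_b,
        sigma_e=sigma_e,
        control_mean=0.30,
        control_hoc_shift=0.046,
    )


def null_truth(sigma_b: float = 0.10, sigma_e: float = 0.15,
               intercept: float = 0.0) -> GeneratorTruth:
    """Generator with every concussion effect set to zero (type-I studies)."""
    beta = (intercept,) + (0.0,) * (len(DESIGN_COLUMNS) - 1)
    return GeneratorTruth(beta=beta, sigma_b=sigma_b, sigma_e=sigma_e,
                          control_mean=intercept)


# ---------------------------------------------------------------------------
# attrition calibration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _attrition_weight(n: int, k: int, rho_target: float) -> float:
    """Latent-score weight giving dropout/dRTP rank correlation ~ rho_target.

    Dropout is assigned to the k largest values of ``w * z + eps`` where z
    is the standardized dRTP rank and eps is standard normal; w is chosen
    on a grid by Monte Carlo (fixed internal seed, so the map is a pure
    function of its arguments).
    """
    if rho_target == 0 or k == 0:
        return 0.0
    rng = np.random.default_rng(20200422)
    z = stats.zscore(np.arange(n, dtype=float))
    grid = np.concatenate([np.linspace(0.0, 3.0, 31), [4.0, 6.0, 10.0]])
    n_rep = 300
    eps = rng.standard_normal((n_rep, n))
    best_w, best_gap = 0.0, np.inf
    for w in grid:
        scores = w * z[None, :] + eps
        rhos = np.empty(n_rep)
        for r in range(n_rep):
            drop = np.zeros(n)
            drop[np.argsort(scores[r])[-k:]] = 1.0
            rhos[r] = stats.spearmanr(z, drop).statistic
        gap = abs(np.mean(rhos) - rho_target)
        if gap < best_gap:
            best_w, best_gap = w, gap
    return float(best_w)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate the cohort table: subjects, covariates and session grid.

    Returns a long DataFrame with one row per (subject, session): controls
    get a single ``BASE`` row, concussed athletes one row per ACU/RTP/1MO/
    1YR with an ``observed`` flag realizing the configured retention
    counts exactly.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    nc, nk = config.n_control, config.n_concussed

    def _hoc_vector(n, frac):
        k = int(round(frac * n))
        v = np.zeros(n, dtype=int)
        v[rng.choice(n, size=k, replace=False)] = 1
        return v

    hoc_ctl = _hoc_vector(nc, config.hoc_fraction_control)
    hoc_con = _hoc_vector(nk, config.hoc_fraction_concussed)

    # static covariates (ages/sex/collision rates mirror a varsity cohort)
    age_ctl = np.round(rng.normal(20.5, 1.7, size=nc).clip(17, 28), 1)
    age_con = np.round(rng.normal(20.3, 2.0, size=nk).clip(17, 28), 1)
    sex_ctl = rng.random(nc) < 36 / 66
    sex_con = rng.random(nk) < 17 / 33
    coll_ctl = rng.random(nc) < 20 / 66
    coll_con = rng.random(nk) < 22 / 33

    # days to RTP: log-normal solved from median and upper quartile
    mu = np.log(config.drtp_median)
    sigma = np.log(config.drtp_q3 / config.drtp_median) / stats.norm.ppf(0.75)
    drtp = np.exp(rng.normal(mu, sigma, size=nk))
    while np.any(drtp > config.drtp_max):
        bad = drtp > config.drtp_max
        drtp[bad] = np.exp(rng.normal(mu, sigma, size=int(bad.sum())))
    # kept continuous: with this heavy a right tail, rounding to whole days
    # piles ties onto the short-recovery end and breaks rank transforms
    dacu = rng.integers(config.dacu_range[0], config.dacu_range[1] + 1, size=nk)

    # per-session dropout: top-k latent scores, weight calibrated to the
    # target rank correlation with dRTP
    rank_z = stats.zscore(stats.rankdata(drtp))
    observed = np.ones((nk, len(SESSIONS)), dtype=bool)
    for j, r_keep in enumerate(config.retention):
        k = nk - r_keep
        if k == 0:
            continue
        w = _attrition_weight(nk, k, float(config.attrition_drtp_rho))
        score = w * rank_z + rng.standard_normal(nk)
        observed[np.argsort(score)[-k:], j] = False

    for i in range(nc):
        rows.append(dict(
            subject_id=f"CTL{i:03d}", group="control", hoc=int(hoc_ctl[i]),
            sex="F" if sex_ctl[i] else "M", age=age_ctl[i],
            collision=int(coll_ctl[i]), session="BASE",
            dacu=np.nan, drtp=np.nan, observed=True,
        ))
    for i in range(nk):
        for j, s in enumerate(SESSIONS):
            rows.append(dict(
                subject_id=f"CON{i:03d}", group="concussed", hoc=int(hoc_con[i]),
                sex="F" if sex_con[i] else "M", age=age_con[i],
                collision=int(coll_con[i]), session=s,
                dacu=float(dacu[i]), drtp=float(drtp[i]),
                observed=bool(observed[i, j]),
            ))
    return pd.DataFrame(rows)


def generate_metabolites(
    cohort: pd.DataFrame,
    truth: GeneratorTruth,
    rng: np.random.Generator,
    name: str = "ins_cr",
) -> pd.DataFrame:
    """Draw one metabolite's log-ratios from the mixed model.

    Values are generated for *every* session row first (stored in
    ``{name}_complete``) and only then masked by the ``observed`` flag
    (column ``{name}``), so missingness never influences the outcome draw.
    Controls get ``control_mean + HOC * control_hoc_shift`` plus the same
    intercept and residual noise.
    """
    df = cohort.copy()
    conc = df["group"] == "concussed"
    mean = np.empty(len(df))

    if conc.any():
        conc_df = prepare_covariates(df.loc[conc])
        design = build_design(conc_df.assign(value=0.0))
        mean[conc.to_numpy()] = design.X @ np.asarray(truth.beta)
    ctl = ~conc
    mean[ctl.to_numpy()] = (
        truth.control_mean + df.loc[ctl, "hoc"].to_numpy() * truth.control_hoc_shift
    )

    ids, codes = np.unique(df["subject_id"].to_numpy(), return_inverse=True)
    b = rng.normal(0.0, truth.sigma_b, size=ids.size)
    e = rng.normal(0.0, truth.sigma_e, size=len(df))
    complete = mean + b[codes] + e
    df[f"{name}_complete"] = complete
    df[name] = np.where(df["observed"].to_numpy(), complete, np.nan)
    return df


def add_cho_variants(
    cohort: pd.DataFrame,
    rng: np.random.Generator,
    noise_sd: float = 0.05,
    pairs=(("naa_cr", "naa_cho"), ("ins_cr", "ins_cho")),
) -> pd.DataFrame:
    """Choline-referenced ratios as Cr-referenced plus small correlated noise
    (the two reference peaks track each other closely in practice)."""
    df = cohort.copy()
    for src, dst in pairs:
        jitter = rng.normal(0.0, noise_sd, size=len(df))
        df[f"{dst}_complete"] = df[f"{src}_complete"] + jitter
        df[dst] = np.where(df["observed"], df[f"{dst}_complete"], np.nan)
    return df


def simulate_study(
    config: CohortConfig,
    ins_truth: GeneratorTruth | None = None,
    naa_truth: GeneratorTruth | None = None,
    cho_variants: bool = True,
) -> pd.DataFrame:
    """Full tabular study: cohort plus all four metabolite columns."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2020]))
    df = generate_cohort(config)
    df = generate_metabolites(df, naa_truth or default_naa_cr_truth(), rng, "naa_cr")
    df = generate_metabolites(df, ins_truth or default_ins_cr_truth(), rng, "ins_cr")
    if cho_variants:
        df = add_cho_variants(df, rng)
    return df


# ---------------------------------------------------------------------------
# voxel map simulation
# ---------------------------------------------------------------------------

@dataclass
class PlantedClusterSpec:
    """Geometry and effect sizes for simulated voxel maps.

    ``clusters`` is a list of ``(center_voxel, radius_voxels, target_rho)``
    tuples; inside each sphere, voxel values are a blend of the subjects'
    metabolite normal scores and smooth noise, with the blend weight solved
    so the expected Spearman correlation equals ``target_rho``.
    """

    grid_shape: tuple = (24, 24, 24)
    voxel_size: tuple = (3.0, 3.0, 3.0)
    mask: np.ndarray | None = None
    smoothing_fwhm: float = 6.0
    clusters: list = field(default_factory=list)

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.ones(self.grid_shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("empty mask")
        for _, _, rho in self.clusters:
            if not abs(rho) < 1:
                raise ValueError("|target rho| must be < 1")

    def cluster_mask(self) -> np.ndarray:
        """Boolean grid of all planted voxels (within the mask)."""
        out = np.zeros(self.grid_shape, dtype=bool)
        idx = np.indices(self.grid_shape)
        for center, radius, _ in self.clusters:
            d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
            out |= d2 <= radius**2
        return out & self.mask


def _blend_weight(target_rho: float) -> float:
    """Blend weight w with Spearman((w z + sqrt(1-w^2) eps), z) = target.

    For a bivariate normal pair with Pearson correlation w the population
    Spearman correlation is (6/pi) asin(w/2); solved by bisection.
    """
    if target_rho == 0:
        return 0.0

    def f(w):
        return 6.0 / np.pi * np.arcsin(w / 2.0) - abs(target_rho)

    w = optimize.brentq(f, 0.0, 1.0)
    return float(np.copysign(w, target_rho))


def generate_voxel_stack(
    metabolite,
    spec: PlantedClusterSpec,
    rng: np.random.Generator,
    rho_map: np.ndarray | None = None,
) -> VoxelStack:
    """Simulate per-subject maps with metabolite-correlated clusters.

    Background is white Gaussian noise smoothed to ``spec.smoothing_fwhm``
    and standardized across subjects per voxel.  Inside planted clusters
    (or wherever ``rho_map`` is nonzero) the value is
    ``w * z_i + sqrt(1 - w^2) * noise`` with ``z_i`` the subject's
    metabolite normal score.  Deterministic given the generator state.
    """
    x = np.asarray(metabolite, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 subjects")
    noise = np.stack([
        smooth_noise_field(spec.grid_shape, spec.smoothing_fwhm, spec.voxel_size, rng)
        for _ in range(n)
    ])
    mu = noise.mean(axis=0, keepdims=True)
    sd = noise.std(axis=0, keepdims=True)
    noise = (noise - mu) / np.where(sd > 0, sd, 1.0)

    ranks = stats.rankdata(x, method="average")
    z = stats.norm.ppf((ranks - 0.5) / n)
    z = (z - z.mean()) / z.std()

    w_vol = np.zeros(spec.grid_shape)
    if rho_map is not None:
        rho_arr = np.asarray(rho_map, dtype=float)
        vec = np.vectorize(_blend_weight)
        w_vol = np.where(rho_arr != 0, vec(np.clip(rho_arr, -0.999, 0.999)), 0.0)
    idx = np.indices(spec.grid_shape)
    for center, radius, rho in spec.clusters:
        d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
        w_vol[(d2 <= radius**2) & spec.mask] = _blend_weight(rho)

    w_flat = w_vol[spec.mask]
    data = (
        w_flat[None, :] * z[:, None]
        + np.sqrt(1.0 - w_flat**2)[None, :] * noise[:, spec.mask]
    )
    return VoxelStack(data=data, mask=spec.mask, voxel_size=spec.voxel_size)
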