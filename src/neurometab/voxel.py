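"""Voxelwise correlation mapping with cluster-extent correction.

Implements the imaging half of the pipeline: SOFT-IMPUTE completion of
missing subject maps, voxelwise (partial) Spearman correlation between a
subject-level metabolite value and FA/MD/Fconn maps, bootstrap p maps,
Gaussian-kernel smoothness estimation from neighbour differences, a
Monte-Carlo null for the minimum cluster-extent threshold, signed cluster
extraction, the connectivity-gradient statistic and regional correlation
summaries with HOC-partial correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass
class VoxelStack:
    """Per-subject maps of one MRI parameter on a common masked grid.

    ``data`` is (n_subjects, n_mask_voxels), flattened in C order over the
    mask.  ``origin`` maps voxel index 0 to mm coordinates (synthetic maps
    use their own space, not MNI).
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_size: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        n_vox = int(self.mask.sum())
        if n_vox == 0:
            raise ValueError("empty mask")
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != n_vox:
            raise ValueError("data columns must match mask voxel count")

    @property
    def grid_shape(self) -> tuple:
        return self.mask.shape

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def unflatten(self, values) -> np.ndarray:
        """Scatter a masked 1-D vector back onto the 3-D grid (NaN outside)."""
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = values
        return vol


@dataclass
class SoftImputeFit:
    lambda_: float
    singular_values: np.ndarray
    rank: int
    converged: bool
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass(frozen=True)
class ClusterReport:
    """One suprathreshold cluster of the correlation map."""

    cluster_id: int
    center_of_mass_mm: tuple
    size_mm3: float
    n_voxels: int
    peak_rho: float
    member_voxels: np.ndarray  # (k, 3) integer grid indices


# ---------------------------------------------------------------------------
# SOFT-IMPUTE matrix completion
# ---------------------------------------------------------------------------

def _nuclear_objective(X, obs, mu, M, lam, nuc):
    resid = np.where(obs, X - mu - M, 0.0)
    return 0.5 * float(np.sum(resid**2)) + lam * float(nuc)


def soft_impute(X, lam: float, tol: float = 1e-7, max_iter: int = 2000):
    """Nuclear-norm regularized matrix completion by soft-thresholded SVD.

    Fits ``X ~ mu + M`` on the observed entries, where ``mu`` is a row of
    column means (re-estimated from the observed residuals each sweep, an
    exact coordinate-descent step) and ``M`` is penalized by ``lam`` times
    its nuclear norm.  Each sweep fills missing entries with the current
    estimate, takes an SVD and soft-thresholds the singular values; both
    steps decrease the objective, so the trace is monotone.  Iteration
    stops when the relative objective change falls below ``tol``.
    Observed entries are passed through unchanged in the returned matrix
    (impute-only contract).

    Returns ``(completed, SoftImputeFit)``.
    """
    X = np.asarray(X, dtype=float)
    obs = np.isfinite(X)
    if np.any(~obs.any(axis=0)) or np.any(~obs.any(axis=1)):
        raise ValueError("every row and column needs >= 1 observed entry")
    M = np.zeros_like(X)
    mu = np.zeros(X.shape[1])
    trace = []
    prev = np.inf
    converged = False
    s = np.zeros(min(X.shape))
    for _ in range(max_iter):
        mu = np.nanmean(np.where(obs, X - M, np.nan), axis=0)
        filled = np.where(obs, X - mu, M)
        U, s_full, Vt = np.linalg.svd(filled, full_matrices=False)
        s = np.maximum(s_full - lam, 0.0)
        M = (U * s) @ Vt
        obj = _nuclear_objective(X, obs, mu, M, lam, s.sum())
        trace.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(abs(prev), 1.0):
            converged = True
            break
        prev = obj
    completed = np.where(obs, X, M + mu)
    fit = SoftImputeFit(
        lambda_=float(lam),
        singular_values=s[s > 0],
        rank=int(np.sum(s > 0)),
        converged=converged,
        objective_trace=np.asarray(trace),
    )
    return completed, fit


def choose_lambda(
    X,
    rng: np.random.Generator,
    validation_fraction: float = 0.1,
    n_lambdas: int = 10,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> float:
    """Pick the SOFT-IMPUTE penalty by held-out reconstruction error.

    A random fraction of the observed entries is masked out, a geometric
    lambda path is walked from ``lambda_max`` (the largest singular value
    of the zero-filled centered matrix) downward, and the lambda minimizing
    squared error on the held-out entries is returned.
    """
    X = np.asarray(X, dtype=float)
    obs = np.argwhere(np.isfinite(X))
    n_hold = max(1, int(round(validation_fraction * len(obs))))
    hold = obs[rng.choice(len(obs), size=n_hold, replace=False)]
    X_train = X.copy()
    X_train[hold[:, 0], hold[:, 1]] = np.nan
    if np.any(~np.isfinite(X_train).any(axis=0)) or np.any(
        ~np.isfinite(X_train).any(axis=1)
    ):
        raise ValueError("holdout emptied a row or column; lower the fraction")
    col_mean = np.nanmean(X_train, axis=0)
    lam_max = np.linalg.svd(
        np.where(np.isfinite(X_train), X_train - col_mean, 0.0), compute_uv=False
    )[0]
    lams = np.geomspace(lam_max, lam_max / 100.0, n_lambdas)
    best_lam, best_err = lams[0], np.inf
    for lam in lams:
        completed, _ = soft_impute(X_train, lam, tol=tol, max_iter=max_iter)
        err = float(
            np.mean((completed[hold[:, 0], hold[:, 1]] - X[hold[:, 0], hold[:, 1]]) ** 2)
        )
        if err < best_err:
            best_lam, best_err = lam, err
    return float(best_lam)


# ---------------------------------------------------------------------------
# Spearman correlation maps
# ---------------------------------------------------------------------------

def _rank_rows(a: np.ndarray) -> np.ndarray:
    """Column-wise average ranks of a (n, V) array (subjects down columns)."""
    return stats.rankdata(a, axis=0, method="average")


def spearman_map(metabolite, stack: VoxelStack) -> np.ndarray:
    """Voxelwise Spearman correlation of a subject covariate with maps.

    Returns one rho per masked voxel; voxels with zero rank variance are
    returned as NaN (they carry no ordering information).
    """
    x = np.asarray(metabolite, dtype=float)
    if x.size != stack.n_subjects:
        raise ValueError("one metabolite value per subject required")
    if x.size < 4:
        raise ValueError("need >= 4 subjects")
    return _spearman_columns(x, stack.data)


def _spearman_columns(x: np.ndarray, data: np.ndarray) -> np.ndarray:
    rx = stats.rankdata(x, method="average")
    rx = rx - rx.mean()
    sx = np.sqrt(np.sum(rx**2))
    ry = _rank_rows(data)
    ry = ry - ry.mean(axis=0)
    sy = np.sqrt(np.sum(ry**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / (sx * sy)
    rho[sy == 0] = np.nan
    if sx == 0:
        rho[:] = np.nan
    return rho


def partial_spearman(x, y, covariate) -> float:
    """Spearman partial correlation of x and y adjusting for a covariate.

    All three variables are ranked; x-ranks and y-ranks are residualized
    on the covariate ranks (with intercept) by least squares and the
    Pearson correlation of the residuals returned.
    """
    x = stats.rankdata(np.asarray(x, dtype=float))
    y = stats.rankdata(np.asarray(y, dtype=float))
    c = np.asarray(covariate, dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 subjects")
    if np.all(c == c[0]):
        raise ValueError("constant covariate")
    c = stats.rankdata(c)
    Z = np.column_stack([np.ones_like(c), c])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    # a variable fully explained by the covariate has only numerical-noise
    # residuals; its partial correlation is zero by convention
    for r, v in ((rx, x), (ry, y)):
        if np.sum(r**2) <= 1e-12 * np.sum((v - v.mean()) ** 2):
            return 0.0
    return float(rx @ ry / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def _spearman_resample(x, counts, order_t) -> np.ndarray:
    """Spearman map of a bootstrap resample given row multiplicities.

    Equivalent to resampling the subjects and ranking with average ranks,
    but computed as a count-weighted Pearson correlation of resample
    ranks: a subject drawn c times occupies c consecutive sorted
    positions, so its average rank is (count of smaller values) +
    (c + 1) / 2.  ``order_t`` is the (V, n) per-voxel argsort of the
    original tie-free voxel data.  No per-replicate ranking of the full
    matrix is needed.
    """
    n = int(counts.sum())
    # x may contain ties (e.g. winsorized values): rank the expanded
    # resample explicitly, then read one average rank per original row
    expanded = np.repeat(np.arange(x.size), counts)
    r_exp = stats.rankdata(x[expanded], method="average")
    rx = np.zeros(x.size)
    np.maximum.at(rx, expanded, r_exp)

    C = counts[order_t].astype(float)  # (V, n), contiguous per voxel
    r_sorted = np.cumsum(C, axis=1) - C + (C + 1.0) / 2.0
    ry = np.empty_like(r_sorted)
    np.put_along_axis(ry, order_t, r_sorted, axis=1)

    w = counts.astype(float)
    mx = float(w @ rx) / n
    my = (ry @ w) / n
    ax = w * (rx - mx)
    num = ry @ ax  # sum_i w_i (rx_i - mx) ry_vi ; the my term cancels
    var_x = float(ax @ (rx - mx))
    var_y = (ry**2) @ w - n * my**2
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / np.sqrt(var_x * var_y)
    rho[var_y <= 1e-12] = np.nan
    if var_x <= 1e-12:
        rho[:] = np.nan
    return rho


def bootstrap_p_map(
    metabolite, stack: VoxelStack, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Voxelwise two-sided empirical p map from a subject bootstrap.

    Subjects are resampled with replacement B times and the Spearman map
    recomputed; the p-value at each voxel is the two-sided tail mass of
    the bootstrap rho distribution about zero, floored at ``1/(B+1)``.
    Degenerate (all-tied) voxels within a replicate are skipped for that
    replicate.
    """
    x = np.asarray(metabolite, dtype=float)
    n = x.size
    V = stack.data.shape[1]
    order_t = np.argsort(stack.data.T, axis=1, kind="stable")
    n_le = np.zeros(V)
    n_ge = np.zeros(V)
    n_ok = np.zeros(V)
    for _ in range(B):
        counts = np.bincount(rng.integers(0, n, size=n), minlength=n)
        rho = _spearman_resample(x, counts, order_t)
        ok = np.isfinite(rho)
        n_le[ok] += rho[ok] <= 0
        n_ge[ok] += rho[ok] >= 0
        n_ok[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * np.minimum(n_le, n_ge) / n_ok
    p = np.where(n_ok > 0, np.clip(p, 1.0 / (B + 1), 1.0), np.nan)
    return p


# ---------------------------------------------------------------------------
# Smoothness estimation and cluster-extent thresholding
# ---------------------------------------------------------------------------

def bootstrap_voxel_level(
    n_subjects: int,
    B: int,
    voxel_p: float,
    rng: np.random.Generator,
    n_voxels: int = 2000,
    n_batches: int = 4,
) -> float:
    """Actual null exceedance rate of the bootstrap voxel test.

    The empirical bootstrap p-value is discrete and, at small n, somewhat
    anti-conservative: the probability that a truly null voxel attains
    ``p < voxel_p`` exceeds ``voxel_p`` itself.  This simulates batches of
    independent null voxels sharing one covariate draw (as in a real map)
    and returns the observed rate, which is the correct per-voxel level at
    which to calibrate the cluster-extent Monte-Carlo null.
    """
    hits = 0
    total = 0
    for _ in range(n_batches):
        x = rng.standard_normal(n_subjects)
        data = rng.standard_normal((n_subjects, n_voxels))
        order_t = np.argsort(data.T, axis=1, kind="stable")
        n_le = np.zeros(n_voxels)
        n_ge = np.zeros(n_voxels)
        for _ in range(B):
            counts = np.bincount(
                rng.integers(0, n_subjects, size=n_subjects), minlength=n_subjects
            )
            rho = _spearman_resample(x, counts, order_t)
            n_le += rho <= 0
            n_ge += rho >= 0
        p = np.clip(2.0 * np.minimum(n_le, n_ge) / B, 1.0 / (B + 1), 1.0)
        hits += int(np.sum(p < voxel_p))
        total += n_voxels
    return max(hits / total, voxel_p)


def estimate_fwhm(maps, mask, voxel_size) -> np.ndarray:
    """Estimate per-axis Gaussian smoothing FWHM (mm) from neighbour diffs.

    For white noise convolved with a Gaussian kernel of width FWHM, the
    lag-1 field autocorrelation along an axis with spacing ``d`` is
    ``r = 1 - var(diff) / (2 var)`` and the kernel width follows as
    ``d * sqrt(-2 ln 2 / ln r)``.  Estimates are averaged over maps.  An
    axis where ``r <= 0`` (rougher than any Gaussian-smoothed field) is
    reported as 0.0, a below-voxel sentinel.
    """
    mask = np.asarray(mask, dtype=bool)
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 3:
        maps = maps[None]
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    fwhm = np.zeros((maps.shape[0], 3))
    for m, vol in enumerate(maps):
        v = float(np.var(vol[mask]))
        for ax in range(3):
            shifted = np.roll(mask, -1, axis=ax)
            # drop wrap-around plane
            valid = mask & shifted
            idx = [slice(None)] * 3
            idx[ax] = slice(0, mask.shape[ax] - 1)
            valid = valid[tuple(idx)]
            d = (np.roll(vol, -1, axis=ax) - vol)[tuple(idx)][valid]
            if d.size < 2 or v == 0:
                fwhm[m, ax] = 0.0
                continue
            r = 1.0 - float(np.var(d)) / (2.0 * v)
            if r <= 0:
                fwhm[m, ax] = 0.0
            else:
                fwhm[m, ax] = voxel_size[ax] * np.sqrt(-2.0 * np.log(2.0) / np.log(r))
    return fwhm.mean(axis=0)


def smooth_noise_field(shape, fwhm_mm, voxel_size, rng: np.random.Generator):
    """White Gaussian noise smoothed to a target kernel FWHM (mm)."""
    field_ = rng.standard_normal(shape)
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    fwhm_mm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    sigma_vox = np.where(fwhm_mm > 0, fwhm_mm / (_FWHM_PER_SIGMA * voxel_size), 0.0)
    if np.any(sigma_vox > 0):
        field_ = ndimage.gaussian_filter(field_, sigma=sigma_vox, mode="constant")
    return field_


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def cluster_size_threshold(
    mask,
    fwhm_mm,
    voxel_p: float = 0.005,
    alpha: float = 0.05,
    n_sims: int = 1000,
    rng: np.random.Generator | None = None,
    connectivity: int = 6,
    voxel_size=(3.0, 3.0, 3.0),
) -> int:
    """Monte-Carlo minimum cluster extent controlling familywise error.

    Null Gaussian fields smoothed to the estimated FWHM are thresholded
    two-sided at ``voxel_p``, same-sign clusters labelled, and the maximum
    cluster size recorded per field.  Returns the smallest size (voxels)
    whose null exceedance probability is <= alpha.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 10:
        raise ValueError("mask too small for cluster simulation")
    rng = rng or np.random.default_rng()
    zcrit = stats.norm.ppf(1.0 - voxel_p / 2.0)
    struct = _connectivity_structure(connectivity)
    maxima = np.empty(n_sims, dtype=int)
    for i in range(n_sims):
        f = smooth_noise_field(mask.shape, fwhm_mm, voxel_size, rng)
        vals = f[mask]
        z = (f - vals.mean()) / vals.std()
        biggest = 0
        for signed in (z > zcrit, z < -zcrit):
            lab, nlab = ndimage.label(signed & mask, structure=struct)
            if nlab:
                biggest = max(biggest, int(np.bincount(lab.ravel())[1:].max()))
        maxima[i] = biggest
    # smallest k with P(max >= k) <= alpha
    k = 1
    while np.mean(maxima >= k) > alpha:
        k += 1
    return int(k)


def extract_clusters(
    rho_map,
    p_map,
    stack: VoxelStack,
    voxel_p: float = 0.005,
    min_size: int = 1,
    connectivity: int = 6,
) -> list[ClusterReport]:
    """Signed suprathreshold clusters of a correlation map.

    Voxels with ``p < voxel_p`` are split by the sign of rho *before*
    connected-component labelling, so abutting clusters of opposite sign
    are never merged.  Components smaller than ``min_size`` voxels are
    discarded.  Centers of mass are |rho|-weighted, in mm.
    """
    rho_vol = stack.unflatten(np.asarray(rho_map, dtype=float))
    p_vol = stack.unflatten(np.asarray(p_map, dtype=float))
    with np.errstate(invalid="ignore"):
        sig = (p_vol < voxel_p) & np.isfinite(rho_vol)
    struct = _connectivity_structure(connectivity)
    voxel_size = np.broadcast_to(np.asarray(stack.voxel_size, dtype=float), (3,))
    origin = np.asarray(stack.origin, dtype=float)
    vol_mm3 = float(np.prod(voxel_size))
    reports = []
    cid = 0
    for signed in (sig & (rho_vol > 0), sig & (rho_vol < 0)):
        lab, nlab = ndimage.label(signed, structure=struct)
        for li in range(1, nlab + 1):
            members = np.argwhere(lab == li)
            if len(members) < min_size:
                continue
            vals = rho_vol[tuple(members.T)]
            w = np.abs(vals)
            com_vox = (members * w[:, None]).sum(axis=0) / w.sum()
            peak = vals[np.argmax(np.abs(vals))]
            cid += 1
            reports.append(
                ClusterReport(
                    cluster_id=cid,
                    center_of_mass_mm=tuple(com_vox * voxel_size + origin),
                    size_mm3=len(members) * vol_mm3,
                    n_voxels=len(members),
                    peak_rho=float(peak),
                    member_voxels=members,
                )
            )
    reports.sort(key=lambda r: -r.size_mm3)
    return [
        ClusterReport(i + 1, r.center_of_mass_mm, r.size_mm3, r.n_voxels,
                      r.peak_rho, r.member_voxels)
        for i, r in enumerate(reports)
    ]


# ---------------------------------------------------------------------------
# Connectivity gradient and regional summaries
# ---------------------------------------------------------------------------

def connectivity_gradient(
    control_mean_map,
    metabolite,
    stack: VoxelStack,
    B: int = 1000,
    rng: np.random.Generator | None = None,
):
    """Spearman correlation of regional connectivity strength with the
    metabolite-Fconn correlation map.

    At each voxel the control group's mean connectivity and the concussed
    group's metabolite-Fconn Spearman rho are paired; the statistic is the
    Spearman correlation across voxels.  Bootstrapping the concussed
    subjects (recomputing the rho map each replicate) yields the 95% CI
    and a two-sided empirical p.  Returns ``(rho, (lo, hi), p)``.
    """
    rng = rng or np.random.default_rng()
    ctl = np.asarray(control_mean_map, dtype=float)
    if np.all(ctl == ctl[0]):
        raise ValueError("constant control map")
    x = np.asarray(metabolite, dtype=float)
    rho_map = spearman_map(x, stack)
    ok = np.isfinite(rho_map)
    rho = float(stats.spearmanr(ctl[ok], rho_map[ok]).statistic)
    order_t = np.argsort(stack.data.T, axis=1, kind="stable")
    boots = np.empty(B)
    for b in range(B):
        counts = np.bincount(rng.integers(0, x.size, size=x.size), minlength=x.size)
        rm = _spearman_resample(x, counts, order_t)
        okb = np.isfinite(rm)
        boots[b] = stats.spearmanr(ctl[okb], rm[okb]).statistic
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p = 2.0 * min(np.mean(boots <= 0), np.mean(boots >= 0))
    p = float(min(max(p, 1.0 / (len(boots) + 1)), 1.0))
    return rho, (float(lo), float(hi)), p


def regional_summary(
    metabolite,
    stack: VoxelStack,
    clusters: list[ClusterReport],
    hoc,
    B: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Correlation statistics over the average of significant voxels.

    The MRI parameter is averaged over all cluster member voxels per
    subject; reported are the Spearman correlation with the metabolite,
    the HOC-partial Spearman correlation, and the change in absolute
    correlation strength ``|pcorr| - |corr|`` with a bootstrap 95% CI and
    a one-sided empirical p for a reduction.  Returns an empty dict when
    no clusters were supplied.
    """
    if not clusters:
        return {}
    rng = rng or np.random.default_rng()
    flat_idx = np.zeros(stack.mask.sum(), dtype=bool)
    lut = stack.unflatten(np.arange(stack.mask.sum(), dtype=float))
    for c in clusters:
        ids = lut[tuple(c.member_voxels.T)]
        flat_idx[ids[np.isfinite(ids)].astype(int)] = True
    region = stack.data[:, flat_idx].mean(axis=1)
    x = np.asarray(metabolite, dtype=float)
    hoc = np.asarray(hoc, dtype=float)
    corr = float(stats.spearmanr(x, region).statistic)
    pcorr = partial_spearman(x, region, hoc)
    change = abs(pcorr) - abs(corr)
    boots = np.empty(B)
    n = x.size
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        if np.all(hoc[idx] == hoc[idx][0]):
            boots[b] = np.nan
            continue
        cb = stats.spearmanr(x[idx], region[idx]).statistic
        pb = partial_spearman(x[idx], region[idx], hoc[idx])
        boots[b] = abs(pb) - abs(cb)
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p_red = float(max(np.mean(boots >= 0), 1.0 / (len(boots) + 1)))
    pct = 100.0 * change / abs(corr) if corr != 0 else np.nan
    return {
        "corr": corr,
        "pcorr": pcorr,
        "change": float(change),
        "change_ci": (float(lo), float(hi)),
        "p_reduction": p_red,
        "percent_reduction": float(pct),
        "n_voxels": int(flat_idx.sum()),
    }
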