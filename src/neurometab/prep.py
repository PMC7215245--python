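"""Metabolite log-ratio preparation and covariate transforms.

Raw spectroscopy output is a pair of concentration ratios (left and right
motor cortex) per metabolite.  The analysis variable is the mean of the two
log-ratios, winsorized across the pooled sample to tame heavy tails, with
sample moments reported before and after.  Skewed covariates (days to
return-to-play) are mapped to normal scores before mean-centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MomentReport:
    """Sample skewness and non-excess kurtosis (Normal = 3).

    Both moments use the maximum-likelihood (biased) estimators
    ``m3 / m2**1.5`` and ``m4 / m2**2``.
    """

    skewness: float
    kurtosis: float


def log_ratio_average(left_ratio, right_ratio):
    """Average log-transformed ratios across left and right hemispheres.

    Parameters
    ----------
    left_ratio, right_ratio : array_like
        Positive concentration ratios.  NaN marks a missing side; if one
        side is missing the other is used alone.

    Returns
    -------
    ndarray or float
        ``mean(log(left), log(right))`` elementwise.
    """
    left = np.asarray(left_ratio, dtype=float)
    right = np.asarray(right_ratio, dtype=float)
    if np.any(left[np.isfinite(left)] <= 0) or np.any(right[np.isfinite(right)] <= 0):
        raise ValueError("concentration ratios must be strictly positive")
    with np.errstate(invalid="ignore"):
        ll = np.log(left)
        lr = np.log(right)
    out = np.nanmean(np.stack([ll, lr]), axis=0)
    if out.ndim == 0:
        return float(out)
    return out


def winsorize(values, total_tail_mass: float = 0.05):
    """Clip the extreme tails of a sample to fixed empirical percentiles.

    With the default 5% total tail mass, values below the 2.5th percentile
    are set to that percentile and values above the 97.5th percentile to
    that percentile (a two-tailed 95% window).  Percentiles are order
    statistics (nearest rank, rounding outward), which makes the clip
    bounds members of the sample and the operation exactly idempotent —
    interpolated percentiles are not, because clipping shifts them inward.
    NaNs pass through unchanged.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ValueError("winsorize needs at least two finite values")
    if not 0 <= total_tail_mass < 1:
        raise ValueError("total_tail_mass must be in [0, 1)")
    lo_q = 100 * total_tail_mass / 2
    lo = np.percentile(finite, lo_q, method="lower")
    hi = np.percentile(finite, 100 - lo_q, method="higher")
    return np.clip(x, lo, hi)


def moments(values) -> MomentReport:
    """Sample skewness and non-excess kurtosis of the finite entries."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("moments needs at least three values")
    if np.var(x) == 0:
        raise ValueError("moments undefined for zero-variance sample")
    skew = float(stats.skew(x, bias=True))
    kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    return MomentReport(skewness=skew, kurtosis=kurt)


def rank_inverse_normal(values):
    """Rank-based inverse-normal transform, mean-centered.

    Each value is replaced by ``Phi^-1((rank - 0.5) / n)`` with average
    ranks for ties, then the mean is subtracted so the output is centered.
    The result depends on the input only through its ranks, so it is
    invariant to any strictly monotone transform.  NaNs are ignored in the
    ranking and preserved in the output.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = np.isfinite(x)
    xo = x[obs]
    if xo.size < 2 or np.all(xo == xo[0]):
        raise ValueError("rank_inverse_normal needs >= 2 distinct values")
    ranks = stats.rankdata(xo, method="average")
    z = stats.norm.ppf((ranks - 0.5) / xo.size)
    out[obs] = z - z.mean()
    if np.isscalar(values):
        return float(out)
    return out


def center(values, reference: float):
    """Subtract a fixed reference (e.g. days post-injury minus 5)."""
    if not np.isfinite(reference):
        raise ValueError("reference must be finite")
    return np.asarray(values, dtype=float) - reference


def normative_logratio_ci(component_cvs, correlation: float = 0.0) -> float:
    """Propagation-of-error half-width of a 95% CI for a log-ratio.

    For a ratio of two measured components with coefficients of variation
    ``cv1, cv2`` (log-scale SDs approximated by the CVs) and correlation
    ``corr`` between them, the log-ratio SD is
    ``sqrt(cv1**2 + cv2**2 - 2*corr*cv1*cv2)`` and the normative half-width
    is 1.96 times that.  With a single component the correlation term is
    absent.
    """
    cvs = np.atleast_1d(np.asarray(component_cvs, dtype=float))
    if np.any(cvs < 0):
        raise ValueError("coefficients of variation must be >= 0")
    var = float(np.sum(cvs**2))
    if cvs.size == 2:
        var -= 2.0 * correlation * cvs[0] * cvs[1]
    if var < 0:
        raise ValueError("propagated variance is negative")
    return 1.96 * np.sqrt(var)
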