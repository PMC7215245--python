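"""Random-intercept linear mixed model for longitudinal metabolite data.

The model for concussed athlete *i* at session *t* is

    y_it = x_it' beta + b_i + e_it,   b_i ~ N(0, sigma_b^2),
                                      e_it ~ N(0, sigma_e^2)

with fixed effects of imaging session (RTP, 1MO, 1YR) relative to the
acute scan (ACU), interactions of each session with history of concussion
(HOC), days post-injury at the acute scan (dACU, centered at 5 days) and
days to return-to-play (dRTP, rank-inverse-normal transformed then
centered).  Fitting is maximum likelihood: beta and sigma_e are profiled
out analytically, leaving a one-dimensional optimization over the variance
ratio theta = sigma_b^2 / sigma_e^2 solved by bounded Brent search.

Controls are never fitted with this model; they enter only cross-sectional
contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from neurometab.prep import center, rank_inverse_normal

SESSIONS = ("ACU", "RTP", "1MO", "1YR")
DACU_REFERENCE_DAYS = 5.0

#: Fixed-effect column order.  The intercept doubles as the ACU reference.
DESIGN_COLUMNS = (
    "ACU",
    "RTP",
    "1MO",
    "1YR",
    "ACU:HOC",
    "RTP:HOC",
    "1MO:HOC",
    "1YR:HOC",
    "ACU:dACU",
    "RTP:dRTP",
    "1MO:dRTP",
    "1YR:dRTP",
)

_THETA_MAX = 1e4


@dataclass
class LongDesign:
    """Long-format design for the random-intercept model.

    ``X`` has one row per (subject, session) with the 12 columns of
    :data:`DESIGN_COLUMNS`; ``groups`` are dense subject codes; ``y`` may
    contain NaN for unobserved sessions (rows kept so imputation can fill
    them).
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    subject_ids: np.ndarray
    columns: tuple = DESIGN_COLUMNS

    @property
    def observed(self) -> np.ndarray:
        return np.isfinite(self.y)

    def n_subjects(self) -> int:
        return int(self.groups.max()) + 1 if self.groups.size else 0


@dataclass
class LMMFit:
    """ML estimates for the random-intercept model."""

    beta: np.ndarray
    sigma_b: float
    sigma_e: float
    loglik: float
    converged: bool
    columns: tuple = DESIGN_COLUMNS
    theta: float = 0.0
    dropped: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "beta": {c: float(b) for c, b in zip(self.columns, self.beta)},
            "sigma_b": float(self.sigma_b),
            "sigma_e": float(self.sigma_e),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "dropped": list(self.dropped),
        }


def prepare_covariates(cohort, drtp_col: str = "drtp", dacu_col: str = "dacu"):
    """Add transformed model covariates to a concussed cohort table.

    Returns a copy with ``dacu_c`` (days post-injury centered at 5) and
    ``drtp_t`` (rank-inverse-normal transform of days-to-RTP over the
    distinct subjects, mean-centered).
    """
    df = cohort.copy()
    df["dacu_c"] = center(df[dacu_col].to_numpy(dtype=float), DACU_REFERENCE_DAYS)
    per_subject = df.drop_duplicates("subject_id").set_index("subject_id")[drtp_col]
    transformed = rank_inverse_normal(per_subject.to_numpy(dtype=float))
    lookup = dict(zip(per_subject.index, transformed))
    df["drtp_t"] = df["subject_id"].map(lookup)
    return df


def build_design(observations, response: str = "value") -> LongDesign:
    """Build the 12-column design from a long concussed-session table.

    ``observations`` needs columns ``subject_id``, ``session`` (one of
    ACU/RTP/1MO/1YR), ``hoc`` (0/1), ``dacu_c``, ``drtp_t`` and the
    response column (NaN allowed for missing sessions).
    """
    sess = observations["session"].to_numpy()
    unknown = set(sess) - set(SESSIONS)
    if unknown:
        raise ValueError(f"unknown session label(s): {sorted(unknown)}")
    n = len(observations)
    X = np.zeros((n, len(DESIGN_COLUMNS)))
    hoc = observations["hoc"].to_numpy(dtype=float)
    dacu_c = observations["dacu_c"].to_numpy(dtype=float)
    drtp_t = observations["drtp_t"].to_numpy(dtype=float)
    X[:, 0] = 1.0
    for j, s in enumerate(SESSIONS):
        on = sess == s
        if j > 0:
            X[on, j] = 1.0
        X[on, 4 + j] = hoc[on]
        if s == "ACU":
            X[on, 8] = dacu_c[on]
        else:
            X[on, 8 + j] = drtp_t[on]
    ids, groups = np.unique(observations["subject_id"].to_numpy(), return_inverse=True)
    y = observations[response].to_numpy(dtype=float)
    return LongDesign(X=X, y=y, groups=groups.astype(np.int64), subject_ids=ids)


def _suff_stats(X, y, groups, n_groups):
    """Per-subject sums that make each profiled-likelihood evaluation O(G p^2)."""
    p = X.shape[1]
    Sx = np.zeros((n_groups, p))
    np.add.at(Sx, groups, X)
    Sy = np.bincount(groups, weights=y, minlength=n_groups)
    ni = np.bincount(groups, minlength=n_groups).astype(float)
    return X.T @ X, X.T @ y, float(y @ y), Sx, Sy, ni


def _profiled_nll(theta, XtX, Xty, yty, Sx, Sy, ni, N):
    c = theta / (1.0 + ni * theta)
    A = XtX - (Sx * c[:, None]).T @ Sx
    b = Xty - Sx.T @ (c * Sy)
    beta = np.linalg.solve(A, b)
    rss = yty - float(np.sum(c * Sy**2)) - float(beta @ b)
    sigma2 = max(rss / N, 1e-300)
    logdet = float(np.sum(np.log1p(ni * theta)))
    nll = 0.5 * (N * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
    return nll, beta, sigma2


def fit_lmm(design: LongDesign, on_deficient: str = "drop") -> LMMFit:
    """Maximum-likelihood fit of the random-intercept model.

    Only rows with a finite response are used.  Rank-deficient designs are
    handled per ``on_deficient``: ``"drop"`` removes collinear columns
    (their coefficients are reported as NaN) with a warning, ``"error"``
    raises.
    """
    obs = design.observed
    X = design.X[obs]
    y = design.y[obs]
    groups = design.groups[obs]
    if X.shape[0] == 0:
        raise ValueError("no observed rows to fit")
    # re-densify group codes over observed subjects
    uniq, groups = np.unique(groups, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 subjects with observations")
    p_full = X.shape[1]
    keep = np.arange(p_full)
    # detect collinear columns via pivoted QR
    _, R, piv = _qr_pivot(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int(np.sum(diag > tol))
    if rank < p_full:
        if on_deficient == "error":
            raise np.linalg.LinAlgError("design is rank deficient")
        keep = np.sort(piv[:rank])
        dropped = tuple(design.columns[j] for j in piv[rank:])
        warnings.warn(f"dropping collinear design columns: {dropped}", stacklevel=2)
        X = X[:, keep]
    else:
        dropped = ()

    N = X.shape[0]
    stats_ = _suff_stats(X, y, groups, uniq.size)

    def nll(theta):
        return _profiled_nll(theta, *stats_, N)[0]

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, _THETA_MAX), method="bounded",
        options={"xatol": 1e-8},
    )
    theta = float(res.x)
    if nll(0.0) <= res.fun:  # boundary solution sigma_b = 0
        theta = 0.0
    nll_val, beta_kept, sigma2 = _profiled_nll(theta, *stats_, N)
    beta = np.full(p_full, np.nan)
    beta[keep] = beta_kept
    return LMMFit(
        beta=beta,
        sigma_b=float(np.sqrt(theta * sigma2)),
        sigma_e=float(np.sqrt(sigma2)),
        loglik=float(-nll_val),
        converged=bool(getattr(res, "success", True)),
        columns=design.columns,
        theta=theta,
        dropped=dropped,
    )


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def loglik_direct(design: LongDesign, beta, sigma_b, sigma_e) -> float:
    """Blockwise multivariate-normal log-density (independent oracle path).

    Evaluates the marginal Gaussian likelihood with covariance
    ``sigma_b^2 J + sigma_e^2 I`` per subject by explicit dense linear
    algebra; used to validate the profiled fitter.
    """
    obs = design.observed
    X, y, groups = design.X[obs], design.y[obs], design.groups[obs]
    ll = 0.0
    for g in np.unique(groups):
        rows = groups == g
        r = y[rows] - X[rows] @ np.asarray(beta)
        n = rows.sum()
        V = sigma_b**2 * np.ones((n, n)) + sigma_e**2 * np.eye(n)
        sign, logdet = np.linalg.slogdet(V)
        ll += -0.5 * (n * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r))
    return float(ll)


def conditional_intercept(fit: LMMFit, X_i, y_i):
    """BLUP of a subject's random intercept and its conditional variance.

    With n observed sessions the shrinkage factor is
    ``n sigma_b^2 / (n sigma_b^2 + sigma_e^2)`` applied to the mean
    residual; a subject with no observations gets the prior (0, sigma_b^2).
    """
    y_i = np.asarray(y_i, dtype=float)
    obs = np.isfinite(y_i)
    n = int(obs.sum())
    vb, ve = fit.sigma_b**2, fit.sigma_e**2
    if n == 0:
        return 0.0, vb
    beta = np.where(np.isfinite(fit.beta), fit.beta, 0.0)
    resid = y_i[obs] - np.asarray(X_i)[obs] @ beta
    denom = n * vb + ve
    if denom == 0:
        return 0.0, 0.0
    return float(n * vb / denom * resid.mean()), float(vb * ve / denom)


def simulate_from_fit(
    fit: LMMFit,
    design: LongDesign,
    rng: np.random.Generator,
    mode: str = "conditional",
) -> np.ndarray:
    """Simulate responses for every design row from a fitted model.

    ``marginal`` draws a fresh intercept per subject; ``conditional`` draws
    from each subject's posterior intercept given its observed rows (the
    default for imputation, as it preserves observed subject means).
    """
    if mode not in ("marginal", "conditional"):
        raise ValueError(f"unknown simulation mode: {mode!r}")
    beta = np.where(np.isfinite(fit.beta), fit.beta, 0.0)
    mean = design.X @ beta
    G = design.n_subjects()
    if mode == "marginal":
        b = rng.normal(0.0, fit.sigma_b, size=G)
    else:
        # vectorized BLUP: mu_g = vb * sum(resid_g) / (n_g vb + ve)
        vb, ve = fit.sigma_b**2, fit.sigma_e**2
        obs = design.observed
        resid = design.y[obs] - mean[obs]
        n_g = np.bincount(design.groups[obs], minlength=G).astype(float)
        s_g = np.bincount(design.groups[obs], weights=resid, minlength=G)
        denom = n_g * vb + ve
        safe = denom > 0
        mu = np.zeros(G)
        var = np.full(G, vb)
        mu[safe & (n_g > 0)] = (vb * s_g / np.where(safe, denom, 1.0))[safe & (n_g > 0)]
        var[safe] = (vb * ve / np.where(safe, denom, 1.0))[safe]
        b = rng.normal(mu, np.sqrt(var))
    return mean + b[design.groups] + rng.normal(0.0, fit.sigma_e, size=mean.size)
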