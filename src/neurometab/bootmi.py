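"""Bootstrap-with-multiple-imputation ("Boot MI") inference.

The resampling unit is the athlete: each bootstrap replicate draws n
subjects with replacement, carrying along *all* of a subject's sessions,
observed and missing alike.  Within each replicate the random-intercept
model is re-fitted to the replicate's observed rows, M complete datasets
are simulated from that fit, the estimator is applied to each and the M
estimates averaged into one point.  The B averaged points form an ordinary
bootstrap empirical distribution, summarized by percentile 95% CIs,
bootstrap ratios (mean / SD) and two-sided empirical p-values with
Benjamini-Hochberg FDR control over a declared family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from neurometab.lmm import DESIGN_COLUMNS, LMMFit, LongDesign, fit_lmm, simulate_from_fit


@dataclass(frozen=True)
class BootSummary:
    """One term's bootstrap distribution reduced to reportable numbers."""

    term: str
    point: float
    ci_low: float
    ci_high: float
    bsr: float
    p: float
    fdr_significant: bool = False


class LongitudinalData:
    """Subject-keyed long dataset for fast subject-level resampling.

    Wraps a :class:`~neurometab.lmm.LongDesign` with precomputed
    per-subject row indices so a bootstrap replicate is a single fancy
    index.  Missing responses stay as NaN rows; they travel with their
    subject.
    """

    def __init__(self, design: LongDesign):
        if design.X.shape[0] == 0:
            raise ValueError("empty dataset")
        self.design = design
        self.n_subjects = design.n_subjects()
        order = np.argsort(design.groups, kind="stable")
        bounds = np.searchsorted(design.groups[order], np.arange(self.n_subjects + 1))
        self._rows = [order[bounds[g]:bounds[g + 1]] for g in range(self.n_subjects)]

    def resample(self, rng: np.random.Generator) -> LongDesign:
        """Draw subjects with replacement; duplicates get distinct codes."""
        draw = rng.integers(0, self.n_subjects, size=self.n_subjects)
        rows = np.concatenate([self._rows[s] for s in draw])
        counts = np.array([self._rows[s].size for s in draw])
        groups = np.repeat(np.arange(self.n_subjects), counts)
        d = self.design
        return LongDesign(
            X=d.X[rows], y=d.y[rows], groups=groups,
            subject_ids=np.arange(self.n_subjects), columns=d.columns,
        )


def subject_bootstrap(data: LongitudinalData, B: int, rng: np.random.Generator):
    """Iterator over B subject-level bootstrap replicates."""
    for _ in range(B):
        yield data.resample(rng)


def _default_estimator(design: LongDesign) -> np.ndarray:
    return fit_lmm(design).beta


def boot_mi(
    data: LongitudinalData,
    B: int,
    M: int,
    rng: np.random.Generator,
    estimator=None,
    imputation_fit: LMMFit | None = None,
    imputation_mode: str = "conditional",
) -> np.ndarray:
    """Boot-MI empirical distribution of a coefficient estimator.

    Returns a (B, p) array of averaged point estimates.  By default the
    imputation model is re-fitted inside each replicate
    (``imputation_fit=None``); passing a fit freezes the full-data
    imputation model instead.  Replicates where the estimator fails are
    recorded as NaN and skipped, with a warning if more than 1% fail.
    """
    estimator = estimator or _default_estimator
    out = None
    n_failed = 0
    n_deficient = 0
    for b, design_b in enumerate(subject_bootstrap(data, B, rng)):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", UserWarning)
                if not np.all(design_b.observed):
                    fit_imp = imputation_fit or fit_lmm(design_b)
                    acc = None
                    for _ in range(M):
                        y_sim = simulate_from_fit(
                            fit_imp, design_b, rng, imputation_mode
                        )
                        completed = LongDesign(
                            X=design_b.X,
                            y=np.where(design_b.observed, design_b.y, y_sim),
                            groups=design_b.groups,
                            subject_ids=design_b.subject_ids,
                            columns=design_b.columns,
                        )
                        est = np.atleast_1d(
                            np.asarray(estimator(completed), dtype=float)
                        )
                        acc = est if acc is None else acc + est
                    point = acc / M
                else:
                    point = np.atleast_1d(
                        np.asarray(estimator(design_b), dtype=float)
                    )
            n_deficient += any("collinear" in str(w.message) for w in caught)
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
            point = None
        if out is None:
            p = len(point) if point is not None else len(DESIGN_COLUMNS)
            out = np.full((B, p), np.nan)
        if point is not None:
            out[b, : len(point)] = point
    if n_deficient:
        warnings.warn(
            f"{n_deficient}/{B} replicates had inestimable terms "
            "(collinear columns dropped; estimable terms retained)",
            stacklevel=2,
        )
    if n_failed > max(1, 0.01 * B):
        warnings.warn(f"{n_failed}/{B} bootstrap replicates failed", stacklevel=2)
    return out


def summarize(distribution, term: str = "") -> BootSummary:
    """Percentile CI, bootstrap ratio and empirical p for one coefficient.

    ``p = 2 * min(#{b* <= 0}, #{b* >= 0}) / B`` floored at ``1/(B+1)`` so
    BH never receives an exact zero.
    """
    d = np.asarray(distribution, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise ValueError("need >= 2 finite bootstrap estimates")
    B = d.size
    point = float(d.mean())
    lo, hi = np.percentile(d, [2.5, 97.5])
    sd = float(d.std(ddof=1))
    floor = 1.0 / (B + 1)
    if sd == 0:
        bsr = float(np.sign(point) * np.inf) if point != 0 else 0.0
        p = floor
    else:
        bsr = point / sd
        p = 2.0 * min(np.sum(d <= 0), np.sum(d >= 0)) / B
        p = float(min(max(p, floor), 1.0))
    return BootSummary(term=term, point=point, ci_low=float(lo), ci_high=float(hi),
                       bsr=float(bsr), p=p)


def fdr_adjust(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags over one family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def summarize_family(distributions: np.ndarray, terms, q: float = 0.05,
                     skip_first: bool = True) -> list[BootSummary]:
    """Summarize a (B, p) Boot-MI distribution with FDR over the family.

    ``skip_first`` excludes the intercept/reference column from the FDR
    family (it is not a concussion effect).
    """
    cols = list(range(distributions.shape[1]))
    summaries = [summarize(distributions[:, j], term=terms[j]) for j in cols]
    fam = cols[1:] if skip_first else cols
    flags = fdr_adjust([summaries[j].p for j in fam], q=q)
    out = []
    for j, s in enumerate(summaries):
        sig = bool(flags[fam.index(j)]) if j in fam else False
        out.append(BootSummary(s.term, s.point, s.ci_low, s.ci_high, s.bsr, s.p, sig))
    return out


def two_sample_boot(
    concussed: LongitudinalData,
    session: str,
    control_values,
    B: int,
    M: int,
    rng: np.random.Generator,
    imputation_mode: str = "conditional",
) -> np.ndarray:
    """Bootstrap distribution of mean(concussed at session) - mean(control).

    Both groups are resampled independently.  The concussed group carries
    its full longitudinal record so missing target-session values can be
    imputed from the within-replicate model fit (Boot MI); controls are a
    single cross-sectional sample.  HOC stratification is the caller's
    responsibility (pass a single-stratum dataset); the resulting constant
    HOC columns are dropped automatically during the imputation fit.
    """
    from neurometab.lmm import SESSIONS

    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r}")
    ctl = np.asarray(control_values, dtype=float)
    ctl = ctl[np.isfinite(ctl)]
    if ctl.size == 0:
        raise ValueError("empty control group")
    j = SESSIONS.index(session)
    target = (concussed.design.X[:, j] == 1.0) if j > 0 else (
        np.sum(concussed.design.X[:, 1:4], axis=1) == 0.0
    )
    if not np.any(target):
        raise ValueError(f"no rows at session {session!r}")
    out = np.full(B, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for b, design_b in enumerate(subject_bootstrap(concussed, B, rng)):
            on = (design_b.X[:, j] == 1.0) if j > 0 else (
                np.sum(design_b.X[:, 1:4], axis=1) == 0.0
            )
            ctl_b = ctl[rng.integers(0, ctl.size, size=ctl.size)]
            if np.all(design_b.observed[on]):
                conc_mean = float(design_b.y[on].mean())
            else:
                try:
                    fit_imp = fit_lmm(design_b)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                means = np.empty(M)
                for m in range(M):
                    y_sim = simulate_from_fit(fit_imp, design_b, rng, imputation_mode)
                    y_c = np.where(design_b.observed, design_b.y, y_sim)
                    means[m] = y_c[on].mean()
                conc_mean = float(means.mean())
            out[b] = conc_mean - float(ctl_b.mean())
    return out
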