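"""Biochemical-recurrence endpoint and prognostic-evaluation statistics.

Endpoint: biochemical recurrence (BCR) is a single post-operative PSA of
0.4 ng/mL or more; time to BCR runs from surgery to the first such
measurement, censored at the final PSA registration otherwise.

Statistics: Kaplan-Meier curves and Mantel-Cox log-rank tests, Cox
proportional-hazards fits (Efron tie handling, Wald tests; group Wald
chi-square for categorical covariates), Harrell's concordance index, ROC
AUC, and Pearson correlation. Interval estimates for the concordance index
and the AUC are bias-corrected and accelerated (BCa) bootstrap percentile
intervals, 10,000 resamples by default, resampling patients as units. The
difference between two c-indices computed on the same patients is tested by
a paired bootstrap: the two-sided p-value is one minus the confidence level
of the largest BCa interval that still excludes zero, located by bisection
on the level.

Kaplan-Meier and Cox machinery is delegated to lifelines; the concordance
index, the BCa construction and the difference test are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

BCR_THRESHOLD = 0.4  # ng/mL

__all__ = [
    "BCR_THRESHOLD", "Outcome", "derive_bcr", "km_curve", "logrank_test",
    "CoxResult", "cox_fit", "concordance_index", "ConcordanceResult",
    "harrell_cindex", "BcaInterval", "bca_ci", "CindexDifference",
    "cindex_difference_test", "roc_auc", "AucResult", "pearson_r",
]


# ---------------------------------------------------------------------------
# endpoint derivation


@dataclass(frozen=True)
class Outcome:
    """Time-to-BCR outcome: time in years from surgery, event indicator."""

    time: float
    event: bool

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("outcome time must be non-negative")


def _to_years(value, surgery) -> float:
    """Decimal years after surgery from a number, ISO date string, or date."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    if isinstance(value, str):
        value = datetime.fromisoformat(value).date()
    if isinstance(value, datetime):
        value = value.date()
    if isinstance(value, date):
        if surgery is None:
            raise ValueError("a surgery date is required to convert dates")
        if isinstance(surgery, str):
            surgery = datetime.fromisoformat(surgery).date()
        if isinstance(surgery, datetime):
            surgery = surgery.date()
        return (value - surgery).days / 365.25
    raise TypeError(f"cannot interpret time value {value!r}")


def derive_bcr(psa_times: Sequence, psa_values: Sequence[float],
               surgery_date=None, threshold: float = BCR_THRESHOLD) -> Outcome:
    """Derive the BCR outcome from a post-surgery PSA series.

    ``psa_times`` may be decimal years after surgery, or ISO-8601 dates with
    ``surgery_date`` supplied. The event falls at the first measurement with
    PSA >= threshold; otherwise the patient is censored at the final
    registration.
    """
    times = [_to_years(t, surgery_date) for t in psa_times]
    values = [float(v) for v in psa_values]
    if len(times) != len(values):
        raise ValueError("psa_times and psa_values must align")
    pairs = sorted((t, v) for t, v in zip(times, values) if t >= 0)
    if not pairs:
        raise ValueError("no post-surgery PSA measurements; "
                         "patient should have been excluded for missing follow-up")
    for t, v in pairs:
        if v >= threshold:
            return Outcome(time=t, event=True)
    return Outcome(time=pairs[-1][0], event=False)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def km_curve(times: Sequence[float], events: Sequence[bool],
             groups: Sequence | None = None) -> dict:
    """Product-limit survival curves per group.

    Returns {group: {"table": step DataFrame, "median": float}}; with no
    groups, a single entry keyed "all". Each table carries the time grid,
    survival probability, numbers at risk, events and censorings.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("survival curves need at least one subject (empty group)")
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
        names = {0: "all"}
    else:
        groups = np.asarray(groups)
        names = {g: g for g in pd.unique(groups)}
    out = {}
    for g, name in names.items():
        sel = groups == g
        if not sel.any():
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        tbl = kmf.event_table.copy()
        tbl["survival"] = kmf.survival_function_["KM_estimate"].reindex(
            tbl.index).values
        out[name] = {"table": tbl.reset_index(),
                     "median": float(kmf.median_survival_time_)}
    return out


def logrank_test(times, events, groups) -> tuple[float, float, int]:
    """Mantel-Cox log-rank test across k groups: (chi2, p, df = k - 1)."""
    from lifelines.statistics import multivariate_logrank_test

    groups = np.asarray(groups)
    k = len(pd.unique(groups))
    if k < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(np.asarray(times, dtype=float),
                                    groups, np.asarray(events, dtype=bool))
    return float(res.test_statistic), float(res.p_value), k - 1


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald inference.

    ``summary`` rows: covariate, hr, ci_low, ci_high, p (per-coefficient
    Wald). ``group_tests``: {covariate group: (chi2, df, p)} Wald tests that
    all coefficients of a categorical covariate are zero.
    """

    summary: pd.DataFrame
    group_tests: dict
    log_likelihood: float
    n: int
    n_events: int


def cox_fit(df: pd.DataFrame, duration_col: str, event_col: str,
            covariates: Sequence[str],
            categorical: dict[str, object] | None = None,
            alpha: float = 0.05) -> CoxResult:
    """Fit a Cox model (Efron ties) and report HRs, Wald CIs and p-values.

    ``categorical`` maps covariate name -> reference level; those columns
    are dummy-coded against the reference, and a group Wald chi-square over
    the dummy coefficients is reported per categorical covariate.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    categorical = categorical or {}
    data = df[[duration_col, event_col, *covariates]].copy()
    n_events = int(data[event_col].sum())
    design_cols: list[str] = []
    groups: dict[str, list[str]] = {}
    for cov in covariates:
        if cov in categorical:
            ref = categorical[cov]
            levels = [l for l in pd.unique(data[cov]) if l != ref]
            levels = sorted(levels, key=str)
            cols = []
            for lev in levels:
                col = f"{cov}[{lev}]"
                data[col] = (data[cov] == lev).astype(float)
                cols.append(col)
            data = data.drop(columns=[cov])
            design_cols += cols
            groups[cov] = cols
        else:
            data[cov] = pd.to_numeric(data[cov])
            design_cols.append(cov)
            groups[cov] = [cov]
    if n_events < len(design_cols):
        raise ValueError(
            f"{n_events} events cannot support {len(design_cols)} coefficients")
    cph = CoxPHFitter(alpha=alpha)
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge: {err}") from err

    summ = cph.summary
    rows = []
    for col in design_cols:
        rows.append({
            "covariate": col,
            "hr": float(summ.loc[col, "exp(coef)"]),
            "ci_low": float(summ.loc[col, f"exp(coef) lower {100 * (1 - alpha):g}%"]),
            "ci_high": float(summ.loc[col, f"exp(coef) upper {100 * (1 - alpha):g}%"]),
            "p": float(summ.loc[col, "p"]),
        })
    # group Wald chi-square: beta' V^-1 beta over each covariate's columns
    V = cph.variance_matrix_
    beta = cph.params_
    group_tests = {}
    for cov, cols in groups.items():
        b = beta.loc[cols].values
        v = V.loc[cols, cols].values
        chi2 = float(b @ np.linalg.solve(v, b))
        dfree = len(cols)
        group_tests[cov] = (chi2, dfree, float(sps.chi2.sf(chi2, dfree)))
    return CoxResult(summary=pd.DataFrame(rows), group_tests=group_tests,
                     log_likelihood=float(cph.log_likelihood_),
                     n=len(data), n_events=n_events)


# ---------------------------------------------------------------------------
# concordance index


def concordance_index(times, events, scores) -> float:
    """Harrell's c-index: concordant / (concordant + discordant) pairs.

    A pair is comparable when the subject with the shorter time had the
    event (the longer-lived subject's status is irrelevant); pairs with
    identical times are comparable only when exactly one subject had the
    event, who then counts as the earlier one. Ties in the risk score score
    0.5. Higher scores must indicate higher risk (shorter times).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    r = np.asarray(scores, dtype=float)
    if t.shape != e.shape or t.shape != r.shape:
        raise ValueError("times, events and scores must align")
    dt = t[:, None] - t[None, :]
    # i strictly earlier with event, or tied time with i event and j censored
    earlier = ((dt < 0) & e[:, None]) | ((dt == 0) & e[:, None] & ~e[None, :])
    dr = r[:, None] - r[None, :]
    concordant = np.sum(earlier & (dr > 0))
    tied = np.sum(earlier & (dr == 0))
    n_pairs = np.sum(earlier)
    if n_pairs == 0:
        raise ValueError("no comparable pairs (check events and times)")
    return float((concordant + 0.5 * tied) / n_pairs)


# ---------------------------------------------------------------------------
# BCa bootstrap


@dataclass
class BcaInterval:
    low: float
    high: float
    level: float
    estimate: float
    n_bootstraps: int
    degenerate: bool = False


class _BcaState:
    """Bootstrap distribution plus BCa correction terms, reusable at any level."""

    def __init__(self, statistic: Callable, data: tuple[np.ndarray, ...],
                 n_bootstraps: int, seed: int | None,
                 vectorized: bool = False):
        n = len(data[0])
        for col in data:
            if len(col) != n:
                raise ValueError("all data columns must align")
        rng = np.random.default_rng(seed)
        self.estimate = float(statistic(*data))
        idx = rng.integers(0, n, size=(n_bootstraps, n))
        if vectorized:
            # statistic accepts stacked (B, n) resamples, reducing axis -1
            boot = np.asarray(statistic(*(col[idx] for col in data)),
                              dtype=float)
        else:
            boot = np.empty(n_bootstraps)
            for b in range(n_bootstraps):
                boot[b] = statistic(*(col[idx[b]] for col in data))
        boot = boot[np.isfinite(boot)]
        if boot.size < max(10, n_bootstraps // 10):
            raise ValueError("too many degenerate bootstrap resamples")
        self.boot = np.sort(boot)
        self.n_bootstraps = n_bootstraps
        self.degenerate = bool(self.boot[0] == self.boot[-1])
        # bias correction from the bootstrap distribution's position
        if self.degenerate:
            self.z0, self.accel = 0.0, 0.0
        else:
            frac = ((np.sum(self.boot < self.estimate)
                     + 0.5 * np.sum(self.boot == self.estimate))
                    / self.boot.size)
            frac = min(max(frac, 1.0 / (2 * self.boot.size)),
                       1.0 - 1.0 / (2 * self.boot.size))
            self.z0 = float(sps.norm.ppf(frac))
            # acceleration from the jackknife
            if vectorized:
                # (n, n-1) leave-one-out index matrix
                jidx = np.array([np.r_[0:i, i + 1:n] for i in range(n)])
                jack = np.asarray(statistic(*(col[jidx] for col in data)),
                                  dtype=float)
            else:
                jack = np.empty(n)
                mask = np.ones(n, dtype=bool)
                for i in range(n):
                    mask[i] = False
                    jack[i] = statistic(*(col[mask] for col in data))
                    mask[i] = True
            jack = jack[np.isfinite(jack)]
            d = jack.mean() - jack
            denom = 6.0 * (np.sum(d ** 2) ** 1.5)
            self.accel = float(np.sum(d ** 3) / denom) if denom > 0 else 0.0

    def interval(self, level: float) -> BcaInterval:
        if not 0 < level < 1:
            raise ValueError("level must lie in (0, 1)")
        if self.degenerate:
            v = float(self.boot[0])
            return BcaInterval(v, v, level, self.estimate,
                               self.n_bootstraps, degenerate=True)
        alpha = 1.0 - level
        lo_hi = []
        for z_a in (sps.norm.ppf(alpha / 2), sps.norm.ppf(1 - alpha / 2)):
            num = self.z0 + z_a
            adj = sps.norm.cdf(self.z0 + num / (1.0 - self.accel * num))
            lo_hi.append(float(np.quantile(self.boot, adj)))
        return BcaInterval(lo_hi[0], lo_hi[1], level, self.estimate,
                           self.n_bootstraps)


def _as_columns(data) -> tuple[np.ndarray, ...]:
    if isinstance(data, tuple):
        return tuple(np.asarray(c) for c in data)
    return (np.asarray(data),)


def bca_ci(statistic: Callable, data, n_bootstraps: int = 10_000,
           level: float = 0.95, seed: int | None = None,
           vectorized: bool = False) -> BcaInterval:
    """BCa percentile interval for ``statistic`` over row resamples of ``data``.

    ``data`` is an array or a tuple of aligned arrays; ``statistic`` receives
    the resampled column(s) positionally. Bias correction z0 comes from the
    bootstrap distribution, acceleration from the jackknife. A degenerate
    bootstrap distribution (all resample values equal) collapses to a point
    interval flagged ``degenerate``. With ``vectorized`` the statistic must
    accept stacked resamples of shape (..., n) and reduce its last axis
    (e.g. ``lambda x: x.mean(axis=-1)``), which removes the Python loop.
    """
    if n_bootstraps < 100:
        raise ValueError("n_bootstraps must be at least 100")
    state = _BcaState(statistic, _as_columns(data), n_bootstraps, seed,
                      vectorized=vectorized)
    return state.interval(level)


# ---------------------------------------------------------------------------
# concordance with CI, difference test, AUC, Pearson


@dataclass
class ConcordanceResult:
    cindex: float
    ci_low: float
    ci_high: float
    level: float
    n_bootstraps: int
    seed: int | None


def harrell_cindex(times, events, scores, n_bootstraps: int = 10_000,
                   level: float = 0.95, seed: int | None = None,
                   with_ci: bool = True) -> ConcordanceResult:
    """Harrell's c-index with a BCa bootstrap CI (patients as resampling unit)."""
    c = concordance_index(times, events, scores)
    if not with_ci:
        return ConcordanceResult(c, math.nan, math.nan, level, 0, seed)

    def stat(t, e, r):
        try:
            return concordance_index(t, e, r)
        except ValueError:
            return math.nan

    iv = bca_ci(stat, (np.asarray(times, float), np.asarray(events, bool),
                       np.asarray(scores, float)),
                n_bootstraps=n_bootstraps, level=level, seed=seed)
    return ConcordanceResult(c, iv.low, iv.high, level, n_bootstraps, seed)


@dataclass
class CindexDifference:
    delta: float
    ci_low: float
    ci_high: float
    p: float
    n_bootstraps: int
    seed: int | None


def cindex_difference_test(times, events, scores_a, scores_b,
                           n_bootstraps: int = 10_000,
                           seed: int | None = None,
                           tol: float = 1e-4) -> CindexDifference:
    """Paired-bootstrap test of c-index(A) - c-index(B) on the same subjects.

    The two-sided p-value is 1 minus the largest BCa confidence level whose
    interval excludes 0, found by bisection on the level to ``tol``
    precision; by construction p < 0.05 iff the 95% BCa interval excludes 0.
    Identical scores short-circuit to delta = 0, p = 1.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if np.array_equal(a, b):
        return CindexDifference(0.0, 0.0, 0.0, 1.0, 0, seed)

    def stat(tt, ee, aa, bb):
        try:
            return concordance_index(tt, ee, aa) - concordance_index(tt, ee, bb)
        except ValueError:
            return math.nan

    state = _BcaState(stat, (t, e, a, b), n_bootstraps, seed)
    iv95 = state.interval(0.95)

    def excludes_zero(level: float) -> bool:
        iv = state.interval(level)
        return iv.low > 0.0 or iv.high < 0.0

    lo, hi = tol, 1.0 - tol
    if not excludes_zero(lo):
        p = 1.0
    elif excludes_zero(hi):
        p = tol
    else:
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if excludes_zero(mid):
                lo = mid
            else:
                hi = mid
        p = 1.0 - lo
    return CindexDifference(state.estimate, iv95.low, iv95.high, float(p),
                            n_bootstraps, seed)


@dataclass
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    level: float
    n_bootstraps: int
    seed: int | None


def roc_auc(truth, scores, n_bootstraps: int = 10_000, level: float = 0.95,
            seed: int | None = None, with_ci: bool = True) -> AucResult:
    """ROC AUC of continuous scores against a binary truth, with BCa CI.

    Bootstrap resamples that lose one of the two classes contribute no
    value (they are dropped from the bootstrap distribution).
    """
    from sklearn.metrics import roc_auc_score

    y = np.asarray(truth).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for AUC")
    auc = float(roc_auc_score(y, s))
    if not with_ci:
        return AucResult(auc, math.nan, math.nan, level, 0, seed)

    def stat(yy, ss):
        if len(np.unique(yy)) < 2:
            return math.nan
        return roc_auc_score(yy, ss)

    iv = bca_ci(stat, (y, s), n_bootstraps=n_bootstraps, level=level,
                seed=seed)
    return AucResult(auc, iv.low, iv.high, level, n_bootstraps, seed)


def pearson_r(x, y, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=level)
    return float(res.statistic), (float(ci.low), float(ci.high))
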