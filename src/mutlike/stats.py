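"""Stratification and survival statistics.

Isoform-ratio stratification (dNp73/TAp73, dNp73/TP53), qPCR 2^-ddCt
quantification, Kaplan-Meier / log-rank / Cox proportional-hazards survival
analysis (months; Efron tie handling), Fisher-z confidence intervals for
Pearson correlations, and Benjamini-Hochberg adjustment.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import IsoformTable

log = logging.getLogger("mutlike")


class StatsError(ValueError):
    pass


def isoform_ratio(
    table: IsoformTable, numerator: str = "dNp73", denominator: str = "TAp73"
) -> pd.Series:
    """Per-sample expression ratio (e.g. dNp73/TAp73), on linear scale only.

    Samples with a zero denominator are excluded with a warning; an all-zero
    denominator is an error.
    """
    if table.scale != "linear":
        raise StatsError(
            f"isoform ratios require linear-scale expression, got {table.scale!r}"
        )
    num = table.table[numerator].astype(float)
    den = table.table[denominator].astype(float)
    zero = den == 0
    if zero.all():
        raise StatsError(f"all {denominator!r} values are zero; no ratio defined")
    if zero.any():
        log.warning(
            "isoform_ratio: excluding %d sample(s) with zero %s: %s",
            int(zero.sum()),
            denominator,
            list(table.table.index[zero])[:5],
        )
    ratio = num[~zero] / den[~zero]
    ratio.name = f"{numerator}/{denominator}"
    return ratio


def ddct_relative_expression(
    ct_target, ct_housekeeping, ct_target_ref, ct_housekeeping_ref
):
    """Relative qPCR expression 2^-ddCt versus housekeeping gene and reference.

    ddCt = (Ct_target - Ct_housekeeping) - (Ct_target_ref - Ct_housekeeping_ref).
    """
    args = [np.asarray(a, dtype=float) for a in
            (ct_target, ct_housekeeping, ct_target_ref, ct_housekeeping_ref)]
    if any(not np.all(np.isfinite(a)) for a in args):
        raise StatsError("Ct values must be finite")
    ddct = (args[0] - args[1]) - (args[2] - args[3])
    out = np.power(2.0, -ddct)
    return float(out) if out.ndim == 0 else out


def dichotomize(values: pd.Series, method: str = "median", cutpoint: float | None = None):
    """Split samples into high/low strata.

    Methods: 'median' (default; ties at the cutpoint go low), 'quartile'
    (upper quartile = high) and 'fixed' (explicit cutpoint). Returns
    (strata Series of 'high'/'low', cutpoint, method).
    """
    vals = values.dropna().astype(float)
    if len(vals) < 4:
        raise StatsError("dichotomization needs >= 4 defined values")
    if vals.nunique() == 1 and method != "fixed":
        raise StatsError("all values identical; no data-driven split exists")
    if method == "median":
        cut = float(np.median(vals))
    elif method == "quartile":
        cut = float(np.percentile(vals, 75))
    elif method == "fixed":
        if cutpoint is None:
            raise StatsError("method='fixed' requires a cutpoint")
        cut = float(cutpoint)
    else:
        raise StatsError(f"unknown dichotomization method {method!r}")
    strata = pd.Series(np.where(vals > cut, "high", "low"), index=vals.index, name="stratum")
    if (strata == "high").sum() == 0 or (strata == "low").sum() == 0:
        log.warning("dichotomize: one stratum is empty at cutpoint %g", cut)
    return strata, cut, method


@dataclass
class KMCurve:
    """Product-limit survival estimate with Greenwood variance."""

    times: np.ndarray       # distinct event times (ascending)
    at_risk: np.ndarray     # risk-set size just before each event time
    n_events: np.ndarray
    survival: np.ndarray    # S(t) at each event time
    variance: np.ndarray    # Greenwood variance of S(t)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate; censored subjects leave the risk set after t."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise StatsError("empty survival input")
    if np.any(times < 0):
        raise StatsError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    t = ev.index.to_numpy(dtype=float)
    d = ev["observed"].to_numpy(dtype=float)
    n = ev["at_risk"].to_numpy(dtype=float)
    surv = np.array([kmf.predict(x) for x in t], dtype=float)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
    var = surv**2 * np.cumsum(terms)
    var = np.where(np.isfinite(var), var, 0.0)  # S=0 after last event: variance 0
    return KMCurve(times=t, at_risk=n, n_events=d, survival=surv, variance=var)


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


def logrank_test_groups(times, events, groups) -> LogRankResult:
    """Log-rank chi-square over >= 2 groups (df = groups - 1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise StatsError("log-rank test needs >= 2 groups")
    for g in labels:
        if (groups == g).sum() == 0:
            raise StatsError(f"group {g!r} is empty")
    if events.sum() == 0:
        raise StatsError("log-rank test needs >= 1 event")
    res = multivariate_logrank_test(times, groups, events)
    return LogRankResult(
        statistic=float(res.test_statistic), df=int(len(labels) - 1), p=float(res.p_value)
    )


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald 95% CIs."""

    table: pd.DataFrame  # index: covariate; columns: coef, hr, ci_low, ci_high, p
    converged: bool
    n: int
    n_events: int


def cox_ph(times, events, covariates: pd.DataFrame) -> CoxResult:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    Raises a diagnostic error on constant covariates or non-convergence
    (e.g. monotone likelihood under perfect separation).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    if len(times) < 2:
        raise StatsError("Cox regression needs >= 2 samples")
    const = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if const:
        raise StatsError(f"covariate(s) constant across samples: {const}")
    if events.sum() < covariates.shape[1]:
        raise StatsError("fewer events than covariates; model unidentifiable")
    df = covariates.copy()
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as e:
        raise StatsError(f"Cox partial likelihood did not converge: {e}") from e
    s = cph.summary
    table = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": np.exp(s["coef"]),
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return CoxResult(
        table=table, converged=True, n=int(len(times)), n_events=int(events.sum())
    )


@dataclass
class CorrelationCI:
    r: float
    n: int
    lower: float
    upper: float
    p: float
    level: float


def pearson_ci(r: float, n: int, level: float = 0.95) -> CorrelationCI:
    """Fisher-z confidence interval and t-test p for a Pearson correlation.

    Bounds: tanh(atanh(r) +/- z_level / sqrt(n - 3)); p from
    t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom (two-sided).
    """
    if not -1 < r < 1:
        raise StatsError("|r| must be < 1 for the Fisher-z interval")
    if n < 4:
        raise StatsError("Fisher-z interval needs n >= 4")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = sps.norm.ppf(0.5 + level / 2.0)
    lower, upper = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationCI(r=r, n=n, lower=float(lower), upper=float(upper), p=float(p), level=level)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
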