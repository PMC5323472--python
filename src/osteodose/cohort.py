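"""Cohort-level statistics: correlations, response metrics, survival.

Implements the statistical toolkit for a dose–response survival study:
Pearson correlation on log-transformed skewed covariates, maximum
biomarker decline from baseline, Kaplan–Meier curves with log-rank tests
and hazard ratios, multivariable Cox proportional-hazards regression
(Efron tie handling), Fisher's exact test on ≥50 % biomarker-decline
proportions, and baseline group comparisons (t or Mann–Whitney).

Survival machinery is delegated to lifelines; scipy provides the exact
tests.  All confidence intervals are 95 % and all p-values two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "CorrelationResult",
    "KMGroupResult",
    "CoxResult",
    "pearson_log",
    "max_change_from_baseline",
    "km_logrank",
    "cox_multivariable",
    "dichotomize",
    "fisher_response_test",
    "baseline_comparison",
]

CONFIDENCE = 0.95


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int

    def summary(self) -> str:
        return (
            f"r = {self.r:.3f} (95 % CI {self.ci_low:.3f} to {self.ci_high:.3f}), "
            f"P = {self.p_value:.3g}, n = {self.n}"
        )


def pearson_log(x, y) -> CorrelationResult:
    """Pearson correlation of (ln x, y) with a Fisher-z confidence interval.

    For right-skewed covariates such as disease volume or ALP the natural
    log restores approximate normality before the linear correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.any(x <= 0):
        raise ValueError("x must be > 0 for the log transform")
    lx = np.log(x)
    if np.ptp(lx) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(lx, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(x.size - 3)
    zcrit = stats.norm.ppf(0.5 + CONFIDENCE / 2.0)
    return CorrelationResult(
        r=float(r),
        p_value=float(p),
        ci_low=float(np.tanh(z - zcrit * se)),
        ci_high=float(np.tanh(z + zcrit * se)),
        n=int(x.size),
    )


def max_change_from_baseline(values) -> float:
    """Maximum fractional decline of a serial biomarker.

    (baseline − nadir) / baseline, where the nadir is the minimum of the
    post-baseline values; negative results mean the marker never fell
    below baseline.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need a baseline plus at least one follow-up value")
    baseline = values[0]
    if not np.isfinite(baseline) or baseline <= 0:
        raise ValueError("baseline must be positive and present")
    return float((baseline - np.min(values[1:])) / baseline)


@dataclass
class KMGroupResult:
    """Two-group Kaplan–Meier comparison."""

    groups: tuple[str, str]
    curves: dict  # group -> DataFrame(time, survival, at_risk)
    median_os: dict  # group -> float (months), NaN if not reached
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float  # second group vs first
    hr_ci: tuple[float, float]
    hr_defined: bool = True

    def summary(self) -> str:
        g0, g1 = self.groups
        hr = f"{self.hazard_ratio:.2f} (95 % CI {self.hr_ci[0]:.2f}-{self.hr_ci[1]:.2f})" if self.hr_defined else "undefined"
        return (
            f"median OS: {g0} = {self.median_os[g0]:.1f}, {g1} = {self.median_os[g1]:.1f} months; "
            f"log-rank P = {self.logrank_p:.3g}; HR ({g1} vs {g0}) = {hr}"
        )


def km_logrank(
    records: pd.DataFrame,
    group_col: str,
    time_col: str = "survival_months",
    event_col: str = "event",
) -> KMGroupResult:
    """Kaplan–Meier curves, median OS, log-rank test and HR for two groups.

    The hazard ratio comes from a single-covariate proportional-hazards
    fit (second group label relative to the first, labels sorted).  A
    group with zero events leaves the HR flagged undefined.
    """
    labels = sorted(records[group_col].unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    curves, medians, events = {}, {}, {}
    for lab in labels:
        sub = records[records[group_col] == lab]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(lab))
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(),
                "survival": sf.iloc[:, 0].to_numpy(),
                "at_risk": kmf.event_table["at_risk"].reindex(sf.index).to_numpy(),
            }
        )
        medians[lab] = float(kmf.median_survival_time_)
        events[lab] = int(sub[event_col].sum())
    a = records[records[group_col] == labels[0]]
    b = records[records[group_col] == labels[1]]
    lr = logrank_test(a[time_col], b[time_col], a[event_col], b[event_col])
    hr, ci, defined = float("nan"), (float("nan"), float("nan")), False
    if min(events.values()) >= 1:
        df = records[[time_col, event_col]].copy()
        df["group_indicator"] = (records[group_col] == labels[1]).astype(float)
        cph = CoxPHFitter()
        cph.fit(df, duration_col=time_col, event_col=event_col)
        coef = float(cph.params_["group_indicator"])
        se = float(cph.standard_errors_["group_indicator"])
        zcrit = stats.norm.ppf(0.5 + CONFIDENCE / 2.0)
        hr = float(np.exp(coef))
        ci = (float(np.exp(coef - zcrit * se)), float(np.exp(coef + zcrit * se)))
        defined = True
    else:
        warnings.warn("a group has zero events; hazard ratio undefined")
    return KMGroupResult(
        groups=(str(labels[0]), str(labels[1])),
        curves={str(k): v for k, v in curves.items()},
        median_os={str(k): v for k, v in medians.items()},
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hazard_ratio=hr,
        hr_ci=ci,
        hr_defined=defined,
    )


@dataclass
class CoxResult:
    """Multivariable Cox proportional-hazards fit."""

    covariates: list[str]
    coefficients: pd.Series
    standard_errors: pd.Series
    hazard_ratios: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    n: int
    n_events: int
    warnings_: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "HR": self.hazard_ratios,
                "HR 95% low": self.ci_low,
                "HR 95% high": self.ci_high,
                "p": self.p_values,
            }
        )


def cox_multivariable(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "survival_months",
    event_col: str = "event",
) -> CoxResult:
    """Multivariable Cox regression (Efron handling of tied event times).

    Warns when events < 5 × covariates; a rank-deficient design (e.g. a
    duplicated covariate) raises with a diagnostic.
    """
    warns: list[str] = []
    n_events = int(records[event_col].sum())
    if n_events < 5 * len(covariates):
        msg = f"only {n_events} events for {len(covariates)} covariates (< 5 per covariate)"
        warnings.warn(msg)
        warns.append(msg)
    design = records[covariates].astype(float)
    rank = np.linalg.matrix_rank(design - design.mean(axis=0))
    if rank < len(covariates):
        raise ValueError(
            f"rank-deficient design: rank {rank} < {len(covariates)} covariates "
            "(collinear or duplicated columns)"
        )
    df = records[[time_col, event_col] + covariates].copy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # convergence failure diagnostics
        raise RuntimeError(f"Cox partial-likelihood maximisation failed: {exc}") from exc
    zcrit = stats.norm.ppf(0.5 + CONFIDENCE / 2.0)
    coef = cph.params_[covariates]
    se = cph.standard_errors_[covariates]
    return CoxResult(
        covariates=covariates,
        coefficients=coef,
        standard_errors=se,
        hazard_ratios=np.exp(coef),
        ci_low=np.exp(coef - zcrit * se),
        ci_high=np.exp(coef + zcrit * se),
        p_values=cph.summary.loc[covariates, "p"],
        n=len(df),
        n_events=n_events,
        warnings_=warns,
    )


def dichotomize(
    records: pd.DataFrame, variable: str, rule: str = "median", cutpoint: float | None = None
) -> pd.Series:
    """Split a cohort at the median (data-oriented) or a fixed cut-point
    (outcome-oriented, e.g. 3.5 GBq administered activity).

    Values equal to the cut go to "below" — the deterministic tie rule.
    """
    values = records[variable].astype(float)
    if values.isna().any():
        raise ValueError(f"{variable} missing for some records")
    if values.nunique() == 1:
        raise ValueError(f"cannot dichotomize {variable}: all values identical")
    if rule == "median":
        cut = float(values.median())
    elif rule == "fixed_cutpoint":
        if cutpoint is None:
            raise ValueError("fixed_cutpoint rule needs a cutpoint")
        cut = float(cutpoint)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    labels = pd.Series(np.where(values > cut, "above", "below"), index=records.index)
    if labels.nunique() == 1:
        raise ValueError(f"degenerate split of {variable} at {cut}")
    return labels


def fisher_response_test(table_2x2) -> float:
    """Two-sided Fisher exact p for a 2×2 response table (e.g. ≥50 %
    biomarker decline by dose group)."""
    table = np.asarray(table_2x2)
    if table.shape != (2, 2) or np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("need a 2x2 table of non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("Fisher test undefined: empty margin")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def baseline_comparison(
    records: pd.DataFrame,
    variable: str,
    group: pd.Series,
    normality_alpha: float = 0.05,
    force_method: str | None = None,
) -> tuple[float, str]:
    """Two-sided between-group comparison of one baseline characteristic.

    Welch's t-test when both groups pass a Shapiro–Wilk normality check,
    otherwise the Mann–Whitney U test (exact for small samples);
    ``force_method`` ("t-test" or "mann-whitney") overrides the normality
    dispatch.  Returns (p, method).
    """
    values = records[variable].astype(float)
    labels = sorted(group.unique())
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    a = values[group == labels[0]].to_numpy()
    b = values[group == labels[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if force_method is not None:
        if force_method not in ("t-test", "mann-whitney"):
            raise ValueError(f"unknown method {force_method!r}")
        normal = force_method == "t-test"
    else:
        normal = True
        for sample in (a, b):
            if len(sample) >= 3 and np.ptp(sample) > 0:
                if stats.shapiro(sample).pvalue < normality_alpha:
                    normal = False
            else:
                normal = False
    if normal:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        method = "t-test"
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        method = "mann-whitney"
    return p, method
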