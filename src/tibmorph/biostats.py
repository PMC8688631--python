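"""The statistical toolkit used by the morphometric study.

Reliability is summarized with ICC(2,1) — two-way random effects, absolute
agreement, single measurement — computed from the two-way ANOVA mean squares.
Side symmetry uses paired t-tests, gender differences independent (pooled
variance) t-tests, relationships Pearson correlation and ordinary least
squares.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError
from .morphometry import PARAMETER_NAMES

__all__ = [
    "IccResult",
    "TTestResult",
    "RegressionResult",
    "icc",
    "paired_t",
    "independent_t",
    "t_from_summary",
    "pearson_r",
    "linreg",
    "population_stats",
    "format_p",
]


@dataclass
class IccResult:
    icc: float
    model: str
    n_subjects: int
    n_raters: int


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float


@dataclass
class RegressionResult:
    intercept: float
    slope: float
    r: float


def icc(ratings) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``ratings`` is a complete subjects x raters matrix.  With row (subject),
    column (rater) and error mean squares MSR, MSC, MSE from the two-way
    ANOVA::

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an (n>=2, k>=2) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must be complete (no missing values)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    if ss_total <= 0:
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedStatisticError("degenerate ANOVA decomposition")
    return IccResult(
        icc=float((msr - mse) / denom),
        model="two-way random, absolute agreement, single measurement",
        n_subjects=n,
        n_raters=k,
    )


def _t_result(t: float, df: float, mean_diff: float) -> TTestResult:
    if np.isnan(t):
        raise UndefinedStatisticError("t statistic undefined")
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p, mean_diff=float(mean_diff))


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t-test; zero-variance differences use the conventions
    p = 1 for a zero mean difference and p = 0 otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired samples must be equal-length 1D, n >= 2")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    n = len(d)
    if sd == 0:
        if md == 0:
            return TTestResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0)
        return TTestResult(t=np.inf if md > 0 else -np.inf, df=n - 1, p=0.0,
                           mean_diff=md)
    return _t_result(md / (sd / np.sqrt(n)), n - 1, md)


def independent_t(x, y, equal_var: bool = True) -> TTestResult:
    """Two-sample t-test: Student (pooled variance) by default, Welch otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) < 2 or len(y) < 2:
        raise ValueError("each sample must be 1D with n >= 2")
    md = float(x.mean() - y.mean())
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        df = len(x) + len(y) - 2
        if md == 0:
            return TTestResult(t=0.0, df=df, p=1.0, mean_diff=0.0)
        return TTestResult(t=np.inf if md > 0 else -np.inf, df=df, p=0.0,
                           mean_diff=md)
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue), mean_diff=md)


def t_from_summary(m1, sd1, n1, m2, sd2, n2) -> TTestResult:
    """Pooled-variance two-sample t from summary statistics alone."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("summary SDs must be positive")
    res = stats.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    return TTestResult(t=float(res.statistic), df=float(n1 + n2 - 2),
                       p=float(res.pvalue), mean_diff=float(m1 - m2))


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def linreg(x, y) -> RegressionResult:
    """Ordinary least squares y = intercept + slope * x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0:
        raise UndefinedStatisticError("constant x; regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(intercept=float(res.intercept),
                            slope=float(res.slope), r=float(res.rvalue))


def format_p(p: float, threshold: float = 1e-4) -> str:
    """Report-style p-value formatting ("< 0.0001" below the threshold)."""
    return f"< {threshold:g}" if p < threshold else f"{p:.4g}"


def population_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Tidy side-symmetry and gender-comparison tests for a population table.

    For every parameter: a paired t between right and left sides (matched by
    subject) and an independent t between genders (right side used so
    observations are independent).  Columns: parameter, test, statistic, df, p.
    """
    rows = []
    wide = records.pivot_table(
        index=["subject_id", "gender"], columns="side",
        values=list(PARAMETER_NAMES), aggfunc="first",
    )
    for param in PARAMETER_NAMES:
        if ("right" in records["side"].values) and ("left" in records["side"].values):
            r = wide[(param, "right")].dropna()
            l = wide[(param, "left")].dropna()
            common = r.index.intersection(l.index)
            if len(common) >= 2:
                res = paired_t(r.loc[common].to_numpy(), l.loc[common].to_numpy())
                rows.append(
                    dict(parameter=param, test="paired_side",
                         statistic=res.t, df=res.df, p=res.p)
                )
        one_side = records[records["side"] == "right"] \
            if "right" in records["side"].values else records
        m = one_side.loc[one_side["gender"] == "male", param].to_numpy()
        f = one_side.loc[one_side["gender"] == "female", param].to_numpy()
        if len(m) >= 2 and len(f) >= 2:
            res = independent_t(m, f)
            rows.append(
                dict(parameter=param, test="independent_gender",
                     statistic=res.t, df=res.df, p=res.p)
            )
    return pd.DataFrame(rows, columns=["parameter", "test", "statistic", "df", "p"])
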