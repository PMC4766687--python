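"""Measurement-error statistics for paired-CT migration studies.

Implements the error framework used to validate marker-based migration
measurement: summary statistics with t confidence intervals, the
Bland-Altman repeatability limit for paired repeated trials, an accuracy
index against a known true value, a balanced two-way fixed-effects ANOVA
over trial and tube-voltage factors, and numeric normality diagnostics.

Conventions
-----------
* Repeatability limit: ``1.96 * sqrt(2) * s_w`` with the within-subject SD
  ``s_w = sqrt(sum d_i^2 / (2 n))`` from paired differences
  ``d_i = trial1_i - trial2_i``.  Under a normal error model the absolute
  difference of two repeated measurements stays below this limit with 95%
  probability, for any error SD.
* Accuracy: ``(1.96 / sqrt(2)) * sqrt(bias^2 + SD^2)`` with
  ``bias = mean - true``.  The plain ``1.96 * RMSE`` variant is available
  via ``variant="rmse"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "SummaryStats",
    "summarize",
    "repeatability_limit",
    "accuracy",
    "accuracy_from_moments",
    "two_way_anova",
    "one_way_anova",
    "normality_diagnostics",
    "DOF_VARIABLES",
]

#: The six analysis variables: rotations (degrees) then translations (mm).
DOF_VARIABLES = ("rx", "ry", "rz", "tx", "ty", "tz")


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    median: float
    min: float
    max: float
    sd: float
    ci_lower: float
    ci_upper: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "median": self.median,
            "min": self.min,
            "max": self.max,
            "sd": self.sd,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
        }


def summarize(values, confidence: float = 0.95) -> SummaryStats:
    """Mean, median, range, SD and Student-t CI of the mean.

    The t interval is used rather than z because some groups are small
    (seven patients); at n = 105 the two are indistinguishable after
    rounding.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 values to summarize, got {n}")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(scipy.stats.t.ppf(0.5 + confidence / 2, n - 1) * sd / np.sqrt(n))
    return SummaryStats(
        n=n,
        mean=mean,
        median=float(np.median(x)),
        min=float(x.min()),
        max=float(x.max()),
        sd=sd,
        ci_lower=mean - half,
        ci_upper=mean + half,
    )


def repeatability_limit(trial1, trial2) -> float:
    """95% repeatability limit of paired repeated measurements.

    ``r = 1.96 * sqrt(2) * s_w`` with ``s_w = sqrt(sum d^2 / (2 n))``;
    equivalently ``1.96 * RMS(d)`` since ``sqrt(2) * s_w = RMS(d)``.
    Inputs must be paired by study, in the same order.
    """
    a = np.asarray(trial1, dtype=float).ravel()
    b = np.asarray(trial2, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(
            f"trials must be paired: got lengths {a.size} and {b.size}"
        )
    if a.size < 1:
        raise ValueError("need at least one pair")
    d = a - b
    s_w = np.sqrt(np.sum(d**2) / (2 * d.size))
    return float(1.96 * np.sqrt(2.0) * s_w)


def accuracy(values, true_value: float = 0.0, variant: str = "ci") -> float:
    """Accuracy of measurements against a known true value.

    ``variant="ci"`` (default): ``(1.96 / sqrt(2)) * sqrt(bias^2 + SD^2)``,
    a one-sided-style 95% distance index combining systematic and random
    error.  ``variant="rmse"``: ``1.96 * sqrt(bias^2 + SD^2)``.  SD uses
    the n-1 denominator.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    bias = float(x.mean()) - true_value
    sd = float(x.std(ddof=1))
    return accuracy_from_moments(bias, sd, variant=variant)


def accuracy_from_moments(bias: float, sd: float, variant: str = "ci") -> float:
    """Accuracy index from a known bias and SD (see :func:`accuracy`).

    Useful when only summary statistics of the measurement groups are
    available.
    """
    if sd < 0:
        raise ValueError("SD must be non-negative")
    root = float(np.hypot(bias, sd))
    if variant == "ci":
        return 1.96 / np.sqrt(2.0) * root
    if variant == "rmse":
        return 1.96 * root
    raise ValueError(f"unknown accuracy variant {variant!r}")


def _check_balanced(df: pd.DataFrame, factors) -> None:
    counts = df.groupby(list(factors), observed=True).size()
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: cell counts "
            f"{sorted(counts.unique().tolist())} across {factors}"
        )


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "trial",
    factor_b: str = "kvp",
) -> pd.DataFrame:
    """Balanced fixed-effects two-way ANOVA with interaction.

    ``data`` is tidy: one row per observation with the response column and
    two categorical factor columns.  Returns the standard table (df, SS,
    MS, F, p) for both main effects, the interaction and the residual.
    Raises on unbalanced layouts, where the type-I/II distinction would
    matter.
    """
    for col in (response, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in data")
    _check_balanced(data, (factor_a, factor_b))
    df = data[[response, factor_a, factor_b]].copy()
    df[factor_a] = df[factor_a].astype(str)
    df[factor_b] = df[factor_b].astype(str)
    model = smf.ols(
        f"Q('{response}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = [factor_a, factor_b, f"{factor_a}:{factor_b}", "residual"]
    table = table.rename(
        columns={"sum_sq": "SS", "df": "df", "F": "F", "PR(>F)": "p"}
    )
    table["MS"] = table["SS"] / table["df"]
    return table[["df", "SS", "MS", "F", "p"]]


def one_way_anova(data: pd.DataFrame, response: str, group: str) -> pd.DataFrame:
    """One-way between-group decomposition, for the between-study view."""
    for col in (response, group):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in data")
    df = data[[response, group]].copy()
    df[group] = df[group].astype(str)
    model = smf.ols(f"Q('{response}') ~ C(Q('{group}'))", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table.index = [group, "residual"]
    table = table.rename(columns={"sum_sq": "SS", "PR(>F)": "p"})
    table["MS"] = table["SS"] / table["df"]
    return table[["df", "SS", "MS", "F", "p"]]


def normality_diagnostics(values, n_quantiles: int = 21) -> dict:
    """Numeric stand-ins for the usual normality plots.

    Returns sample skewness, excess kurtosis, the Shapiro-Wilk statistic
    and p-value, and a quantile table pairing sample quantiles with the
    matching standard-normal quantiles (the numbers behind a Q-Q plot).
    A constant sample is reported with ``degenerate=True`` and no test.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 8:
        raise ValueError(f"need at least 8 values, got {x.size}")
    if np.ptp(x) == 0:
        return {
            "degenerate": True,
            "skewness": 0.0,
            "excess_kurtosis": float("nan"),
            "shapiro_w": float("nan"),
            "shapiro_p": float("nan"),
            "quantiles": None,
        }
    probs = np.linspace(0, 1, n_quantiles + 2)[1:-1]
    qq = pd.DataFrame(
        {
            "prob": probs,
            "sample_quantile": np.quantile(x, probs),
            "normal_quantile": scipy.stats.norm.ppf(probs, loc=x.mean(), scale=x.std(ddof=1)),
        }
    )
    # Shapiro-Wilk is calibrated for n <= 5000; subsample deterministically
    # above that (evenly spaced order statistics).
    xs = np.sort(x)
    if xs.size > 5000:
        xs = xs[np.linspace(0, xs.size - 1, 5000).astype(int)]
    w, p = scipy.stats.shapiro(xs)
    return {
        "degenerate": False,
        "skewness": float(scipy.stats.skew(x, bias=False)),
        "excess_kurtosis": float(scipy.stats.kurtosis(x, bias=False)),
        "shapiro_w": float(w),
        "shapiro_p": float(p),
        "quantiles": qq,
    }
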