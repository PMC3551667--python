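"""Univariate statistical battery for the identity/arousal analyses.

Fisher's omnibus combination of p-values is the multiple-testing gatekeeper
throughout: k p-values are combined as X = -2 * sum(ln p) ~ chi-square with
2k degrees of freedom under the joint null. Per-parameter tests are
standard one-way ANOVA, dependent/independent t-tests, Pearson correlation
and Wilcoxon signed-rank; classification accuracies are compared against
chance with exact binomial tail tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import PARAMETER_COLUMNS


@dataclass(frozen=True)
class TestResult:
    """A single test: statistic, degrees of freedom, p-value, sample size."""

    statistic: float
    p: float
    df: float | tuple[float, float] | None = None
    n: int | None = None
    tail: str = "two"
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of range: {self.p}")


def fisher_omnibus(pvals) -> TestResult:
    """Combine p-values: X = -2*sum(ln p), chi-square upper tail on 2k df."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1] (ln diverges at 0)")
    stat = -2.0 * float(np.log(p).sum())
    df = 2 * p.size
    return TestResult(statistic=stat, p=float(sps.chi2.sf(stat, df)), df=df,
                      n=p.size)


def paired_t(x, y) -> TestResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired test needs equal-length samples, n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TestResult(0.0, 1.0, df=x.size - 1, n=x.size,
                              note="zero differences")
        return TestResult(np.nan, np.nan, df=x.size - 1, n=x.size,
                          note="zero variance of differences")
    t, p = sps.ttest_rel(x, y)
    return TestResult(float(t), float(p), df=x.size - 1, n=x.size)


def independent_t(x, y, equal_var: bool = True) -> TestResult:
    """Independent-samples t (pooled variance by default; Welch optional)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("independent test needs n >= 2 per group")
    if np.allclose(np.concatenate([x - x.mean(), y - y.mean()]), 0.0):
        same = np.isclose(x.mean(), y.mean())
        return TestResult(0.0 if same else np.nan, 1.0 if same else np.nan,
                          df=x.size + y.size - 2, n=x.size + y.size,
                          note="zero variance")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    df = (x.size + y.size - 2) if equal_var else None
    return TestResult(float(t), float(p), df=df, n=x.size + y.size)


def pearson(x, y) -> TestResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlation needs equal-length samples, n >= 3")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        return TestResult(np.nan, np.nan, n=x.size, note="zero variance")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), df=x.size - 2, n=x.size)


def wilcoxon_signed(x, y=None) -> TestResult:
    """Wilcoxon signed-rank test (zero differences handled by Pratt's
    method; exact null distribution for n <= 25 without ties)."""
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    if d.size < 1:
        raise ValueError("empty sample")
    if np.allclose(d, 0.0):
        return TestResult(0.0, 1.0, n=d.size, note="all differences zero")
    res = sps.wilcoxon(d, zero_method="pratt", mode="auto")
    return TestResult(float(res.statistic), float(res.pvalue), n=d.size)


def binomial_above_chance(k_correct: int, n_trials: int, p_chance: float
                          ) -> TestResult:
    """Exact one-sided binomial tail: P(X >= k) for X ~ Bin(n, p_chance)."""
    if not (0 <= k_correct <= n_trials):
        raise ValueError("need 0 <= k_correct <= n_trials")
    if not (0.0 < p_chance < 1.0):
        raise ValueError("p_chance must lie in (0, 1)")
    p = float(sps.binom.sf(k_correct - 1, n_trials, p_chance))
    return TestResult(float(k_correct), min(p, 1.0), n=n_trials, tail="one")


def anova_per_parameter(ft: pd.DataFrame, group: str,
                        parameters: list[str] | None = None
                        ) -> tuple[pd.DataFrame, TestResult | None]:
    """One-way fixed-effects ANOVA per acoustic parameter, plus the Fisher
    omnibus combination of the per-parameter p-values.

    Rows with missing values are excluded listwise per parameter; constant
    columns are flagged (NaN statistic) and excluded from the combination.
    """
    parameters = parameters if parameters is not None else [
        c for c in PARAMETER_COLUMNS if c in ft.columns
    ]
    if ft[group].nunique() < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    rows = []
    for col in parameters:
        sub = ft[[group, col]].dropna()
        groups = [g[col].to_numpy() for _, g in sub.groupby(group, sort=True)]
        groups = [g for g in groups if g.size > 0]
        n = int(sum(g.size for g in groups))
        pooled = np.concatenate(groups) if groups else np.array([])
        if len(groups) < 2 or n - len(groups) < 1 or np.allclose(
                pooled.std(), 0.0):
            rows.append({"parameter": col, "F": np.nan, "df_between": np.nan,
                         "df_within": np.nan, "p": np.nan, "n": n,
                         "note": "constant or insufficient"})
            continue
        f, p = sps.f_oneway(*groups)
        if not np.isfinite(f):
            rows.append({"parameter": col, "F": np.nan, "df_between": np.nan,
                         "df_within": np.nan, "p": np.nan, "n": n,
                         "note": "degenerate"})
            continue
        rows.append({
            "parameter": col, "F": float(f),
            "df_between": len(groups) - 1, "df_within": n - len(groups),
            "p": float(p), "n": n, "note": "",
        })
    table = pd.DataFrame(rows)
    valid_p = table["p"].dropna()
    valid_p = valid_p[valid_p > 0.0]
    omnibus = fisher_omnibus(valid_p) if len(valid_p) else None
    return table, omnibus
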