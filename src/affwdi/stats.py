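"""Univariate and multivariable statistics for two-group clinical cohorts.

Covers the toolkit used for baseline ("Table-1 style") comparisons of a good
versus poor prognosis group: Pearson chi-square on 2x2 contingency tables
(no continuity correction), the two-sample pooled-variance t-test computed
from summary statistics alone, and multivariable logistic regression with
Wald statistics, odds ratios and 95% confidence intervals, with an optional
forward-stepwise entry mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["TwoByTwoTable", "GroupSummary", "LogisticFit", "chi_square",
           "pooled_t_test", "logistic_multivariable"]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts of a 2x2 table; rows = prognosis group, columns = factor level."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard deviation and size of one group of a continuous variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class LogisticFit:
    """Per-variable logistic regression summary (Wald inference)."""

    variable: str
    beta: float
    se: float
    wald_chi2: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float


def chi_square(table: TwoByTwoTable) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, 1 df.

    Returns ``(statistic, p_value)``.  Raises on a zero marginal, where the
    expected counts are undefined.
    """
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("a zero row or column marginal leaves expected "
                         "counts undefined")
    expected = np.outer(row, col) / obs.sum()
    stat = float(np.sum((obs - expected) ** 2 / expected))
    return stat, float(sps.chi2.sf(stat, df=1))


def pooled_t_test(g1: GroupSummary, g2: GroupSummary) -> tuple[float, float]:
    """Two-sample pooled-variance t-test from group summaries.

    Returns ``(t, p_value)`` with ``n1 + n2 - 2`` degrees of freedom.
    """
    res = sps.ttest_ind_from_stats(g1.mean, g1.sd, g1.n,
                                   g2.mean, g2.sd, g2.n, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def _check_design(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("design matrix contains missing or non-finite values")
    rank = np.linalg.matrix_rank(mat - mat.mean(axis=0))
    if rank < mat.shape[1]:
        # name the columns involved in the collinearity
        bad = []
        cols = list(X.columns)
        kept: list[int] = []
        centered = mat - mat.mean(axis=0)
        for j in range(mat.shape[1]):
            trial = centered[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(cols[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> sm.Logit:
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    design = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.Logit(y, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(disp=0, method="newton", tol=1e-8, maxiter=100)
    except PerfectSeparationWarning:
        raise ValueError(
            "complete separation: a predictor perfectly splits the outcome, "
            "so the maximum-likelihood coefficient diverges") from None
    if not res.mle_retvals.get("converged", True) or \
            np.any(np.abs(res.params.to_numpy()) > 30):
        raise ValueError(
            "logistic fit did not converge (possible complete separation); "
            "inspect the predictors for a variable that perfectly splits "
            "the outcome")
    return res


def logistic_multivariable(cohort: pd.DataFrame, variables: Sequence[str],
                           outcome: str = "outcome",
                           stepwise: bool = False,
                           entry_p: float = 0.05) -> list[LogisticFit]:
    """Maximum-likelihood multivariable logistic regression.

    Fits the binary ``outcome`` on ``variables`` by Newton/IRLS (tolerance
    1e-8, at most 100 iterations) and reports, per variable, the coefficient,
    its standard error, the Wald chi-square ``(beta/se)^2``, the p-value, the
    odds ratio ``exp(beta)`` and the 95% CI ``exp(beta +/- 1.96 se)``.

    With ``stepwise=True``, variables enter forward-stepwise: at each round
    the candidate with the smallest Wald p-value below ``entry_p`` joins the
    model, until no candidate qualifies.
    """
    y = cohort[outcome].to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X_all = cohort[list(variables)]
    _check_design(X_all)

    if stepwise:
        selected: list[str] = []
        remaining = list(variables)
        while remaining:
            best_var, best_p = None, entry_p
            for var in remaining:
                res = _fit_logit(y, X_all[selected + [var]])
                p = float(res.pvalues[var])
                if p < best_p:
                    best_var, best_p = var, p
            if best_var is None:
                break
            selected.append(best_var)
            remaining.remove(best_var)
        if not selected:
            raise ValueError(f"no variable met the entry criterion p < {entry_p}")
        fit_vars = selected
    else:
        fit_vars = list(variables)

    res = _fit_logit(y, X_all[fit_vars])
    out = []
    for var in fit_vars:
        beta = float(res.params[var])
        se = float(res.bse[var])
        out.append(LogisticFit(
            variable=var, beta=beta, se=se,
            wald_chi2=(beta / se) ** 2,
            p_value=float(sps.chi2.sf((beta / se) ** 2, df=1)),
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.96 * se)),
            ci_high=float(np.exp(beta + 1.96 * se)),
        ))
    return out
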