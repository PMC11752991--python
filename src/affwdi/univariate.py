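"""Univariate group-comparison tables from a counts/summary file.

The input is a long-format CSV with columns ``variable, kind, level, good,
poor``.  Categorical variables contribute two ``count`` rows (one per level)
and are compared with the Pearson chi-square test; continuous variables
contribute ``mean``, ``sd`` and ``n`` rows and are compared with the pooled
two-sample t-test.  A copy of the reference cohort's published summary
(good prognosis n = 207 vs poor prognosis n = 96) ships with the package
and doubles as the default configuration of the synthetic cohort generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import GroupSummary, TwoByTwoTable, chi_square, pooled_t_test

__all__ = ["reference_counts_path", "load_counts", "univariate_table"]

_COLUMNS = ["variable", "kind", "level", "good", "poor"]


def reference_counts_path() -> str:
    """Path of the packaged reference cohort summary."""
    return str(resources.files("affwdi.data") / "reference_counts.csv")


def load_counts(path: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path if path is not None else reference_counts_path())
    if df.empty:
        raise ValueError("counts file is empty")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts file lacks required column(s): {missing}")
    return df


def univariate_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-variable test statistic and p-value.

    Returns a frame with columns ``variable, test, statistic, p_value``;
    ``test`` is ``chi2`` for categorical rows and ``t`` for continuous ones.
    Variable order follows first appearance; permuting input rows of a
    variable does not change its statistic.
    """
    rows = []
    for variable in counts["variable"].drop_duplicates():
        sub = counts[counts["variable"] == variable]
        kinds = set(sub["kind"])
        if kinds == {"count"}:
            if len(sub) != 2:
                raise ValueError(f"{variable}: expected exactly two count "
                                 f"levels, got {len(sub)}")
            sub = sub.sort_values("level", kind="stable")
            (g0, p0), (g1, p1) = sub[["good", "poor"]].to_numpy(int)
            stat, p = chi_square(TwoByTwoTable(a=g0, b=g1, c=p0, d=p1))
            rows.append({"variable": variable, "test": "chi2",
                         "statistic": stat, "p_value": p})
        elif kinds == {"mean", "sd", "n"}:
            by = sub.set_index("kind")
            g = GroupSummary(mean=float(by.loc["mean", "good"]),
                             sd=float(by.loc["sd", "good"]),
                             n=int(by.loc["n", "good"]))
            q = GroupSummary(mean=float(by.loc["mean", "poor"]),
                             sd=float(by.loc["sd", "poor"]),
                             n=int(by.loc["n", "poor"]))
            t, p = pooled_t_test(g, q)
            rows.append({"variable": variable, "test": "t",
                         "statistic": t, "p_value": p})
        else:
            raise ValueError(f"{variable}: unrecognized row kinds {sorted(kinds)}")
    return pd.DataFrame(rows)
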