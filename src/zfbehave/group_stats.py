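"""Two-group comparison ladder and direction-coded significance matrices.

Each endpoint is compared between two independent groups: Shapiro-Wilk
normality on each group, Levene's test for equal variances, then a pooled
Student's t, a Welch t, or a Mann-Whitney U with normal approximation,
two-tailed throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["GroupComparison", "compare_groups", "significance_matrix",
           "compare_table"]


@dataclass
class GroupComparison:
    endpoint: str
    n_a: int
    n_b: int
    test: str                   # "student_t" | "welch_t" | "mann_whitney"
    statistic: float
    p: float                    # two-tailed
    df: Optional[float]         # None for Mann-Whitney
    direction: str              # "increase" | "decrease" | "none"
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def _is_constant(x: np.ndarray) -> bool:
    return np.ptp(x) == 0


def compare_groups(a: Sequence[float], b: Sequence[float],
                   alpha: float = 0.05, endpoint: str = "endpoint") -> GroupComparison:
    """Adaptive two-group test.

    Both groups normal by Shapiro-Wilk (at ``alpha``): Student's t pooled
    if Levene's test passes, Welch's t otherwise.  Any non-normal group:
    Mann-Whitney U (asymptotic, tie-corrected).  Direction refers to group
    ``a`` relative to ``b``; ``significant`` means p < alpha, two-tailed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")

    if _is_constant(a) and _is_constant(b) and a[0] == b[0]:
        # degenerate equal-constant case: no evidence of any difference
        return GroupComparison(endpoint, a.size, b.size, "student_t",
                               0.0, 1.0, float(a.size + b.size - 2),
                               "none", False)

    parametric = True
    for sample in (a, b):
        if _is_constant(sample):
            logger.warning("constant sample: normality undefined; "
                           "falling back to Mann-Whitney")
            parametric = False
            break
        if stats.shapiro(sample).pvalue <= alpha:
            parametric = False
            break

    if parametric:
        # classic Levene (mean-centred), matching common statistical suites
        lev = stats.levene(a, b, center="mean")
        if lev.pvalue > alpha:
            res = stats.ttest_ind(a, b, equal_var=True)
            test = "student_t"
            df = float(a.size + b.size - 2)
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            test = "welch_t"
            df = float(res.df)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # exact-with-ties warnings
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic")
        test = "mann_whitney"
        statistic, p = float(res.statistic), float(res.pvalue)
        df = None

    if np.isnan(p):
        p, statistic = 1.0, 0.0

    diff = float(np.mean(a) - np.mean(b))
    direction = "none" if diff == 0 else ("increase" if diff > 0 else "decrease")
    return GroupComparison(endpoint=endpoint, n_a=a.size, n_b=b.size,
                           test=test, statistic=statistic, p=p, df=df,
                           direction=direction, significant=bool(p < alpha))


def compare_table(df: pd.DataFrame, group_a: str, group_b: str,
                  alpha: float = 0.05,
                  by: Sequence[str] = ("endpoint",)) -> pd.DataFrame:
    """Run compare_groups for every endpoint (x optional extra keys).

    ``df`` is tidy: columns group, value, plus the ``by`` keys
    (e.g. endpoint and age_dpf).
    """
    rows = []
    for keys, sub in df.groupby(list(by)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        a = sub.loc[sub["group"] == group_a, "value"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "value"].to_numpy()
        if a.size < 3 or b.size < 3:
            logger.warning("skipping %s: fewer than 3 observations per group", keys)
            continue
        c = compare_groups(a, b, alpha=alpha, endpoint=str(keys[0]))
        row = dict(zip(by, keys))
        row.update({"n_a": c.n_a, "n_b": c.n_b, "test": c.test,
                    "statistic": c.statistic, "p": c.p, "df": c.df,
                    "direction": c.direction, "significant": c.significant})
        rows.append(row)
    return pd.DataFrame(rows)


def significance_matrix(comparisons: pd.DataFrame, index: str = "endpoint",
                        columns: Optional[str] = None) -> pd.DataFrame:
    """Direction-coded matrix: '+' significant increase, '-' significant
    decrease, '.' otherwise."""

    def symbol(row) -> str:
        if not row["significant"] or row["direction"] == "none":
            return "."
        return "+" if row["direction"] == "increase" else "-"

    df = comparisons.copy()
    df["symbol"] = df.apply(symbol, axis=1)
    if columns is None:
        return df.set_index(index)[["symbol"]]
    return df.pivot(index=index, columns=columns, values="symbol").fillna(".")
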