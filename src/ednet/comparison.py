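"""Between-subtype comparisons: two-tailed t-tests with Bonferroni correction.

Works either from raw subject-level data or from published summary statistics
(mean, SD, n per group).  Welch's unequal-variance variant is the default —
the reference sample has unequal group sizes (57 restricting vs 27
binge-purging) and visibly unequal variances — with Student's pooled test
available.  ``REFERENCE_GROUP_SUMMARY`` carries the published demographic and
clinical summary table of that sample (20 variables) so the comparison can be
reproduced exactly from the printed numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SubscaleMatrix

__all__ = [
    "REFERENCE_GROUP_SUMMARY",
    "t_test_from_summary",
    "bonferroni",
    "compare_groups",
    "compare_from_summary",
]

#: variable -> ((mean, sd, n) restricting, (mean, sd, n) binge-purging)
REFERENCE_GROUP_SUMMARY = {
    "Age": ((26.33, 8.19, 57), (28.76, 10.09, 27)),
    "BMI": ((16.77, 1.87, 57), (17.24, 1.78, 27)),
    "AgeAtOnset": ((17.48, 4.92, 57), (17.64, 4.95, 27)),
    "IllnessDuration": ((8.22, 7.94, 57), (8.73, 8.75, 27)),
    "IDEA_Total": ((1.98, 1.10, 57), (2.34, 0.97, 27)),
    "GEO": ((1.84, 1.07, 57), (1.85, 0.99, 27)),
    "OM": ((2.22, 1.36, 57), (2.73, 1.05, 27)),
    "EB": ((1.73, 1.29, 57), (2.38, 1.07, 27)),
    "S": ((2.23, 1.33, 57), (2.66, 1.03, 27)),
    "IN": ((11.35, 8.65, 57), (15.00, 8.18, 27)),
    "MF": ((10.11, 6.37, 57), (10.54, 7.47, 27)),
    "SI": ((8.60, 4.52, 57), (9.38, 4.21, 27)),
    "BD": ((12.61, 8.10, 57), (15.27, 7.39, 27)),
    "P": ((6.93, 5.04, 57), (7.65, 4.45, 27)),
    "ID": ((8.00, 5.11, 57), (8.04, 4.62, 27)),
    "I": ((7.25, 6.83, 57), (9.96, 8.35, 27)),
    "DT": ((11.61, 8.08, 57), (14.81, 6.30, 27)),
    "BU": ((1.30, 2.38, 57), (7.35, 6.51, 27)),
    "IA": ((11.25, 8.09, 57), (16.00, 8.01, 27)),
    "ASC": ((6.75, 4.92, 57), (9.38, 6.86, 27)),
}


def t_test_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "welch",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics; returns (t, df, p).

    ``variant='welch'`` uses the unequal-variance statistic with
    Welch-Satterthwaite degrees of freedom; ``'student'`` pools variances
    with df = n1 + n2 - 2.  p is two-tailed.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both groups have zero variance")
    v1, v2 = sd1**2, sd2**2
    if variant == "welch":
        se2 = v1 / n1 + v2 / n2
        t = (mean1 - mean2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    elif variant == "student":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        raise ValueError("variant must be 'welch' or 'student'")
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bonferroni(pvalues) -> np.ndarray:
    """Bonferroni adjustment: each p multiplied by the family size, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def _comparison_table(rows: list[dict], alpha: float) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bonferroni(df["p_raw"].to_numpy())
    df["significant"] = df["p_adjusted"] < alpha
    return df


def compare_groups(
    data: SubscaleMatrix,
    variables: list[str] | None = None,
    variant: str = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable two-tailed t-tests between the two groups in ``data``.

    Bonferroni correction uses the number of variables actually tested as the
    family size.  Requires exactly two group levels with n >= 2 each.
    """
    if data.group is None:
        raise ValueError("data carries no group labels")
    levels = sorted(set(data.group))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}: {levels}")
    g1, g2 = levels
    m1 = data.group == g1
    m2 = data.group == g2
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs n >= 2")
    variables = list(variables) if variables is not None else list(data.node_labels)
    rows = []
    for var in variables:
        x1 = data.column(var)[m1]
        x2 = data.column(var)[m2]
        t, df, p = t_test_from_summary(
            x1.mean(), x1.std(ddof=1), x1.size, x2.mean(), x2.std(ddof=1), x2.size,
            variant=variant,
        )
        rows.append(
            {
                "variable": var,
                f"mean_{g1}": x1.mean(),
                f"mean_{g2}": x2.mean(),
                "t": t,
                "df": df,
                "p_raw": p,
            }
        )
    return _comparison_table(rows, alpha)


def compare_from_summary(
    summary: dict | None = None, variant: str = "welch", alpha: float = 0.05
) -> pd.DataFrame:
    """Run the comparison from a summary table (defaults to the reference one)."""
    summary = summary if summary is not None else REFERENCE_GROUP_SUMMARY
    rows = []
    for var, ((mu1, sd1, n1), (mu2, sd2, n2)) in summary.items():
        t, df, p = t_test_from_summary(mu1, sd1, n1, mu2, sd2, n2, variant=variant)
        rows.append({"variable": var, "t": t, "df": df, "p_raw": p})
    return _comparison_table(rows, alpha)
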