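"""Group-comparison reporting.

Descriptive statistics are mean ± SEM; hypothesis tests are delegated to
scipy/statsmodels (two-group t or rank tests, one-way ANOVA with Tukey
post hoc) — the package's contribution is the measures feeding them, not
the tests themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupReport", "compare_groups"]


@dataclass
class GroupReport:
    """Descriptive statistics and a delegated hypothesis test."""

    design: str
    groups: dict  # name -> {'n', 'mean', 'sem'}
    test_name: str
    statistic: float
    p_value: float
    df: float | None = None
    posthoc: list = field(default_factory=list)  # (a, b, meandiff, p_adj)


def _describe(values: np.ndarray) -> dict:
    return {
        "n": int(len(values)),
        "mean": float(np.mean(values)),
        "sem": float(sps.sem(values)) if len(values) > 1 else float("nan"),
    }


def compare_groups(
    data: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    design: str = "unpaired_t",
) -> GroupReport:
    """Compare ≥2 groups of a measure.

    ``design`` selects the delegated test: ``unpaired_t``, ``paired_t``,
    ``mann_whitney`` (two groups) or ``anova_tukey`` (any number of groups;
    one-way ANOVA with Tukey post hoc).

    Raises
    ------
    ValueError
        With fewer than 2 groups, a group of n < 2, or a two-group design
        applied to more groups.
    """
    names = list(dict.fromkeys(data[group_col]))
    samples = {g: data.loc[data[group_col] == g, value_col].to_numpy(dtype=float) for g in names}
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n={len(v)} < 2")

    groups = {g: _describe(v) for g, v in samples.items()}
    posthoc: list = []
    df: float | None = None

    if design in ("unpaired_t", "paired_t", "mann_whitney"):
        if len(names) != 2:
            raise ValueError(f"{design} requires exactly 2 groups, got {len(names)}")
        a, b = (samples[g] for g in names)
        if design == "unpaired_t":
            res = sps.ttest_ind(a, b)
            df = float(len(a) + len(b) - 2)
            test_name = "Student's t (unpaired)"
        elif design == "paired_t":
            res = sps.ttest_rel(a, b)
            df = float(len(a) - 1)
            test_name = "Student's t (paired)"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            test_name = "Mann-Whitney U"
        statistic, p = float(res.statistic), float(res.pvalue)
    elif design == "anova_tukey":
        res = sps.f_oneway(*samples.values())
        statistic, p = float(res.statistic), float(res.pvalue)
        k, n = len(names), sum(len(v) for v in samples.values())
        df = float(n - k)
        test_name = "one-way ANOVA"
        tuk = sps.tukey_hsd(*samples.values())
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                posthoc.append(
                    (
                        names[i],
                        names[j],
                        float(np.mean(samples[names[i]]) - np.mean(samples[names[j]])),
                        float(tuk.pvalue[i, j]),
                    )
                )
    else:
        raise ValueError(f"unknown design {design!r}")

    return GroupReport(
        design=design,
        groups=groups,
        test_name=test_name,
        statistic=statistic,
        p_value=p,
        df=df,
        posthoc=posthoc,
    )
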