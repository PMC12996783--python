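"""Composition percentages, binomial margins of error, and group tests.

Covers the descriptive and inferential statistics the quantification
pipeline reports: percent-of-sum normalisation of lipid panels (every
species expressed relative to the total response of its sample, and
relative to its class total), the margin of error on phenotype
frequencies, and the two-group / multi-group tests with SEM reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FrequencyRecord",
    "lipid_percentages",
    "binomial_moe",
    "group_tests",
    "significance_stars",
]

#: significance-star convention: thresholds for *, **, ***, ****
STAR_LEVELS = (0.05, 0.01, 0.001, 0.0001)


def significance_stars(p: float) -> str:
    return "*" * sum(p < a for a in STAR_LEVELS) or "n.s."


@dataclass(frozen=True)
class FrequencyRecord:
    """A phenotype frequency with its margin of error (both proportions)."""

    label: str
    k: int
    n: int
    p_hat: float
    moe: float
    confidence: float
    method: str


def lipid_percentages(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Percent-of-sum normalisation of a long lipid table.

    Parameters
    ----------
    table
        Long table with columns sample_id, group, class, species, response.

    Returns
    -------
    dict with three frames:

    ``class_percent``
        per sample: 100 x (class response sum) / (sample total response);
        each sample's class percentages sum to 100.
    ``species_percent_of_class``
        per sample and species: 100 x species response / class sum.
    ``group_summary``
        per group and class: mean class percentage ± SEM over samples.
    """
    if (table["response"] < 0).any():
        bad = table.loc[table["response"] < 0, "sample_id"].iloc[0]
        raise ValueError(f"negative response in sample {bad!r}")
    totals = table.groupby("sample_id")["response"].sum()
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has no positive response")

    df = table.copy()
    df["sample_total"] = df["sample_id"].map(totals)
    class_sums = (
        df.groupby(["sample_id", "group", "class"], as_index=False)["response"].sum()
    )
    class_sums["percent"] = 100.0 * class_sums["response"] / class_sums["sample_id"].map(totals)

    cls_totals = class_sums.set_index(["sample_id", "class"])["response"]
    df["class_total"] = [
        cls_totals[(s, c)] for s, c in zip(df["sample_id"], df["class"])
    ]
    df["percent_of_class"] = np.where(
        df["class_total"] > 0, 100.0 * df["response"] / df["class_total"], 0.0
    )

    group_summary = (
        class_sums.groupby(["group", "class"])["percent"]
        .agg(mean_percent="mean", sem_percent=stats.sem, n="size")
        .reset_index()
    )
    return {
        "class_percent": class_sums[["sample_id", "group", "class", "percent"]],
        "species_percent_of_class": df[
            ["sample_id", "group", "class", "species", "percent_of_class"]
        ],
        "group_summary": group_summary,
    }


def binomial_moe(
    k: int,
    n: int,
    confidence: float = 0.95,
    label: str = "",
    method: str = "wald",
) -> FrequencyRecord:
    """Margin of error (half-width) of a binomial proportion interval.

    Default is the Wald margin z * sqrt(p(1-p)/n).  The Wald margin
    degenerates to 0 at p in {0, 1}; the Wilson half-width is available via
    ``method="wilson"``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = k / n
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    if method == "wald":
        moe = z * np.sqrt(p * (1 - p) / n)
    elif method == "wilson":
        denom = 1 + z**2 / n
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        moe = half
    else:
        raise ValueError("method must be 'wald' or 'wilson'")
    return FrequencyRecord(label, k, n, p, float(moe), confidence, method)


def group_tests(samples: pd.DataFrame, value: str = "value", group: str = "group") -> pd.DataFrame:
    """Two-group Welch t test or one-way ANOVA, with per-group SEM.

    Two groups are compared with a two-tailed Welch (unequal-variance)
    t test; three or more with a one-way ANOVA.  Every group needs at
    least two samples.  Returns a one-row table with the statistic, the
    two-tailed p value, per-group mean ± SEM, and significance stars.
    """
    groups = {g: sub[value].to_numpy(float) for g, sub in samples.groupby(group)}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    names = sorted(groups)
    arrays = [groups[g] for g in names]
    if len(arrays) == 2:
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        test, statistic, p = "welch_t", float(res.statistic), float(res.pvalue)
    else:
        res = stats.f_oneway(*arrays)
        test, statistic, p = "anova_f", float(res.statistic), float(res.pvalue)
    row = {"test": test, "statistic": statistic, "p_value": p, "stars": significance_stars(p)}
    for g in names:
        v = groups[g]
        row[f"mean_{g}"] = float(v.mean())
        row[f"sem_{g}"] = float(stats.sem(v))
        row[f"n_{g}"] = int(v.size)
    return pd.DataFrame([row])
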